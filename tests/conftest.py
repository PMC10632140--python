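import numpy as np
import pytest

import gliosynapse as gs


@pytest.fixture(scope="session")
def small_expression():
    """A compact planted-state matrix shared by expression-level tests."""
    spec = gs.SyntheticExpressionSpec(
        n_cells=150,
        n_genes=400,
        signature_effect=2.0,
        dropout_rate=0.05,
        target_gene_correlations={f"CORR_{i:02d}": 0.6 for i in range(5)},
        seed=11,
    )
    matrix, truth = gs.generate_expression(spec)
    return spec, matrix, truth


@pytest.fixture(scope="session")
def default_field():
    """One rendered punctum field and its full pipeline result (reused: the
    rolling-ball step dominates runtime)."""
    spec = gs.SyntheticImageSpec(seed=3)
    field, truth = gs.generate_puncta_image(spec)
    result = gs.puncta_pipeline(field)
    return spec, field, truth, result


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
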