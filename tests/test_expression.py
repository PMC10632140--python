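"""Expression transform, gene filtering, signature scoring and state assignment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hst

import gliosynapse as gs
from gliosynapse.expression import inverse_transform


def make_matrix(values, is_log=False, samples=None):
    values = np.asarray(values, float)
    g, c = values.shape
    meta = None
    if samples is not None:
        meta = pd.DataFrame(
            {"sample": samples, "malignant": True},
            index=[f"c{i}" for i in range(c)],
        )
    return gs.ExpressionMatrix(
        values=values,
        gene_ids=[f"g{i}" for i in range(g)],
        cell_ids=[f"c{i}" for i in range(c)],
        cell_meta=meta,
        is_log=is_log,
    )


class TestTransform:
    @pytest.mark.parametrize("tpm,expected", [(0, 0), (10, 1), (30, 2)])
    def test_log_values(self, tpm, expected):
        m = gs.transform_expression(make_matrix([[tpm]]))
        assert m.values[0, 0] == pytest.approx(expected, abs=1e-12)

    def test_refuses_double_transform(self):
        m = gs.transform_expression(make_matrix([[10.0]]))
        with pytest.raises(ValueError, match="already"):
            gs.transform_expression(m)

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            make_matrix([[-1.0]])

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            gs.ExpressionMatrix(
                values=np.ones((2, 1)), gene_ids=["g", "g"], cell_ids=["c"]
            )

    @given(
        hst.lists(hst.floats(0, 1e6, allow_nan=False), min_size=1, max_size=30)
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_roundtrip_with_generator_inverse(self, tpms):
        logv = np.log2(np.array(tpms) / 10 + 1)
        back = inverse_transform(logv)
        assert np.allclose(back, tpms, rtol=1e-9, atol=1e-9)


class TestFilterAnalysable:
    def test_all_zero_gene_excluded_constant_one_included(self):
        # gene0 all-zero (log value 0), gene1 constant at 1.0 log2 units
        logm = make_matrix([[0, 0], [1.0, 1.0]], is_log=True)
        assert gs.filter_analysable_genes(logm) == ["g1"]

    def test_threshold_is_strict(self):
        logm = make_matrix([[0.25, 0.25], [0.2500001, 0.2500001]], is_log=True)
        assert gs.filter_analysable_genes(logm, min_mean=0.25) == ["g1"]

    def test_mean_over_malignant_cells_only(self):
        logm = make_matrix([[1.0, 0.0]], is_log=True)
        logm.cell_meta["malignant"] = [True, False]
        assert gs.filter_analysable_genes(logm) == ["g0"]

    def test_no_cells_errors(self):
        logm = make_matrix([[1.0]], is_log=True)
        logm.cell_meta["malignant"] = [False]
        with pytest.raises(ValueError, match="no cells"):
            gs.filter_analysable_genes(logm)


def oracle_score(values, gene_ids, sig_genes, n_bins):
    """Direct per-cell recomputation of the bin-matched-control score."""
    means = values.mean(axis=1)
    centred = values - means[:, None]
    order = np.argsort(means, kind="stable")
    bins = [list(b) for b in np.array_split(order, n_bins) if len(b)]
    scores = []
    for c in range(values.shape[1]):
        sig_vals, ctrl_vals = [], []
        for g in sig_genes:
            gi = gene_ids.index(g)
            sig_vals.append(centred[gi, c])
            members = next(b for b in bins if gi in b)
            others = [m for m in members if m != gi] or [gi]
            ctrl_vals.append(np.mean([centred[m, c] for m in others]))
        scores.append(np.mean(sig_vals) - np.mean(ctrl_vals))
    return np.array(scores)


class TestScoreSignature:
    def test_matches_direct_oracle(self, rng):
        values = rng.uniform(0, 4, size=(20, 10))
        gene_ids = [f"g{i}" for i in range(20)]
        logm = make_matrix(values, is_log=True)
        sig = gs.Signature("S", tuple(gene_ids[i] for i in (1, 4, 7, 13)))
        got = gs.score_signature(logm, sig, n_bins=5)
        want = oracle_score(values, gene_ids, sig.genes, n_bins=5)
        assert np.allclose(got.to_numpy(), want, atol=1e-10)

    def test_constant_matrix_scores_zero(self):
        logm = make_matrix(np.full((12, 6), 2.0), is_log=True)
        sig = gs.Signature("S", ("g0", "g3"))
        assert np.allclose(gs.score_signature(logm, sig, n_bins=3), 0, atol=1e-12)

    def test_whole_universe_signature_scores_zero(self, rng):
        values = rng.uniform(0, 3, size=(15, 8))
        logm = make_matrix(values, is_log=True)
        sig = gs.Signature("ALL", tuple(f"g{i}" for i in range(15)))
        assert np.allclose(gs.score_signature(logm, sig, n_bins=4), 0, atol=1e-10)

    def test_order_preserving_gene_offsets_leave_scores_unchanged(self, rng):
        # adding per-gene constants that preserve the mean-expression ranking
        # keeps both the centred values and the bins, hence the scores
        values = rng.uniform(0, 3, size=(30, 12))
        logm = make_matrix(values, is_log=True)
        sig = gs.Signature("S", ("g2", "g9", "g17"))
        base = gs.score_signature(logm, sig, n_bins=6)
        offsets = np.sort(rng.uniform(0, 5, size=30))
        rank = np.argsort(np.argsort(values.mean(axis=1), kind="stable"))
        shifted = make_matrix(values + offsets[rank][:, None], is_log=True)
        again = gs.score_signature(shifted, sig, n_bins=6)
        assert np.allclose(base, again, atol=1e-10)

    def test_per_sample_centring(self, rng):
        values = rng.uniform(0, 3, size=(20, 10))
        samples = ["a"] * 4 + ["b"] * 6
        logm = make_matrix(values, is_log=True, samples=samples)
        sig = gs.Signature("S", ("g1", "g5"))
        got = gs.score_signature(logm, sig, n_bins=4, per_sample=True)
        wa = oracle_score(values[:, :4], [f"g{i}" for i in range(20)], sig.genes, 4)
        wb = oracle_score(values[:, 4:], [f"g{i}" for i in range(20)], sig.genes, 4)
        assert np.allclose(got.to_numpy(), np.concatenate([wa, wb]), atol=1e-10)

    def test_missing_signature_warns_empty_errors(self, rng):
        logm = make_matrix(rng.uniform(0, 3, size=(10, 5)), is_log=True)
        with pytest.warns(UserWarning, match="absent"):
            gs.score_signature(logm, gs.Signature("S", ("g1", "nope")), n_bins=3)
        with pytest.raises(ValueError, match="no genes"):
            gs.score_signature(logm, gs.Signature("S", ("nope",)), n_bins=3)


class TestAssignState:
    @pytest.mark.parametrize(
        "triple,expected",
        [
            ((0.9, 0.1, 0.2), "AC-like"),
            ((0.4, 0.3, 0.2), "unresolved"),
            ((0.1, 0.8, 0.2), "OC-like"),
            ((0.1, 0.2, 0.51), "OPC-like"),
            ((0.5, 0.5, 0.5), "unresolved"),  # at threshold
            ((0.9, 0.9, 0.2), "unresolved"),  # tie at the max
        ],
    )
    def test_examples(self, triple, expected):
        scores = pd.DataFrame([triple], columns=list(gs.STATE_NAMES))
        assert gs.assign_state(scores).iloc[0] == expected

    def test_missing_score_errors(self):
        scores = pd.DataFrame({"AC-like": [1.0], "OC-like": [0.1]})
        with pytest.raises(ValueError, match="missing"):
            gs.assign_state(scores)
        scores = pd.DataFrame(
            [[np.nan, 0.1, 0.2]], columns=list(gs.STATE_NAMES)
        )
        with pytest.raises(ValueError):
            gs.assign_state(scores)

    @given(
        hst.tuples(*[hst.floats(-2, 2, allow_nan=False)] * 3),
        hst.floats(0.01, 3),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_raising_winning_score_is_monotone(self, triple, bump):
        scores = pd.DataFrame([list(triple)], columns=list(gs.STATE_NAMES))
        label = gs.assign_state(scores).iloc[0]
        if label == gs.UNRESOLVED:
            return
        scores.loc[0, label] += bump
        assert gs.assign_state(scores).iloc[0] == label


class TestHierarchyCoords:
    @pytest.mark.parametrize(
        "triple,lineage,stemness",
        [
            ((1.0, 0.0, 0.0), 1.0, -1.0),
            ((0.0, 0.0, 1.0), 0.0, 1.0),
            ((0.7, 0.7, 0.2), 0.0, -0.5),
        ],
    )
    def test_two_axis_formula(self, triple, lineage, stemness):
        scores = pd.DataFrame([triple], columns=list(gs.STATE_NAMES))
        coords = gs.hierarchy_coords(scores)
        assert coords["lineage"].iloc[0] == pytest.approx(lineage)
        assert coords["stemness"].iloc[0] == pytest.approx(stemness)
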