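"""Detection rate, kNN smoothing and per-state co-expression with a target gene."""

import heapq

import numpy as np
import pandas as pd
import pytest

import gliosynapse as gs
from gliosynapse.expression import STATE_NAMES


def make_log_matrix(values, cell_ids=None):
    values = np.asarray(values, float)
    g, c = values.shape
    return gs.ExpressionMatrix(
        values=values,
        gene_ids=[f"g{i}" for i in range(g)],
        cell_ids=cell_ids or [f"c{i}" for i in range(c)],
        is_log=True,
    )


class TestDetectionRate:
    def test_all_none_and_planted_fraction(self):
        n = 100
        expr = np.zeros((1, 3 * n))
        expr[0, :n] = 1.0  # AC cells all positive
        expr[0, n : n + 30] = 0.5  # 30 of 100 OC cells positive
        logm = make_log_matrix(expr)
        assignments = pd.Series(
            ["AC-like"] * n + ["OC-like"] * n + ["OPC-like"] * n,
            index=logm.cell_ids,
        )
        rates = gs.detection_rate(logm, "g0", assignments)
        assert rates["AC-like"] == 1.0
        assert rates["OC-like"] == pytest.approx(0.30)
        assert rates["OPC-like"] == 0.0

    def test_empty_state_is_missing_not_zero(self):
        logm = make_log_matrix(np.ones((1, 4)))
        assignments = pd.Series(["AC-like"] * 4, index=logm.cell_ids)
        rates = gs.detection_rate(logm, "g0", assignments)
        assert np.isnan(rates["OC-like"])

    def test_unresolved_cells_excluded(self):
        logm = make_log_matrix([[1.0, 0.0, 1.0]])
        assignments = pd.Series(
            ["AC-like", "unresolved", "AC-like"], index=logm.cell_ids
        )
        assert gs.detection_rate(logm, "g0", assignments)["AC-like"] == 1.0


def oracle_knn(values, coords, k):
    """Independent per-point selection with explicit (distance, index) ranking."""
    out = np.empty_like(values, dtype=float)
    for i in range(len(values)):
        cand = [
            (np.hypot(*(coords[j] - coords[i])), j)
            for j in range(len(values))
            if j != i
        ]
        nbrs = heapq.nsmallest(k, cand)
        out[i] = np.mean([values[j] for _, j in nbrs])
    return out


class TestKnnSmooth:
    def test_constant_values_unchanged(self, rng):
        coords = rng.normal(size=(20, 2))
        res = gs.knn_smooth(np.full(20, 3.0), coords, k=5)
        assert np.allclose(res.table["smoothed"], 3.0)

    def test_n_equals_k_plus_one_forces_neighbour_set(self, rng):
        vals = rng.normal(size=6)
        coords = rng.normal(size=(6, 2))
        res = gs.knn_smooth(vals, coords, k=5)
        for i in range(6):
            expected = np.mean(np.delete(vals, i))
            assert res.table["smoothed"].iloc[i] == pytest.approx(expected)

    def test_matches_bruteforce_oracle_exactly(self, rng):
        vals = rng.normal(size=50)
        coords = rng.normal(size=(50, 2))
        res = gs.knn_smooth(vals, coords, k=10)
        assert np.array_equal(res.table["smoothed"].to_numpy(), oracle_knn(vals, coords, 10))

    def test_output_bounded_by_raw_range(self, rng):
        vals = rng.normal(size=40)
        res = gs.knn_smooth(vals, rng.normal(size=(40, 2)), k=7)
        assert res.table["smoothed"].min() >= vals.min() - 1e-12
        assert res.table["smoothed"].max() <= vals.max() + 1e-12

    def test_too_few_cells_errors(self, rng):
        with pytest.raises(ValueError, match="k\\+1"):
            gs.knn_smooth(np.ones(5), rng.normal(size=(5, 2)), k=5)


def oracle_state_correlation(values, assignments, target_idx, gene_idx, state):
    """Direct formula: global gene-centring, then cosine over the state's cells."""
    assignable = np.isin(assignments, list(STATE_NAMES))
    sub = values[:, assignable]
    centred = sub - sub.mean(axis=1, keepdims=True)
    in_state = assignments[assignable] == state
    x = centred[target_idx, in_state]
    y = centred[gene_idx, in_state]
    return float(np.sum(x * y) / np.sqrt(np.sum(x * x) * np.sum(y * y)))


class TestPerStateCorrelation:
    @pytest.fixture()
    def random_case(self, rng):
        values = rng.uniform(0, 4, size=(30, 60))
        values[1] = values[0]  # duplicate of the target row
        assignments = np.array(
            ["AC-like"] * 20 + ["OC-like"] * 20 + ["OPC-like"] * 15 + ["unresolved"] * 5
        )
        logm = make_log_matrix(values)
        aseries = pd.Series(assignments, index=logm.cell_ids)
        return values, logm, aseries, assignments

    def test_duplicate_row_gives_one(self, random_case):
        _, logm, aseries, _ = random_case
        table = gs.per_state_correlation(logm, "g0", aseries)
        assert np.allclose(table.loc["g1", ["r_AC", "r_OC", "r_OPC"]], 1.0, atol=1e-12)
        assert np.allclose(table.loc["g0", ["r_AC", "r_OC", "r_OPC"]], 1.0, atol=1e-12)

    def test_negated_centred_target_gives_minus_one(self, random_case):
        values, logm, aseries, _ = random_case
        # a gene whose centred profile is the negation of the centred target
        neg = 5.0 - values[0]  # stays positive; centred profile is exactly -x
        values2 = np.vstack([values, neg])
        logm2 = make_log_matrix(values2)
        aseries.index = logm2.cell_ids
        table = gs.per_state_correlation(logm2, "g0", aseries)
        # global centring differs from per-state centring, but the negation
        # relation is preserved under any common centring
        assert np.allclose(
            table.loc["g30", ["r_AC", "r_OC", "r_OPC"]], -1.0, atol=1e-10
        )

    def test_matches_direct_formula(self, random_case):
        values, logm, aseries, assignments = random_case
        table = gs.per_state_correlation(logm, "g0", aseries)
        for state, col in [("AC-like", "r_AC"), ("OC-like", "r_OC"), ("OPC-like", "r_OPC")]:
            for gi in (2, 7, 19, 29):
                want = oracle_state_correlation(values, assignments, 0, gi, state)
                assert table.loc[f"g{gi}", col] == pytest.approx(want, abs=1e-10)

    def test_symmetry_under_role_swap(self, random_case):
        values, logm, aseries, _ = random_case
        t1 = gs.per_state_correlation(logm, "g0", aseries)
        t2 = gs.per_state_correlation(logm, "g5", aseries)
        assert t1.loc["g5", "r_OC"] == pytest.approx(t2.loc["g0", "r_OC"], abs=1e-12)

    def test_all_r_within_unit_interval(self, random_case):
        _, logm, aseries, _ = random_case
        table = gs.per_state_correlation(logm, "g0", aseries)
        sub = table[["r_AC", "r_OC", "r_OPC"]].to_numpy()
        assert np.nanmin(sub) >= -1.0 and np.nanmax(sub) <= 1.0

    def test_zero_variance_target_flagged_missing(self):
        values = np.vstack([np.r_[np.ones(6), np.arange(6.0)], np.random.default_rng(0).uniform(1, 2, 12)])
        logm = make_log_matrix(values)
        aseries = pd.Series(["AC-like"] * 6 + ["OC-like"] * 6, index=logm.cell_ids)
        with pytest.warns(UserWarning):
            table = gs.per_state_correlation(logm, "g0", aseries)
        assert np.isnan(table.loc["g1", "r_AC"])
        assert np.isfinite(table.loc["g1", "r_OC"])


class TestSelectCorrelatedGenes:
    def make_table(self, rows):
        return pd.DataFrame(
            rows, columns=["r_AC", "r_OC", "r_OPC"],
            index=pd.Index([f"g{i}" for i in range(len(rows))], name="gene"),
        )

    def test_all_below_threshold_gives_empty_sets(self):
        table = self.make_table([[0.1, -0.2, 0.0], [0.24, 0.2, -0.24]])
        sel = gs.select_correlated_genes(table)
        assert sel["union"] == []
        assert all(v == [] for v in sel["positive"].values())

    def test_union_contains_positive_sets_and_excludes_target(self):
        table = self.make_table(
            [[0.9, 0.0, 0.0], [-0.4, 0.1, 0.0], [0.0, 0.3, 0.26], [0.2, 0.1, 0.0]]
        )
        sel = gs.select_correlated_genes(table, target_gene="g0")
        assert sel["union"] == ["g1", "g2"]  # g0 excluded as the target
        for state, genes in sel["positive"].items():
            assert set(genes) <= set(sel["union"]) | {"g0"}
        assert sel["positive"]["OC-like"] == ["g2"]
        assert sel["positive"]["OPC-like"] == ["g2"]
        assert sel["positive"]["AC-like"] == []

    def test_threshold_is_strict(self):
        table = self.make_table([[0.25, 0.0, 0.0]])
        assert gs.select_correlated_genes(table)["union"] == []

    def test_missing_r_never_passes(self):
        table = self.make_table([[np.nan, np.nan, np.nan]])
        assert gs.select_correlated_genes(table)["union"] == []
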