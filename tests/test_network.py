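import numpy as np
import pandas as pd
import pytest

from fmstab import (CommunityTable, CooccurrenceAnalysis, discretize_abundance,
                    nc_score_pair, nc_score_matrix, score_significance,
                    build_network, positive_score_excess, mantel_test,
                    degree_abundance_association, to_proportions)
from fmstab.network import ScoreMatrix

from conftest import make_table


def gamma_oracle(x, y):
    """Brute-force Goodman-Kruskal gamma over all unordered sample pairs."""
    c = d = 0
    n = len(x)
    for s in range(n):
        for t in range(s + 1, n):
            prod = (x[s] - x[t]) * (y[s] - y[t])
            if prod > 0:
                c += 1
            elif prod < 0:
                d += 1
    if c + d == 0:
        return float("nan"), 0
    return (c - d) / (c + d), c + d


class TestDiscretize:
    def _props(self, rows):
        rows = np.asarray(rows, dtype=float)
        return make_table(rows / rows.sum(axis=0), mode="proportions")

    def test_zeros_map_to_bin_zero(self):
        table = self._props([[0, 0, 0, 0], [1, 2, 3, 4]])
        binned = discretize_abundance(table)
        assert (binned.iloc[0] == 0).all()

    def test_monotone_labels(self):
        table = self._props([[1, 2, 3, 4, 5, 6], [6, 5, 4, 3, 2, 1]])
        binned = discretize_abundance(table, n_bins=4)
        order = np.argsort(table.values[0])
        assert (np.diff(binned.iloc[0].to_numpy()[order]) >= 0).all()
        assert set(binned.iloc[0]) <= {1, 2, 3}

    def test_two_distinct_values_separated(self):
        table = self._props([[1, 1, 4, 4], [4, 4, 1, 1]])
        binned = discretize_abundance(table, n_bins=4)
        low = binned.iloc[0, :2]
        high = binned.iloc[0, 2:]
        assert low.nunique() == 1 and high.nunique() == 1
        assert low.iloc[0] < high.iloc[0]

    def test_too_few_bins_rejected(self):
        table = self._props([[1, 2], [2, 1]])
        with pytest.raises(ValueError):
            discretize_abundance(table, n_bins=1)


class TestNcScore:
    def test_perfect_concordance_and_checkerboard(self):
        assert nc_score_pair([1, 0, 1, 0], [1, 0, 1, 0])[0] == 1.0
        assert nc_score_pair([1, 0, 1, 0], [0, 1, 0, 1])[0] == -1.0

    def test_constant_vector_undefined(self):
        score, n_inf = nc_score_pair([2, 2, 2], [0, 1, 2])
        assert np.isnan(score) and n_inf == 0

    def test_matches_gamma_oracle_on_random_binned_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = rng.integers(4, 15)
            x = rng.integers(0, 4, n)
            y = rng.integers(0, 4, n)
            score, n_inf = nc_score_pair(x, y)
            o_score, o_inf = gamma_oracle(x, y)
            assert n_inf == o_inf
            if n_inf:
                assert score == pytest.approx(o_score)
            else:
                assert np.isnan(score)

    def test_matrix_symmetric_and_order_invariant(self):
        rng = np.random.default_rng(1)
        binned = pd.DataFrame(rng.integers(0, 4, size=(6, 12)),
                              index=[f"o{k}" for k in range(6)])
        sm = nc_score_matrix(binned)
        np.testing.assert_allclose(sm.values, sm.values.T, equal_nan=True)
        perm = rng.permutation(12)
        sm2 = nc_score_matrix(binned.iloc[:, perm])
        np.testing.assert_allclose(sm.values, sm2.values, equal_nan=True)


class TestSignificance:
    def test_duplicated_otu_hits_minimum_p(self):
        rng = np.random.default_rng(2)
        x = rng.integers(0, 4, 20)
        binned = pd.DataFrame([x, x.copy(), rng.integers(0, 4, 20)],
                              index=["a", "a_copy", "b"])
        p, q = score_significance(binned, n_perm=199, seed=0)
        assert p.loc["a", "a_copy"] == pytest.approx(1 / 200)

    def test_seed_reproducible(self):
        rng = np.random.default_rng(3)
        binned = pd.DataFrame(rng.integers(0, 4, size=(5, 15)))
        p1, _ = score_significance(binned, n_perm=99, seed=5)
        p2, _ = score_significance(binned, n_perm=99, seed=5)
        pd.testing.assert_frame_equal(p1, p2)

    def test_independent_otus_give_uniformish_p(self):
        """KS check of p-values against uniform under independence."""
        from scipy.stats import kstest
        rng = np.random.default_rng(4)
        pvals = []
        for _ in range(10):
            binned = pd.DataFrame(rng.integers(0, 4, size=(8, 30)))
            p, _ = score_significance(binned, n_perm=199, seed=int(rng.integers(2**31)))
            iu, ju = np.triu_indices(8, k=1)
            pvals.extend(p.to_numpy()[iu, ju])
        pvals = np.asarray(pvals)
        pvals = pvals[np.isfinite(pvals)]
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestNetwork:
    def _fit(self, seed=0, alpha=0.05):
        rng = np.random.default_rng(seed)
        base = rng.random((8, 24)) + 0.05
        table = make_table(base / base.sum(axis=0), mode="proportions")
        analysis = CooccurrenceAnalysis(table)
        return analysis.fit(n_perm=99, seed=seed, alpha=alpha)

    def test_alpha_one_gives_complete_graph(self):
        res = self._fit(alpha=1.0000001)
        n = len(res.scores.otu_ids)
        defined = np.isfinite(res.q.to_numpy()).sum() // 2
        assert res.network.n_edges == defined == n * (n - 1) // 2

    def test_no_significant_pairs_empty_network(self):
        scores = ScoreMatrix(["a", "b"], np.array([[np.nan, 0.1], [0.1, np.nan]]),
                             np.array([[0, 5], [5, 0]]))
        q = pd.DataFrame([[np.nan, 0.9], [0.9, np.nan]], index=["a", "b"],
                         columns=["a", "b"])
        net = build_network(scores, q)
        assert net.n_edges == 0
        assert (net.degrees == 0).all()

    def test_edge_frame_columns(self):
        res = self._fit(alpha=1.0000001)
        frame = res.network.edge_frame()
        assert list(frame.columns) == ["otu_i", "otu_j", "score", "p", "q", "sign"]


class TestPositiveExcess:
    def test_all_positive_scores_significant(self):
        n = 6
        vals = np.full((n, n), 0.5)
        np.fill_diagonal(vals, np.nan)
        sm = ScoreMatrix([f"o{k}" for k in range(n)], vals,
                         np.full((n, n), 10))
        stat, p = positive_score_excess(sm)
        assert p < 0.05

    def test_single_score_two_outcome_p(self):
        vals = np.array([[np.nan, 0.4], [0.4, np.nan]])
        sm = ScoreMatrix(["a", "b"], vals, np.full((2, 2), 5))
        _, p = positive_score_excess(sm)
        assert p == pytest.approx(0.5)

    def test_all_zero_scores_p_one(self):
        vals = np.zeros((3, 3))
        np.fill_diagonal(vals, np.nan)
        sm = ScoreMatrix(["a", "b", "c"], vals, np.full((3, 3), 5))
        assert positive_score_excess(sm)[1] == 1.0

    def test_symmetric_scores_near_half(self):
        rng = np.random.default_rng(6)
        n = 20
        iu, ju = np.triu_indices(n, k=1)
        vals = np.full((n, n), np.nan)
        draws = rng.normal(0, 0.3, iu.size)
        vals[iu, ju] = draws
        vals[ju, iu] = draws
        sm = ScoreMatrix([f"o{k}" for k in range(n)], vals,
                         np.full((n, n), 10))
        _, p = positive_score_excess(sm)
        assert 0.01 < p < 0.99


class TestMantel:
    def _random_scores(self, rng, n=12, ids=None):
        iu, ju = np.triu_indices(n, k=1)
        vals = np.full((n, n), np.nan)
        draws = rng.uniform(-1, 1, iu.size)
        vals[iu, ju] = draws
        vals[ju, iu] = draws
        return ScoreMatrix(ids or [f"o{k}" for k in range(n)], vals,
                           np.full((n, n), 8))

    def test_identity_gives_r_one(self):
        rng = np.random.default_rng(7)
        A = self._random_scores(rng)
        r, p = mantel_test(A, A, n_perm=199, seed=1)
        assert r == pytest.approx(1.0)
        assert p <= 0.05

    def test_negation_gives_r_minus_one(self):
        rng = np.random.default_rng(8)
        A = self._random_scores(rng)
        B = ScoreMatrix(A.otu_ids, -A.values, A.n_informative)
        r, p = mantel_test(A, B, n_perm=199, seed=1)
        assert r == pytest.approx(-1.0)
        assert p > 0.5

    def test_independent_matrices_mostly_null(self):
        rng = np.random.default_rng(9)
        hits = 0
        for rep in range(20):
            A = self._random_scores(rng, n=20)
            B = self._random_scores(rng, n=20)
            r, p = mantel_test(A, B, n_perm=199, seed=int(rng.integers(2**31)))
            if abs(r) < 0.3 and p > 0.05:
                hits += 1
        assert hits >= 18

    def test_too_few_common_otus(self):
        rng = np.random.default_rng(10)
        A = self._random_scores(rng, n=4, ids=["a", "b", "c", "d"])
        B = self._random_scores(rng, n=4, ids=["a", "b", "x", "y"])
        with pytest.raises(ValueError, match="common OTUs"):
            mantel_test(A, B)


class TestDegreeAbundance:
    def test_empty_or_flat_network_flagged(self):
        rng = np.random.default_rng(11)
        base = rng.random((4, 10)) + 0.1
        table = make_table(base / base.sum(axis=0), mode="proportions")
        res = CooccurrenceAnalysis(table).fit(n_perm=49, seed=0, alpha=1e-9)
        rho, p = degree_abundance_association(res.network, table)
        assert np.isnan(rho) and np.isnan(p)

    def test_planted_hub_abundance_correlation(self):
        """High-abundance OTUs carrying the edges yield a positive rho."""
        rng = np.random.default_rng(12)
        n_samples = 40
        factor = rng.normal(size=n_samples)
        rows = []
        for k in range(2):      # dominant, nearly constant: pin the denominator
            rows.append(np.exp(3.0 + 0.05 * rng.normal(size=n_samples)))
        for k in range(4):      # mid-abundance block sharing a latent factor
            rows.append(np.exp(1.5 + 1.0 * factor + 0.3 * rng.normal(size=n_samples)))
        for k in range(6):      # rare, independent OTUs
            rows.append(np.exp(-2.0 + 0.5 * rng.normal(size=n_samples)))
        rows = np.asarray(rows)
        table = make_table(rows / rows.sum(axis=0), mode="proportions")
        res = CooccurrenceAnalysis(table).fit(n_perm=199, seed=3)
        rho, p = degree_abundance_association(res.network, table)
        assert rho > 0
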