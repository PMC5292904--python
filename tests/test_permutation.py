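import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fmstab import cliffs_d, StabilityPermutationTest, run_comparison
from fmstab.comparisons import PairDesign


def brute_force_cliffs_d(focal, reference):
    gt = sum(1 for r in reference for f in focal if r > f)
    lt = sum(1 for r in reference for f in focal if r < f)
    return (gt - lt) / (len(focal) * len(reference))


def make_design(values, roles, strata):
    """PairDesign over synthetic pair values (samples are placeholders)."""
    n = len(values)
    return PairDesign("synthetic", [f"s{i}" for i in range(n + 1)],
                      np.arange(n), np.arange(1, n + 1),
                      np.asarray(roles, dtype=object),
                      np.asarray(strata, dtype=object))


def exhaustive_oracle(values, roles, strata, alternative="greater"):
    """Enumerate every within-stratum role reassignment directly."""
    values = np.asarray(values, float)
    roles = np.asarray(roles, object)
    strata = np.asarray(strata, object)
    inc = roles != "excluded"
    idx = np.flatnonzero(inc)
    per_stratum = []
    for s in np.unique(strata[inc]):
        members = [i for i in idx if strata[i] == s]
        k = sum(roles[i] == "focal" for i in members)
        per_stratum.append([set(c) for c in itertools.combinations(members, k)])
    n_f = int(np.sum(roles == "focal"))
    n_r = int(np.sum(roles == "reference"))
    diffs = []
    for assignment in itertools.product(*per_stratum):
        focal_set = set().union(*assignment) if assignment else set()
        f = np.array([values[i] for i in focal_set])
        r = np.array([values[i] for i in idx if i not in focal_set])
        diffs.append(r.mean() - f.mean())
    diffs = np.asarray(diffs)
    f0 = values[roles == "focal"]
    r0 = values[roles == "reference"]
    obs = r0.mean() - f0.mean()
    if alternative == "greater":
        p = np.mean(diffs >= obs - 1e-12)
    else:
        p = np.mean(np.abs(diffs) >= abs(obs) - 1e-12)
    return obs, p, diffs


class TestCliffsD:
    @pytest.mark.parametrize("focal,reference,expected", [
        ([0.1, 0.2], [0.3, 0.4], 1.0),
        ([1, 3], [2, 4], 0.5),
        ([1], [1], 0.0),
    ])
    def test_hand_examples(self, focal, reference, expected):
        assert cliffs_d(focal, reference) == expected

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            nf, nr = rng.integers(1, 51, size=2)
            # mix of continuous values and ties
            f = rng.integers(0, 10, nf) + rng.random(nf) * rng.integers(0, 2)
            r = rng.integers(0, 10, nr) + rng.random(nr) * rng.integers(0, 2)
            assert cliffs_d(f, r) == brute_force_cliffs_d(list(f), list(r))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cliffs_d([], [1.0])

    @given(st.lists(st.integers(0, 5), min_size=1, max_size=20),
           st.lists(st.integers(0, 5), min_size=1, max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_bounded_and_antisymmetric(self, f, r):
        d = cliffs_d(f, r)
        assert -1.0 <= d <= 1.0
        assert d == -cliffs_d(r, f)


class TestExhaustiveEnumeration:
    def test_spec_worked_example(self):
        """focal {0.1}, reference {.5,.6,.7}: 4 assignments, p = 1/4."""
        values = [0.1, 0.5, 0.6, 0.7]
        roles = ["focal", "reference", "reference", "reference"]
        strata = ["a"] * 4
        test = StabilityPermutationTest.from_pair_values(
            np.array(values), make_design(values, roles, strata))
        res = test.fit(n_perm=9999, seed=0)
        assert res.exhaustive
        assert res.observed_diff == pytest.approx(0.5)
        assert res.p_value == pytest.approx(0.25)
        assert res.n_permutations == 4

    def test_matches_independent_enumeration_on_random_designs(self):
        import math
        rng = np.random.default_rng(7)
        for _ in range(25):
            while True:  # keep designs small enough for exact enumeration
                values, roles, strata = [], [], []
                total = 1
                for s in range(rng.integers(1, 4)):
                    m = int(rng.integers(2, 8))
                    k = int(rng.integers(1, m))
                    total *= math.comb(m, k)
                    values.extend(rng.normal(size=m).tolist())
                    roles.extend(["focal"] * k + ["reference"] * (m - k))
                    strata.extend([f"st{s}"] * m)
                if total <= 10_000:
                    break
            obs, p_oracle, diffs = exhaustive_oracle(values, roles, strata)
            test = StabilityPermutationTest.from_pair_values(
                np.array(values), make_design(values, roles, strata))
            res = test.fit(seed=0)
            assert res.exhaustive
            assert res.n_permutations == diffs.size
            assert res.observed_diff == pytest.approx(obs)
            assert res.p_value == pytest.approx(p_oracle)

    def test_identical_values_give_p_one(self):
        values = [0.3] * 6
        roles = ["focal", "focal", "reference", "reference", "reference",
                 "reference"]
        test = StabilityPermutationTest.from_pair_values(
            np.array(values), make_design(values, roles, ["a"] * 6))
        res = test.fit(seed=1)
        assert res.observed_diff == pytest.approx(0.0)
        assert res.p_value == 1.0
        assert res.cliffs_d == 0.0


class TestMonteCarlo:
    def _big_design(self, rng):
        n = 40
        values = rng.normal(size=n)
        roles = np.array(["focal"] * 15 + ["reference"] * 25, dtype=object)
        strata = np.array(["a"] * 20 + ["b"] * 20, dtype=object)
        return values, make_design(values, roles, strata)

    def test_seed_reproducible(self):
        rng = np.random.default_rng(3)
        values, design = self._big_design(rng)
        t = StabilityPermutationTest.from_pair_values(values, design)
        r1 = t.fit(n_perm=500, seed=11)
        r2 = t.fit(n_perm=500, seed=11)
        assert not r1.exhaustive
        assert r1.p_value == r2.p_value
        assert (r1.null_low, r1.null_high) == (r2.null_low, r2.null_high)

    def test_engine_calibrated_on_exchangeable_values(self):
        """With iid pair values the permutation test is exact: the rejection
        rate at alpha=.05 sits inside the binomial 95% band."""
        rng = np.random.default_rng(2024)
        n_rep, rej = 400, 0
        for _ in range(n_rep):
            n = 24
            values = rng.normal(size=n)
            roles = np.where(rng.random(n) < 0.35, "focal", "reference").astype(object)
            roles[:2] = ["focal", "reference"]
            strata = rng.integers(0, 2, n).astype(str).astype(object)
            t = StabilityPermutationTest.from_pair_values(
                values, make_design(values, roles, strata))
            if t.fit(n_perm=199, seed=int(rng.integers(2 ** 31))).p_value <= 0.05:
                rej += 1
        from scipy.stats import binom
        lo, hi = binom.interval(0.95, n_rep, 0.05)
        assert lo <= rej <= hi

    def test_lone_role_stratum_warns(self):
        values = np.array([1.0, 2.0, 3.0, 4.0])
        roles = ["focal", "reference", "focal", "focal"]
        strata = ["a", "a", "b", "b"]
        with pytest.warns(UserWarning, match="single role"):
            StabilityPermutationTest.from_pair_values(
                values, make_design(values, roles, strata))


class TestRunComparison:
    def test_stability_signal_positive_cliffs_d(self):
        from fmstab import preset_configs, simulate_community
        table, meta, tree, truth = simulate_community(
            preset_configs()["stability"], seed=5)
        res = run_comparison(table, meta, "adult_within_individual_within_year",
                             metric="bray_curtis", n_perm=199, seed=1)
        assert res.cliffs_d > 0
        assert res.p_value < 0.05
        assert res.metric == "bray_curtis"

    def test_deterministic_under_seed(self):
        from fmstab import preset_configs, simulate_community
        table, meta, tree, truth = simulate_community(
            preset_configs()["null"], seed=6)
        a = run_comparison(table, meta, "juv_within_nest", n_perm=99, seed=4)
        b = run_comparison(table, meta, "juv_within_nest", n_perm=99, seed=4)
        assert a.p_value == b.p_value and a.observed_diff == b.observed_diff

    def test_summary_mentions_comparison(self):
        from fmstab import preset_configs, simulate_community
        table, meta, tree, truth = simulate_community(
            preset_configs()["null"], seed=6)
        res = run_comparison(table, meta, "adult_within_year", n_perm=99, seed=0)
        text = res.summary()
        assert "adult_within_year" in text and "Cliff's d" in text

    def test_individual_relabel_mode_runs(self):
        from fmstab import preset_configs, simulate_community
        table, meta, tree, truth = simulate_community(
            preset_configs()["null"], seed=8)
        res = run_comparison(table, meta, "adult_within_individual_within_year",
                             n_perm=29, seed=2, mode="individuals")
        assert 0 < res.p_value <= 1
        with pytest.raises(ValueError, match="individual-identity"):
            run_comparison(table, meta, "adult_within_colony", n_perm=9,
                           seed=2, mode="individuals")
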