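"""Stratified pair-permutation test for community temporal stability.

The test asks whether dissimilarities within a host grouping (focal pairs)
are lower than between groups (reference pairs). The observed statistic is

    diff = mean(reference dissimilarities) - mean(focal dissimilarities)

with the non-parametric Cliff's d as effect size. The null distribution is
built by reshuffling the focal/reference role labels among the pair
dissimilarity values, independently within each permutation stratum
(preserving per-stratum role counts), so systematic differences between
strata (colony, year, nest, age-class ...) cannot masquerade as a stability
signal. Pair values sharing a sample are not mutually independent; permuting
pair labels is therefore an approximation (see docs), with a stricter
individual-relabelling mode available for individual-identity comparisons.

When the number of distinct role assignments is small (<= 10,000 by default)
the null is enumerated exhaustively and the p-value is the exact proportion
of assignments with a difference at least as large as observed; otherwise a
Monte-Carlo null with the add-one convention p = (1 + #{null >= obs}) /
(1 + n_perm) is used.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np

from .community import CommunityTable, to_proportions, rarefy
from .comparisons import (COMPARISONS, INDIVIDUAL_COMPARISONS, PairDesign,
                          build_pair_design)
from . import diversity

__all__ = ["cliffs_d", "StabilityPermutationTest", "PermutationTestResults",
           "run_comparison", "dissimilarity_for_metric", "METRICS"]

METRICS = ("bray_curtis", "jaccard_binary", "unweighted_unifrac", "weighted_unifrac")


def cliffs_d(focal_values, reference_values) -> float:
    """Cliff's d effect size between reference and focal value sets.

    d = [#(r > f) - #(r < f)] / (n_f * n_r) over all cross pairs; ties
    contribute 0. Positive d means reference (between-group) dissimilarities
    exceed focal (within-group) ones, i.e. a stability signal.
    """
    f = np.asarray(focal_values, dtype=float).ravel()
    r = np.sort(np.asarray(reference_values, dtype=float).ravel())
    if f.size == 0 or r.size == 0:
        raise ValueError("cliffs_d requires non-empty value sets")
    greater = np.sum(r.size - np.searchsorted(r, f, side="right"))
    less = np.sum(np.searchsorted(r, f, side="left"))
    return float((greater - less) / (f.size * r.size))


@dataclass
class PermutationTestResults:
    """Results of a stratified pair-permutation stability test."""

    comparison: str
    metric: str | None
    observed_diff: float
    cliffs_d: float
    p_value: float
    null_low: float            # 2.5% quantile of the permutation null
    null_high: float           # 97.5% quantile
    n_permutations: int
    exhaustive: bool
    n_focal: int
    n_reference: int
    alternative: str

    def summary(self) -> str:
        method = ("exhaustive enumeration" if self.exhaustive
                  else "Monte-Carlo permutation")
        lines = [
            "Stratified pair-permutation stability test",
            "=" * 46,
            f"comparison:      {self.comparison}",
            f"metric:          {self.metric or '-'}",
            f"n focal pairs:   {self.n_focal}",
            f"n reference:     {self.n_reference}",
            f"observed diff:   {self.observed_diff: .6f}",
            f"Cliff's d:       {self.cliffs_d: .4f}",
            f"null 95% range:  [{self.null_low: .6f}, {self.null_high: .6f}]",
            f"p ({self.alternative}):     {self.p_value:.4g}",
            f"null:            {method}, n={self.n_permutations}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "comparison": self.comparison, "metric": self.metric,
            "observed_diff": self.observed_diff, "ci_low": self.null_low,
            "ci_high": self.null_high, "p": self.p_value,
            "cliffs_d": self.cliffs_d, "n_focal": self.n_focal,
            "n_reference": self.n_reference,
        }


class StabilityPermutationTest:
    """Model object pairing pair dissimilarities with a :class:`PairDesign`.

    Build from a distance matrix via the constructor, or from precomputed
    per-pair values via :meth:`from_pair_values` (used by the per-OTU
    screen to avoid materialising full matrices). ``fit`` runs the test.
    """

    def __init__(self, dissimilarity, design: PairDesign):
        order = [dissimilarity.index(s) for s in design.sample_ids]
        data = dissimilarity.data
        values = data[np.asarray(order)[design.i], np.asarray(order)[design.j]]
        self._init_from_values(values, design)

    @classmethod
    def from_pair_values(cls, values: np.ndarray, design: PairDesign):
        self = cls.__new__(cls)
        self._init_from_values(np.asarray(values, dtype=float), design)
        return self

    def _init_from_values(self, values: np.ndarray, design: PairDesign):
        if values.shape != design.role.shape:
            raise ValueError("pair values do not match design shape")
        self.design = design
        focal_mask = design.role == "focal"
        ref_mask = design.role == "reference"
        if not focal_mask.any():
            raise ValueError(f"{design.comparison}: no focal pairs")
        if not ref_mask.any():
            raise ValueError(f"{design.comparison}: no reference pairs")
        self.focal_values = values[focal_mask]
        self.reference_values = values[ref_mask]
        # per-stratum value blocks, focal count first
        self._strata = []
        lone = 0
        included = focal_mask | ref_mask
        strata = design.stratum[included]
        vals = values[included]
        foc = focal_mask[included]
        for s in np.unique(strata):
            m = strata == s
            v = vals[m]
            k = int(foc[m].sum())
            if k == 0 or k == v.size:
                lone += 1
            self._strata.append((v, k))
        if lone:
            warnings.warn(
                f"{lone} stratum/strata contain a single role and contribute "
                "no permutation variation", UserWarning)

    def fit(self, n_perm: int = 9999, seed=None, alternative: str = "greater",
            exhaustive_limit: int = 10000) -> PermutationTestResults:
        """Run the stratified permutation test.

        ``alternative="greater"`` tests the directional stability hypothesis
        (reference > focal); ``"two-sided"`` uses |diff|.
        """
        if alternative not in ("greater", "two-sided"):
            raise ValueError("alternative must be 'greater' or 'two-sided'")
        n_f = self.focal_values.size
        n_r = self.reference_values.size
        total = self.focal_values.sum() + self.reference_values.sum()

        def diff_from_focal_sum(fs):
            return (total - fs) / n_r - fs / n_f

        observed = diff_from_focal_sum(self.focal_values.sum())
        d = cliffs_d(self.focal_values, self.reference_values)

        n_assign = 1
        for v, k in self._strata:
            n_assign *= math.comb(v.size, k)
            if n_assign > exhaustive_limit:
                break
        exhaustive = n_assign <= exhaustive_limit

        if exhaustive:
            sums = np.zeros(1)
            for v, k in self._strata:
                if k == 0 or k == v.size:
                    stratum_sums = np.array([v[:k].sum() if k else 0.0])
                else:
                    stratum_sums = np.array(
                        [sum(c) for c in itertools.combinations(v, k)])
                sums = (sums[:, None] + stratum_sums[None, :]).ravel()
            null = diff_from_focal_sum(sums)
            n_used = null.size
        else:
            rng = np.random.default_rng(seed)
            focal_sums = np.zeros(n_perm)
            for v, k in self._strata:
                if k == 0:
                    continue
                if k == v.size:
                    focal_sums += v.sum()
                    continue
                keys = rng.random((n_perm, v.size))
                idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
                focal_sums += v[idx].sum(axis=1)
            null = diff_from_focal_sum(focal_sums)
            n_used = n_perm

        tol = 1e-12 * max(1.0, abs(observed))
        if alternative == "greater":
            hits = int(np.sum(null >= observed - tol))
        else:
            hits = int(np.sum(np.abs(null) >= abs(observed) - tol))
        if exhaustive:
            p = hits / n_used
        else:
            p = (1 + hits) / (1 + n_used)

        lo, hi = np.percentile(null, [2.5, 97.5])
        return PermutationTestResults(
            comparison=self.design.comparison, metric=None,
            observed_diff=float(observed), cliffs_d=d, p_value=float(p),
            null_low=float(lo), null_high=float(hi), n_permutations=n_used,
            exhaustive=exhaustive, n_focal=n_f, n_reference=n_r,
            alternative=alternative,
        )


def dissimilarity_for_metric(table: CommunityTable, metric: str, tree=None,
                             depth=None, seed=None):
    """Normalise a counts table as required by ``metric`` and compute it.

    Proportion normalisation feeds the abundance-based metrics; rarefaction
    (to ``depth``, default the minimum column sum) feeds the presence-based
    ones.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; valid: {list(METRICS)}")
    if metric in ("bray_curtis", "weighted_unifrac"):
        props = table if table.mode == "proportions" else to_proportions(table)
        if metric == "bray_curtis":
            return diversity.bray_curtis_matrix(props)
        return diversity.weighted_unifrac_matrix(props, tree)
    if table.mode == "proportions":
        raise ValueError(f"{metric} requires a counts table (for rarefaction)")
    rare = rarefy(table, depth=depth, seed=seed)
    if metric == "jaccard_binary":
        return diversity.jaccard_binary_matrix(rare)
    return diversity.unweighted_unifrac_matrix(rare, tree)


def run_comparison(table: CommunityTable, metadata, comparison: str,
                   metric: str = "bray_curtis", tree=None, n_perm: int = 9999,
                   seed=None, depth=None, alternative: str = "greater",
                   exclude_extra_pair: bool = False,
                   exclude_parasitic: bool = False,
                   mode: str = "pair_labels") -> PermutationTestResults:
    """End-to-end stability test: normalise -> dissimilarity -> design -> test.

    ``mode="individuals"`` switches individual-identity comparisons to the
    stricter null that permutes individual labels across samples (within
    cohort x colony x year cells) and rebuilds the design per permutation.
    """
    meta = metadata.loc[table.sample_ids]
    ss = np.random.SeedSequence(seed) if seed is not None else np.random.SeedSequence()
    rarefy_seed, perm_seed = [int(s) for s in ss.generate_state(2) % (2 ** 31)]
    dm = dissimilarity_for_metric(table, metric, tree=tree, depth=depth,
                                  seed=rarefy_seed)
    if mode == "individuals":
        result = _individual_relabel_test(dm, meta, comparison, n_perm,
                                          perm_seed, alternative)
    elif mode == "pair_labels":
        design = build_pair_design(meta, comparison,
                                   exclude_extra_pair=exclude_extra_pair,
                                   exclude_parasitic=exclude_parasitic)
        result = StabilityPermutationTest(dm, design).fit(
            n_perm=n_perm, seed=perm_seed, alternative=alternative)
    else:
        raise ValueError("mode must be 'pair_labels' or 'individuals'")
    result.metric = metric
    return result


def _individual_relabel_test(dm, metadata, comparison, n_perm, seed,
                             alternative) -> PermutationTestResults:
    """Stricter null: permute individual identities among samples.

    Individual labels are reshuffled within cohort x colony x year cells so
    that the group structure (colony, year, cohort sizes) is preserved while
    any true within-individual signal is destroyed; the pair design is
    rebuilt for every permutation.
    """
    if comparison not in INDIVIDUAL_COMPARISONS:
        raise ValueError(
            "individual-relabelling mode applies only to individual-identity "
            f"comparisons {INDIVIDUAL_COMPARISONS}")
    rng = np.random.default_rng(seed)

    def stat(meta):
        design = build_pair_design(meta, comparison)
        test = StabilityPermutationTest(dm, design)
        obs = test.reference_values.mean() - test.focal_values.mean()
        return obs, test

    observed, test0 = stat(metadata)
    d = cliffs_d(test0.focal_values, test0.reference_values)
    cells = metadata.groupby(
        [metadata["cohort"], metadata["colony_id"], metadata["year"]],
        sort=False, observed=True)
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm = metadata.copy()
        for _, group in cells:
            idx = group.index.to_numpy()
            perm.loc[idx, "individual_id"] = group["individual_id"].to_numpy()[
                rng.permutation(idx.size)]
        null[b], _ = stat(perm)
    tol = 1e-12 * max(1.0, abs(observed))
    if alternative == "greater":
        hits = int(np.sum(null >= observed - tol))
    else:
        hits = int(np.sum(np.abs(null) >= abs(observed) - tol))
    p = (1 + hits) / (1 + n_perm)
    lo, hi = np.percentile(null, [2.5, 97.5])
    return PermutationTestResults(
        comparison=comparison, metric=None, observed_diff=float(observed),
        cliffs_d=d, p_value=float(p), null_low=float(lo), null_high=float(hi),
        n_permutations=n_perm, exhaustive=False,
        n_focal=test0.focal_values.size, n_reference=test0.reference_values.size,
        alternative=alternative,
    )
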