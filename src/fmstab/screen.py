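"""Per-OTU temporal-stability screen with independent filtering and q-values.

Each OTU is tested with the same stratified pair-permutation machinery as the
whole community, on the single-OTU Bray-Curtis dissimilarity
|p_s - p_t| / (p_s + p_t). Near-constant OTUs are removed *before* multiple
testing correction by a variance filter that ignores the identity labels, so
filtering does not distort the null (independent filtering). q-values use
Storey's procedure by default, falling back to Benjamini-Hochberg when too
few tests make pi0 estimation unstable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .community import CommunityTable, to_proportions
from .comparisons import build_pair_design
from .diversity import per_otu_bray_curtis_values
from .permutation import (PermutationTestResults, StabilityPermutationTest,
                          run_comparison)

__all__ = ["qvalues", "OtuStabilityScreen", "OtuScreenResults",
           "stable_subset_reanalysis"]

#: below this many tests Storey's pi0 estimate is unstable; fall back to BH
_STOREY_MIN_TESTS = 50


def qvalues(pvalues, method: str = "storey") -> np.ndarray:
    """False-discovery-rate q-values for a vector of p-values.

    ``bh`` is Benjamini-Hochberg (pi0 = 1). ``storey`` rescales the BH
    step-up values by an estimate of the null proportion pi0, obtained by
    averaging pi0(lambda) = #{p > lambda} / (m (1 - lambda)) over a lambda
    grid (the mean variant of Storey's smoother); with fewer than
    ``50`` tests the BH values are returned unchanged.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    if method not in ("storey", "bh"):
        raise ValueError("method must be 'storey' or 'bh'")
    bh = multipletests(p, method="fdr_bh")[1]
    if method == "bh" or p.size < _STOREY_MIN_TESTS:
        return bh
    lambdas = np.arange(0.05, 0.96, 0.05)
    pi0_grid = np.array([np.mean(p > lam) / (1.0 - lam) for lam in lambdas])
    pi0 = float(np.clip(pi0_grid.mean(), 1.0 / p.size, 1.0))
    return np.minimum(pi0 * bh, 1.0)


class OtuScreenResults:
    """Results table of the per-OTU stability screen."""

    def __init__(self, frame: pd.DataFrame, comparison: str, q_method: str):
        self.frame = frame
        self.comparison = comparison
        self.q_method = q_method

    def stable_otus(self, q_threshold: float = 0.05) -> list:
        f = self.frame
        mask = f["passed_filter"] & (f["q_value"] < q_threshold)
        return list(f.index[mask])

    def summary(self) -> str:
        f = self.frame
        n_stable = len(self.stable_otus())
        lines = [
            "Per-OTU temporal-stability screen",
            "=" * 40,
            f"comparison:        {self.comparison}",
            f"OTUs tested:       {int(f['passed_filter'].sum())} "
            f"(of {len(f)}; variance filter)",
            f"q-value method:    {self.q_method}",
            f"stable (q < .05):  {n_stable}",
        ]
        return "\n".join(lines)

    def write_tsv(self, path) -> None:
        out = self.frame.copy()
        out.index.name = "otu_id"
        out.to_csv(path, sep="\t", float_format="%.6g")


class OtuStabilityScreen:
    """Screen every (sufficiently variable) OTU for within-group stability.

    Parameters
    ----------
    table : CommunityTable
        Counts or proportions; converted to proportions internally.
    metadata : pandas.DataFrame
        Sample metadata indexed by sample id.
    comparison : str
        An individual-identity comparison name (e.g.
        ``adult_within_individual_within_year``).
    log10_var_threshold : float
        Independent-filter threshold on log10 across-sample variance of
        relative abundance (OTUs at or below are skipped, default -8).
    """

    def __init__(self, table: CommunityTable, metadata: pd.DataFrame,
                 comparison: str = "adult_within_individual_within_year",
                 log10_var_threshold: float = -8.0,
                 exclude_extra_pair: bool = False,
                 exclude_parasitic: bool = False):
        self.table = table if table.mode == "proportions" else to_proportions(table)
        self.metadata = metadata.loc[self.table.sample_ids]
        self.comparison = comparison
        self.log10_var_threshold = log10_var_threshold
        self.design = build_pair_design(
            self.metadata, comparison,
            exclude_extra_pair=exclude_extra_pair,
            exclude_parasitic=exclude_parasitic)

    def fit(self, n_perm: int = 999, seed: int = 0,
            q_method: str = "storey") -> OtuScreenResults:
        """Run the screen; per-OTU seeds are ``seed + otu index`` for
        reproducibility."""
        values = self.table.values
        var = values.var(axis=1, ddof=1)
        passed = var > 10.0 ** self.log10_var_threshold
        if not passed.any():
            raise ValueError("variance filter removed all OTUs")
        pairs = (self.design.i, self.design.j)
        records = []
        for k, otu in enumerate(self.table.otu_ids):
            rec = {"otu_id": otu, "mean_abundance": float(values[k].mean()),
                   "passed_filter": bool(passed[k]),
                   "observed_diff": np.nan, "cliffs_d": np.nan,
                   "p_value": np.nan}
            if passed[k]:
                d = per_otu_bray_curtis_values(values[k], pairs=pairs)
                test = StabilityPermutationTest.from_pair_values(d, self.design)
                res = test.fit(n_perm=n_perm, seed=seed + k)
                rec.update(observed_diff=res.observed_diff,
                           cliffs_d=res.cliffs_d, p_value=res.p_value)
            records.append(rec)
        frame = pd.DataFrame(records).set_index("otu_id")
        frame["q_value"] = np.nan
        tested = frame["passed_filter"].to_numpy()
        frame.loc[tested, "q_value"] = qvalues(
            frame.loc[tested, "p_value"].to_numpy(), method=q_method)
        frame = frame.sort_values(["q_value", "p_value"], na_position="last")
        frame = frame[["observed_diff", "cliffs_d", "p_value", "q_value",
                       "mean_abundance", "passed_filter"]]
        return OtuScreenResults(frame, self.comparison, q_method)


def stable_subset_reanalysis(table: CommunityTable, metadata, stable_otu_ids,
                             comparison: str, metric: str = "bray_curtis",
                             tree=None, n_perm: int = 9999,
                             seed=None) -> PermutationTestResults:
    """Re-run the whole-community test on the stable-OTU subset only.

    The table is restricted to ``stable_otu_ids``, re-normalised to
    proportions and passed through the usual pipeline; restricting to all
    OTUs reproduces the full analysis exactly.
    """
    ids = list(stable_otu_ids)
    if not ids:
        raise ValueError("stable OTU set is empty")
    missing = [o for o in ids if o not in set(table.otu_ids)]
    if missing:
        raise KeyError(f"unknown OTU id(s): {missing[:5]}")
    sub = table.subset_otus(ids)
    colsums = sub.values.sum(axis=0)
    zero = np.flatnonzero(colsums == 0)
    if zero.size:
        names = [sub.sample_ids[z] for z in zero]
        raise ValueError(
            f"stable subset leaves sample(s) empty: {names}")
    if metric in ("bray_curtis", "weighted_unifrac"):
        frame = pd.DataFrame(sub.values / colsums, index=sub.data.index,
                             columns=sub.data.columns)
        sub = CommunityTable(frame, mode="proportions")
    elif sub.mode != "counts":
        raise ValueError(f"{metric} reanalysis requires a counts table")
    return run_comparison(sub, metadata, comparison, metric=metric,
                          tree=tree, n_perm=n_perm, seed=seed)
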