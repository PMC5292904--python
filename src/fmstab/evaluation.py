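"""Simulation-based validation of the analysis pipeline.

Each routine simulates datasets under a named study condition (see
:func:`fmstab.simulate.preset_configs`), pushes them through the ordinary
analysis surface and measures an operating characteristic: type-I error
calibration under the null, power and screening accuracy under planted
stability, maternal-effect recovery, co-occurrence block recovery and
false-edge control, and the adult:juvenile richness contrast. These are the
quantities the package's acceptance checks and reproduction script compute.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .community import to_proportions, rarefy
from .comparisons import COMPARISONS, build_pair_design
from .diversity import alpha_diversity_table
from .network import CooccurrenceAnalysis
from .permutation import METRICS, StabilityPermutationTest, \
    dissimilarity_for_metric, run_comparison
from .screen import OtuStabilityScreen
from .simulate import preset_configs, simulate_community

__all__ = [
    "null_calibration", "stability_power", "screen_auc", "maternal_recovery",
    "network_block_recovery", "network_null_edge_rate", "age_contrast_ratio",
]


def _spawn_seeds(seed, n):
    return [int(s) for s in
            np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)]


def null_calibration(n_reps: int = 200, n_perm: int = 199, seed: int = 0,
                     alpha: float = 0.05) -> pd.DataFrame:
    """Rejection counts of every comparison x metric under the null preset.

    Returns a DataFrame indexed by comparison with one column per metric,
    holding rejection counts out of ``n_reps`` (nominal rate ``alpha``).
    """
    cfg = preset_configs()["null"]
    counts = {(c, m): 0 for c in COMPARISONS for m in METRICS}
    designs = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for rep_seed in _spawn_seeds(seed, n_reps):
            sub = _spawn_seeds(rep_seed, 3)
            table, meta, tree, _ = simulate_community(cfg, seed=sub[0])
            if designs is None:
                designs = {c: build_pair_design(meta, c) for c in COMPARISONS}
            dms = {m: dissimilarity_for_metric(table, m, tree=tree,
                                               seed=sub[1])
                   for m in METRICS}
            prng = np.random.default_rng(sub[2])
            for m in METRICS:
                for c in COMPARISONS:
                    res = StabilityPermutationTest(dms[m], designs[c]).fit(
                        n_perm=n_perm, seed=int(prng.integers(2 ** 31)))
                    if res.p_value <= alpha:
                        counts[(c, m)] += 1
    frame = pd.DataFrame(
        {m: [counts[(c, m)] for c in COMPARISONS] for m in METRICS},
        index=list(COMPARISONS))
    frame.attrs["n_reps"] = n_reps
    return frame


def stability_power(n_reps: int = 50, n_perm: int = 199, seed: int = 0,
                    alpha: float = 0.05) -> dict:
    """Rejection rates of the Bray-Curtis individual-identity tests under
    the stability preset (ICC 0.6 on 40/150 OTUs)."""
    cfg = preset_configs()["stability"]
    rej = {"adult": 0, "juvenile": 0}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for rep_seed in _spawn_seeds(seed, n_reps):
            sub = _spawn_seeds(rep_seed, 3)
            table, meta, tree, _ = simulate_community(cfg, seed=sub[0])
            res = run_comparison(table, meta,
                                 "adult_within_individual_within_year",
                                 metric="bray_curtis", n_perm=n_perm,
                                 seed=sub[1])
            rej["adult"] += res.p_value <= alpha
            res = run_comparison(table, meta, "juv_within_individual",
                                 metric="bray_curtis", n_perm=n_perm,
                                 seed=sub[2])
            rej["juvenile"] += res.p_value <= alpha
    return {k: v / n_reps for k, v in rej.items()}


def screen_auc(n_reps: int = 20, n_perm: int = 499, seed: int = 0) -> float:
    """Mean ROC-AUC of the per-OTU screen's (-p) ranking against the planted
    stable-OTU truth under the stability preset."""
    cfg = preset_configs()["stability"]
    aucs = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for rep_seed in _spawn_seeds(seed, n_reps):
            sub = _spawn_seeds(rep_seed, 2)
            table, meta, tree, truth = simulate_community(cfg, seed=sub[0])
            screen = OtuStabilityScreen(
                table, meta, comparison="adult_within_individual_within_year")
            frame = screen.fit(n_perm=n_perm, seed=sub[1]).frame
            tested = frame[frame["passed_filter"]]
            is_stable = tested.index.isin(truth.stable_otu_ids)
            if is_stable.all() or not is_stable.any():
                continue
            score = -tested["p_value"].to_numpy()
            u = stats.mannwhitneyu(score[is_stable], score[~is_stable],
                                   alternative="greater").statistic
            aucs.append(u / (is_stable.sum() * (~is_stable).sum()))
    return float(np.mean(aucs))


def maternal_recovery(n_reps: int = 50, n_perm: int = 199, seed: int = 0,
                      alpha: float = 0.05) -> dict:
    """Mother- vs father-offspring similarity under the maternal preset
    (tau = 0.5 applied to social mothers only)."""
    cfg = preset_configs()["maternal"]
    out = {"mother_rejections": 0, "father_rejections": 0, "mother_d": [],
           "father_d": []}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for rep_seed in _spawn_seeds(seed, n_reps):
            sub = _spawn_seeds(rep_seed, 3)
            table, meta, tree, _ = simulate_community(cfg, seed=sub[0])
            res = run_comparison(table, meta, "offspring_vs_mother",
                                 metric="bray_curtis", n_perm=n_perm,
                                 seed=sub[1])
            out["mother_rejections"] += res.p_value <= alpha
            out["mother_d"].append(res.cliffs_d)
            res = run_comparison(table, meta, "offspring_vs_father",
                                 metric="bray_curtis", n_perm=n_perm,
                                 seed=sub[2])
            out["father_rejections"] += res.p_value <= alpha
            out["father_d"].append(res.cliffs_d)
    return {
        "mother_rejection_rate": out["mother_rejections"] / n_reps,
        "father_rejection_rate": out["father_rejections"] / n_reps,
        "mother_median_cliffs_d": float(np.median(out["mother_d"])),
        "father_median_cliffs_d": float(np.median(out["father_d"])),
    }


def _cooccurrence_fit(table, n_perm, seed):
    # cohorts are statistically identical under the network presets, so all
    # samples contribute to the co-occurrence fit
    return CooccurrenceAnalysis(to_proportions(table)).fit(
        n_perm=n_perm, seed=seed)


def network_block_recovery(n_reps: int = 20, n_perm: int = 2999,
                           seed: int = 0) -> float:
    """Fraction of replicates where the planted block OTUs occupy the top
    degrees (min block degree strictly above max non-block degree)."""
    cfg = preset_configs()["network"]
    hits = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for rep_seed in _spawn_seeds(seed, n_reps):
            sub = _spawn_seeds(rep_seed, 2)
            table, meta, tree, truth = simulate_community(cfg, seed=sub[0])
            res = _cooccurrence_fit(table, n_perm, sub[1])
            deg = res.network.degrees
            block = {table.otu_ids[k] for b in truth.block_memberships
                     for k in b}
            block_deg = deg[deg.index.isin(block)]
            other_deg = deg[~deg.index.isin(block)]
            if block_deg.min() > other_deg.max():
                hits += 1
    return hits / n_reps


def network_null_edge_rate(n_reps: int = 50, n_perm: int = 299,
                           seed: int = 0, alpha: float = 0.05) -> float:
    """Mean q < alpha edge fraction among defined pairs with no planted
    association (loading 0)."""
    from dataclasses import replace
    cfg = replace(preset_configs()["network"], block_loading=0.0, blocks=())
    rates = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for rep_seed in _spawn_seeds(seed, n_reps):
            sub = _spawn_seeds(rep_seed, 2)
            table, meta, tree, _ = simulate_community(cfg, seed=sub[0])
            res = _cooccurrence_fit(table, n_perm, sub[1])
            q = res.q.to_numpy()
            iu, ju = np.triu_indices(q.shape[0], k=1)
            vals = q[iu, ju]
            vals = vals[np.isfinite(vals)]
            if vals.size:
                rates.append(np.mean(vals < alpha))
    return float(np.mean(rates))


def age_contrast_ratio(n_reps: int = 5, seed: int = 0) -> float:
    """Mean adult:juvenile observed-OTU richness ratio (after rarefaction)
    under the age-contrast preset."""
    cfg = preset_configs()["age_contrast"]
    ratios = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for rep_seed in _spawn_seeds(seed, n_reps):
            sub = _spawn_seeds(rep_seed, 2)
            table, meta, tree, _ = simulate_community(cfg, seed=sub[0])
            rare = rarefy(table, seed=sub[1])
            alpha_frame = alpha_diversity_table(rare)
            obs = alpha_frame["observed_otus"]
            adults = obs[meta["cohort"] == "adult"].mean()
            juv = obs[meta["cohort"] == "juvenile"].mean()
            ratios.append(adults / juv)
    return float(np.mean(ratios))
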