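"""Hierarchical synthetic community generator with known ground truth.

Emulates a multi-colony, multi-nest, repeat-sampled fecal-microbiota study:
adults sampled repeatedly within (and across) breeding seasons, juveniles
sampled at fixed age-classes within nests, social mother/father links, and
optional extra-pair / parasitic flags. Counts follow a log-linear
compositional model: for sample ``s`` and OTU ``k``

    eta_sk = mu_k + cohort_shift_k + colony + nest + year
             + a_{i(s),k} + lambda * f_block(s) + e_sk

where ``a`` is a persistent per-individual effect (one draw per
individual x OTU; zero for unstable OTUs; correlated between social mother
and offspring with correlation tau), ``e`` is fresh transient noise per
sample, and block factors induce planted co-occurrence structure. Relative
abundances are softmax(eta) over OTUs (with a structural-zero OTU subset in
juveniles producing the adult/juvenile richness contrast) and counts are
multinomial draws at log-normally distributed sequencing depths. The
per-OTU intraclass correlation is ICC = sigma_ind^2 / (sigma_ind^2 +
sigma_samp^2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .community import CommunityTable
from .trees import read_tree_string

__all__ = ["SimConfig", "SimTruth", "simulate_tree", "simulate_community",
           "preset_configs"]


@dataclass
class SimConfig:
    """Parameters of the hierarchical community simulator.

    All effect magnitudes are standard deviations on the natural-log relative
    abundance scale. Defaults describe a small three-colony study with
    repeat-sampled adults (two seasons) and nest-reared juveniles (one
    season) and *no* structuring effects: add stability, maternal, block or
    cohort effects via the presets or by overriding fields.
    """

    n_otus: int = 150
    n_colonies: int = 3
    nests_per_colony: int = 2
    juveniles_per_nest: int = 2
    n_adults: int = 12
    samples_per_individual: int = 2      # adult samples per year
    n_years: int = 2
    juvenile_age_classes: tuple = (6, 9, 12)
    depth_lognorm_mean: float = float(np.log(10_000.0))
    depth_lognorm_sigma: float = 0.3
    sigma_base: float = 2.0              # spread of baseline log abundances
    sigma_ind: float = 0.0               # persistent individual effect (stable OTUs)
    sigma_samp: float = 1.0              # transient per-sample noise
    fraction_stable_otus: float = 0.0
    adult_shift_scale: float = 0.0       # cohort effect sd on a subset of OTUs
    adult_shift_fraction: float = 0.25
    juvenile_zero_fraction: float = 0.0  # fraction of OTUs structurally absent in juveniles
    sigma_nest: float = 0.0
    sigma_col: float = 0.0
    sigma_year: float = 0.0
    maternal_tau: float = 0.0
    blocks: tuple = ()                   # tuples of OTU indices sharing a latent factor
    block_loading: float = 0.0
    # block members get this fixed modest baseline so planted co-variation
    # stays a minor share of total mass and does not couple all other OTUs
    # through the compositional denominator
    block_baseline: float = -1.0
    extra_pair_fraction: float = 0.0
    parasitic_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("sigma_base", "sigma_ind", "sigma_samp", "sigma_nest",
                     "sigma_col", "sigma_year", "adult_shift_scale",
                     "block_loading"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("fraction_stable_otus", "juvenile_zero_fraction",
                     "maternal_tau", "adult_shift_fraction",
                     "extra_pair_fraction", "parasitic_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_otus < 2:
            raise ValueError("n_otus must be >= 2")
        females = self.n_adults // self.n_colonies // 2
        if self.nests_per_colony > 0 and females == 0:
            raise ValueError("need at least 2 adults per colony to staff nests")
        for block in self.blocks:
            if any(k >= self.n_otus for k in block):
                raise ValueError("block member index out of range")

    @property
    def icc(self) -> float:
        denom = self.sigma_ind ** 2 + self.sigma_samp ** 2
        return self.sigma_ind ** 2 / denom if denom else 0.0


@dataclass
class SimTruth:
    """Ground truth accompanying one simulated dataset."""

    stable_otu_ids: list
    icc: np.ndarray                       # per-OTU ICC
    individual_effects: pd.DataFrame      # individuals x OTUs persistent effects
    block_memberships: tuple
    tau: float
    juvenile_zero_otu_ids: list = field(default_factory=list)


def simulate_tree(n_otus: int, seed=None):
    """Random coalescent-style rooted tree with exponential branch lengths."""
    if n_otus < 2:
        raise ValueError("n_otus must be >= 2")
    rng = np.random.default_rng(seed)
    nodes = [f"otu_{k + 1}" for k in range(n_otus)]
    newicks = {name: name for name in nodes}
    active = list(nodes)
    while len(active) > 1:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[i], active[j]
        la, lb = rng.exponential(0.5, size=2)
        merged = f"({newicks.pop(a)}:{la:.6f},{newicks.pop(b)}:{lb:.6f})"
        key = f"{a}+{b}"
        newicks[key] = merged
        active = [x for x in active if x not in (a, b)] + [key]
    return read_tree_string(newicks[active[0]] + ";")


def _softmax_rows(eta: np.ndarray) -> np.ndarray:
    z = eta - eta.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def simulate_community(config: SimConfig, seed=None):
    """Simulate ``(counts table, metadata, tree, truth)`` for one dataset.

    ``seed`` overrides ``config.seed``; identical (config, seed) pairs give
    bit-identical outputs. All randomness flows from one SeedSequence so the
    tree, effects and counts are independently reproducible.
    """
    config.validate()
    master = np.random.SeedSequence(config.seed if seed is None else seed)
    ss_tree, ss_effects, ss_counts = master.spawn(3)
    rng = np.random.default_rng(ss_effects)

    K = config.n_otus
    otu_ids = [f"otu_{k + 1}" for k in range(K)]
    tree = simulate_tree(K, seed=ss_tree)

    # --- hosts -------------------------------------------------------------
    colonies = [f"C{c + 1}" for c in range(config.n_colonies)]
    years = [2013 + y for y in range(config.n_years)]
    juv_year = years[-1]

    adults = []
    per_colony = config.n_adults // config.n_colonies
    extra = config.n_adults - per_colony * config.n_colonies
    a = 0
    for c, colony in enumerate(colonies):
        n_here = per_colony + (1 if c < extra else 0)
        for k in range(n_here):
            adults.append({"individual_id": f"A{a + 1:03d}", "colony_id": colony,
                           "sex": "F" if k % 2 == 0 else "M"})
            a += 1
    adults = pd.DataFrame(adults)

    nests = []
    juveniles = []
    for colony in colonies:
        here = adults[adults["colony_id"] == colony]
        females = here[here["sex"] == "F"]["individual_id"].tolist()
        males = here[here["sex"] == "M"]["individual_id"].tolist()
        if config.nests_per_colony > (0 if not females else len(females)) or \
           config.nests_per_colony > (0 if not males else len(males)):
            raise ValueError(
                f"colony {colony}: not enough adult females/males to staff "
                f"{config.nests_per_colony} nest(s)")
        for t in range(config.nests_per_colony):
            nest_id = f"{colony}_N{t + 1}"
            mother, father = females[t], males[t]
            nests.append({"nest_id": nest_id, "colony_id": colony,
                          "mother": mother, "father": father})
            for u in range(config.juveniles_per_nest):
                juveniles.append({
                    "individual_id": f"J_{nest_id}_{u + 1}",
                    "colony_id": colony, "nest_id": nest_id,
                    "mother": mother, "father": father,
                })
    juveniles = pd.DataFrame(juveniles) if juveniles else pd.DataFrame(
        columns=["individual_id", "colony_id", "nest_id", "mother", "father"])
    if len(juveniles):
        juveniles["is_extra_pair"] = rng.random(len(juveniles)) < config.extra_pair_fraction
        juveniles["is_parasitic"] = rng.random(len(juveniles)) < config.parasitic_fraction

    # --- OTU-level effects -------------------------------------------------
    mu = rng.normal(0.0, config.sigma_base, K)
    for block in config.blocks:
        mu[list(block)] = config.block_baseline
    n_stable = int(round(config.fraction_stable_otus * K))
    stable_idx = np.sort(rng.choice(K, size=n_stable, replace=False))
    stable_mask = np.zeros(K, bool)
    stable_mask[stable_idx] = True
    sigma_ind_k = np.where(stable_mask, config.sigma_ind, 0.0)

    shift = np.zeros(K)
    if config.adult_shift_scale > 0:
        n_shift = int(round(config.adult_shift_fraction * K))
        shift_idx = rng.choice(K, size=n_shift, replace=False)
        shift[shift_idx] = rng.normal(0.0, config.adult_shift_scale, n_shift)

    n_zero = int(round(config.juvenile_zero_fraction * K))
    juv_zero_idx = np.sort(rng.choice(K, size=n_zero, replace=False))
    juv_present = np.ones(K, bool)
    juv_present[juv_zero_idx] = False

    colony_eff = {c: rng.normal(0.0, config.sigma_col, K) for c in colonies}
    year_eff = {y: rng.normal(0.0, config.sigma_year, K) for y in years}
    nest_eff = {n["nest_id"]: rng.normal(0.0, config.sigma_nest, K)
                for n in nests}

    # persistent individual effects; offspring correlated with social mother
    ind_effects = {}
    for ind in adults["individual_id"]:
        ind_effects[ind] = sigma_ind_k * rng.normal(0.0, 1.0, K)
    tau = config.maternal_tau
    for _, row in juveniles.iterrows():
        fresh = sigma_ind_k * rng.normal(0.0, 1.0, K)
        ind_effects[row["individual_id"]] = (
            tau * ind_effects[row["mother"]] + np.sqrt(1.0 - tau ** 2) * fresh)

    # --- samples -----------------------------------------------------------
    records = []
    for _, ad in adults.iterrows():
        for y in years:
            for r in range(config.samples_per_individual):
                records.append({
                    "individual_id": ad["individual_id"], "cohort": "adult",
                    "age_class": pd.NA, "nest_id": pd.NA,
                    "colony_id": ad["colony_id"], "year": y,
                    "sampling_date": int(rng.integers(130, 221)),
                    "social_mother_id": pd.NA, "social_father_id": pd.NA,
                    "is_extra_pair": False, "is_parasitic": False,
                    "sex": ad["sex"],
                })
    for _, jv in juveniles.iterrows():
        hatch = int(rng.integers(150, 191))
        for age in config.juvenile_age_classes:
            records.append({
                "individual_id": jv["individual_id"], "cohort": "juvenile",
                "age_class": int(age), "nest_id": jv["nest_id"],
                "colony_id": jv["colony_id"], "year": juv_year,
                "sampling_date": hatch + int(age),
                "social_mother_id": jv["mother"],
                "social_father_id": jv["father"],
                "is_extra_pair": bool(jv["is_extra_pair"]),
                "is_parasitic": bool(jv["is_parasitic"]),
                "sex": pd.NA,
            })
    metadata = pd.DataFrame(records)
    metadata.index = [f"S{i + 1:04d}" for i in range(len(metadata))]
    metadata.index.name = "sample_id"
    n_samples = len(metadata)

    # --- linear predictor, probabilities, counts ---------------------------
    crng = np.random.default_rng(ss_counts)
    eta = np.empty((n_samples, K))
    block_factors = {tuple(b): crng.normal(0.0, 1.0, n_samples)
                     for b in config.blocks}
    is_juv = (metadata["cohort"] == "juvenile").to_numpy()
    for s in range(n_samples):
        row = metadata.iloc[s]
        e = mu.copy()
        e += colony_eff[row["colony_id"]]
        e += year_eff[row["year"]]
        if not is_juv[s]:
            e += shift
        elif not pd.isna(row["nest_id"]):
            e += nest_eff[row["nest_id"]]
        e += ind_effects[row["individual_id"]]
        for block, f in block_factors.items():
            e[list(block)] += config.block_loading * f[s]
        e += crng.normal(0.0, config.sigma_samp, K)
        eta[s] = e

    probs = _softmax_rows(eta)
    if n_zero:
        probs[np.ix_(is_juv, ~juv_present)] = 0.0
        norm = probs.sum(axis=1, keepdims=True)
        if (norm == 0).any():
            raise ValueError("structural zeros removed all OTUs from a sample")
        probs = probs / norm

    depths = np.maximum(
        crng.lognormal(config.depth_lognorm_mean, config.depth_lognorm_sigma,
                       n_samples).astype(int), 100)
    counts = np.empty((K, n_samples), dtype=float)
    for s in range(n_samples):
        counts[:, s] = crng.multinomial(depths[s], probs[s])

    table = CommunityTable(
        pd.DataFrame(counts, index=otu_ids, columns=metadata.index),
        mode="counts")

    icc = np.where(stable_mask, config.icc, 0.0)
    truth = SimTruth(
        stable_otu_ids=[otu_ids[k] for k in stable_idx],
        icc=icc,
        individual_effects=pd.DataFrame(ind_effects, index=otu_ids).T,
        block_memberships=tuple(tuple(b) for b in config.blocks),
        tau=tau,
        juvenile_zero_otu_ids=[otu_ids[k] for k in juv_zero_idx],
    )
    _warn_empty_designs(metadata)
    return table, metadata, tree, truth


def _warn_empty_designs(metadata: pd.DataFrame) -> None:
    from .comparisons import COMPARISONS, build_pair_design
    empty = []
    for name in COMPARISONS:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                build_pair_design(metadata, name)
        except ValueError:
            empty.append(name)
    if empty:
        warnings.warn(
            f"simulated metadata yields empty designs for: {empty}", UserWarning)


_ICC_06_SIGMA_IND = float(np.sqrt(1.5))  # ICC 0.6 with sigma_samp = 1


def preset_configs() -> dict:
    """Named study conditions used throughout testing and validation.

    ``null``
        No structuring effects at all; every stability test should be
        calibrated.
    ``stability``
        40 of 150 OTUs persistent at ICC 0.6; 12 adults x 2 within-season
        samples plus 12 juveniles x 2 age-classes.
    ``maternal``
        Stability effects plus mother-offspring correlation tau = 0.5 of the
        persistent vectors (social fathers uncorrelated).
    ``network``
        Two planted 5-OTU co-occurrence blocks (loading 2.0) in a 30-OTU
        community; no host-structure effects.
    ``age_contrast``
        Half the OTU pool structurally absent from juveniles, targeting a
        roughly two-fold adult:juvenile richness contrast.
    """
    base = SimConfig()
    stability = replace(
        base, n_years=1, samples_per_individual=2,
        juvenile_age_classes=(6, 9),
        fraction_stable_otus=40 / 150, sigma_ind=_ICC_06_SIGMA_IND)
    maternal = replace(
        stability, n_adults=18, nests_per_colony=3, maternal_tau=0.5)
    # 60 OTUs: large enough that two 5-OTU blocks do not dominate the
    # compositional denominator, small enough that permutation q-values can
    # fall below 0.05 (the p floor 1/(n_perm+1) must be well under
    # alpha * k / n_pairs for any FDR discovery)
    network = replace(
        base, n_otus=60, n_years=1,
        blocks=(tuple(range(0, 5)), tuple(range(5, 10))), block_loading=2.0)
    age_contrast = replace(base, n_years=1, juvenile_zero_fraction=0.5)
    presets = {
        "null": base,
        "stability": stability,
        "maternal": maternal,
        "network": network,
        "age_contrast": age_contrast,
    }
    for cfg in presets.values():
        cfg.validate()
    return presets
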