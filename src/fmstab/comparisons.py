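"""Classification of sample pairs into focal / reference / excluded sets.

Each named comparison asks whether community dissimilarity within some host
grouping (same individual, same nest, same colony, same year, or offspring
vs. its social parent) is lower than between groups. A :class:`PairDesign`
assigns every unordered sample pair a role and a permutation stratum; pairs
irrelevant to the comparison, or capable of biasing it (e.g. adult-juvenile
pairs in an adult comparison, cross-colony pairs when colony is not the
contrast), are excluded before testing. The concrete rules are a
reconstruction from the published comparison tables and figure captions:

``adult_within_individual_within_year``
    focal: same adult individual, same year; reference: different adults,
    same colony, same year; strata: colony x year.
``adult_within_individual_among_years``
    focal: same adult, different years; reference: different adults, same
    colony, different years; strata: colony.
``adult_within_colony``
    focal: different adults, same colony, same year; reference: different
    adults, different colonies, same year; strata: year.
``adult_within_year``
    focal: different adults, same colony, same year; reference: different
    adults, same colony, different years; strata: colony.
``juv_within_individual``
    focal: same juvenile, different age-classes; reference: different
    juveniles, same nest, different age-classes; strata: nest.
``juv_within_nest``
    focal: different juveniles, same nest, same age-class; reference:
    different juveniles, different nests, same colony, same age-class;
    strata: colony x age-class.
``juv_within_colony``
    focal: juveniles from different nests, same colony, same age-class;
    reference: different colonies, same age-class; strata: age-class.
``offspring_vs_mother`` / ``offspring_vs_father``
    focal: juvenile paired with its social mother (father); reference: the
    same juvenile paired with other adult females (males) from the same
    colony and year; strata: juvenile identity. Parasitic (extra-pair) young
    can be excluded via options.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["COMPARISONS", "ADULT_COMPARISONS", "JUVENILE_COMPARISONS",
           "PARENTAGE_COMPARISONS", "PairDesign", "build_pair_design"]

ADULT_COMPARISONS = (
    "adult_within_individual_within_year",
    "adult_within_individual_among_years",
    "adult_within_colony",
    "adult_within_year",
)
JUVENILE_COMPARISONS = (
    "juv_within_individual",
    "juv_within_nest",
    "juv_within_colony",
)
PARENTAGE_COMPARISONS = ("offspring_vs_mother", "offspring_vs_father")
COMPARISONS = ADULT_COMPARISONS + JUVENILE_COMPARISONS + PARENTAGE_COMPARISONS

#: comparisons whose focal set is defined by individual identity
INDIVIDUAL_COMPARISONS = (
    "adult_within_individual_within_year",
    "adult_within_individual_among_years",
    "juv_within_individual",
)


@dataclass
class PairDesign:
    """Role and stratum of every unordered sample pair for one comparison."""

    comparison: str
    sample_ids: list
    i: np.ndarray            # first-sample index per pair (i < j)
    j: np.ndarray
    role: np.ndarray         # "focal" | "reference" | "excluded"
    stratum: np.ndarray      # stratum label ("" for excluded pairs)

    @property
    def n_focal(self) -> int:
        return int(np.sum(self.role == "focal"))

    @property
    def n_reference(self) -> int:
        return int(np.sum(self.role == "reference"))

    def to_frame(self) -> pd.DataFrame:
        ids = np.asarray(self.sample_ids, dtype=object)
        return pd.DataFrame({
            "sample_i": ids[self.i], "sample_j": ids[self.j],
            "role": self.role, "stratum": self.stratum,
        })

    def included(self):
        """(pair indices, strata codes) of the non-excluded pairs."""
        mask = self.role != "excluded"
        return np.flatnonzero(mask)


def _codes(series: pd.Series) -> np.ndarray:
    return pd.factorize(series.astype(object).where(series.notna(), None))[0]


def build_pair_design(metadata: pd.DataFrame, comparison: str,
                      exclude_extra_pair: bool = False,
                      exclude_parasitic: bool = False) -> PairDesign:
    """Classify all unordered sample pairs of ``metadata`` for one comparison.

    ``metadata`` must be indexed by sample id (see :mod:`fmstab.metadata`).
    Raises if the comparison yields no focal or no reference pairs.
    """
    if comparison not in COMPARISONS:
        raise ValueError(
            f"unknown comparison {comparison!r}; valid names: {list(COMPARISONS)}"
        )
    samples = list(metadata.index)
    n = len(samples)
    iu, ju = np.triu_indices(n, k=1)

    juv = (metadata["cohort"] == "juvenile").to_numpy()
    ind = _codes(metadata["individual_id"])
    colony = _codes(metadata["colony_id"])
    year = metadata["year"].to_numpy(int)
    nest = _codes(metadata["nest_id"]) if "nest_id" in metadata else np.full(n, -1)
    age = metadata["age_class"].to_numpy(object) if "age_class" in metadata else np.full(n, None)
    age = np.array([-1 if pd.isna(a) else int(a) for a in age])

    both_adult = ~juv[iu] & ~juv[ju]
    both_juv = juv[iu] & juv[ju]
    same_ind = ind[iu] == ind[ju]
    same_year = year[iu] == year[ju]
    same_col = colony[iu] == colony[ju]
    same_nest = (nest[iu] == nest[ju]) & (nest[iu] >= 0)
    same_age = (age[iu] == age[ju]) & (age[iu] >= 0)

    role = np.full(iu.size, "excluded", dtype=object)
    stratum = np.full(iu.size, "", dtype=object)

    def label(mask, parts):
        out = parts[0].astype(str)
        for p in parts[1:]:
            out = np.char.add(np.char.add(out, "|"), p.astype(str))
        stratum[mask] = out[mask]

    col_s = colony[iu]  # stratum building blocks (same on both ends when used)
    year_s = year[iu]
    nest_s = nest[iu]
    age_s = age[iu]

    if comparison == "adult_within_individual_within_year":
        base = both_adult & same_year
        focal = base & same_ind
        ref = base & ~same_ind & same_col
        strata_parts = (col_s, year_s)
    elif comparison == "adult_within_individual_among_years":
        base = both_adult & ~same_year & same_col
        focal = base & same_ind
        ref = base & ~same_ind
        strata_parts = (col_s,)
    elif comparison == "adult_within_colony":
        base = both_adult & same_year & ~same_ind
        focal = base & same_col
        ref = base & ~same_col
        strata_parts = (year_s,)
    elif comparison == "adult_within_year":
        base = both_adult & ~same_ind & same_col
        focal = base & same_year
        ref = base & ~same_year
        strata_parts = (col_s,)
    elif comparison == "juv_within_individual":
        base = both_juv & ~same_age & (age[iu] >= 0) & (age[ju] >= 0)
        focal = base & same_ind
        ref = base & ~same_ind & same_nest
        strata_parts = (nest_s,)
    elif comparison == "juv_within_nest":
        base = both_juv & ~same_ind & same_age
        focal = base & same_nest
        ref = base & ~same_nest & same_col
        strata_parts = (col_s, age_s)
    elif comparison == "juv_within_colony":
        base = both_juv & ~same_nest & same_age
        focal = base & same_col
        ref = base & ~same_col
        strata_parts = (age_s,)
    elif comparison in PARENTAGE_COMPARISONS:
        return _parentage_design(metadata, comparison, samples, iu, ju, juv,
                                 ind, colony, year, role, stratum,
                                 exclude_extra_pair, exclude_parasitic)
    role[ref] = "reference"
    role[focal] = "focal"
    label(focal | ref, strata_parts)

    design = PairDesign(comparison, samples, iu, ju, role, stratum)
    _check_nonempty(design)
    return design


def _parentage_design(metadata, comparison, samples, iu, ju, juv, ind, colony,
                      year, role, stratum, exclude_extra_pair, exclude_parasitic):
    n = len(samples)
    sex = metadata["sex"].astype(object).where(metadata["sex"].notna(), None).to_numpy()
    mother = metadata["social_mother_id"].astype(object).where(
        metadata["social_mother_id"].notna(), None).to_numpy()
    father = metadata["social_father_id"].astype(object).where(
        metadata["social_father_id"].notna(), None).to_numpy()
    indiv = metadata["individual_id"].to_numpy(object)
    extra = metadata["is_extra_pair"].to_numpy(bool)
    parasitic = metadata["is_parasitic"].to_numpy(bool)

    if comparison == "offspring_vs_mother":
        parent_of, adult_sex, drop_flag, do_drop = mother, "F", parasitic, exclude_parasitic
    else:
        parent_of, adult_sex, drop_flag, do_drop = father, "M", extra, exclude_extra_pair

    if not any(parent_of[k] is not None for k in range(n) if juv[k]):
        raise ValueError(
            f"{comparison} requires social-parent links; none present in metadata"
        )

    mixed = juv[iu] ^ juv[ju]
    juv_idx = np.where(juv[iu], iu, ju)
    ad_idx = np.where(juv[iu], ju, iu)

    has_parent = np.array([parent_of[k] is not None for k in juv_idx])
    right_sex = np.array([sex[k] == adult_sex for k in ad_idx])
    same_col = colony[juv_idx] == colony[ad_idx]
    same_year = year[juv_idx] == year[ad_idx]
    is_parent = np.array(
        [parent_of[a] == indiv[b] for a, b in zip(juv_idx, ad_idx)]
    )
    keep_juv = ~np.array([drop_flag[k] for k in juv_idx]) if do_drop \
        else np.ones(iu.size, bool)

    base = mixed & has_parent & right_sex & same_col & same_year & keep_juv
    focal = base & is_parent
    ref = base & ~is_parent
    role[ref] = "reference"
    role[focal] = "focal"
    juv_label = np.array([str(indiv[k]) for k in juv_idx], dtype=object)
    stratum[focal | ref] = juv_label[focal | ref]

    design = PairDesign(comparison, samples, iu, ju, role, stratum)
    _check_nonempty(design)
    return design


def _check_nonempty(design: PairDesign) -> None:
    if design.n_focal == 0:
        raise ValueError(f"{design.comparison}: no focal pairs")
    if design.n_reference == 0:
        raise ValueError(f"{design.comparison}: no reference pairs")
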