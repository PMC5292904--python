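"""OTU-table container with normalisation, rarefaction and subsetting utilities.

The central object is :class:`CommunityTable`, an OTU x sample matrix of
counts, proportions or presence flags. All downstream dissimilarity and
permutation machinery consumes this container. Abundance-based metrics
(Bray-Curtis, weighted UniFrac) are computed on sample-wise proportions;
presence-based metrics (binary Jaccard, unweighted UniFrac) on counts rarefied
to a common depth, mirroring the usual split in amplicon workflows where
proportion normalisation is not meaningful for presence/absence analysis.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "CommunityTable",
    "read_otu_table",
    "write_otu_table",
    "to_proportions",
    "rarefy",
    "filter_low_variance_otus",
    "select_one_sample_per_individual",
]

_MODES = ("counts", "proportions", "presence")
_PROP_TOL = 1e-9


class CommunityTable:
    """OTU x sample abundance matrix.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows indexed by OTU id, columns by sample id, non-negative values.
    mode : {"counts", "proportions", "presence"}
        Interpretation of the values. In ``proportions`` mode every column
        must sum to 1 (within 1e-9); all-zero columns are forbidden.
    """

    def __init__(self, data: pd.DataFrame, mode: str = "counts",
                 validate_sums: bool = True):
        if mode not in _MODES:
            raise ValueError(f"unknown mode {mode!r}; expected one of {_MODES}")
        if data.index.duplicated().any():
            dup = data.index[data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate OTU id: {dup}")
        if data.columns.duplicated().any():
            dup = data.columns[data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample id: {dup}")
        values = data.to_numpy(dtype=float)
        if values.size == 0:
            raise ValueError("no data rows")
        if np.isnan(values).any():
            r, c = np.argwhere(np.isnan(values))[0]
            raise ValueError(
                f"non-numeric cell at OTU {data.index[r]!r}, sample {data.columns[c]!r}"
            )
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative value at OTU {data.index[r]!r}, sample {data.columns[c]!r}"
            )
        if mode == "proportions" and validate_sums:
            colsums = values.sum(axis=0)
            bad = np.flatnonzero(np.abs(colsums - 1.0) > _PROP_TOL)
            if bad.size:
                raise ValueError(
                    "proportions columns must sum to 1: "
                    f"{[data.columns[b] for b in bad[:5]]}"
                )
        self.data = data.astype(float)
        self.mode = mode

    # -- basic introspection -------------------------------------------------
    @property
    def otu_ids(self) -> list:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def copy(self) -> "CommunityTable":
        return CommunityTable(self.data.copy(), self.mode)

    def subset_samples(self, sample_ids) -> "CommunityTable":
        return CommunityTable(self.data.loc[:, list(sample_ids)], self.mode)

    def subset_otus(self, otu_ids) -> "CommunityTable":
        return CommunityTable(self.data.loc[list(otu_ids)], self.mode)

    def __repr__(self):
        n_otu, n_samp = self.shape
        return f"CommunityTable({n_otu} OTUs x {n_samp} samples, mode={self.mode!r})"

    # -- I/O ------------------------------------------------------------------
    @classmethod
    def read_tsv(cls, path) -> "CommunityTable":
        raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        if raw.shape[0] == 0 or raw.shape[1] == 0:
            raise ValueError(f"no data rows in {path}")
        numeric = {}
        for col in raw.columns:
            converted = pd.to_numeric(raw[col], errors="coerce")
            bad = converted.isna() & raw[col].notna()
            if bad.any():
                row = raw.index[bad.to_numpy().argmax()]
                raise ValueError(
                    f"non-numeric cell at OTU {row!r}, sample {col!r} in {path}"
                )
            numeric[col] = converted
        frame = pd.DataFrame(numeric, index=raw.index)
        frame.index.name = "#OTU_ID"
        return cls(frame, mode="counts")

    def write_tsv(self, path) -> None:
        out = self.data.copy()
        out.index.name = "#OTU_ID"
        if self.mode == "counts":
            out = out.astype(int)
            out.to_csv(path, sep="\t")
        else:
            out.to_csv(path, sep="\t", float_format="%.12g")


def read_otu_table(path) -> CommunityTable:
    """Read a tab-separated OTU table (first column OTU ids, header sample ids)."""
    return CommunityTable.read_tsv(path)


def write_otu_table(table: CommunityTable, path) -> None:
    table.write_tsv(path)


def to_proportions(table: CommunityTable) -> CommunityTable:
    """Convert counts to sample-specific proportions (each column sums to 1)."""
    if table.mode != "counts":
        raise ValueError("to_proportions expects a counts-mode table")
    values = table.values
    colsums = values.sum(axis=0)
    zero = np.flatnonzero(colsums == 0)
    if zero.size:
        names = [table.sample_ids[z] for z in zero]
        raise ValueError(f"all-zero sample column(s): {names}")
    frame = pd.DataFrame(
        values / colsums, index=table.data.index, columns=table.data.columns
    )
    return CommunityTable(frame, mode="proportions")


def rarefy(table: CommunityTable, depth: int | None = None, seed=None) -> CommunityTable:
    """Subsample each sample without replacement to a common depth.

    Each column is drawn from a multivariate hypergeometric distribution, so
    every rarefied cell is bounded by the original cell and column sums equal
    ``depth`` exactly. Default depth is the minimum column sum.
    """
    if table.mode != "counts":
        raise ValueError("rarefy expects a counts-mode table")
    counts = np.rint(table.values).astype(np.int64)
    if not np.allclose(counts, table.values):
        raise ValueError("rarefy requires integer counts")
    colsums = counts.sum(axis=0)
    if depth is None:
        depth = int(colsums.min())
    depth = int(depth)
    if depth <= 0:
        raise ValueError("depth must be a positive integer")
    shallow = np.flatnonzero(colsums < depth)
    if shallow.size:
        names = [table.sample_ids[s] for s in shallow]
        raise ValueError(f"depth {depth} exceeds column sum for samples: {names}")
    rng = np.random.default_rng(seed)
    out = np.empty_like(counts)
    for j in range(counts.shape[1]):
        out[:, j] = rng.multivariate_hypergeometric(counts[:, j], depth)
    frame = pd.DataFrame(out, index=table.data.index, columns=table.data.columns)
    return CommunityTable(frame.astype(float), mode="counts")


def filter_low_variance_otus(
    table: CommunityTable, log10_var_threshold: float = -8.0
) -> CommunityTable:
    """Drop near-constant OTUs prior to per-OTU testing (independent filtering).

    Retains OTUs whose log10 across-sample variance of relative abundance is
    strictly greater than ``log10_var_threshold``; OTUs with identical
    proportions in every sample (variance 0) are always removed. The filter
    statistic does not look at any sample labels, so it preserves the type-I
    error of downstream identity tests.
    """
    if table.mode != "proportions":
        raise ValueError("variance filter expects a proportions-mode table")
    if table.shape[1] < 2:
        raise ValueError("variance filter needs at least 2 samples")
    var = table.values.var(axis=1, ddof=1)
    keep = var > 10.0 ** log10_var_threshold
    if not keep.any():
        raise ValueError("variance filter removed all OTUs")
    # per-OTU relative abundances are kept as-is (columns no longer sum to 1)
    return CommunityTable(table.data.loc[keep], mode="proportions",
                          validate_sums=False)


def select_one_sample_per_individual(table: CommunityTable, metadata: pd.DataFrame, seed=None):
    """Keep a single random sample per individual (pseudo-replication control).

    Returns the reduced ``(CommunityTable, metadata)`` pair; selection is
    uniform over each individual's samples and reproducible under ``seed``.
    """
    missing = [s for s in table.sample_ids if s not in metadata.index]
    if missing:
        raise ValueError(f"metadata missing samples: {missing[:5]}")
    rng = np.random.default_rng(seed)
    meta = metadata.loc[table.sample_ids]
    chosen = []
    for _, group in meta.groupby("individual_id", sort=True):
        samples = list(group.index)
        chosen.append(samples[rng.integers(len(samples))])
    keep = [s for s in table.sample_ids if s in set(chosen)]
    return table.subset_samples(keep), metadata.loc[keep]
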