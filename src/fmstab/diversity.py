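"""Alpha-diversity indices and the four community beta-dissimilarities.

Abundance-based dissimilarities (Bray-Curtis, weighted UniFrac) operate on
proportion-normalised tables; presence-based ones (binary Jaccard, unweighted
UniFrac) on rarefied counts. Pairwise distances are delegated to scipy and
scikit-bio; the package-specific per-OTU Bray-Curtis (the single-OTU statistic
behind the per-OTU stability screen) is implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.diversity import beta_diversity
from skbio.diversity.alpha import chao1

from .community import CommunityTable

__all__ = [
    "AlphaDiversityRecord",
    "alpha_diversity",
    "alpha_diversity_table",
    "bray_curtis_matrix",
    "jaccard_binary_matrix",
    "unweighted_unifrac_matrix",
    "weighted_unifrac_matrix",
    "per_otu_bray_curtis",
    "write_dissimilarity_tsv",
    "read_dissimilarity_tsv",
]


@dataclass(frozen=True)
class AlphaDiversityRecord:
    """Within-sample diversity: richness, Chao1, Shannon (nats), Good's coverage."""

    observed_otus: int
    chao1: float
    shannon: float
    goods_coverage: float


def alpha_diversity(counts) -> AlphaDiversityRecord:
    """Alpha-diversity record for one sample's count vector.

    ``observed_otus`` is the number of non-zero OTUs; Chao1 uses the
    bias-corrected estimator S + F1(F1-1)/(2(F2+1)); Shannon is -sum p ln p
    (natural log); Good's coverage is 1 - F1/N with F1 the singleton count.
    """
    x = np.asarray(counts, dtype=float)
    if x.sum() <= 0:
        raise ValueError("alpha diversity undefined for an all-zero sample")
    if (x < 0).any():
        raise ValueError("negative counts")
    nz = x[x > 0]
    p = nz / x.sum()
    f1 = int(np.sum(x == 1))
    return AlphaDiversityRecord(
        observed_otus=int(nz.size),
        chao1=float(chao1(x.astype(int), bias_corrected=True)),
        shannon=float(-(p * np.log(p)).sum()),
        goods_coverage=float(1.0 - f1 / x.sum()),
    )


def alpha_diversity_table(table: CommunityTable) -> pd.DataFrame:
    """Per-sample alpha diversity for a counts table."""
    if table.mode != "counts":
        raise ValueError("alpha diversity expects a counts-mode table")
    rows = {s: vars(alpha_diversity(table.values[:, j]))
            for j, s in enumerate(table.sample_ids)}
    return pd.DataFrame.from_dict(rows, orient="index")


def _as_distance_matrix(condensed, ids) -> DistanceMatrix:
    return DistanceMatrix(squareform(condensed, checks=False), ids=list(ids))


def bray_curtis_matrix(table: CommunityTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between samples of a proportions table."""
    if table.mode != "proportions":
        raise ValueError("bray_curtis_matrix expects a proportions-mode table")
    return _as_distance_matrix(pdist(table.values.T, metric="braycurtis"),
                               table.sample_ids)


def jaccard_binary_matrix(table: CommunityTable) -> DistanceMatrix:
    """Binary Jaccard dissimilarity on presence/absence of a counts table."""
    if table.mode == "proportions":
        raise ValueError("jaccard_binary_matrix expects (rarefied) counts")
    presence = table.values > 0
    empty = np.flatnonzero(~presence.any(axis=0))
    if empty.size:
        names = [table.sample_ids[j] for j in empty]
        raise ValueError(f"sample(s) with no OTUs present: {names}")
    return _as_distance_matrix(pdist(presence.T, metric="jaccard"),
                               table.sample_ids)


def _unifrac(table: CommunityTable, tree, metric: str, **kwargs) -> DistanceMatrix:
    tips = {t.name for t in tree.tips()}
    present = np.asarray(table.otu_ids)[table.values.any(axis=1)]
    missing = sorted(set(present) - tips)
    if missing:
        raise ValueError(f"OTUs missing from tree: {missing[:10]}")
    return beta_diversity(
        metric,
        table.values.T,
        ids=table.sample_ids,
        taxa=table.otu_ids,
        tree=tree,
        **kwargs,
    )


def unweighted_unifrac_matrix(table: CommunityTable, tree) -> DistanceMatrix:
    """Unweighted UniFrac on rarefied counts: unique / covered branch length."""
    if table.mode == "proportions":
        raise ValueError("unweighted UniFrac expects (rarefied) counts")
    return _unifrac(table, tree, "unweighted_unifrac")


def _tree_arrays(tree, otu_ids):
    """Postorder node arrays: parent index, branch length, tip row, root depth."""
    nodes = list(tree.postorder(include_self=True))
    index = {id(node): i for i, node in enumerate(nodes)}
    n = len(nodes)
    parent = np.full(n, -1, dtype=int)
    length = np.zeros(n)
    for i, node in enumerate(nodes):
        length[i] = node.length or 0.0
        if node.parent is not None:
            parent[i] = index[id(node.parent)]
    root = n - 1
    length[root] = 0.0
    depth = np.zeros(n)
    for i in range(n - 2, -1, -1):  # preorder via reversed postorder
        depth[i] = depth[parent[i]] + length[i]
    tip_row = {}
    for i, node in enumerate(nodes):
        if node.is_tip():
            tip_row[node.name] = i
    missing = [o for o in otu_ids if o not in tip_row]
    if missing:
        raise ValueError(f"OTUs missing from tree: {missing[:10]}")
    return parent, length, depth, tip_row


def weighted_unifrac_matrix(table: CommunityTable, tree,
                            normalized: bool = True) -> DistanceMatrix:
    """Weighted UniFrac between samples of a proportions table.

    Raw weighted UniFrac is sum_b l_b |p_A(b) - p_B(b)| over branches, with
    p(b) the summed proportion of tips descending from branch b. The
    normalised variant (default) divides by the pair's scaling term
    sum_tips d_root(tip) (p_A(tip) + p_B(tip)), bounding values to [0, 1].

    Computed in-package on float proportions; the scikit-bio implementation
    (integer abundances only) serves as a cross-check on count data.
    """
    if table.mode != "proportions":
        raise ValueError("weighted UniFrac expects a proportions-mode table")
    parent, length, depth, tip_row = _tree_arrays(tree, table.otu_ids)
    n_nodes = length.size
    n_samples = table.shape[1]
    node_prop = np.zeros((n_nodes, n_samples))
    values = table.values
    for k, otu in enumerate(table.otu_ids):
        node_prop[tip_row[otu]] = values[k]
    for i in range(n_nodes - 1):  # postorder accumulation to parents
        node_prop[parent[i]] += node_prop[i]
    raw = squareform(pdist((node_prop * length[:, None]).T, metric="cityblock"),
                     checks=False)
    if not normalized:
        return DistanceMatrix(raw, ids=table.sample_ids)
    tip_depth = np.zeros(n_nodes)
    for i in tip_row.values():
        tip_depth[i] = depth[i]
    scale_per_sample = (node_prop * tip_depth[:, None]).sum(axis=0)
    scale = scale_per_sample[:, None] + scale_per_sample[None, :]
    off = ~np.eye(n_samples, dtype=bool)
    if np.any(scale[off] == 0):
        bad = np.argwhere((scale == 0) & off)[0]
        raise ValueError(
            "zero weighted-UniFrac scaling term for pair "
            f"({table.sample_ids[bad[0]]}, {table.sample_ids[bad[1]]})")
    out = np.where(off, raw / np.where(scale > 0, scale, 1.0), 0.0)
    return DistanceMatrix(out, ids=table.sample_ids)


def per_otu_bray_curtis(table: CommunityTable, otu_id,
                        zero_zero: str = "zero") -> DistanceMatrix:
    """Single-OTU Bray-Curtis matrix: |p_s - p_t| / (p_s + p_t) per sample pair.

    Pairs where the OTU is absent from both samples are 0 by convention
    (identical trivial communities), keeping matrices complete; pass
    ``zero_zero="nan"`` to flag them instead (returned as a plain DataFrame,
    since distance-matrix containers reject missing values).
    """
    if table.mode != "proportions":
        raise ValueError("per_otu_bray_curtis expects a proportions-mode table")
    if otu_id not in table.data.index:
        raise KeyError(f"unknown OTU id {otu_id!r}")
    p = table.data.loc[otu_id].to_numpy()
    values = per_otu_bray_curtis_values(p, zero_zero=zero_zero)
    if zero_zero == "nan":
        frame = pd.DataFrame(squareform(np.nan_to_num(values), checks=False),
                             index=table.sample_ids, columns=table.sample_ids)
        mask = squareform(np.isnan(values).astype(float), checks=False) > 0
        return frame.mask(mask)
    return _as_distance_matrix(values, table.sample_ids)


def per_otu_bray_curtis_values(p: np.ndarray, pairs=None,
                               zero_zero: str = "zero") -> np.ndarray:
    """Condensed (or pair-indexed) single-OTU Bray-Curtis values.

    ``pairs`` is an optional ``(i_idx, j_idx)`` tuple restricting computation
    to specific sample pairs; default is all unordered pairs in condensed
    (upper-triangle) order.
    """
    p = np.asarray(p, dtype=float)
    if pairs is None:
        i, j = np.triu_indices(p.size, k=1)
    else:
        i, j = pairs
    num = np.abs(p[i] - p[j])
    den = p[i] + p[j]
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    if zero_zero == "nan":
        d = np.where(den > 0, d, np.nan)
    return d


def write_dissimilarity_tsv(dm: DistanceMatrix, path) -> None:
    frame = pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))
    frame.to_csv(path, sep="\t", float_format="%.12g")


def read_dissimilarity_tsv(path) -> DistanceMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(frame.to_numpy(), ids=list(frame.index))
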