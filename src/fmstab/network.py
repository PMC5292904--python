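"""Checkerboard-score (nc.score) co-occurrence analysis.

The nc.score used here is a concordance statistic on quantile-binned
abundances: for an OTU pair, every unordered sample pair is concordant if
both OTUs move in the same direction between the two samples, discordant if
they move in opposite directions, and tied otherwise; the score is
(C - D) / (C + D), a Goodman-Kruskal-gamma-style index in [-1, 1]. Positive
scores indicate co-occurrence, negative ones checkerboard (co-avoidance)
patterns; zeros occupy a dedicated lowest bin so presence structure and
abundance structure both contribute. Edge significance uses a permutation
null that shuffles each OTU's sample order independently (preserving
marginal bin distributions, destroying association), with Storey q-values
over all defined pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .community import CommunityTable
from .screen import qvalues

__all__ = ["discretize_abundance", "nc_score_pair", "nc_score_matrix",
           "ScoreMatrix", "score_significance", "build_network",
           "CooccurrenceNetwork", "positive_score_excess", "mantel_test",
           "degree_abundance_association", "CooccurrenceAnalysis",
           "CooccurrenceResults"]


def discretize_abundance(table: CommunityTable, n_bins: int = 4) -> pd.DataFrame:
    """Quantile-bin each OTU's abundances into ordinal levels 0..n_bins-1.

    Zeros map to bin 0; the non-zero values of each OTU are split into
    ``n_bins - 1`` quantile bins computed over that OTU's non-zero values.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if table.mode != "proportions":
        raise ValueError("discretize_abundance expects a proportions-mode table")
    values = table.values
    out = np.zeros(values.shape, dtype=int)
    qs = np.linspace(0, 1, n_bins)[1:-1]  # internal quantile cut points
    for k in range(values.shape[0]):
        row = values[k]
        nz = row > 0
        if not nz.any():
            continue
        edges = np.quantile(row[nz], qs) if qs.size else np.array([])
        out[k, nz] = 1 + np.searchsorted(edges, row[nz], side="left")
    return pd.DataFrame(out, index=table.data.index, columns=table.data.columns)


def nc_score_pair(x, y) -> tuple:
    """nc.score for one ordinal vector pair: ((C - D)/(C + D), C + D).

    Returns ``(nan, 0)`` when no sample pair is untied in both vectors.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("vectors must have equal length >= 2")
    i, j = np.triu_indices(x.size, k=1)
    sx = np.sign(x[i] - x[j])
    sy = np.sign(y[i] - y[j])
    prod = sx * sy
    informative = int(np.count_nonzero((sx != 0) & (sy != 0)))
    if informative == 0:
        return (float("nan"), 0)
    return (float(prod.sum() / informative), informative)


@dataclass
class ScoreMatrix:
    """Symmetric OTU x OTU score matrix with per-pair informative counts."""

    otu_ids: list
    values: np.ndarray        # nan where undefined (incl. diagonal)
    n_informative: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.otu_ids, columns=self.otu_ids)


def _score_arrays(binned: np.ndarray, iu, ju):
    signs = np.sign(binned[:, iu] - binned[:, ju]).astype(np.float64)
    informative_mask = (signs != 0).astype(np.float64)
    num = signs @ signs.T
    den = informative_mask @ informative_mask.T
    with np.errstate(invalid="ignore", divide="ignore"):
        score = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return score, den.astype(int)


def nc_score_matrix(binned: pd.DataFrame) -> ScoreMatrix:
    """All pairwise nc.scores of a binned (OTU x sample) matrix."""
    X = binned.to_numpy()
    n = X.shape[1]
    iu, ju = np.triu_indices(n, k=1)
    score, den = _score_arrays(X, iu, ju)
    np.fill_diagonal(score, np.nan)
    np.fill_diagonal(den, 0)
    return ScoreMatrix(list(binned.index), score, den)


def score_significance(binned: pd.DataFrame, n_perm: int = 1000, seed=None,
                       q_method: str = "storey"):
    """Permutation p- and q-value matrices for all defined nc.scores.

    The null shuffles each OTU's sample order independently per permutation;
    the two-sided p is (1 + #{|null| >= |obs|}) / (1 + n_perm). q-values are
    computed over the defined (upper-triangle) pairs only.
    """
    X = binned.to_numpy()
    m, n = X.shape
    if n < 3:
        raise ValueError("score significance requires >= 3 samples")
    iu, ju = np.triu_indices(n, k=1)
    obs, _ = _score_arrays(X, iu, ju)
    np.fill_diagonal(obs, np.nan)
    defined = np.isfinite(obs)

    rng = np.random.default_rng(seed)
    hits = np.zeros((m, m))
    abs_obs = np.abs(obs)
    base = np.tile(np.arange(n), (m, 1))
    for _ in range(n_perm):
        idx = rng.permuted(base, axis=1)
        Xp = np.take_along_axis(X, idx, axis=1)
        null, _ = _score_arrays(Xp, iu, ju)
        hits += np.where(np.isfinite(null) & defined,
                         np.abs(null) >= abs_obs - 1e-12, 0.0)
    p = np.where(defined, (1.0 + hits) / (1.0 + n_perm), np.nan)

    q = np.full((m, m), np.nan)
    ti, tj = np.triu_indices(m, k=1)
    mask = defined[ti, tj]
    qvals = qvalues(p[ti, tj][mask], method=q_method)
    q[ti[mask], tj[mask]] = qvals
    q[tj[mask], ti[mask]] = qvals
    ids = list(binned.index)
    return (pd.DataFrame(p, index=ids, columns=ids),
            pd.DataFrame(q, index=ids, columns=ids))


@dataclass
class CooccurrenceNetwork:
    """Significant co-occurrence/co-avoidance edges and per-OTU degrees."""

    graph: nx.Graph
    alpha: float

    @property
    def degrees(self) -> pd.Series:
        return pd.Series(dict(self.graph.degree()), dtype=int)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def mean_links_per_otu(self) -> float:
        n = self.graph.number_of_nodes()
        return 2.0 * self.n_edges / n if n else float("nan")

    @property
    def positive_edge_share(self) -> float:
        if self.n_edges == 0:
            return float("nan")
        pos = sum(1 for *_, d in self.graph.edges(data=True)
                  if d["sign"] == "positive")
        return pos / self.n_edges

    def edge_frame(self) -> pd.DataFrame:
        rows = [{"otu_i": u, "otu_j": v, **d}
                for u, v, d in self.graph.edges(data=True)]
        cols = ["otu_i", "otu_j", "score", "p", "q", "sign"]
        return pd.DataFrame(rows, columns=cols)


def build_network(scores: ScoreMatrix, q: pd.DataFrame, p: pd.DataFrame | None = None,
                  alpha: float = 0.05) -> CooccurrenceNetwork:
    """Keep edges with q < alpha; returns the network with degrees and summary."""
    ids = scores.otu_ids
    g = nx.Graph()
    g.add_nodes_from(ids)
    qv = q.to_numpy()
    pv = p.to_numpy() if p is not None else np.full_like(qv, np.nan)
    iu, ju = np.triu_indices(len(ids), k=1)
    for a, b in zip(iu, ju):
        if np.isfinite(qv[a, b]) and qv[a, b] < alpha:
            s = scores.values[a, b]
            g.add_edge(ids[a], ids[b], score=float(s), p=float(pv[a, b]),
                       q=float(qv[a, b]),
                       sign="positive" if s > 0 else "negative")
    return CooccurrenceNetwork(g, alpha)


def positive_score_excess(scores: ScoreMatrix) -> tuple:
    """One-sample Wilcoxon signed-rank test for excess of positive scores.

    Tests the defined off-diagonal scores against 0, upper tail (more
    co-occurrence than co-avoidance). Returns ``(statistic, p)``.
    """
    iu, ju = np.triu_indices(len(scores.otu_ids), k=1)
    vals = scores.values[iu, ju]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no defined off-diagonal scores")
    if np.all(vals == 0):
        return (0.0, 1.0)
    res = stats.wilcoxon(vals, alternative="greater")
    return (float(res.statistic), float(res.pvalue))


def mantel_test(A: ScoreMatrix, B: ScoreMatrix, n_perm: int = 999, seed=None):
    """Mantel correlation between two score matrices.

    OTU sets are intersected; pairs undefined in either matrix are dropped.
    r is the Pearson correlation of upper-triangle scores; the null permutes
    the OTU labels of B jointly on rows and columns; one-sided (upper) p.
    """
    common = [o for o in A.otu_ids if o in set(B.otu_ids)]
    if len(common) < 3:
        raise ValueError("need >= 3 common OTUs for a Mantel test")
    ia = [A.otu_ids.index(o) for o in common]
    ib = [B.otu_ids.index(o) for o in common]
    MA = A.values[np.ix_(ia, ia)]
    MB = B.values[np.ix_(ib, ib)]
    k = len(common)
    iu, ju = np.triu_indices(k, k=1)

    def corr(mb):
        a = MA[iu, ju]
        b = mb[iu, ju]
        mask = np.isfinite(a) & np.isfinite(b)
        if mask.sum() < 3 or np.std(a[mask]) == 0 or np.std(b[mask]) == 0:
            return np.nan
        return np.corrcoef(a[mask], b[mask])[0, 1]

    observed = corr(MB)
    rng = np.random.default_rng(seed)
    hits = 0
    used = 0
    for _ in range(n_perm):
        perm = rng.permutation(k)
        r = corr(MB[np.ix_(perm, perm)])
        if np.isnan(r):
            continue
        used += 1
        if r >= observed - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + used) if used else float("nan")
    return (float(observed), float(p))


def degree_abundance_association(network: CooccurrenceNetwork,
                                 table: CommunityTable):
    """Spearman correlation of node degree with log10 mean relative abundance.

    Returns ``(rho, p)``; ``(nan, nan)`` (flagged) when all degrees are equal
    or the network is empty.
    """
    props = table if table.mode == "proportions" else None
    if props is None:
        raise ValueError("degree_abundance_association expects proportions")
    nodes = [o for o in network.graph.nodes if o in set(table.otu_ids)]
    if len(nodes) != network.graph.number_of_nodes():
        raise ValueError("network nodes must be a subset of table OTUs")
    if not nodes:
        return (float("nan"), float("nan"))
    deg = np.array([network.graph.degree(o) for o in nodes], dtype=float)
    if np.all(deg == deg[0]):
        return (float("nan"), float("nan"))
    mean_ab = table.data.loc[nodes].mean(axis=1).to_numpy()
    mean_ab = np.maximum(mean_ab, 1e-12)
    rho, pval = stats.spearmanr(deg, np.log10(mean_ab))
    return (float(rho), float(pval))


class CooccurrenceResults:
    """Scores, significance and network for one cohort's co-occurrence fit."""

    def __init__(self, scores: ScoreMatrix, p: pd.DataFrame, q: pd.DataFrame,
                 network: CooccurrenceNetwork, n_bins: int):
        self.scores = scores
        self.p = p
        self.q = q
        self.network = network
        self.n_bins = n_bins

    def positive_score_excess(self):
        return positive_score_excess(self.scores)

    def degree_abundance_association(self, table: CommunityTable):
        return degree_abundance_association(self.network, table)

    def summary(self) -> str:
        stat, pw = self.positive_score_excess()
        lines = [
            "Checkerboard-score co-occurrence analysis",
            "=" * 44,
            f"OTUs:                  {len(self.scores.otu_ids)}",
            f"bins:                  {self.n_bins}",
            f"edges (q < {self.network.alpha:g}):      {self.network.n_edges}",
            f"mean links per OTU:    {self.network.mean_links_per_otu:.3f}",
            f"positive edge share:   {self.network.positive_edge_share:.3f}",
            f"positive-score excess: Wilcoxon p = {pw:.4g}",
        ]
        return "\n".join(lines)


class CooccurrenceAnalysis:
    """Model object: quantile-binned table -> scores, significance, network."""

    def __init__(self, table: CommunityTable, n_bins: int = 4):
        self.table = table
        self.n_bins = n_bins
        self.binned = discretize_abundance(table, n_bins=n_bins)

    def fit(self, n_perm: int = 1000, seed=None, alpha: float = 0.05,
            q_method: str = "storey") -> CooccurrenceResults:
        scores = nc_score_matrix(self.binned)
        p, q = score_significance(self.binned, n_perm=n_perm, seed=seed,
                                  q_method=q_method)
        net = build_network(scores, q, p=p, alpha=alpha)
        return CooccurrenceResults(scores, p, q, net, self.n_bins)
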