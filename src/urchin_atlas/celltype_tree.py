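"""Cell-type tree reconstruction from cluster expression profiles.

Pairwise distances between cluster pseudobulk profiles (restricted to the
genes expressed anywhere, optionally intersected with a gene catalogue such
as transcription factors) feed classic Saitou–Nei neighbor joining; branch
support comes from resampling the gene universe with replacement and
counting, for every internal bipartition of the point-estimate tree, the
percentage of replicate trees that contain it.

Distance metrics:

* ``spearman``: 1 - Spearman rank correlation of mean CPM (the primary
  metric; bounded in [0, 2], invariant to monotone transforms);
* ``pearson_log``: 1 - Pearson correlation of log1p(CPM);
* ``pearson_sqrt``: 1 - Pearson correlation of sqrt(CPM);
* ``euclidean_scaled``: Euclidean distance of per-gene z-scored log1p(CPM).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from skbio import TreeNode

from .core_io import (
    AtlasError,
    GeneSetPanel,
    IntegrityError,
    ParameterError,
    bipartitions,
)
from .profiles import ClusterProfile, ExpressedGeneSets

METRICS = ("spearman", "pearson_log", "pearson_sqrt", "euclidean_scaled")


@dataclass
class DistanceMatrix:
    """Symmetric, hollow, non-negative distance matrix over cluster labels."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise IntegrityError(f"distance matrix shape {self.d.shape} != ({n},{n})")
        if not np.allclose(self.d, self.d.T, atol=1e-9):
            raise IntegrityError("distance matrix is not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise IntegrityError("distance matrix diagonal must be zero")
        if self.d.min() < 0:
            raise IntegrityError("distances must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)


# ---------------------------------------------------------------------------
# Expression distances
# ---------------------------------------------------------------------------

def _correlation_distance(X: np.ndarray, labels: Sequence[str]) -> np.ndarray:
    sds = X.std(axis=1)
    flat = [labels[i] for i in np.flatnonzero(sds == 0)]
    if flat:
        raise AtlasError(
            f"zero-variance profile under a correlation metric for clusters {flat}"
        )
    d = 1.0 - np.corrcoef(X)
    np.fill_diagonal(d, 0.0)
    return np.maximum(0.5 * (d + d.T), 0.0)


def expression_distance(
    p: ClusterProfile,
    expressed: ExpressedGeneSets,
    metric: str = "spearman",
    exclude: Iterable[str] = (),
    gene_set: GeneSetPanel | None = None,
) -> DistanceMatrix:
    """Pairwise cluster distances over the expressed-anywhere gene universe.

    ``exclude`` drops clusters (e.g. an 'undefined' catch-all) before the
    distance computation; ``gene_set`` intersects the universe with a
    catalogue (e.g. transcription factors only).
    """
    if metric not in METRICS:
        raise ParameterError(f"unknown metric {metric!r}; choose from {METRICS}")
    exclude = set(exclude)
    labels = [c for c in p.clusters if c not in exclude]
    if len(labels) < 3:
        raise ParameterError(f"need at least 3 clusters after exclusion, got {len(labels)}")
    universe = expressed.anywhere()
    if gene_set is not None:
        universe &= gene_set.gene_ids
    genes = [g for g in p.genes if g in universe]
    if not genes:
        raise AtlasError("empty gene universe after filtering")
    X = p.mean_cpm.loc[labels, genes].to_numpy(dtype=float)
    return DistanceMatrix(labels, _metric_distance(X, labels, metric))


def _metric_distance(X: np.ndarray, labels: Sequence[str], metric: str) -> np.ndarray:
    if metric == "spearman":
        return _correlation_distance(stats.rankdata(X, axis=1), labels)
    if metric == "pearson_log":
        return _correlation_distance(np.log1p(X), labels)
    if metric == "pearson_sqrt":
        return _correlation_distance(np.sqrt(X), labels)
    # euclidean_scaled: per-gene z-score of log1p across clusters
    L = np.log1p(X)
    sd = L.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (L - L.mean(axis=0)) / sd
    diff = Z[:, None, :] - Z[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2))
    np.fill_diagonal(d, 0.0)
    return d


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    # negative branch length: clamp to zero, transfer the deficit to the
    # sister edge so the path length through the new node is preserved
    if li < 0:
        lj = max(lj + li, 0.0)
        li = 0.0
    if lj < 0:
        li = max(li + lj, 0.0)
        lj = 0.0
    return li, lj


def neighbor_joining(D: DistanceMatrix) -> TreeNode:
    """Classic Saitou–Nei neighbor joining with deterministic tie-breaking.

    Q-matrix pair selection, standard branch-length and distance-update
    formulas; when several pairs minimize Q the lexicographically smallest
    pair of subtree keys (smallest leaf label in each subtree) is joined.
    Negative branch lengths are clamped to zero with the deficit moved to the
    sister edge. Returns an unrooted tree as a trifurcating-rooted TreeNode.
    """
    n = len(D.labels)
    if n < 3:
        raise ParameterError("neighbor joining needs at least 3 labels")
    d = D.d.copy()
    nodes: list[TreeNode] = [TreeNode(name=l) for l in D.labels]
    keys: list[str] = list(D.labels)

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        order = sorted(range(m), key=lambda i: keys[i])
        best, bi, bj = None, -1, -1
        for a in range(m):
            for b in range(a + 1, m):
                i, j = order[a], order[b]
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if best is None or q < best:
                    best, bi, bj = q, i, j
        li = 0.5 * d[bi, bj] + (r[bi] - r[bj]) / (2.0 * (m - 2))
        lj = d[bi, bj] - li
        li, lj = _clamp_pair(li, lj)
        nodes[bi].length = li
        nodes[bj].length = lj
        parent = TreeNode(children=[nodes[bi], nodes[bj]])
        newd = 0.5 * (d[bi, :] + d[bj, :] - d[bi, bj])
        newd = np.maximum(newd, 0.0)
        keep = [k for k in range(m) if k not in (bi, bj)]
        d2 = np.empty((m - 1, m - 1))
        d2[: m - 2, : m - 2] = d[np.ix_(keep, keep)]
        d2[: m - 2, m - 2] = d2[m - 2, : m - 2] = newd[keep]
        d2[m - 2, m - 2] = 0.0
        nodes = [nodes[k] for k in keep] + [parent]
        keys = [keys[k] for k in keep] + [min(keys[bi], keys[bj])]
        d = d2

    (a, b, c) = range(3)
    va = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    vb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    vc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    for node, v in zip(nodes, (va, vb, vc)):
        node.length = max(v, 0.0)
    order = sorted(range(3), key=lambda i: keys[i])
    return TreeNode(children=[nodes[i] for i in order])


def path_distance_matrix(tree: TreeNode, labels: Sequence[str]) -> DistanceMatrix:
    """Leaf-to-leaf path-length distances on a tree (additive by construction)."""
    dm = tree.tip_tip_distances()
    ids = list(dm.ids)
    idx = [ids.index(l) for l in labels]
    return DistanceMatrix(list(labels), dm.data[np.ix_(idx, idx)])


# ---------------------------------------------------------------------------
# Bootstrap supports
# ---------------------------------------------------------------------------

def bootstrap_supports(
    p: ClusterProfile,
    expressed: ExpressedGeneSets,
    metric: str = "spearman",
    n_reps: int = 10000,
    seed: int = 0,
    exclude: Iterable[str] = (),
    gene_set: GeneSetPanel | None = None,
    recompute_universe: bool = False,
) -> tuple[TreeNode, dict[frozenset, int]]:
    """Point-estimate NJ tree with gene-resampling bootstrap supports.

    The gene universe (expressed anywhere, optionally intersected with
    ``gene_set``) is fixed once from the full profile; each replicate
    resamples that universe with replacement at its original size, recomputes
    the distance matrix and the NJ tree, and every internal bipartition of
    the point tree is scored by the integer percentage of replicate trees
    containing it. With ``recompute_universe=True`` the resample is drawn
    from all profiled genes and the expressed filter is re-applied within
    each replicate. Supports are written into the internal-node labels of the
    returned tree and also returned as a bipartition -> percent map.
    """
    if n_reps < 1:
        raise ParameterError("n_reps must be at least 1")
    if metric not in METRICS:
        raise ParameterError(f"unknown metric {metric!r}; choose from {METRICS}")
    exclude = set(exclude)
    labels = [c for c in p.clusters if c not in exclude]
    if len(labels) < 3:
        raise ParameterError(f"need at least 3 clusters after exclusion, got {len(labels)}")

    universe = expressed.anywhere()
    if gene_set is not None:
        universe &= gene_set.gene_ids
    genes = [g for g in p.genes if g in universe]
    if not genes:
        raise AtlasError("empty gene universe after filtering")
    X = p.mean_cpm.loc[labels, genes].to_numpy(dtype=float)

    point = neighbor_joining(DistanceMatrix(labels, _metric_distance(X, labels, metric)))
    point_splits = bipartitions(point)
    counts = {s: 0 for s in point_splits}

    if recompute_universe:
        pool = p.mean_cpm.loc[labels].to_numpy(dtype=float)
        thr = expressed.threshold_tpm
    rng = np.random.default_rng(seed)
    n_genes = X.shape[1]
    for _ in range(n_reps):
        if recompute_universe:
            idx = rng.integers(pool.shape[1], size=pool.shape[1])
            Xb = pool[:, idx]
            Xb = Xb[:, (Xb > thr).any(axis=0)]
            if Xb.shape[1] == 0:
                continue
        else:
            Xb = X[:, rng.integers(n_genes, size=n_genes)]
        rep = neighbor_joining(DistanceMatrix(labels, _metric_distance(Xb, labels, metric)))
        for s in bipartitions(rep):
            if s in counts:
                counts[s] += 1

    supports = {s: int(round(100.0 * c / n_reps)) for s, c in counts.items()}
    leafset = frozenset(labels)
    for node in point.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        split = frozenset((side, leafset - side))
        if split in supports:
            node.name = str(supports[split])
    return point, supports
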