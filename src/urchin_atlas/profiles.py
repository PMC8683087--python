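"""Cluster expression profiling: QC, pseudobulk CPM, expressed calls, markers.

"Transcripts per million" is implemented as pseudobulk counts-per-million per
cluster: counts are summed over the cluster's cells and rescaled to one
million. UMI counts carry no gene-length bias, so CPM is the natural reading
of TPM for 3'-tag data; a mean-of-per-cell-CPM variant is available via
``cell_mean=True``. A gene is called expressed in a cluster when its CPM is
strictly greater than the threshold (default 3).

Marker detection tests each gene passing a detection-fraction (min.pct)
filter with a two-sided Wilcoxon rank-sum test on log1p-normalized per-cell
expression (cluster vs rest), Bonferroni-corrected. Groups of at most ten
cells each are tested by exact permutation enumeration (correct under ties);
larger groups use the tie-corrected normal approximation with continuity
correction.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .core_io import (
    AtlasError,
    CountMatrix,
    GeneSetPanel,
    ParameterError,
    logger,
    validate_annotation,
)

EXACT_MAX_GROUP = 10  # exact rank-sum enumeration when both groups are <= this


@dataclass
class ClusterProfile:
    """Per-cluster pseudobulk CPM and detection fractions.

    ``mean_cpm`` and ``pct_expressing`` are clusters x genes DataFrames with
    identical index/columns; ``n_cells`` counts cells per cluster.
    """

    mean_cpm: pd.DataFrame
    pct_expressing: pd.DataFrame
    n_cells: pd.Series

    @property
    def clusters(self) -> list[str]:
        return list(self.mean_cpm.index)

    @property
    def genes(self) -> list[str]:
        return list(self.mean_cpm.columns)


@dataclass
class ExpressedGeneSets:
    """Per-cluster sets of genes whose pseudobulk CPM exceeds the threshold."""

    sets: dict[str, set[str]]
    threshold_tpm: float = 3.0

    def __getitem__(self, cluster: str) -> set[str]:
        return self.sets[cluster]

    def anywhere(self) -> set[str]:
        """Genes expressed in at least one cluster (the tree-building universe)."""
        out: set[str] = set()
        for s in self.sets.values():
            out |= s
        return out


# ---------------------------------------------------------------------------
# QC filtering
# ---------------------------------------------------------------------------

def filter_qc(m: CountMatrix, min_cells: int = 3, min_genes: int = 200) -> CountMatrix:
    """Remove rarely detected genes, then sparsely covered cells.

    Genes detected (count > 0) in fewer than ``min_cells`` cells are dropped
    first; cells with fewer than ``min_genes`` detected genes among the
    remaining genes are dropped second. Each pass runs once, genes before
    cells, so the operation is idempotent. Exactly-at-threshold genes and
    cells are retained (the cuts are strict "fewer than").
    """
    detected = m.values > 0
    gene_keep = np.asarray(detected.sum(axis=1)).ravel() >= min_cells
    detected = detected[gene_keep]
    cell_keep = np.asarray(detected.sum(axis=0)).ravel() >= min_genes
    if not cell_keep.any():
        logger.warning("QC filtering removed every cell")
    return CountMatrix(
        m.values[gene_keep][:, cell_keep],
        [g for g, k in zip(m.gene_ids, gene_keep) if k],
        [c for c, k in zip(m.cell_ids, cell_keep) if k],
    )


# ---------------------------------------------------------------------------
# Cluster profiles and expressed-gene calling
# ---------------------------------------------------------------------------

def _groups(m: CountMatrix, ann: pd.DataFrame, level: str) -> dict[str, np.ndarray]:
    """Map each group label to the column indices of its cells."""
    if level not in ("cluster", "subcluster"):
        raise ParameterError(f"unknown annotation level {level!r}")
    # the annotation may cover more cells than m (e.g. after QC filtering);
    # every cell of m must be annotated, not vice versa
    validate_annotation(ann)
    lookup = dict(zip(ann["cell_id"], ann.get(level, pd.Series(dtype=str))))
    missing = [
        c for c in m.cell_ids if c not in lookup or pd.isna(lookup.get(c))
    ]
    if missing:
        raise AtlasError(
            f"{len(missing)} cells lack a {level} annotation, e.g. {missing[:5]}"
        )
    out: dict[str, list[int]] = {}
    for j, c in enumerate(m.cell_ids):
        out.setdefault(str(lookup[c]), []).append(j)
    return {k: np.array(v, dtype=int) for k, v in sorted(out.items())}


def cluster_profile(
    m: CountMatrix,
    ann: pd.DataFrame,
    level: str = "cluster",
    cell_mean: bool = False,
) -> ClusterProfile:
    """Pseudobulk CPM and detection fraction per cluster (or subcluster).

    ``mean_cpm[c, g] = 1e6 * sum_g(counts in c) / sum_all(counts in c)``;
    with ``cell_mean=True`` the per-cell CPM vectors are averaged instead.
    """
    groups = _groups(m, ann, level)
    labels = [k for k, idx in groups.items() if len(idx) > 0]
    csc = sp.csc_matrix(m.values)
    cpm_rows, pct_rows, ncells = [], [], []
    for lab in labels:
        idx = groups[lab]
        sub = csc[:, idx]
        if cell_mean:
            totals = np.asarray(sub.sum(axis=0)).ravel()
            totals[totals == 0] = 1.0
            cpm = np.asarray(
                sub.multiply(1e6 / totals[None, :]).mean(axis=1)
            ).ravel()
        else:
            sums = np.asarray(sub.sum(axis=1)).ravel().astype(float)
            total = sums.sum()
            cpm = 1e6 * sums / total if total > 0 else np.zeros_like(sums)
        pct = np.asarray((sub > 0).sum(axis=1)).ravel() / len(idx)
        cpm_rows.append(cpm)
        pct_rows.append(pct)
        ncells.append(len(idx))
    return ClusterProfile(
        mean_cpm=pd.DataFrame(cpm_rows, index=labels, columns=m.gene_ids),
        pct_expressing=pd.DataFrame(pct_rows, index=labels, columns=m.gene_ids),
        n_cells=pd.Series(ncells, index=labels),
    )


def call_expressed(p: ClusterProfile, threshold_tpm: float = 3.0) -> ExpressedGeneSets:
    """Per-cluster expressed-gene sets under the strict > threshold CPM rule."""
    sets = {
        c: set(p.mean_cpm.columns[(p.mean_cpm.loc[c] > threshold_tpm).to_numpy()])
        for c in p.clusters
    }
    return ExpressedGeneSets(sets=sets, threshold_tpm=threshold_tpm)


# ---------------------------------------------------------------------------
# Marker detection
# ---------------------------------------------------------------------------

def _lognorm(values: sp.spmatrix, target_sum: float = 1e4) -> np.ndarray:
    """Per-cell depth normalization to ``target_sum`` followed by log1p (dense)."""
    totals = np.asarray(values.sum(axis=0)).ravel().astype(float)
    totals[totals == 0] = 1.0
    dense = np.asarray(values.todense(), dtype=float)
    return np.log1p(dense * (target_sum / totals[None, :]))


def rank_sum_test(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value for samples ``x`` vs ``y``.

    Average ranks for ties. Both groups of size <= EXACT_MAX_GROUP: exact
    permutation p = Pr(|W - E W| >= |w - E W|) by full enumeration; otherwise
    tie-corrected normal approximation with continuity correction.
    """
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ParameterError("rank-sum test needs two non-empty groups")
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    w = ranks[:n1].sum()
    n = n1 + n2
    mu = n1 * (n + 1) / 2.0
    if n1 <= EXACT_MAX_GROUP and n2 <= EXACT_MAX_GROUP:
        obs = abs(w - mu)
        hits = 0
        total = 0
        for comb in itertools.combinations(range(n), n1):
            total += 1
            if abs(ranks[list(comb)].sum() - mu) >= obs - 1e-9:
                hits += 1
        return hits / total
    _, counts = np.unique(combined, return_counts=True)
    tie_term = (counts**3 - counts).sum()
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 1.0
    diff = w - mu
    z = (diff - 0.5 * np.sign(diff)) / math.sqrt(var)
    return min(1.0, 2.0 * stats.norm.sf(abs(z)))


def find_markers(
    m: CountMatrix,
    ann: pd.DataFrame,
    cluster: str,
    min_pct: float = 0.01,
    min_pct_mode: str = "or",
    level: str = "cluster",
    target_sum: float = 1e4,
) -> pd.DataFrame:
    """Marker table for ``cluster`` against all remaining cells.

    Genes are tested only if their detection fraction reaches ``min_pct`` in
    the cluster or (``min_pct_mode='and'``: and) in the rest group. Columns:
    gene_id, cluster, log2_fc (pseudobulk CPM+1 ratio), pct_in, pct_out, p,
    p_adj (Bonferroni over tested genes); sorted by p_adj, then descending
    absolute fold change.
    """
    if min_pct_mode not in ("or", "and"):
        raise ParameterError(f"min_pct_mode must be 'or' or 'and', got {min_pct_mode!r}")
    groups = _groups(m, ann, level)
    if cluster not in groups:
        raise ParameterError(f"cluster {cluster!r} not present in the annotation")
    if len(groups) < 2:
        raise ParameterError("marker detection needs at least two clusters")
    in_idx = groups[cluster]
    out_idx = np.concatenate([v for k, v in groups.items() if k != cluster])
    if len(in_idx) < 3:
        raise ParameterError(
            f"cluster {cluster!r} has {len(in_idx)} cells; at least 3 required"
        )

    detected = m.values > 0
    pct_in = np.asarray(detected[:, in_idx].sum(axis=1)).ravel() / len(in_idx)
    pct_out = np.asarray(detected[:, out_idx].sum(axis=1)).ravel() / len(out_idx)
    if min_pct_mode == "or":
        tested = (pct_in >= min_pct) | (pct_out >= min_pct)
    else:
        tested = (pct_in >= min_pct) & (pct_out >= min_pct)
    tested_idx = np.flatnonzero(tested)
    if len(tested_idx) == 0:
        return pd.DataFrame(
            columns=["gene_id", "cluster", "log2_fc", "pct_in", "pct_out", "p", "p_adj"]
        )

    # pseudobulk fold changes on the CPM scale
    sums_in = np.asarray(m.values[:, in_idx].sum(axis=1)).ravel().astype(float)
    sums_out = np.asarray(m.values[:, out_idx].sum(axis=1)).ravel().astype(float)
    cpm_in = 1e6 * sums_in / max(sums_in.sum(), 1.0)
    cpm_out = 1e6 * sums_out / max(sums_out.sum(), 1.0)
    log2_fc = np.log2((cpm_in + 1.0) / (cpm_out + 1.0))

    logn = _lognorm(m.values[tested_idx], target_sum=target_sum)
    pvals = np.empty(len(tested_idx))
    for r in range(len(tested_idx)):
        pvals[r] = rank_sum_test(logn[r, in_idx], logn[r, out_idx])
    p_adj = np.minimum(1.0, pvals * len(tested_idx))

    table = pd.DataFrame(
        {
            "gene_id": [m.gene_ids[i] for i in tested_idx],
            "cluster": cluster,
            "log2_fc": log2_fc[tested_idx],
            "pct_in": pct_in[tested_idx],
            "pct_out": pct_out[tested_idx],
            "p": pvals,
            "p_adj": p_adj,
        }
    )
    table["_absfc"] = table["log2_fc"].abs()
    table = table.sort_values(
        ["p_adj", "_absfc", "gene_id"], ascending=[True, False, True]
    ).drop(columns="_absfc")
    return table.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Dotplot summaries
# ---------------------------------------------------------------------------

def dotplot_table(p: ClusterProfile, genes: GeneSetPanel) -> pd.DataFrame:
    """Long-form dotplot summary: detection fraction and scaled expression.

    For each requested gene present in the profile, the z-score of
    log1p(mean CPM) across clusters (sample SD, so a two-cluster contrast
    scales to +-1/sqrt(2); zero-variance genes get z = 0) and the detection
    fraction, one row per (gene, cluster). Missing genes are reported via the
    log and omitted.
    """
    present = [g for g in sorted(genes.gene_ids) if g in p.mean_cpm.columns]
    missing = sorted(genes.gene_ids - set(present))
    if missing:
        logger.warning("dotplot: %d panel genes absent from profile: %s",
                       len(missing), missing[:10])
    rows = []
    for g in present:
        vals = np.log1p(p.mean_cpm[g].to_numpy(dtype=float))
        sd = vals.std(ddof=1) if len(vals) > 1 else 0.0
        z = (vals - vals.mean()) / sd if sd > 0 else np.zeros_like(vals)
        for c, zi, pct in zip(p.clusters, z, p.pct_expressing[g]):
            rows.append((g, c, float(pct), float(zi)))
    return pd.DataFrame(rows, columns=["gene_id", "cluster", "pct_expressing", "z"])
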