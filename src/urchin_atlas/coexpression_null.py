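"""Independent-swap randomization test for gene-panel co-expression.

Asks whether a gene panel (e.g. 20 endocrine-pancreas genes) is co-expressed
in a target subcluster more than expected when the subcluster's count matrix
is randomized under a marginal-preserving null. The null is a quantitative
independent swap: repeatedly sample a 2x2 quartet of matrix cells (two rows,
two columns); when the quartet is an occupancy checkerboard (one diagonal
nonzero, the other zero) the two nonzero values slide along their rows onto
the zero diagonal. This conserves the grand total, each row's multiset of
nonzero values, and the binarized row and column sums — the documented
guarantees of the independent-swap null for occupancy matrices, generalized
to abundances.

The summary statistic compares the observed number of panel genes expressed
in the target subcluster with the mean count over randomized replicates
(rounded to the nearest integer), via a 2x2 chi-squared test on the
expressed / not-expressed proportions; an empirical permutation p-value over
the replicate counts is reported alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy import stats

from .core_io import (
    AtlasError,
    CountMatrix,
    GeneSetPanel,
    IntegrityError,
    ParameterError,
)

RULES = ("any_cell", "mean_gt0", "mean_gt_thr")


# ---------------------------------------------------------------------------
# Matrix extraction
# ---------------------------------------------------------------------------

def extract_subfamily_matrix(
    m: CountMatrix, ann: pd.DataFrame, family: str
) -> CountMatrix:
    """Counts of one cell-type family: its cells, genes with any count there."""
    cells = ann.loc[ann["cluster"].astype(str) == str(family), "cell_id"].tolist()
    if not cells:
        raise AtlasError(f"family {family!r} has no cells in the annotation")
    sub = m.subset(cells=cells)
    totals = np.asarray(sub.values.sum(axis=1)).ravel()
    genes = [g for g, t in zip(sub.gene_ids, totals) if t > 0]
    return sub.subset(genes=genes)


# ---------------------------------------------------------------------------
# Independent swap
# ---------------------------------------------------------------------------

@njit(cache=True)
def _swap_kernel(m, ri, rk, cj, cl):  # pragma: no cover - compiled
    successes = 0
    for t in range(ri.shape[0]):
        i, k, j, l = ri[t], rk[t], cj[t], cl[t]
        a = m[i, j]
        b = m[k, l]
        c = m[i, l]
        e = m[k, j]
        if a > 0 and b > 0 and c == 0 and e == 0:
            m[i, l] = a
            m[k, j] = b
            m[i, j] = 0.0
            m[k, l] = 0.0
            successes += 1
        elif c > 0 and e > 0 and a == 0 and b == 0:
            m[i, j] = c
            m[k, l] = e
            m[i, l] = 0.0
            m[k, j] = 0.0
            successes += 1
    return successes


def _quartets(rng: np.random.Generator, nr: int, nc: int, n: int):
    ri = rng.integers(nr, size=n)
    rk = rng.integers(nr - 1, size=n)
    rk = rk + (rk >= ri)
    cj = rng.integers(nc, size=n)
    cl = rng.integers(nc - 1, size=n)
    cl = cl + (cl >= cj)
    return ri, rk, cj, cl


def independent_swap(
    m: np.ndarray,
    n_iter: int = 100_000,
    seed: int | np.random.Generator = 0,
    count_successful: bool = False,
    max_attempt_factor: int = 100,
) -> np.ndarray:
    """Randomize a non-negative matrix under the independent-swap null.

    ``n_iter`` counts attempted swaps (uniformly sampled 2x2 quartets, most
    of which are not checkerboards and leave the matrix unchanged); with
    ``count_successful=True`` it counts successful swaps instead, attempting
    at most ``max_attempt_factor * n_iter`` quartets. Returns a new matrix;
    the input is untouched.
    """
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ParameterError("independent swap needs a matrix with >= 2 rows and columns")
    if n_iter < 0:
        raise ParameterError("n_iter must be non-negative")
    if m.min() < 0:
        raise IntegrityError("matrix entries must be non-negative")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    out = np.ascontiguousarray(m.copy())
    if n_iter == 0:
        return out
    nr, nc = out.shape
    if not count_successful:
        out_successes = _swap_kernel(out, *_quartets(rng, nr, nc, n_iter))
        return out
    done = 0
    attempted = 0
    budget = max_attempt_factor * n_iter
    while done < n_iter and attempted < budget:
        batch = min(n_iter, budget - attempted)
        done += _swap_kernel(out, *_quartets(rng, nr, nc, batch))
        attempted += batch
    return out


# ---------------------------------------------------------------------------
# Panel counting
# ---------------------------------------------------------------------------

def _count_rows(block: np.ndarray, rule: str, threshold: float) -> int:
    if rule == "any_cell":
        return int((block > 0).any(axis=1).sum())
    if rule == "mean_gt0":
        return int((block.mean(axis=1) > 0).sum())
    if rule == "mean_gt_thr":
        return int((block.mean(axis=1) > threshold).sum())
    raise ParameterError(f"unknown rule {rule!r}; choose from {RULES}")


def panel_expressed_count(
    m: CountMatrix,
    genes: GeneSetPanel,
    rule: str = "any_cell",
    threshold: float = 0.0,
) -> int:
    """Number of panel genes satisfying the detection rule in the matrix.

    Panel genes absent from the matrix count as not expressed. Rules:
    ``any_cell`` (>= 1 nonzero entry), ``mean_gt0``, ``mean_gt_thr``
    (mean over cells strictly above ``threshold``).
    """
    gi = m.gene_index()
    rows = [gi[g] for g in genes.gene_ids if g in gi]
    if not rows:
        return 0
    block = np.asarray(m.values[rows].todense(), dtype=float)
    return _count_rows(block, rule, threshold)


# ---------------------------------------------------------------------------
# Chi-squared test on a 2x2 table
# ---------------------------------------------------------------------------

@dataclass
class ContingencyTable2x2:
    """Rows {actual, randomized} x columns {expressed, not expressed}."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise IntegrityError("contingency counts must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


def chi_squared_2x2(
    t: ContingencyTable2x2, continuity: bool = True
) -> tuple[float, float]:
    """Pearson chi-squared for a 2x2 table, Yates-corrected by default.

    chi2 = N (|ad - bc| - N/2)^2 / (r1 r2 c1 c2) with the N/2 term only under
    the continuity correction (floored at zero); p from chi-squared with one
    degree of freedom. Degenerate tables (a zero row or column margin) return
    (0, 1).
    """
    a, b, c, d = (float(x) for x in (t.a, t.b, t.c, t.d))
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        return 0.0, 1.0
    dev = abs(a * d - b * c)
    if continuity:
        dev = max(dev - n / 2.0, 0.0)
    chi2 = n * dev**2 / (r1 * r2 * c1 * c2)
    return chi2, float(stats.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# The full randomization test
# ---------------------------------------------------------------------------

@dataclass
class CoexpressionTestResult:
    """Observed vs randomized panel expression in a target subcluster."""

    panel: GeneSetPanel
    target: str
    G: int
    k_obs: int
    k_rand_mean: float
    k_rand_rounded: int
    per_replicate_counts: list[int]
    table: ContingencyTable2x2
    chi2: float
    p: float
    p_empirical: float
    params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "panel": self.panel.name,
            "panel_size": self.G,
            "target_subcluster": self.target,
            "k_obs": self.k_obs,
            "k_rand_mean": self.k_rand_mean,
            "k_rand_rounded": self.k_rand_rounded,
            "contingency_table": self.table.as_array().astype(int).tolist(),
            "chi2": self.chi2,
            "p": self.p,
            "p_empirical": self.p_empirical,
            "params": self.params,
        }


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def coexpression_test(
    m: CountMatrix,
    ann: pd.DataFrame,
    family: str,
    target_subcluster: str,
    panel: GeneSetPanel,
    n_swap_iters: int = 100_000,
    n_replicates: int = 500,
    rule: str = "any_cell",
    threshold: float = 0.0,
    seed: int = 0,
    continuity: bool = True,
    count_successful: bool = False,
) -> CoexpressionTestResult:
    """Independent-swap significance test for panel expression in a subcluster.

    The family-level submatrix (all cells of ``family``, genes detected
    there) is randomized ``n_replicates`` times with ``n_swap_iters``
    swap attempts each (replicate-specific substreams of ``seed``); the panel
    count is read from the target subcluster's columns of each randomized
    matrix. The chi-squared p compares observed vs rounded-mean randomized
    proportions; ``p_empirical`` is (1 + #{replicate counts >= observed}) /
    (n_replicates + 1).
    """
    if n_replicates < 1:
        raise ParameterError("n_replicates must be at least 1")
    if rule not in RULES:
        raise ParameterError(f"unknown rule {rule!r}; choose from {RULES}")
    fam = extract_subfamily_matrix(m, ann, family)
    if "subcluster" not in ann.columns:
        raise AtlasError("annotation has no 'subcluster' column")
    target_cells = ann.loc[
        ann["subcluster"].astype(str) == str(target_subcluster), "cell_id"
    ].tolist()
    if not target_cells:
        raise AtlasError(f"target subcluster {target_subcluster!r} is empty")
    fam_cells = set(fam.cell_ids)
    outside = [c for c in target_cells if c not in fam_cells]
    if outside:
        raise AtlasError(
            f"target subcluster {target_subcluster!r} has cells outside family "
            f"{family!r}, e.g. {outside[:5]}"
        )

    col_of = fam.cell_index()
    target_cols = np.array([col_of[c] for c in target_cells], dtype=int)
    gi = fam.gene_index()
    panel_rows = np.array(
        [gi[g] for g in panel.gene_ids if g in gi], dtype=int
    )
    G = len(panel)
    k_obs = panel_expressed_count(
        fam.subset(cells=target_cells), panel, rule=rule, threshold=threshold
    )

    dense = np.ascontiguousarray(fam.values.todense(), dtype=float)
    streams = np.random.SeedSequence(seed).spawn(n_replicates)
    counts = []
    for ss in streams:
        rnd = independent_swap(
            dense,
            n_iter=n_swap_iters,
            seed=np.random.default_rng(ss),
            count_successful=count_successful,
        )
        if len(panel_rows):
            block = rnd[np.ix_(panel_rows, target_cols)]
            counts.append(_count_rows(block, rule, threshold))
        else:
            counts.append(0)

    k_rand_mean = float(np.mean(counts))
    k_rand_rounded = _round_half_up(k_rand_mean)
    table = ContingencyTable2x2(k_obs, G - k_obs, k_rand_rounded, G - k_rand_rounded)
    chi2, p = chi_squared_2x2(table, continuity=continuity)
    p_emp = (1 + sum(c >= k_obs for c in counts)) / (n_replicates + 1)
    return CoexpressionTestResult(
        panel=panel,
        target=str(target_subcluster),
        G=G,
        k_obs=k_obs,
        k_rand_mean=k_rand_mean,
        k_rand_rounded=k_rand_rounded,
        per_replicate_counts=[int(c) for c in counts],
        table=table,
        chi2=chi2,
        p=p,
        p_empirical=float(p_emp),
        params={
            "family": str(family),
            "n_swap_iters": n_swap_iters,
            "n_replicates": n_replicates,
            "rule": rule,
            "threshold": threshold,
            "seed": seed,
            "continuity": continuity,
            "count_successful": count_successful,
        },
    )
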