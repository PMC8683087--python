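"""Data model and readers/writers for the atlas pipeline.

External formats handled here:

* 10x-style Matrix Market directories (``matrix.mtx`` + ``features.tsv`` +
  ``barcodes.tsv``, plain or gzipped) for sparse gene x cell count matrices;
* tab-separated tables (mandatory header, UTF-8) for cell annotations,
  gene lists, germ-layer maps and bulk differential-expression results;
* Newick for cell-type trees, with integer bootstrap percentages stored as
  internal-node labels;
* flat TOML key-value files for run configuration.

All readers enforce the invariants of the in-memory types and raise
:class:`FormatError` / :class:`IntegrityError` rather than silently dropping
or coercing rows.
"""

from __future__ import annotations

import gzip
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from skbio import TreeNode

logger = logging.getLogger("urchin_atlas")


def setup_logging(level: str = "INFO") -> None:
    """Configure package logging (used by the CLI; library code only emits)."""
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class AtlasError(Exception):
    """Base class for all package errors."""


class FormatError(AtlasError):
    """A file is missing or cannot be parsed (names the offending file)."""


class IntegrityError(AtlasError):
    """Parsed data violates a structural invariant (duplicates, dims, range)."""


class ConfigError(AtlasError):
    """An infeasible or inconsistent configuration."""


class ParameterError(AtlasError):
    """An operation parameter is out of its allowed range."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

def _check_unique(ids: Iterable[str], what: str) -> list[str]:
    ids = list(ids)
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dups = sorted({i for i in ids if i in seen or seen.add(i)})  # type: ignore[func-returns-value]
        raise IntegrityError(f"duplicate {what}: {dups[:10]}")
    return ids


@dataclass
class CountMatrix:
    """Sparse non-negative integer gene x cell count matrix.

    Rows are genes (``gene_ids``), columns are cells (``cell_ids``); both id
    lists are ordered and duplicate-free.
    """

    values: sp.csr_matrix
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.gene_ids = _check_unique((str(g) for g in self.gene_ids), "gene_ids")
        self.cell_ids = _check_unique((str(c) for c in self.cell_ids), "cell_ids")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise IntegrityError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if self.values.nnz and self.values.data.min() < 0:
            raise IntegrityError("negative counts are not allowed")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def cell_index(self) -> dict[str, int]:
        return {c: i for i, c in enumerate(self.cell_ids)}

    def subset(
        self,
        genes: Iterable[str] | None = None,
        cells: Iterable[str] | None = None,
    ) -> "CountMatrix":
        """Submatrix restricted to the given gene/cell ids (input order kept)."""
        gi = self.gene_index()
        ci = self.cell_index()
        rows = np.arange(self.n_genes) if genes is None else np.array(
            [gi[g] for g in genes], dtype=int
        )
        cols = np.arange(self.n_cells) if cells is None else np.array(
            [ci[c] for c in cells], dtype=int
        )
        vals = self.values[rows][:, cols]
        return CountMatrix(
            vals,
            [self.gene_ids[i] for i in rows],
            [self.cell_ids[j] for j in cols],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.cell_ids == other.cell_ids
            and (self.values != other.values).nnz == 0
        )


@dataclass
class GeneSetPanel:
    """A named, non-empty, duplicate-free set of gene identifiers."""

    name: str
    gene_ids: set[str]

    def __post_init__(self) -> None:
        self.gene_ids = set(map(str, self.gene_ids))
        if not self.gene_ids:
            raise IntegrityError(f"gene set panel {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def __iter__(self):
        return iter(sorted(self.gene_ids))


# Annotation and DE tables are plain DataFrames with validated columns;
# module functions below enforce the invariants.

ANNOTATION_COLUMNS = ("cell_id", "cluster", "subcluster", "replicate")
DE_COLUMNS = ("gene_id", "log_fc", "adj_p", "significant")


def validate_annotation(
    ann: pd.DataFrame, matrix: CountMatrix | None = None
) -> pd.DataFrame:
    """Check a cell annotation table (unique cell_id, known cells)."""
    if "cell_id" not in ann.columns or "cluster" not in ann.columns:
        raise FormatError("annotation requires 'cell_id' and 'cluster' columns")
    _check_unique(ann["cell_id"].astype(str), "cell_id")
    if matrix is not None:
        unknown = set(ann["cell_id"]) - set(matrix.cell_ids)
        if unknown:
            raise IntegrityError(
                f"annotation refers to cells absent from the matrix: "
                f"{sorted(unknown)[:10]}"
            )
    return ann


def validate_de_table(de: pd.DataFrame) -> pd.DataFrame:
    """Check a knockdown differential-expression table."""
    for col in ("gene_id", "log_fc", "adj_p"):
        if col not in de.columns:
            raise FormatError(f"DE table requires a {col!r} column")
    _check_unique(de["gene_id"].astype(str), "gene_id")
    bad = de[(de["adj_p"] < 0) | (de["adj_p"] > 1)]
    if len(bad):
        raise IntegrityError(
            f"adj_p outside [0, 1] for genes {bad['gene_id'].tolist()[:10]}"
        )
    return de


# ---------------------------------------------------------------------------
# MTX directory I/O
# ---------------------------------------------------------------------------

def _find(path: Path, stem: str, alts: tuple[str, ...] = ()) -> Path:
    for name in (stem, stem + ".gz", *alts, *(a + ".gz" for a in alts)):
        p = path / name
        if p.exists():
            return p
    raise FormatError(f"missing {stem}[.gz] in {path}")


def _read_id_table(path: Path) -> pd.DataFrame:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt", encoding="utf-8") as fh:
        try:
            return pd.read_csv(fh, sep="\t", header=None, dtype=str)
        except pd.errors.EmptyDataError:
            return pd.DataFrame(columns=[0])


def read_count_matrix(path: str | Path) -> CountMatrix:
    """Read a 10x-style MTX directory (matrix.mtx + features.tsv + barcodes.tsv).

    Feature tables may have one to three columns (id / id+name / id+name+type);
    gene identity is the first column, matched exactly. Plain or gzipped files
    are accepted.
    """
    path = Path(path)
    if not path.is_dir():
        raise FormatError(f"{path} is not a directory")
    mtx = _find(path, "matrix.mtx")
    feat = _find(path, "features.tsv", alts=("genes.tsv",))
    barc = _find(path, "barcodes.tsv")
    try:
        m = scipy.io.mmread(str(mtx))
    except Exception as exc:  # noqa: BLE001 - reraise as format error
        raise FormatError(f"cannot parse {mtx}: {exc}") from exc
    features = _read_id_table(feat)
    barcodes = _read_id_table(barc)
    if m.shape[0] != len(features):
        raise IntegrityError(
            f"{mtx} declares {m.shape[0]} genes but {feat} lists {len(features)}"
        )
    if m.shape[1] != len(barcodes):
        raise IntegrityError(
            f"{mtx} declares {m.shape[1]} cells but {barc} lists {len(barcodes)}"
        )
    values = sp.csr_matrix(m, dtype=np.int64)
    return CountMatrix(values, features[0].tolist(), barcodes[0].tolist())


def write_count_matrix(m: CountMatrix, path: str | Path) -> None:
    """Write an MTX directory readable by :func:`read_count_matrix`.

    Emits a coordinate integer Matrix Market file plus a three-column feature
    table (id, name, type) and a one-column barcode table, uncompressed.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    coo = sp.coo_matrix(m.values).astype(np.int64)
    scipy.io.mmwrite(str(path / "matrix.mtx"), coo, field="integer")
    feats = pd.DataFrame(
        {0: m.gene_ids, 1: m.gene_ids, 2: ["Gene Expression"] * m.n_genes}
    )
    feats.to_csv(path / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(m.cell_ids).to_csv(
        path / "barcodes.tsv", sep="\t", header=False, index=False
    )


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"missing file {path}")
    return pd.read_csv(path, sep="\t", dtype={0: str})


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a cell annotation TSV (cell_id, cluster[, subcluster, replicate])."""
    ann = _read_tsv(path)
    extra = [c for c in ann.columns if c not in ANNOTATION_COLUMNS]
    if extra:
        logger.warning("ignoring unknown annotation columns %s", extra)
        ann = ann.drop(columns=extra)
    ann = ann.astype({c: str for c in ann.columns if c in ("cell_id", "cluster")})
    return validate_annotation(ann)


def write_annotation(ann: pd.DataFrame, path: str | Path) -> None:
    validate_annotation(ann).to_csv(path, sep="\t", index=False)


def read_gene_list(path: str | Path, name: str | None = None) -> GeneSetPanel:
    """Read a gene list TSV with a ``gene_id`` column into a panel."""
    tab = _read_tsv(path)
    if "gene_id" not in tab.columns:
        raise FormatError(f"{path} has no 'gene_id' column")
    extra = [c for c in tab.columns if c != "gene_id"]
    if extra:
        logger.warning("ignoring unknown gene-list columns %s", extra)
    genes = _check_unique(tab["gene_id"].astype(str), "gene_id")
    return GeneSetPanel(name or Path(path).stem, set(genes))


def write_gene_list(panel: GeneSetPanel, path: str | Path) -> None:
    pd.DataFrame({"gene_id": sorted(panel.gene_ids)}).to_csv(
        path, sep="\t", index=False
    )


def read_de_table(path: str | Path, alpha: float = 0.05) -> pd.DataFrame:
    """Read a knockdown DE TSV (gene_id, log_fc, adj_p[, significant]).

    log_fc is oriented knockdown-vs-control: negative means downregulated in
    the knockdown. A missing ``significant`` column is derived as
    ``adj_p < alpha``.
    """
    de = _read_tsv(path)
    extra = [c for c in de.columns if c not in DE_COLUMNS]
    if extra:
        logger.warning("ignoring unknown DE columns %s", extra)
        de = de.drop(columns=extra)
    de = validate_de_table(de)
    if "significant" not in de.columns:
        de = de.assign(significant=de["adj_p"] < alpha)
    de["significant"] = de["significant"].astype(bool)
    return de


def write_de_table(de: pd.DataFrame, path: str | Path) -> None:
    validate_de_table(de).to_csv(path, sep="\t", index=False)


def read_layer_map(path: str | Path) -> dict[str, str]:
    """Read a cluster -> germ layer TSV (columns: cluster, layer)."""
    tab = _read_tsv(path)
    for col in ("cluster", "layer"):
        if col not in tab.columns:
            raise FormatError(f"{path} has no {col!r} column")
    _check_unique(tab["cluster"].astype(str), "cluster")
    allowed = {"ectoderm", "mesoderm", "endoderm"}
    bad = set(tab["layer"]) - allowed
    if bad:
        raise IntegrityError(f"unknown germ layers {sorted(bad)}; allowed {sorted(allowed)}")
    return dict(zip(tab["cluster"].astype(str), tab["layer"]))


# ---------------------------------------------------------------------------
# Newick trees
# ---------------------------------------------------------------------------
# CellTypeTree is represented as an skbio TreeNode: leaves carry cluster
# labels, branch lengths are non-negative reals, and integer bootstrap
# percentages live in internal-node labels.

CellTypeTree = TreeNode


def write_newick(tree: TreeNode, path: str | Path) -> None:
    """Serialize a tree to Newick with branch lengths and support labels."""
    tree.write(str(path), format="newick")


def read_newick(path: str | Path) -> TreeNode:
    """Parse a Newick tree; raises :class:`FormatError` on malformed input."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"missing file {path}")
    try:
        return TreeNode.read(str(path), format="newick", convert_underscores=False)
    except Exception as exc:  # skbio NewickFormatError carries the position
        raise FormatError(f"cannot parse newick {path}: {exc}") from exc


def bipartitions(tree: TreeNode) -> set[frozenset[frozenset[str]]]:
    """Non-trivial leaf bipartitions of an (unrooted) tree.

    Each split is the unordered pair {side, complement} of leaf-name sets, so
    the result is invariant to rooting; only internal edges (both sides with
    at least two leaves) are reported.
    """
    leaves = frozenset(l.name for l in tree.tips())
    out: set[frozenset[frozenset[str]]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(l.name for l in node.tips())
        other = leaves - side
        if len(side) >= 2 and len(other) >= 2:
            out.add(frozenset((side, other)))
    return out


# ---------------------------------------------------------------------------
# Config and JSON results
# ---------------------------------------------------------------------------

def read_config(path: str | Path) -> dict:
    """Read a flat TOML key-value configuration file."""
    import tomllib

    path = Path(path)
    if not path.exists():
        raise FormatError(f"missing config file {path}")
    with open(path, "rb") as fh:
        try:
            return tomllib.load(fh)
        except tomllib.TOMLDecodeError as exc:
            raise FormatError(f"cannot parse config {path}: {exc}") from exc


def write_json(obj: Mapping, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, default=_default)
        fh.write("\n")
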