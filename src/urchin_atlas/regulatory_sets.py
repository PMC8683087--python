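"""Germ-layer transcription-factor sharing and knockdown-DE intersection.

Builds per-germ-layer expressed transcription-factor sets (union over the
layer's clusters of expressed genes intersected with a TF catalogue), counts
the seven exclusive regions of the three-set Venn, tabulates pairwise shared
counts, and intersects a subcluster's expressed genes with a bulk knockdown
differential-expression table to summarize putative targets and the fraction
downregulated.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core_io import AtlasError, GeneSetPanel, ParameterError, validate_de_table
from .profiles import ExpressedGeneSets

VENN_REGIONS = ("a_only", "b_only", "c_only", "ab", "ac", "bc", "abc")


def layer_tf_sets(
    expressed: ExpressedGeneSets,
    layers: dict[str, str],
    tf_catalogue: GeneSetPanel,
) -> dict[str, set[str]]:
    """Expressed transcription factors per germ layer.

    For each layer: the union over its clusters of (cluster expressed set
    intersected with the catalogue). Every cluster in ``expressed`` must be
    mapped to a layer.
    """
    unmapped = [c for c in expressed.sets if c not in layers]
    if unmapped:
        raise AtlasError(f"clusters missing from the germ-layer map: {unmapped}")
    out: dict[str, set[str]] = {layer: set() for layer in sorted(set(layers.values()))}
    for cluster, genes in expressed.sets.items():
        out[layers[cluster]] |= genes & tf_catalogue.gene_ids
    return out


@dataclass
class VennCounts:
    """Exclusive region counts of a three-set Venn diagram."""

    regions: dict[str, int]

    def total(self) -> int:
        return sum(self.regions.values())


def venn_regions(a: set, b: set, c: set) -> VennCounts:
    """Exact exclusive region counts for three sets (sum equals |a U b U c|)."""
    abc = a & b & c
    ab = (a & b) - abc
    ac = (a & c) - abc
    bc = (b & c) - abc
    return VennCounts(
        {
            "a_only": len(a - b - c),
            "b_only": len(b - a - c),
            "c_only": len(c - a - b),
            "ab": len(ab),
            "ac": len(ac),
            "bc": len(bc),
            "abc": len(abc),
        }
    )


def venn_region_members(a: set, b: set, c: set) -> dict[str, set]:
    """The gene sets behind each exclusive Venn region."""
    abc = a & b & c
    return {
        "a_only": a - b - c,
        "b_only": b - a - c,
        "c_only": c - a - b,
        "ab": (a & b) - abc,
        "ac": (a & c) - abc,
        "bc": (b & c) - abc,
        "abc": abc,
    }


def pairwise_shared(sets: dict[str, set]) -> pd.DataFrame:
    """Symmetric matrix of pairwise intersection sizes (diagonal: set sizes)."""
    if len(sets) < 2:
        raise ParameterError("pairwise sharing needs at least two sets")
    labels = sorted(sets)
    out = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for i in labels:
        for j in labels:
            out.loc[i, j] = len(sets[i] & sets[j])
    return out


@dataclass
class IntersectionSummary:
    """Overlap of a subcluster's genes with significant knockdown DE genes."""

    n_cluster_genes: int
    n_de: int
    n_overlap: int
    n_down: int
    frac_down: float | None
    overlap: pd.DataFrame  # gene_id, log_fc, adj_p

    def to_dict(self) -> dict:
        return {
            "n_cluster_genes": self.n_cluster_genes,
            "n_de": self.n_de,
            "n_overlap": self.n_overlap,
            "n_down": self.n_down,
            "frac_down": self.frac_down,
        }


def kd_intersect(
    cluster_genes: set[str], de: pd.DataFrame, alpha: float = 0.05
) -> IntersectionSummary:
    """Intersect a gene set with significant knockdown DE genes.

    A DE gene is significant when ``adj_p < alpha``; downregulated means
    ``log_fc < 0`` in the knockdown-vs-control orientation. ``frac_down`` is
    None when the overlap is empty.
    """
    if not 0.0 < alpha <= 1.0:
        raise ParameterError("alpha must lie in (0, 1]")
    de = validate_de_table(de)
    sig = de[de["adj_p"] < alpha]
    overlap = sig[sig["gene_id"].isin(cluster_genes)].copy()
    overlap = overlap.sort_values("adj_p").reset_index(drop=True)
    n_overlap = len(overlap)
    n_down = int((overlap["log_fc"] < 0).sum())
    return IntersectionSummary(
        n_cluster_genes=len(cluster_genes),
        n_de=int(len(sig)),
        n_overlap=n_overlap,
        n_down=n_down,
        frac_down=(n_down / n_overlap) if n_overlap else None,
        overlap=overlap[["gene_id", "log_fc", "adj_p"]],
    )
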