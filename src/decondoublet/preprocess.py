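"""Label standardization and optional cell-cycle gene-cluster removal.

Before reference construction, cluster labels (which may be strings from
upstream tools) are converted to 1..K integers in order of first appearance
along the cell axis, preserving the left-to-right ordering of the clustered
heatmap. Optionally, gene clusters enriched for cell-cycle genes are removed
wholesale: cycling subpopulations can split one cell type into several
clusters, which degrades the merged references used for deconvolution.

Enrichment is a one-sided hypergeometric test of each gene cluster against a
bundled (user-overridable) cell-cycle gene set, with Benjamini-Hochberg
correction across gene clusters; clusters with adjusted p <= alpha are
dropped from all downstream analyses.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io_formats import AnnotatedExpression

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "bundled_cell_cycle",
    "standardize_labels",
    "remove_cell_cycle",
]


@dataclass
class GeneSetCollection:
    """Named gene sets plus the rule for the enrichment background.

    ``universe_policy`` is fixed to ``"expression-table"``: the background is
    the set of genes present in the marker expression table.
    """

    sets: dict[str, set]
    universe_policy: str = "expression-table"

    def union(self) -> set:
        out: set = set()
        for genes in self.sets.values():
            out |= genes
        return out


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file (set name, description, gene symbols...)."""
    sets: dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = {g.upper() for g in parts[2:] if g}
    return GeneSetCollection(sets)


def bundled_cell_cycle(species: str = "Hs") -> GeneSetCollection:
    """The shipped cell-cycle gene set for species 'Hs' or 'Mm'."""
    if species not in ("Hs", "Mm"):
        raise ValueError(f"species must be 'Hs' or 'Mm', got {species!r}")
    ref = importlib.resources.files("decondoublet.data") / f"cell_cycle_{species}.gmt"
    with importlib.resources.as_file(ref) as path:
        return read_gmt(path)


def _first_appearance_map(labels: pd.Series) -> dict:
    mapping: dict = {}
    for lab in labels:
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
    return mapping


def standardize_labels(
    ae: AnnotatedExpression,
) -> tuple[AnnotatedExpression, dict]:
    """Convert cell- and gene-cluster labels to 1..K integers.

    Numbering follows order of first appearance along the (cluster-contiguous)
    cell axis / gene axis. Returns the relabeled table plus
    ``{"cells": original -> int, "genes": original -> int}``.
    """
    cell_map = _first_appearance_map(ae.cell_cluster)
    new_cc = ae.cell_cluster.map(cell_map)
    gene_map: dict = {}
    new_gc = None
    if ae.gene_cluster is not None:
        gene_map = _first_appearance_map(ae.gene_cluster)
        new_gc = ae.gene_cluster.map(gene_map)
    out = AnnotatedExpression(ae.values, new_cc, new_gc)
    return out, {"cells": cell_map, "genes": gene_map}


def remove_cell_cycle(
    ae: AnnotatedExpression,
    gene_sets: GeneSetCollection,
    alpha: float = 0.05,
) -> tuple[AnnotatedExpression, pd.DataFrame]:
    """Drop gene clusters enriched for cell-cycle genes.

    For each gene cluster, a one-sided hypergeometric test of its overlap
    with the cell-cycle set against the expression-table universe; p-values
    BH-adjusted across gene clusters; every gene of each cluster with
    adjusted p <= alpha is removed. Returns the filtered table and a report
    (cluster, size, overlap, p, p_adj, removed).
    """
    if ae.gene_cluster is None:
        raise ValueError(
            "no gene clusters supplied; disable cell-cycle removal or provide "
            "a gene-clustered expression file"
        )
    if not (0 <= alpha < 1):
        raise ValueError(f"alpha must be in [0, 1), got {alpha}")
    universe = {str(g).upper() for g in ae.genes}
    cc = gene_sets.union() & universe
    M, n_cc = len(universe), len(cc)

    rows = []
    for cid in pd.unique(ae.gene_cluster):
        members = [g for g in ae.genes if ae.gene_cluster[g] == cid]
        overlap = sum(str(g).upper() in cc for g in members)
        N = len(members)
        p = float(hypergeom.sf(overlap - 1, M, n_cc, N))
        rows.append({"gene_cluster": cid, "size": N, "overlap": overlap, "p": p})
    report = pd.DataFrame(rows)
    if len(report):
        report["p_adj"] = multipletests(report["p"], method="fdr_bh")[1]
        report["removed"] = (report["p_adj"] <= alpha) & (alpha > 0)
    else:
        report["p_adj"] = []
        report["removed"] = []

    removed_clusters = set(report.loc[report["removed"], "gene_cluster"])
    keep = [g for g in ae.genes if ae.gene_cluster[g] not in removed_clusters]
    return ae.subset_genes(keep), report
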