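"""Readers and writers for the tab-delimited marker/cluster file dialect.

The pipeline consumes three related files produced by upstream unsupervised
clustering workflows (ICGS-style):

* a *clustered expression* file: marker genes x ordered cells, carrying a
  per-cell cluster row and an optional per-gene cluster column,
* a *groups* file mapping every cell to its cluster label,
* optionally the *full* expression matrix (all genes).

Seurat-style exports (normalized log expression + marker table + identities)
are converted into the same in-memory structure by :func:`seurat_prep`.

Dialect (pinned, since upstream tools vary):

* expression file: row 1 holds cell identifiers (first header token is an
  arbitrary corner label, second is ``row_clusters-flat`` when per-gene
  clusters are present); row 2 is ``column_clusters-flat`` with the numeric
  cluster of each cell; column 1 holds gene identifiers; the remaining body
  is numeric.
* groups file: two tab-separated columns (cell id, cluster label), no header.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "AnnotatedExpression",
    "OutputBundle",
    "read_icgs",
    "write_icgs",
    "seurat_prep",
    "write_outputs",
]

GENE_CLUSTER_TOKEN = "row_clusters-flat"
CELL_CLUSTER_TOKEN = "column_clusters-flat"

OUTPUT_FILES = (
    "DRS_doublet_table.txt",
    "DRS_results.txt",
    "Final_doublets_groups.txt",
    "Final_nondoublets_groups.txt",
    "Final_doublets_exp.txt",
    "Final_nondoublets_exp.txt",
    "Synthetic_doublet_DCPs.txt",
)


class FormatError(ValueError):
    """Raised when an input file violates the expected dialect."""


@dataclass
class AnnotatedExpression:
    """Genes x cells expression table with cluster annotations.

    Parameters
    ----------
    values
        Log-normalized expression, genes as rows and cells as columns.
        Must be finite and non-negative.
    cell_cluster
        Cluster label for every cell (indexed by cell identifier).
    gene_cluster
        Optional gene-cluster label for every gene.
    """

    values: pd.DataFrame
    cell_cluster: pd.Series
    gene_cluster: pd.Series | None = None

    def __post_init__(self) -> None:
        self.values = self.values.copy()
        self.cell_cluster = pd.Series(self.cell_cluster).copy()
        if self.gene_cluster is not None:
            self.gene_cluster = pd.Series(self.gene_cluster).copy()
        self._validate()

    def _validate(self) -> None:
        genes = self.values.index
        cells = self.values.columns
        for axis, ids in (("gene", genes), ("cell", cells)):
            if ids.duplicated().any():
                dupes = sorted(set(ids[ids.duplicated()]))
                raise FormatError(f"duplicate {axis} identifiers: {dupes[:10]}")
        missing = [c for c in cells if c not in self.cell_cluster.index]
        if missing:
            raise FormatError(f"cells without a cluster label: {missing[:10]}")
        self.cell_cluster = self.cell_cluster.loc[cells]
        vals = self.values.to_numpy()
        if not np.isfinite(vals).all():
            raise FormatError("expression values must be finite")
        if (vals < 0).any():
            raise FormatError("expression values must be non-negative")
        if self.gene_cluster is not None:
            missing_g = [g for g in genes if g not in self.gene_cluster.index]
            if missing_g:
                raise FormatError(
                    f"genes without a gene-cluster label: {missing_g[:10]}"
                )
            self.gene_cluster = self.gene_cluster.loc[genes]

    # -- convenience accessors -------------------------------------------------
    @property
    def genes(self) -> list:
        return list(self.values.index)

    @property
    def cells(self) -> list:
        return list(self.values.columns)

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def cluster_ids(self) -> list:
        """Cluster labels in order of first appearance along the cell axis."""
        seen: dict = {}
        for c in self.cell_cluster:
            seen.setdefault(c, None)
        return list(seen)

    def cells_of(self, cluster) -> list:
        mask = self.cell_cluster == cluster
        return list(self.cell_cluster.index[mask])

    def subset_genes(self, genes) -> "AnnotatedExpression":
        gc = self.gene_cluster.loc[genes] if self.gene_cluster is not None else None
        return AnnotatedExpression(self.values.loc[genes], self.cell_cluster, gc)

    def subset_cells(self, cells) -> "AnnotatedExpression":
        return AnnotatedExpression(
            self.values[list(cells)], self.cell_cluster.loc[list(cells)],
            self.gene_cluster,
        )

    def ordered_by_cluster(self) -> "AnnotatedExpression":
        """Reorder cells so same-cluster cells are contiguous.

        Clusters keep their order of first appearance; within-cluster
        order is preserved.
        """
        order: list = []
        for cid in self.cluster_ids():
            order.extend(self.cells_of(cid))
        return self.subset_cells(order)


@dataclass
class OutputBundle:
    """The seven tabular outputs of a pipeline run.

    ``final_doublets_groups`` and ``final_nondoublets_groups`` must
    partition the input cells.
    """

    drs_doublet_table: pd.DataFrame
    drs_results: pd.DataFrame
    final_doublets_groups: pd.DataFrame
    final_nondoublets_groups: pd.DataFrame
    final_doublets_exp: pd.DataFrame
    final_nondoublets_exp: pd.DataFrame
    synthetic_dcps: pd.DataFrame

    def __post_init__(self) -> None:
        doub = set(self.final_doublets_groups.index)
        nond = set(self.final_nondoublets_groups.index)
        allc = set(self.drs_results.index)
        if doub & nond:
            raise FormatError("doublet and non-doublet cell sets overlap")
        if doub | nond != allc:
            raise FormatError("doublets + non-doublets do not partition the cells")


def _parse_body(df: pd.DataFrame, path: str) -> pd.DataFrame:
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        raw = df[col]
        try:
            # astype(float) round-trips repr() output exactly
            out[col] = raw.astype(float)
        except (ValueError, TypeError):
            converted = pd.to_numeric(raw, errors="coerce")
            bad = converted.isna() & ~raw.isna()
            gene = bad.idxmax()
            raise FormatError(
                f"{path}: non-numeric expression value {raw[gene]!r} "
                f"at gene {gene!r}, cell {col!r}"
            ) from None
    return out


def read_icgs(
    expression_path: str | os.PathLike,
    groups_path: str | os.PathLike,
    full_expression_path: str | os.PathLike | None = None,
) -> AnnotatedExpression | tuple[AnnotatedExpression, AnnotatedExpression]:
    """Read clustered expression + groups files into an AnnotatedExpression.

    Cluster labels are taken from the groups file; gene clusters from the
    expression file when present. When ``full_expression_path`` is given,
    a second AnnotatedExpression (all genes, same cells/labels) is returned.
    """
    raw = pd.read_csv(expression_path, sep="\t", index_col=0, dtype=str)
    has_gene_clusters = len(raw.columns) > 0 and raw.columns[0] == GENE_CLUSTER_TOKEN
    if CELL_CLUSTER_TOKEN not in raw.index:
        raise FormatError(
            f"{expression_path}: missing '{CELL_CLUSTER_TOKEN}' row"
        )
    gene_cluster = None
    if has_gene_clusters:
        gc_col = raw[GENE_CLUSTER_TOKEN].drop(CELL_CLUSTER_TOKEN, errors="ignore")
        gene_cluster = pd.to_numeric(gc_col).astype(int)
        raw = raw.drop(columns=[GENE_CLUSTER_TOKEN])
    body = raw.drop(index=CELL_CLUSTER_TOKEN)
    values = _parse_body(body, str(expression_path))

    groups = pd.read_csv(
        groups_path, sep="\t", header=None, names=["cell", "cluster"], dtype=str
    )
    if groups["cell"].duplicated().any():
        dup = sorted(set(groups["cell"][groups["cell"].duplicated()]))
        raise FormatError(f"{groups_path}: duplicate cell identifiers: {dup[:10]}")
    gcells = set(groups["cell"])
    ecells = set(values.columns)
    if gcells != ecells:
        only_g = sorted(gcells - ecells)
        only_e = sorted(ecells - gcells)
        raise FormatError(
            f"cell sets disagree between groups and expression files; "
            f"groups-only: {only_g[:10]}, expression-only: {only_e[:10]}"
        )
    labels = groups.set_index("cell")["cluster"]
    try:
        labels = labels.astype(int)
    except (ValueError, TypeError):
        pass
    ae = AnnotatedExpression(values, labels, gene_cluster)

    if full_expression_path is None:
        return ae
    if str(full_expression_path).endswith(".mtx"):
        full_vals = read_mtx(full_expression_path)
    else:
        raw_full = pd.read_csv(
            full_expression_path, sep="\t", index_col=0, dtype=str
        )
        if raw_full.columns[0] == GENE_CLUSTER_TOKEN:
            raw_full = raw_full.drop(columns=[GENE_CLUSTER_TOKEN])
        raw_full = raw_full.drop(index=CELL_CLUSTER_TOKEN, errors="ignore")
        full_vals = _parse_body(raw_full, str(full_expression_path))
    missing = [c for c in values.columns if c not in full_vals.columns]
    if missing:
        raise FormatError(
            f"full matrix is missing cells from the marker file: {missing[:10]}"
        )
    full_vals = full_vals[values.columns]
    full = AnnotatedExpression(full_vals, labels)
    return ae, full


def read_mtx(
    matrix_path: str | os.PathLike,
    features_path: str | os.PathLike | None = None,
    barcodes_path: str | os.PathLike | None = None,
) -> pd.DataFrame:
    """Load a MatrixMarket genes x cells matrix, densified.

    ``features_path`` / ``barcodes_path`` default to ``features.tsv`` (or
    ``genes.tsv``) and ``barcodes.tsv`` next to the matrix, following the
    droplet-pipeline directory convention. The feature file's first column
    is used as the gene identifier.
    """
    from scipy.io import mmread

    directory = os.path.dirname(os.fspath(matrix_path))
    if features_path is None:
        for cand in ("features.tsv", "genes.tsv"):
            p = os.path.join(directory, cand)
            if os.path.exists(p):
                features_path = p
                break
        else:
            raise FormatError(
                f"no features.tsv/genes.tsv next to {matrix_path}"
            )
    if barcodes_path is None:
        barcodes_path = os.path.join(directory, "barcodes.tsv")
        if not os.path.exists(barcodes_path):
            raise FormatError(f"no barcodes.tsv next to {matrix_path}")
    genes = pd.read_csv(features_path, sep="\t", header=None)[0].astype(str)
    cells = pd.read_csv(barcodes_path, sep="\t", header=None)[0].astype(str)
    mat = np.asarray(mmread(matrix_path).todense(), dtype=float)
    if mat.shape != (len(genes), len(cells)):
        raise FormatError(
            f"matrix shape {mat.shape} does not match "
            f"{len(genes)} features x {len(cells)} barcodes"
        )
    return pd.DataFrame(mat, index=genes, columns=cells)


def write_icgs(
    ae: AnnotatedExpression,
    expression_path: str | os.PathLike,
    groups_path: str | os.PathLike,
) -> None:
    """Write an AnnotatedExpression in the dialect :func:`read_icgs` reads."""
    with open(expression_path, "w") as fh:
        cols = ae.cells
        header = ["UID"]
        if ae.gene_cluster is not None:
            header.append(GENE_CLUSTER_TOKEN)
        header.extend(str(c) for c in cols)
        fh.write("\t".join(header) + "\n")
        row = [CELL_CLUSTER_TOKEN]
        if ae.gene_cluster is not None:
            row.append("")
        row.extend(str(ae.cell_cluster[c]) for c in cols)
        fh.write("\t".join(row) + "\n")
        mat = ae.values.to_numpy()
        for i, g in enumerate(ae.genes):
            row = [str(g)]
            if ae.gene_cluster is not None:
                row.append(str(ae.gene_cluster[g]))
            row.extend(repr(float(v)) for v in mat[i])
            fh.write("\t".join(row) + "\n")
    with open(groups_path, "w") as fh:
        for c in ae.cells:
            fh.write(f"{c}\t{ae.cell_cluster[c]}\n")


def seurat_prep(
    normalized_expression: pd.DataFrame,
    marker_table: pd.DataFrame,
    cluster_identities: Mapping | pd.Series,
    top_n: int = 50,
    already_log: bool = True,
) -> tuple[AnnotatedExpression, pd.DataFrame, AnnotatedExpression]:
    """Convert Seurat-style exports into the pipeline's input structure.

    Parameters
    ----------
    normalized_expression
        Genes x cells normalized expression matrix.
    marker_table
        Columns ``gene``, ``cluster``, ``rank`` (rank 1 = top marker).
    cluster_identities
        Cell -> cluster mapping covering every expression column.
    top_n
        Number of top markers retained per cluster (default 50).
    already_log
        When False, values are converted to log2(x + 1).

    Returns
    -------
    (marker AnnotatedExpression, groups table, full AnnotatedExpression)
    """
    idents = pd.Series(cluster_identities)
    missing = [c for c in normalized_expression.columns if c not in idents.index]
    if missing:
        raise FormatError(f"cells without identities: {missing[:10]}")
    idents = idents.loc[normalized_expression.columns]

    expr = normalized_expression.astype(float)
    if not already_log:
        expr = np.log2(expr + 1.0)

    present = set(expr.index)
    marker_genes: list = []
    gene_cluster_map: dict = {}
    for cid, sub in marker_table.groupby("cluster", sort=False):
        sub = sub.sort_values("rank", kind="stable").head(top_n)
        if sub.empty:
            raise FormatError(f"cluster {cid!r} has no marker genes")
        for g in sub["gene"]:
            if g not in present:
                import warnings

                warnings.warn(
                    f"marker gene {g!r} absent from expression matrix; dropped",
                    stacklevel=2,
                )
                continue
            if g not in gene_cluster_map:
                gene_cluster_map[g] = cid
                marker_genes.append(g)

    # cells ordered by cluster (order of first appearance), stable within
    cell_order: list = []
    seen: dict = {}
    for c in expr.columns:
        seen.setdefault(idents[c], []).append(c)
    for cid in seen:
        cell_order.extend(seen[cid])

    marker_vals = expr.loc[marker_genes, cell_order]
    gene_cluster = pd.Series(
        [gene_cluster_map[g] for g in marker_genes], index=marker_genes
    )
    marker_ae = AnnotatedExpression(marker_vals, idents.loc[cell_order], gene_cluster)
    groups = pd.DataFrame(
        {"cell": cell_order, "cluster": [idents[c] for c in cell_order]}
    )
    full_ae = AnnotatedExpression(expr[cell_order], idents.loc[cell_order])
    return marker_ae, groups, full_ae


def write_outputs(bundle: OutputBundle, directory: str | os.PathLike) -> dict:
    """Write the seven tabular outputs; returns a name -> path map."""
    os.makedirs(directory, exist_ok=True)
    frames = {
        "DRS_doublet_table.txt": bundle.drs_doublet_table,
        "DRS_results.txt": bundle.drs_results,
        "Final_doublets_groups.txt": bundle.final_doublets_groups,
        "Final_nondoublets_groups.txt": bundle.final_nondoublets_groups,
        "Final_doublets_exp.txt": bundle.final_doublets_exp,
        "Final_nondoublets_exp.txt": bundle.final_nondoublets_exp,
        "Synthetic_doublet_DCPs.txt": bundle.synthetic_dcps,
    }
    paths = {}
    for name, frame in frames.items():
        path = os.path.join(directory, name)
        frame.to_csv(path, sep="\t")
        paths[name] = path
    return paths
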