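"""Remove -> Recluster -> Rescue: turning DCPs into final doublet calls.

*Remove*: each cell's DCP is compared against (a) the centroid DCP of every
reference cluster and (b) the mean DCP of every synthetic doublet set. The
similarity is Pearson correlation when there are more than 2 references and
negative Euclidean distance when there are exactly 2 (length-2 DCPs make
Pearson degenerate). A cell whose best match is a synthetic set becomes a
putative doublet; exact ties resolve toward singlet.

*Recluster*: putative doublets are grouped by their two largest DCP
components ("a|b", ids sorted ascending); in weighted-synthetics mode the
weight-class suffix of the best-matching synthetic set (".even", ".one",
".two") is appended. Putative doublets leave their original clusters.

*Rescue*: for each doublet cluster Z_j, genes uniquely expressed in Z_j are
counted: a gene is unique when the overall one-way ANOVA p <= 0.05, every
Tukey-adjusted pairwise p of Z_j versus each retained cluster is <= 0.05,
and Z_j has strictly higher mean than every retained cluster. Clusters with
at least U unique genes are rescued wholesale (all member cells return to
their original clusters as singlets); the rest are final doublets.

The ANOVA/Tukey machinery works from per-cluster total sums (TS) and sums
of squares (TSS) on 1,000-gene chunks, so arbitrarily large matrices can be
processed with bounded memory; results are independent of chunk boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import AnnotatedExpression

__all__ = [
    "DoubletCalls",
    "RescueReport",
    "remove_step",
    "recluster_step",
    "rescue_step",
    "unique_genes",
    "chunked_anova",
    "ALPHA",
    "CHUNK_SIZE",
]

ALPHA = 0.05        # fixed significance level of the rescue tests
CHUNK_SIZE = 1000   # genes per ANOVA block


@dataclass
class DoubletCalls:
    """Per-cell call state through the pipeline.

    ``table`` is indexed by cell with columns: original_cluster, best_match,
    similarity, state (singlet / putative_doublet / rescued_singlet /
    final_doublet), recluster_label, final_label.
    """

    table: pd.DataFrame

    @property
    def putative_doublets(self) -> list:
        mask = self.table["state"].isin(
            ["putative_doublet", "rescued_singlet", "final_doublet"]
        )
        return list(self.table.index[mask])

    @property
    def final_doublets(self) -> list:
        return list(self.table.index[self.table["state"] == "final_doublet"])

    @property
    def non_doublets(self) -> list:
        return list(self.table.index[self.table["state"] != "final_doublet"])


@dataclass
class RescueReport:
    """Per doublet-cluster rescue outcome."""

    U: int
    clusters: pd.DataFrame  # index Z_j label; columns unique_gene_count, decision
    unique_gene_lists: dict = field(default_factory=dict)


def _similarity(cell_dcps: np.ndarray, cand: np.ndarray, n_refs: int) -> np.ndarray:
    """Cells x candidates similarity matrix (higher = more similar)."""
    if n_refs == 2:
        diff = cell_dcps[:, None, :] - cand[None, :, :]
        return -np.sqrt((diff ** 2).sum(axis=2))
    a = cell_dcps - cell_dcps.mean(axis=1, keepdims=True)
    b = cand - cand.mean(axis=1, keepdims=True)
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    degen_a = na == 0
    degen_b = nb == 0
    if degen_a.any() or degen_b.any():
        warnings.warn(
            "constant DCP vector(s): Pearson similarity undefined, "
            "treated as -inf",
            stacklevel=3,
        )
    na[degen_a] = 1.0
    nb[degen_b] = 1.0
    sim = (a / na[:, None]) @ (b / nb[:, None]).T
    sim[degen_a, :] = -np.inf
    sim[:, degen_b] = -np.inf
    return sim


def remove_step(
    cell_dcps: pd.DataFrame,
    reference_dcps: pd.DataFrame,
    synthetic_mean_dcps: pd.DataFrame,
    cell_cluster: pd.Series,
) -> DoubletCalls:
    """Flag cells whose DCP best matches a synthetic doublet set.

    ``reference_dcps`` rows are real-cluster centroid DCPs (index = merged
    cluster id); ``synthetic_mean_dcps`` rows are per-set mean DCPs (index =
    "a|b.<class>" labels). Exact ties resolve toward singlet.
    """
    if synthetic_mean_dcps.empty:
        raise ValueError("synthetic mean DCPs must be non-empty")
    n_refs = cell_dcps.shape[1]
    cand = pd.concat([reference_dcps, synthetic_mean_dcps])
    sim = _similarity(
        cell_dcps.to_numpy(dtype=float), cand.to_numpy(dtype=float), n_refs
    )
    n_real = len(reference_dcps)
    best_real = sim[:, :n_real].max(axis=1)
    best_synth = sim[:, n_real:].max(axis=1)
    is_doublet = best_synth > best_real  # ties -> singlet
    best_idx = np.where(
        is_doublet, n_real + sim[:, n_real:].argmax(axis=1),
        sim[:, :n_real].argmax(axis=1),
    )
    labels = [str(cand.index[i]) for i in best_idx]
    table = pd.DataFrame(
        {
            "original_cluster": cell_cluster.loc[cell_dcps.index],
            "best_match": labels,
            "similarity": sim[np.arange(len(sim)), best_idx],
            "state": np.where(is_doublet, "putative_doublet", "singlet"),
            "recluster_label": "",
            "final_label": "",
        },
        index=cell_dcps.index,
    )
    singlets = table["state"] == "singlet"
    table.loc[singlets, "final_label"] = (
        table.loc[singlets, "original_cluster"].astype(str)
    )
    return DoubletCalls(table)


def recluster_step(
    calls: DoubletCalls,
    cell_dcps: pd.DataFrame,
    only50: bool = False,
) -> DoubletCalls:
    """Group putative doublets by their two highest contributing clusters."""
    table = calls.table.copy()
    ref_ids = list(cell_dcps.columns)
    for cell in table.index[table["state"] == "putative_doublet"]:
        weights = cell_dcps.loc[cell].to_numpy(dtype=float)
        # two largest components; ties broken toward the lowest reference id
        order = np.lexsort((np.arange(len(weights)), -weights))
        top = sorted([ref_ids[order[0]], ref_ids[order[1]]], key=str)
        label = f"{top[0]}|{top[1]}"
        if not only50:
            best = table.at[cell, "best_match"]
            if "." in best:
                label = f"{label}.{best.rsplit('.', 1)[1]}"
        table.at[cell, "recluster_label"] = label
        table.at[cell, "final_label"] = label
    return DoubletCalls(table)


def _group_aggregates(block: np.ndarray, indicator: np.ndarray):
    """Per-group TS, TSS and sizes for a genes x cells block."""
    ts = block @ indicator
    tss = (block ** 2) @ indicator
    sizes = indicator.sum(axis=0)
    return ts, tss, sizes


def chunked_anova(
    values: pd.DataFrame,
    group_labels: pd.Series,
    focal: str,
    chunk_size: int = CHUNK_SIZE,
    screen: bool = False,
) -> pd.DataFrame:
    """One-way ANOVA + Tukey-Kramer contrasts of ``focal`` vs every group.

    Works on ``chunk_size``-gene blocks using only per-group total sums (TS)
    and sums of squares (TSS), so memory stays bounded; per-gene results are
    by construction independent of the chunking. Returns a frame indexed by
    gene with columns ``F``, ``p`` and ``tukey_p_<group>`` /
    ``diff_<group>`` (focal mean minus group mean) for each non-focal group.
    With ``screen=True`` the (expensive) studentized-range p is evaluated
    only where a gene can still qualify as uniquely expressed (overall test
    significant, focal mean strictly highest); other genes get NaN.

    Genes with zero within-group degrees of freedom raise; genes with zero
    within-group variance get p = 0 for nonzero between-group differences
    and p = 1 otherwise.
    """
    labels = pd.Series(group_labels).loc[values.columns]
    groups = list(pd.unique(labels))
    if focal not in groups:
        raise ValueError(f"focal group {focal!r} not present")
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    k = len(groups)
    indicator = np.column_stack(
        [(labels == g).to_numpy(dtype=float) for g in groups]
    )
    sizes = indicator.sum(axis=0)
    if (sizes < 1).any():
        raise ValueError("every group needs at least one cell")
    N = int(sizes.sum())
    df_between = k - 1
    df_within = N - k
    if df_within == 0:
        raise ValueError("zero within-group degrees of freedom")
    others = [g for g in groups if g != focal]
    fi = groups.index(focal)

    out_frames = []
    mat = values.to_numpy(dtype=float)
    for start in range(0, mat.shape[0], chunk_size):
        block = mat[start : start + chunk_size]
        ts, tss, _ = _group_aggregates(block, indicator)
        grand = ts.sum(axis=1)
        ss_between = (ts ** 2 / sizes).sum(axis=1) - grand ** 2 / N
        ss_within = (tss - ts ** 2 / sizes).sum(axis=1)
        ss_between = np.clip(ss_between, 0.0, None)
        ss_within = np.clip(ss_within, 0.0, None)
        ms_between = ss_between / df_between
        ms_within = ss_within / df_within
        with np.errstate(divide="ignore", invalid="ignore"):
            F = ms_between / ms_within
        zero_within = ms_within <= 0
        F = np.where(zero_within, np.where(ss_between > 0, np.inf, 0.0), F)
        p = np.where(
            np.isinf(F), 0.0,
            np.where(F == 0, 1.0, stats.f.sf(F, df_between, df_within)),
        )
        chunk = pd.DataFrame(
            {"F": F, "p": p},
            index=values.index[start : start + chunk_size],
        )
        means = ts / sizes
        diffs, qs = {}, {}
        for g in others:
            gi = groups.index(g)
            diffs[g] = means[:, fi] - means[:, gi]
            se = np.sqrt(
                ms_within / 2.0 * (1.0 / sizes[fi] + 1.0 / sizes[gi])
            )
            with np.errstate(divide="ignore", invalid="ignore"):
                qs[g] = (np.abs(diffs[g]) / se, se)
        if screen:
            # the Tukey p only matters where a gene can still qualify as
            # unique: overall test significant and focal mean highest.
            # elsewhere the p is reported as NaN (never <= alpha).
            need = p <= ALPHA
            for g in others:
                need &= diffs[g] > 0
        else:
            need = np.ones(len(p), dtype=bool)
        for g in others:
            q, se = qs[g]
            tukey_p = np.full(len(p), np.nan)
            sel = need & (se > 0)
            tukey_p[sel] = stats.studentized_range.sf(q[sel], k, df_within)
            degen = need & (se <= 0)
            tukey_p[degen] = np.where(np.abs(diffs[g][degen]) > 0, 0.0, 1.0)
            chunk[f"diff_{g}"] = diffs[g]
            chunk[f"tukey_p_{g}"] = tukey_p
        out_frames.append(chunk)
    return pd.concat(out_frames)


def unique_genes(
    values: pd.DataFrame,
    zj_cells: list,
    retained_clusters: pd.Series,
    alpha: float = ALPHA,
    chunk_size: int = CHUNK_SIZE,
) -> list:
    """Genes uniquely expressed in the doublet cluster Z_j.

    ``retained_clusters`` maps each non-doublet cell to its cluster (the
    post-removal clusters A*_i). A gene qualifies when the overall ANOVA
    p <= alpha, every Tukey-adjusted contrast of Z_j against each cluster is
    <= alpha, and Z_j's mean is strictly highest. Genes with zero variance
    across all groups cannot qualify and are excluded.
    """
    focal = "__Zj__"
    labels = pd.concat(
        [
            pd.Series(focal, index=pd.Index(zj_cells)),
            retained_clusters.astype(str),
        ]
    )
    cols = list(labels.index)
    res = chunked_anova(
        values[cols], labels, focal, chunk_size=chunk_size, screen=True
    )
    ok = res["p"] <= alpha
    for col in res.columns:
        if col.startswith("tukey_p_"):
            ok &= res[col] <= alpha
        elif col.startswith("diff_"):
            ok &= res[col] > 0
    return list(res.index[ok])


def rescue_step(
    calls: DoubletCalls,
    expression: AnnotatedExpression,
    U: int = 4,
    full_expression: AnnotatedExpression | None = None,
) -> tuple[DoubletCalls, RescueReport]:
    """Return doublet clusters bearing >= U unique genes to singlet status.

    Rescue is all-or-none per doublet cluster. When ``full_expression`` is
    given, unique genes are counted over the full gene list (the suggested
    threshold there is U = 30 rather than the marker-mode default 4).
    """
    if U < 0:
        raise ValueError("U must be >= 0")
    table = calls.table.copy()
    source = full_expression if full_expression is not None else expression
    doublet_mask = table["state"] == "putative_doublet"
    retained = table.loc[~doublet_mask, "original_cluster"]

    rows = []
    gene_lists: dict = {}
    for label in pd.unique(table.loc[doublet_mask, "recluster_label"]):
        members = list(table.index[doublet_mask & (table["recluster_label"] == label)])
        genes = unique_genes(source.values, members, retained)
        gene_lists[label] = genes
        decision = "rescued" if len(genes) >= U else "doublet"
        rows.append(
            {"cluster": label, "unique_gene_count": len(genes), "decision": decision}
        )
        if decision == "rescued":
            table.loc[members, "state"] = "rescued_singlet"
            table.loc[members, "final_label"] = (
                table.loc[members, "original_cluster"].astype(str)
            )
        else:
            table.loc[members, "state"] = "final_doublet"
    report = RescueReport(
        U=U,
        clusters=pd.DataFrame(
            rows, columns=["cluster", "unique_gene_count", "decision"]
        ).set_index("cluster"),
        unique_gene_lists=gene_lists,
    )
    return DoubletCalls(table), report
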