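"""Reference-cluster construction and similarity-based cluster merging.

Upstream clustering often splits one transcriptional cell type into several
clusters. Because synthetic doublets are built between every pair of
reference clusters, redundant clusters yield synthetic doublets that look
like singlets and inflate the doublet call rate. This module merges
transcriptionally similar clusters before synthetic-doublet generation:

1. compute a per-cluster signature (per-gene centroid, or medoid) over the
   marker genes,
2. form the K x K Pearson correlation matrix r of the signatures,
3. binarize at the data-driven threshold  rho_T = mean(r_ij) + rho' * sd(r_ij)
   computed over the off-diagonal upper triangle (rho' is the user scaling,
   default 1; lower rho' merges more),
4. if any pair passes, run Markov clustering (MCL) on the binary matrix to
   read off merged clusters; otherwise keep the identity partition.

Merged signatures are recomputed from the pooled member cells so downstream
deconvolution sees true merged centroids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import AnnotatedExpression

__all__ = [
    "MergeDecision",
    "ReferenceSet",
    "compute_signatures",
    "decide_merges",
    "merge_clusters",
    "mcl",
]


@dataclass
class MergeDecision:
    """The correlation matrix, threshold, binary matrix and partition."""

    r: pd.DataFrame
    rho_prime: float
    rho_T: float
    B: pd.DataFrame
    partition: dict  # original cluster -> merged cluster id (1..n)


@dataclass
class ReferenceSet:
    """Merged reference clusters and their signature matrix.

    ``signatures`` has genes as rows and one column per merged cluster;
    ``provenance`` maps each original cluster to its merged cluster id.
    """

    merged_ids: list
    signatures: pd.DataFrame
    mode: str
    provenance: dict

    def members(self, merged_id) -> list:
        return [k for k, v in self.provenance.items() if v == merged_id]


def compute_signatures(ae: AnnotatedExpression, mode: str = "centroid") -> pd.DataFrame:
    """Per-cluster signature matrix (genes x K).

    ``centroid`` = per-gene mean over the cluster's cells; ``medoid`` =
    per-gene median (a marginal medoid).
    """
    if mode not in ("centroid", "medoid"):
        raise ValueError(f"mode must be 'centroid' or 'medoid', got {mode!r}")
    cols = {}
    for cid in ae.cluster_ids():
        cells = ae.cells_of(cid)
        if not cells:
            raise ValueError(f"cluster {cid!r} is empty")
        block = ae.values[cells]
        cols[cid] = block.mean(axis=1) if mode == "centroid" else block.median(axis=1)
    return pd.DataFrame(cols)


def _pairwise_correlation(signatures: pd.DataFrame) -> pd.DataFrame:
    mat = signatures.to_numpy(dtype=float)
    K = mat.shape[1]
    sds = mat.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(mat, rowvar=False)
    r = np.atleast_2d(r)
    bad = sds == 0
    if bad.any():
        warnings.warn(
            "zero-variance signature column(s); their correlations set to 0",
            stacklevel=2,
        )
        r[bad, :] = 0.0
        r[:, bad] = 0.0
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=signatures.columns, columns=signatures.columns)


def decide_merges(r: pd.DataFrame, rho_prime: float = 1.0, **mcl_params) -> MergeDecision:
    """Threshold a signature correlation matrix and partition the clusters.

    The threshold statistics (mean, sample sd) use the off-diagonal upper
    triangle of ``r``. With a single cluster pair (K = 2) the sample sd is
    undefined and no merging occurs.
    """
    K = r.shape[0]
    if K < 2:
        raise ValueError("need at least 2 clusters")
    iu = np.triu_indices(K, k=1)
    off = r.to_numpy()[iu]
    mean = float(off.mean())
    if off.size >= 2:
        sd = float(off.std(ddof=1))
        rho_T = mean + rho_prime * sd
    else:
        rho_T = np.inf  # sd undefined for a single pair: never merge
    B = (r.to_numpy() >= rho_T).astype(int)
    np.fill_diagonal(B, 1)
    B = pd.DataFrame(B, index=r.index, columns=r.columns)

    labels = list(r.index)
    any_pass = bool(B.to_numpy()[iu].any())
    if not any_pass:
        partition = {lab: i + 1 for i, lab in enumerate(labels)}
    else:
        groups = mcl(B.to_numpy(), **mcl_params)
        partition = {labels[node]: gid + 1 for gid, nodes in enumerate(groups)
                     for node in nodes}
    return MergeDecision(r=r, rho_prime=rho_prime, rho_T=rho_T, B=B,
                         partition=partition)


def merge_clusters(
    ae: AnnotatedExpression,
    rho_prime: float = 1.0,
    mode: str = "centroid",
    **mcl_params,
) -> tuple[MergeDecision, ReferenceSet]:
    """Merge similar clusters and build the reference signature matrix.

    Merged signatures are recomputed from the pooled cells of each merged
    cluster (not averaged from the old signatures).
    """
    signatures = compute_signatures(ae, mode=mode)
    decision = decide_merges(_pairwise_correlation(signatures), rho_prime,
                             **mcl_params)
    merged_ids = sorted(set(decision.partition.values()))
    cols = {}
    for mid in merged_ids:
        members = [k for k, v in decision.partition.items() if v == mid]
        cells: list = []
        for cid in members:
            cells.extend(ae.cells_of(cid))
        block = ae.values[cells]
        cols[mid] = block.mean(axis=1) if mode == "centroid" else block.median(axis=1)
    refs = ReferenceSet(
        merged_ids=merged_ids,
        signatures=pd.DataFrame(cols),
        mode=mode,
        provenance=dict(decision.partition),
    )
    return decision, refs


def mcl(
    B: np.ndarray,
    expansion: int = 2,
    inflation: float = 2.0,
    add_loops: bool = True,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> list[list[int]]:
    """Markov clustering of a symmetric binary adjacency matrix.

    The column-stochastic flow matrix is alternately expanded (matrix power)
    and inflated (elementwise power + column renormalization) until the flow
    matrix changes by less than ``tol`` in max norm. Clusters are read from
    attractor rows; a node attracted by several clusters goes to the
    lowest-indexed one.
    """
    B = np.asarray(B, dtype=float)
    if B.ndim != 2 or B.shape[0] != B.shape[1]:
        raise ValueError("B must be square")
    if not np.array_equal(B, B.T):
        raise ValueError("B must be symmetric")
    M = B.copy()
    if add_loops:
        np.fill_diagonal(M, 1.0)
    M = M / M.sum(axis=0, keepdims=True)

    converged = False
    for _ in range(max_iter):
        prev = M
        M = np.linalg.matrix_power(M, expansion)
        M = M ** inflation
        colsums = M.sum(axis=0, keepdims=True)
        M = M / colsums
        M[M < 1e-12] = 0.0
        M = M / M.sum(axis=0, keepdims=True)
        residual = np.abs(M - prev).max()
        if residual < tol:
            converged = True
            break
    if not converged:
        raise RuntimeError(
            f"MCL did not converge within {max_iter} iterations "
            f"(residual {residual:.3g})"
        )

    n = M.shape[0]
    attractors = [i for i in range(n) if M[i, i] > tol]
    raw = [set(np.nonzero(M[i] > tol)[0]) | {i} for i in attractors]
    # attractor supports sharing an attractor belong to one cluster
    clusters: list[set] = []
    attr_set = set(attractors)
    for s in raw:
        target = None
        for c in clusters:
            if c & s & attr_set:
                target = c
                break
        if target is None:
            clusters.append(set(s))
        else:
            target |= s
    # a node attracted by several clusters goes to the lowest-indexed one
    clusters.sort(key=min)
    assigned: set = set()
    out: list[list[int]] = []
    for c in clusters:
        nodes = sorted(c - assigned)
        if nodes:
            out.append(nodes)
            assigned |= set(nodes)
    for i in range(n):  # unattracted isolated nodes become singletons
        if i not in assigned:
            out.append([i])
            assigned.add(i)
    out.sort(key=lambda nodes: nodes[0])
    return out
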