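"""Deconvolution cell profiles (DCPs) via simplex-constrained least squares.

Each expression column y (a real cell or a synthetic doublet) is decomposed
against the merged reference signature matrix S (marker genes x n clusters):

    minimize  || S x - y ||^2   subject to   x >= 0,  sum(x) = 1

The solution x is the cell's Deconvolution Cell Profile: the estimated
fractional contribution of each reference cell state, non-negative and
summing to 1. The quadratic program is solved exactly with a primal
active-set method on the simplex (equality-constrained least squares on the
free set, bound activation/release via KKT multipliers).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .merge import ReferenceSet
from .synthetics import SyntheticDoubletSet

__all__ = [
    "solve_dcp",
    "dcp_table",
    "simplex_nnls",
    "reference_dcps",
    "synthetic_mean_dcps",
]

_FEAS_TOL = 1e-10
_CLIP_TOL = 1e-9


def simplex_nnls(S: np.ndarray, y: np.ndarray, max_iter: int | None = None) -> np.ndarray:
    """Solve min ||S x - y||^2 s.t. x >= 0, sum(x) = 1 (primal active set).

    Returns the optimal weight vector. Rank-deficient S is handled via
    least-squares solves of the KKT system (a warning is emitted upstream).
    """
    S = np.asarray(S, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = S.shape[1]
    Q = S.T @ S
    c = S.T @ y
    if max_iter is None:
        max_iter = 50 * (n + 1)

    x = np.full(n, 1.0 / n)
    active = np.zeros(n, dtype=bool)
    for _ in range(max_iter):
        free = ~active
        k = int(free.sum())
        K = np.zeros((k + 1, k + 1))
        K[:k, :k] = Q[np.ix_(free, free)]
        K[:k, k] = 1.0
        K[k, :k] = 1.0
        rhs = np.append(c[free], 1.0)
        sol, *_ = np.linalg.lstsq(K, rhs, rcond=None)
        x_new = np.zeros(n)
        x_new[free] = sol[:k]
        mu = sol[k]

        if x_new[free].min() >= -_FEAS_TOL:
            x = x_new
            if not active.any():
                break
            grad = Q @ x - c
            lam = grad[active] + mu
            if lam.min() >= -_FEAS_TOL:
                break
            # release the bound with the most negative multiplier
            idx = np.flatnonzero(active)
            active[idx[np.argmin(lam)]] = False
        else:
            # step toward x_new until the first free variable hits zero
            d = x_new - x
            blocking = free & (x_new < -_FEAS_TOL)
            with np.errstate(divide="ignore", invalid="ignore"):
                alphas = np.where(blocking, x / (x - x_new), np.inf)
            j = int(np.argmin(alphas))
            x = x + alphas[j] * d
            x[j] = 0.0
            active[j] = True
    x = np.clip(x, 0.0, None)
    total = x.sum()
    if total <= 0:
        x = np.full(n, 1.0 / n)
    else:
        x = x / total
    return x


def solve_dcp(
    profile: np.ndarray | pd.Series,
    signature_matrix: pd.DataFrame,
    scale_mode: str = "none",
) -> pd.Series:
    """DCP of one expression profile against the reference signatures.

    ``scale_mode`` is ``"none"`` (use values as provided) or
    ``"zscore-columns"`` (z-score each signature column and the profile
    before solving).
    """
    y = np.asarray(profile, dtype=float).ravel()
    S = signature_matrix.to_numpy(dtype=float)
    if S.shape[1] < 2:
        raise ValueError("signature matrix needs at least 2 columns")
    if y.shape[0] != S.shape[0]:
        raise ValueError("profile and signatures have different gene axes")
    if not np.any(y != 0):
        raise ValueError("all-zero profile: no deconvolution possible")
    if scale_mode == "zscore-columns":
        S = _zscore_cols(S)
        y = _zscore_cols(y[:, None]).ravel()
    elif scale_mode != "none":
        raise ValueError(f"unknown scale_mode {scale_mode!r}")
    if np.linalg.matrix_rank(S) < S.shape[1]:
        warnings.warn(
            "signature matrix is rank-deficient on the marker genes; "
            "the DCP may not be unique",
            stacklevel=2,
        )
    x = simplex_nnls(S, y)
    x[(x < 0) & (x > -_CLIP_TOL)] = 0.0
    x = x / x.sum()
    return pd.Series(x, index=signature_matrix.columns)


def _zscore_cols(mat: np.ndarray) -> np.ndarray:
    mean = mat.mean(axis=0, keepdims=True)
    sd = mat.std(axis=0, keepdims=True)
    sd[sd == 0] = 1.0
    return (mat - mean) / sd


def dcp_table(
    profiles: pd.DataFrame,
    refs: ReferenceSet,
    scale_mode: str = "none",
) -> pd.DataFrame:
    """DCPs of every profile column (rows = profiles, columns = references)."""
    sig = refs.signatures
    missing = [g for g in sig.index if g not in profiles.index]
    if missing:
        raise ValueError(
            f"profiles are missing marker genes: {missing[:10]}"
        )
    aligned = profiles.loc[sig.index]
    S = sig.to_numpy(dtype=float)
    if scale_mode == "zscore-columns":
        S = _zscore_cols(S)
    elif scale_mode != "none":
        raise ValueError(f"unknown scale_mode {scale_mode!r}")
    if np.linalg.matrix_rank(S) < S.shape[1]:
        warnings.warn(
            "signature matrix is rank-deficient on the marker genes; "
            "DCPs may not be unique",
            stacklevel=2,
        )
    Y = aligned.to_numpy(dtype=float)
    out = np.empty((Y.shape[1], S.shape[1]))
    for j in range(Y.shape[1]):
        y = Y[:, j]
        if not np.any(y != 0):
            raise ValueError(
                f"all-zero profile {aligned.columns[j]!r}: no deconvolution possible"
            )
        if scale_mode == "zscore-columns":
            y = _zscore_cols(y[:, None]).ravel()
        x = simplex_nnls(S, y)
        x[(x < 0) & (x > -_CLIP_TOL)] = 0.0
        out[j] = x / x.sum()
    return pd.DataFrame(out, index=aligned.columns, columns=sig.columns)


def reference_dcps(refs: ReferenceSet, scale_mode: str = "none") -> pd.DataFrame:
    """Centroid DCPs: each reference signature deconvolved against all."""
    return dcp_table(refs.signatures, refs, scale_mode=scale_mode)


def synthetic_mean_dcps(
    synth: SyntheticDoubletSet,
    refs: ReferenceSet,
    scale_mode: str = "none",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-profile DCPs and their per-set means for the synthetic doublets."""
    dcps = dcp_table(synth.profiles, refs, scale_mode=scale_mode)
    return dcps, synth.mean_dcps(dcps)
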