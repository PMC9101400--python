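"""Multivariate curve resolution–alternating least squares (MCR-ALS).

Factorizes the pixel × channel matrix D into non-negative concentrations C
and non-negative pure-component spectra S, ``D ≈ C·Sᵀ``, by alternating
exact non-negative least-squares solves for each factor.  Component spectra
are renormalized to unit trapezoidal area over 400–3100 cm⁻¹ after every
cycle (with the inverse scale absorbed into C), which pins down MCR's scale
indeterminacy and makes the concentrations area fractions — directly
comparable across pixels and grains.  Initial spectra default to the HCA
cluster means, clipped at zero.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize

from .core import WavenumberAxis, window_trapz

logger = logging.getLogger("pollenraman")

__all__ = [
    "MCRResult",
    "nnls",
    "nnls_matrix",
    "mcr_als",
    "lack_of_fit",
    "grain_mean_concentrations",
    "match_components",
]


def nnls(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Solve min ‖Ax − b‖₂ subject to x ≥ 0 (Lawson–Hanson active set).

    The solution satisfies the KKT conditions: x ≥ 0, gradient
    Aᵀ(Ax − b) ≥ 0, and complementary slackness.
    """
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float)
    if A.ndim != 2 or b.shape != (A.shape[0],):
        raise ValueError(f"dimension mismatch: A {A.shape}, b {b.shape}")
    x, _ = scipy.optimize.nnls(A, b)
    return x


def nnls_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Column-wise NNLS for many right-hand sides: min ‖AX − B‖_F, X ≥ 0.

    For a small number of unknowns k the optimal support of each column is
    found by an exhaustive search over the 2ᵏ candidate active sets on the
    normal equations, vectorized across columns — exact, and far faster
    than looping a single-RHS solver over thousands of pixels or channels.
    Falls back to per-column Lawson–Hanson for k > 14.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.ndim != 2 or B.ndim != 2 or A.shape[0] != B.shape[0]:
        raise ValueError(f"dimension mismatch: A {A.shape}, B {B.shape}")
    k, m = A.shape[1], B.shape[1]
    if k > 14:
        return np.column_stack([nnls(A, B[:, j]) for j in range(m)])
    G = A.T @ A
    F = A.T @ B                                 # (k, m)
    best_obj = np.zeros(m)                      # objective offset for x = 0
    best_X = np.zeros((k, m))
    for r in range(1, k + 1):
        for support in itertools.combinations(range(k), r):
            S = list(support)
            Gs = G[np.ix_(S, S)]
            try:
                Xs = np.linalg.solve(Gs, F[S])
            except np.linalg.LinAlgError:
                Xs, *_ = np.linalg.lstsq(Gs, F[S], rcond=None)
            feasible = np.all(Xs >= -1e-12, axis=0)
            if not feasible.any():
                continue
            Xs = np.clip(Xs, 0.0, None)
            # ‖Ax−b‖² = ‖b‖² + xᵀGx − 2 xᵀf; compare the x-dependent part
            obj = np.einsum("im,im->m", Xs, Gs @ Xs) - \
                2.0 * np.einsum("im,im->m", Xs, F[S])
            better = feasible & (obj < best_obj - 1e-15 * np.abs(best_obj))
            if better.any():
                best_obj[better] = obj[better]
                cols = np.zeros((k, int(better.sum())))
                cols[S] = Xs[:, better]
                best_X[:, better] = cols
    return best_X


@dataclass
class MCRResult:
    S: np.ndarray                 # (k, n_channels), rows unit-area, >= 0
    C: np.ndarray                 # (n_pixels, k), >= 0
    axis: WavenumberAxis
    ss_history: list[float]       # residual SS after each full cycle
    lof_percent: float            # 100·sqrt(SS_res / SS_tot)
    r_squared: float              # explained variance 1 − SS_res/SS_tot
    n_iter: int
    converged: bool
    frozen_components: list[int] = field(default_factory=list)
    component_names: tuple[str, ...] | None = None

    @property
    def concentration_sums(self) -> np.ndarray:
        """Per-pixel Σc — ≈ 1 for well-fit pixels on unit-area data."""
        return self.C.sum(axis=1)

    def residual(self, D: np.ndarray) -> np.ndarray:
        return np.asarray(D) - self.C @ self.S


def mcr_als(D: np.ndarray, S0: np.ndarray, axis: WavenumberAxis,
            tol: float = 1e-8, max_iter: int = 500,
            component_names=None, norm_range=(400.0, 3100.0)) -> MCRResult:
    """Alternating non-negative least squares resolution of D = C·Sᵀ + E.

    Each cycle solves every pixel's concentrations given S, then every
    component spectrum given C — both as exact NNLS subproblems, so the
    residual sum of squares is non-increasing (asserted every iteration).
    After each cycle the rows of S are renormalized to unit trapezoidal
    area over ``norm_range`` and the scales absorbed into C.  Iteration
    stops when the relative change of the residual SS drops below ``tol``.
    A component whose spectrum collapses to zero is frozen at its previous
    shape with a warning and qualifies the convergence flag.
    """
    D = np.asarray(D, dtype=float)
    S = np.asarray(S0, dtype=float).copy()
    if S.ndim != 2 or D.ndim != 2 or S.shape[1] != D.shape[1]:
        raise ValueError(f"shape mismatch: D {D.shape}, S0 {S.shape}")
    k = S.shape[0]
    if k > D.shape[0] or k > D.shape[1]:
        raise ValueError(f"k={k} exceeds pixel or channel count {D.shape}")
    S = np.clip(S, 0.0, None)
    S = _renorm_rows(S, axis, norm_range)
    S0_ref = S.copy()

    ss_tot = float(np.sum(D * D))
    ss_history: list[float] = []
    frozen: set[int] = set()
    prev_ss = np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        C = nnls_matrix(S.T, D.T).T             # (n_pix, k)
        live = [i for i in range(k) if i not in frozen]
        if live:
            S_new = nnls_matrix(C[:, live], D)  # (len(live), n_chan)
            for row, i in enumerate(live):
                if not np.any(S_new[row] > 0):
                    frozen.add(i)
                    logger.warning("mcr_als: component %d collapsed to zero; "
                                   "frozen at previous shape", i)
                else:
                    S[i] = S_new[row]
        S, C = _renorm_pair(S, C, axis, norm_range)
        ss = float(np.sum((D - C @ S) ** 2))
        if ss > prev_ss * (1 + 1e-9) + 1e-12 * ss_tot:
            raise AssertionError(
                f"residual SS increased at iteration {n_iter}: "
                f"{prev_ss} -> {ss}")
        ss_history.append(ss)
        if np.isfinite(prev_ss) and prev_ss > 0 and \
                abs(prev_ss - ss) / prev_ss < tol:
            converged = True
            break
        if ss <= 1e-24 * ss_tot:  # numerically perfect fit
            converged = True
            break
        prev_ss = ss

    # final concentrations consistent with the reported S
    C = nnls_matrix(S.T, D.T).T
    ss = float(np.sum((D - C @ S) ** 2))
    perm = _match_to_reference(S, S0_ref)
    S, C = S[perm], C[:, perm]
    frozen_list = sorted(int(np.nonzero(perm == f)[0][0]) for f in frozen)
    lof = 100.0 * np.sqrt(ss / ss_tot) if ss_tot > 0 else 0.0
    result = MCRResult(
        S=S, C=C, axis=axis, ss_history=ss_history, lof_percent=lof,
        r_squared=1.0 - ss / ss_tot if ss_tot > 0 else 1.0,
        n_iter=n_iter, converged=converged and not frozen,
        frozen_components=frozen_list,
        component_names=tuple(component_names) if component_names else None)
    logger.info("stage=mcr_als k=%d iters=%d lof=%.4g%% r2=%.6f converged=%s",
                k, n_iter, lof, result.r_squared, result.converged)
    return result


def _renorm_rows(S, axis, norm_range):
    areas = window_trapz(axis, S, *norm_range)
    ok = areas > 0
    S = S.copy()
    S[ok] = S[ok] / areas[ok, None]
    return S


def _renorm_pair(S, C, axis, norm_range):
    areas = window_trapz(axis, S, *norm_range)
    ok = areas > 0
    S = S.copy()
    C = C.copy()
    S[ok] = S[ok] / areas[ok, None]
    C[:, ok] = C[:, ok] * areas[ok]
    return S, C


def _match_to_reference(S: np.ndarray, S_ref: np.ndarray) -> np.ndarray:
    """Permutation aligning rows of S to S_ref by maximal correlation."""
    k = S.shape[0]
    Sc = S - S.mean(axis=1, keepdims=True)
    Rc = S_ref - S_ref.mean(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (Rc @ Sc.T) / np.outer(np.linalg.norm(Rc, axis=1),
                                      np.linalg.norm(Sc, axis=1))
    corr = np.nan_to_num(corr, nan=-1.0)
    _, cols = scipy.optimize.linear_sum_assignment(-corr)
    return cols


def lack_of_fit(result: MCRResult, D: np.ndarray) -> float:
    """100·sqrt(Σ(D − C·Sᵀ)² / ΣD²), the standard MCR diagnostic."""
    D = np.asarray(D, dtype=float)
    ss_res = float(np.sum(result.residual(D) ** 2))
    ss_tot = float(np.sum(D * D))
    return 100.0 * np.sqrt(ss_res / ss_tot) if ss_tot > 0 else 0.0


def grain_mean_concentrations(result: MCRResult, grain_meta: "list[dict]",
                              grain_slices: "list[slice] | None" = None
                              ) -> pd.DataFrame:
    """Per-grain × component mean concentration, in long format.

    ``grain_meta`` carries one record per grain (``grain_id``, optional
    ``species`` and ``site``); ``grain_slices`` delimits each grain's rows
    of C (default: single grain spanning all rows).
    """
    if grain_slices is None:
        grain_slices = [slice(0, result.C.shape[0])]
    if len(grain_meta) != len(grain_slices):
        raise ValueError("one meta record per grain required")
    names = result.component_names or tuple(
        f"component_{i + 1}" for i in range(result.S.shape[0]))
    rows = []
    for meta, sl in zip(grain_meta, grain_slices):
        sub = result.C[sl]
        if sub.shape[0] == 0:
            raise ValueError(f"empty grain mask for {meta.get('grain_id')}")
        means = sub.mean(axis=0)
        for comp, val in zip(names, means):
            rows.append({"grain_id": meta.get("grain_id"),
                         "species": meta.get("species"),
                         "site": meta.get("site"),
                         "component": comp,
                         "mean_coefficient": float(val)})
    return pd.DataFrame(rows)


def match_components(S_rec: np.ndarray, S_true: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Optimal one-to-one matching of recovered to true spectra.

    Maximizes total cosine similarity over all assignments; returns
    ``(assignment, similarities)`` where ``assignment[i]`` is the recovered
    row matched to true row i.
    """
    S_rec = np.asarray(S_rec, dtype=float)
    S_true = np.asarray(S_true, dtype=float)
    if S_rec.shape != S_true.shape:
        raise ValueError(f"shape mismatch: {S_rec.shape} vs {S_true.shape}")
    Rn = S_rec / np.clip(np.linalg.norm(S_rec, axis=1, keepdims=True),
                         1e-300, None)
    Tn = S_true / np.clip(np.linalg.norm(S_true, axis=1, keepdims=True),
                          1e-300, None)
    cos = Tn @ Rn.T
    _, cols = scipy.optimize.linear_sum_assignment(-cos)
    return cols, cos[np.arange(len(cols)), cols]
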