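"""Dense EM-REML solver for small variance-component models.

Solves Henderson's mixed-model equations for models of the form

    y = X b + sum_k Z_k u_k + e,   u_k ~ N(0, sigma_k^2 I),  e ~ N(0, sigma_e^2 I)

with variance components estimated by expectation-maximisation on the MME
(the classic EM-REML updates).  Correlated random effects with covariance
``sigma^2 K`` are handled by the caller through the factorisation
``Z -> Z L`` with ``K = L L'``, which reduces them to the iid form above.

Everything is dense; the solver targets the problem sizes of single-trial
and diallel analyses (tens to a few hundred effects), where forming and
inverting the coefficient matrix outright is both simple and fast.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np


@dataclass
class MixedFit:
    beta: np.ndarray
    u: list[np.ndarray]
    var_e: float
    var_u: list[float]
    converged: bool
    n_iter: int
    resid_df: float
    rank_x: int


def _solve_mme(WtW: np.ndarray, Wty: np.ndarray, p: int,
               q: Sequence[int], lambdas: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Solve the MME at given variance ratios; returns (solution, inverse)."""
    M = WtW.copy()
    off = p
    for qk, lam in zip(q, lambdas):
        idx = np.arange(off, off + qk)
        M[idx, idx] += lam
        off += qk
    try:
        C = np.linalg.inv(M)
    except np.linalg.LinAlgError:
        C = np.linalg.pinv(M)
    return C @ Wty, C


def fit_mixed(y: np.ndarray, X: np.ndarray,
              Z_list: Sequence[np.ndarray] = (),
              *,
              fix_vars: Optional[tuple[float, Sequence[float]]] = None,
              tol: float = 1e-8,
              max_iter: int = 500) -> MixedFit:
    """Fit a variance-component model by EM-REML (or at fixed variances).

    Parameters
    ----------
    y, X, Z_list:
        Response, fixed-effect design and the random-effect design matrices.
    fix_vars:
        Optional ``(var_e, [var_k, ...])``; when given, no EM is run and the
        MME are solved once at these values (the GLS/BLUP solution).
    tol:
        Relative-change convergence tolerance on the variance components.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = len(y)
    rank_x = int(np.linalg.matrix_rank(X))
    Z_list = [np.asarray(Z, dtype=float) for Z in Z_list]

    if not Z_list:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        df = max(n - rank_x, 1)
        var_e = float(resid @ resid) / df
        return MixedFit(beta=beta, u=[], var_e=var_e, var_u=[],
                        converged=True, n_iter=0, resid_df=n - rank_x,
                        rank_x=rank_x)

    q = [Z.shape[1] for Z in Z_list]
    p = X.shape[1]
    W = np.hstack([X] + list(Z_list))
    WtW = W.T @ W
    Wty = W.T @ y
    yty = float(y @ y)
    vy = float(np.var(y, ddof=1)) if n > 1 else 0.0
    resid_df = max(n - rank_x, 1)

    if vy <= 1e-14 * max(1.0, abs(float(np.mean(y)))) ** 2 or vy == 0.0:
        # degenerate: constant response
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return MixedFit(beta=beta, u=[np.zeros(qk) for qk in q],
                        var_e=0.0, var_u=[0.0] * len(q), converged=True,
                        n_iter=0, resid_df=resid_df, rank_x=rank_x)

    if fix_vars is not None:
        var_e, var_u = float(fix_vars[0]), [float(v) for v in fix_vars[1]]
        lambdas = [var_e / max(v, 1e-12 * vy) for v in var_u]
        sol, _ = _solve_mme(WtW, Wty, p, q, lambdas)
        beta = sol[:p]
        u, off = [], p
        for qk in q:
            u.append(sol[off:off + qk])
            off += qk
        return MixedFit(beta=beta, u=u, var_e=var_e, var_u=var_u,
                        converged=True, n_iter=0, resid_df=resid_df,
                        rank_x=rank_x)

    K = len(Z_list)
    var_u = [vy / (2.0 * K)] * K
    var_e = vy / 2.0
    floor = 1e-10 * vy
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        lambdas = [var_e / max(v, floor) for v in var_u]
        sol, C = _solve_mme(WtW, Wty, p, q, lambdas)
        new_e = (yty - float(sol @ Wty)) / resid_df
        new_e = max(new_e, floor)
        new_u, off = [], p
        for k, qk in enumerate(q):
            uk = sol[off:off + qk]
            tr = float(np.trace(C[off:off + qk, off:off + qk]))
            new_u.append(max((float(uk @ uk) + new_e * tr) / qk, floor))
            off += qk
        old = np.array([var_e] + var_u)
        new = np.array([new_e] + new_u)
        var_e, var_u = new_e, new_u
        if np.max(np.abs(new - old) / np.maximum(np.abs(old), floor)) < tol:
            converged = True
            break

    lambdas = [var_e / max(v, floor) for v in var_u]
    sol, _ = _solve_mme(WtW, Wty, p, q, lambdas)
    beta = sol[:p]
    u, off = [], p
    for qk in q:
        u.append(sol[off:off + qk])
        off += qk
    # snap numerically-floored components to zero
    var_u = [0.0 if v <= 2 * floor else v for v in var_u]
    return MixedFit(beta=beta, u=u, var_e=var_e, var_u=var_u,
                    converged=converged, n_iter=it, resid_df=resid_df,
                    rank_x=rank_x)


def dummies(values, drop_first: bool = False) -> tuple[np.ndarray, list]:
    """0/1 indicator matrix for a categorical vector; levels sorted."""
    levels = sorted(set(values))
    if drop_first:
        use = levels[1:]
    else:
        use = levels
    arr = np.zeros((len(values), len(use)))
    pos = {lv: i for i, lv in enumerate(use)}
    for r, v in enumerate(values):
        if v in pos:
            arr[r, pos[v]] = 1.0
    return arr, use
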