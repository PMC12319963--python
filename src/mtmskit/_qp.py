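"""Dense convex QP solver: min 0.5 x'Px + q'x  s.t.  l <= Ax <= u.

Operator-splitting (ADMM) iteration with over-relaxation, in the style of
OSQP, followed by an active-set "polish" step that solves the equality KKT
system on the constraints active at the ADMM solution.  P must be positive
definite (the magnetic-energy matrix always is), which keeps the linear
system a single Cholesky factorization reused across iterations.

Deterministic: no randomization anywhere; a fixed iteration cap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve

__all__ = ["solve_qp", "QPResult", "InfeasibleProblemError"]


class InfeasibleProblemError(RuntimeError):
    """The constraint set admits no solution (primal infeasibility)."""

    def __init__(self, message: str, worst_row: int | None = None):
        super().__init__(message)
        self.worst_row = worst_row


@dataclass
class QPResult:
    x: np.ndarray
    y: np.ndarray  # dual variables of the range constraints
    iterations: int
    kkt_residual: float
    polished: bool


def _kkt_residual(P, q, A, l, u, x, y) -> float:
    """Max-norm KKT residual: stationarity, feasibility, complementarity."""
    r_stat = P @ x + q + A.T @ y
    z = A @ x
    with np.errstate(invalid="ignore"):
        r_feas = np.maximum(z - u, 0.0) + np.minimum(z - l, 0.0)
    r_feas = np.nan_to_num(r_feas, nan=0.0, posinf=0.0, neginf=0.0)
    # complementary slackness: y+ only where z at u, y- only where z at l
    finite_u = np.isfinite(u)
    finite_l = np.isfinite(l)
    slack_u = np.maximum(y[finite_u], 0.0) * np.abs(u[finite_u] - z[finite_u])
    slack_l = np.maximum(-y[finite_l], 0.0) * np.abs(z[finite_l] - l[finite_l])
    comp = np.max(np.concatenate([slack_u, slack_l, [0.0]]))
    return max(
        float(np.max(np.abs(r_stat), initial=0.0)),
        float(np.max(np.abs(r_feas), initial=0.0)),
        comp,
    )


def _polish(P, q, A, l, u, x, y, active_tol):
    """Equality-solve on the active set; returns (x, y, ok)."""
    z = A @ x
    act_u = (u - z < active_tol) & np.isfinite(u)
    act_l = (z - l < active_tol) & np.isfinite(l)
    act = act_u | act_l
    if not np.any(act):
        try:
            c, low = cho_factor(P)
            xs = cho_solve((c, low), -q)
            return xs, np.zeros_like(y), True
        except np.linalg.LinAlgError:
            return x, y, False
    Aa = A[act]
    ba = np.where(act_u[act], u[act], l[act])
    n, m = P.shape[0], Aa.shape[0]
    reg = 1e-12
    K = np.block([[P, Aa.T], [Aa, -reg * np.eye(m)]])
    rhs = np.concatenate([-q, ba])
    try:
        sol = np.linalg.solve(K, rhs)
    except np.linalg.LinAlgError:
        sol, *_ = np.linalg.lstsq(K, rhs, rcond=None)
    xs = sol[:n]
    ys = np.zeros_like(y)
    ys[act] = sol[n:]
    return xs, ys, True


def solve_qp(
    P: np.ndarray,
    q: np.ndarray,
    A: np.ndarray,
    l: np.ndarray,
    u: np.ndarray,
    max_iter: int = 20000,
    eps: float = 1e-8,
    rho: float = 0.1,
    sigma: float = 1e-6,
    alpha: float = 1.6,
    adapt_every: int = 200,
    polish_every: int = 500,
    x0: np.ndarray | None = None,
    y0: np.ndarray | None = None,
) -> QPResult:
    """Solve the box-constrained QP; raises on detected primal infeasibility.

    ``eps`` is the target for both the ADMM residuals and the final KKT
    residual (checked after polishing).
    """
    P = np.asarray(P, dtype=float)
    q = np.asarray(q, dtype=float)
    A_orig = np.asarray(A, dtype=float)
    l_orig = np.asarray(l, dtype=float)
    u_orig = np.asarray(u, dtype=float)
    n = P.shape[0]
    m = A_orig.shape[0]
    if np.any(l_orig > u_orig):
        raise InfeasibleProblemError(
            "constraint bounds crossed (l > u)", worst_row=int(np.argmax(l_orig - u_orig))
        )
    # row equilibration: unit-infinity-norm constraint rows keep the ADMM
    # penalty meaningful when row scales span orders of magnitude
    row_scale = np.max(np.abs(A_orig), axis=1)
    row_scale[row_scale == 0] = 1.0
    A = A_orig / row_scale[:, None]
    with np.errstate(invalid="ignore"):
        l = l_orig / row_scale
        u = u_orig / row_scale

    # per-row penalty: stiffer on equality rows; Gram matrices cached per
    # class so rho adaptation refactors in O(n^2) instead of O(m n^2)
    eq = (u - l) < 1e-14
    rho_vec = np.where(eq, rho * 1e3, rho)
    G_eq = A[eq].T @ A[eq] if np.any(eq) else 0.0
    G_in = A[~eq].T @ A[~eq] if np.any(~eq) else 0.0

    def factor(rho_vec):
        r_eq = rho_vec[eq][0] if np.any(eq) else 0.0
        r_in = rho_vec[~eq][0] if np.any(~eq) else 0.0
        M = P + sigma * np.eye(n) + r_eq * G_eq + r_in * G_in
        return cho_factor(M)

    fac = factor(rho_vec)
    x = np.zeros(n) if x0 is None else np.asarray(x0, dtype=float).copy()
    z = np.clip(A @ x, l, u)
    y = np.zeros(m) if y0 is None else np.asarray(y0, dtype=float) * row_scale

    scale = max(1.0, float(np.max(np.abs(u[np.isfinite(u)]), initial=1.0)))
    dy_acc = np.zeros(m)
    for it in range(1, max_iter + 1):
        rhs = sigma * x - q + A.T @ (rho_vec * z - y)
        x_t = cho_solve(fac, rhs)
        z_t = A @ x_t
        x_new = alpha * x_t + (1 - alpha) * x
        z_relax = alpha * z_t + (1 - alpha) * z
        z_new = np.clip(z_relax + y / rho_vec, l, u)
        y_new = y + rho_vec * (z_relax - z_new)

        dy = y_new - y
        x, z, y = x_new, z_new, y_new

        if it % 25 == 0 or it == max_iter:
            Ax = A @ x
            r_prim = float(np.max(np.abs(Ax - z), initial=0.0))
            r_dual = float(np.max(np.abs(P @ x + q + A.T @ y), initial=0.0))
            if r_prim < eps * scale and r_dual < eps * max(
                1.0, float(np.max(np.abs(P @ x)))
            ):
                break
            # primal infeasibility certificate (OSQP-style)
            dy_acc = dy
            nrm = np.max(np.abs(dy_acc), initial=0.0)
            if nrm > 1e-12:
                d = dy_acc / nrm
                if np.max(np.abs(A.T @ d)) < 1e-10:
                    support = float(
                        np.sum(np.where(d > 0, u, 0.0) * d)
                        + np.sum(np.where(d < 0, l, 0.0) * d)
                    )
                    if support < -1e-10:
                        worst = int(np.argmax(np.abs(d)))
                        raise InfeasibleProblemError(
                            "primal infeasible constraint set", worst_row=worst
                        )
        if it % polish_every == 0:
            # once primal feasibility is roughly met, the active set is
            # usually stable; an equality polish then gives machine-precision
            # KKT residuals long before ADMM itself converges
            if np.max(np.abs(A @ x - z), initial=0.0) < 1e-4 * scale:
                xs, ys, ok = _polish(P, q, A, l, u, x, y, active_tol=1e-6 * scale)
                if ok and _kkt_residual(P, q, A, l, u, xs, ys) < eps * max(
                    1.0, float(np.max(np.abs(P @ xs + q)))
                ):
                    return QPResult(
                        xs,
                        ys / row_scale,
                        it,
                        _kkt_residual(P, q, A, l, u, xs, ys),
                        polished=True,
                    )
        if it % adapt_every == 0:
            Ax = A @ x
            r_prim = np.max(np.abs(Ax - z), initial=0.0)
            r_dual = np.max(np.abs(P @ x + q + A.T @ y), initial=0.0)
            base = float(np.min(rho_vec))
            if r_prim > 10 * r_dual and base < 1e7:
                rho_vec = rho_vec * 5.0
                fac = factor(rho_vec)
            elif r_dual > 10 * r_prim and base > 1e-7:
                rho_vec = rho_vec / 5.0
                fac = factor(rho_vec)

    xs, ys, ok = _polish(P, q, A, l, u, x, y, active_tol=1e-7 * scale)
    if ok:
        res_pol = _kkt_residual(P, q, A, l, u, xs, ys)
        res_raw = _kkt_residual(P, q, A, l, u, x, y)
        if res_pol <= res_raw:
            return QPResult(xs, ys / row_scale, it, res_pol, polished=True)
    return QPResult(
        x, y / row_scale, it, _kkt_residual(P, q, A, l, u, x, y), polished=False
    )
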