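"""Row-wise sparse recovery of direct influence with principled residual budgets.

Each row of the direct-influence matrix is recovered by basis-pursuit
denoising,

    minimize ||s_i||_1  subject to  ||B^T s_i - c_i||_2 <= eps_i,

where (B, C) come from the deconvolution or response-system mapping and
``eps_i`` is the allowable *total perturbation*: how far the noisy linear
relation may be violated before noise is being fitted. The module provides
three per-row budgets — the oracle "true" bound (needs the ground-truth
matrix), an approximation built from the realized noise ``dG`` and its
largest singular value, and a loose Frobenius upper bound — together with
the standard restricted-isometry recovery-error bound and the Hoyer
sparsity statistic.

The convex program is solved exactly by the lasso homotopy path: the
penalized solution whose residual norm equals ``eps_i`` coincides with the
constrained optimum, and along the piecewise-linear path that point is found
by solving a per-segment quadratic. The equality case ``eps_i = 0`` is a
basis-pursuit linear program.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog, minimize
from sklearn.linear_model import lars_path

from .deconv import LinearSystemForm, nd_closed_form
from .netsim import DirectInfluence, NoiseSpec, TotalInfluence


class SolverError(RuntimeError):
    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


class InfeasibleError(SolverError):
    pass


@dataclass
class BoundEstimate:
    """Per-row total-perturbation budgets eps_i plus their spectral diagnostics."""

    eps: np.ndarray
    gamma: float = 0.0  # largest eigenvalue magnitude of the noise matrix dG
    delta_K: float = 0.0  # assumed restricted isometry constant (diagnostic)
    kind: str = "approx"  # true | approx | upper

    def __post_init__(self) -> None:
        self.eps = np.atleast_1d(np.asarray(self.eps, dtype=float))
        if np.any(self.eps < 0):
            raise ValueError("eps must be nonnegative")


@dataclass
class SolveResult:
    S_hat: DirectInfluence
    residual_norms: np.ndarray
    status: list[str] = field(default_factory=list)  # optimal | infeasible-relaxed


def _basis_pursuit_eq(A: np.ndarray, c: np.ndarray) -> np.ndarray:
    """min ||s||_1 s.t. A s = c via the split-variable LP (HiGHS)."""
    n, p = A.shape
    res = linprog(
        np.ones(2 * p),
        A_eq=np.hstack([A, -A]),
        b_eq=c,
        bounds=(0, None),
        method="highs",
    )
    if not res.success:
        raise InfeasibleError("equality-constrained system is inconsistent")
    x = res.x
    return x[:p] - x[p:]


def _bpdn_slsqp(A: np.ndarray, c: np.ndarray, eps: float, x0: np.ndarray) -> np.ndarray:
    """Fallback solver: split positives/negatives, smooth quadratic constraint."""
    p = A.shape[1]
    z0 = np.concatenate([np.clip(x0, 0, None), np.clip(-x0, 0, None)])

    def obj(z):
        return z.sum()

    def obj_grad(z):
        return np.ones_like(z)

    def con(z):
        r = A @ (z[:p] - z[p:]) - c
        return eps**2 - r @ r

    def con_grad(z):
        r = A @ (z[:p] - z[p:]) - c
        g = -2.0 * (A.T @ r)
        return np.concatenate([g, -g])

    res = minimize(
        obj,
        z0,
        jac=obj_grad,
        method="SLSQP",
        bounds=[(0, None)] * (2 * p),
        constraints=[{"type": "ineq", "fun": con, "jac": con_grad}],
        options={"maxiter": 500, "ftol": 1e-14},
    )
    z = res.x
    return z[:p] - z[p:]


def _bpdn(A: np.ndarray, c: np.ndarray, eps: float, tol: float) -> np.ndarray:
    """Exact basis-pursuit denoising via the lasso homotopy path."""
    p = A.shape[1]
    nc = float(np.linalg.norm(c))
    if nc <= eps + tol:
        return np.zeros(p)  # zero is feasible, hence l1-minimal
    if eps <= tol:
        return _basis_pursuit_eq(A, c)
    try:
        _, _, coefs = lars_path(A, c, method="lasso", alpha_min=0.0)
    except Exception:  # degenerate path: polish from least squares
        x_ls = np.linalg.lstsq(A, c, rcond=None)[0]
        return _bpdn_slsqp(A, c, eps, x_ls)
    resid = c[:, None] - A @ coefs
    norms = np.linalg.norm(resid, axis=0)
    feas = np.nonzero(norms <= eps + tol)[0]
    if feas.size == 0:
        # path may stop short of the attainable residual on ill-conditioned A
        x_ls, _, _, _ = np.linalg.lstsq(A, c, rcond=None)
        if np.linalg.norm(A @ x_ls - c) <= eps + tol:
            return _bpdn_slsqp(A, c, eps, x_ls)
        raise InfeasibleError(
            f"minimum attainable residual {norms.min():.3e} exceeds eps={eps:.3e}"
        )
    k = int(feas[0])
    if k == 0:
        return coefs[:, 0]
    w0 = coefs[:, k - 1]
    dw = coefs[:, k] - w0
    r0 = c - A @ w0
    Adw = A @ dw
    a = float(Adw @ Adw)
    if a <= 0:
        return coefs[:, k]
    b = float(r0 @ Adw)
    c0 = float(r0 @ r0) - eps**2
    disc = max(b * b - a * c0, 0.0)
    t = (b - np.sqrt(disc)) / a  # first crossing of ||r|| = eps from above
    t = float(np.clip(t, 0.0, 1.0))
    s = w0 + t * dw
    # numerical safety: certify feasibility, else polish
    if np.linalg.norm(A @ s - c) > eps + max(1e-7, 10 * tol):
        s = _bpdn_slsqp(A, c, eps, s)
    return s


def solve_row(
    B: np.ndarray,
    c_i: np.ndarray,
    eps_i: float,
    solver_tol: float = 1e-9,
    row: int | None = None,
) -> tuple[np.ndarray, str]:
    """Recover one row: min ||s||_1 s.t. ||B^T s - c_i||_2 <= eps_i.

    Returns (s_i, status); an infeasible budget is relaxed by 10% once and
    flagged ``infeasible-relaxed`` before giving up.
    """
    if eps_i < 0:
        raise ValueError("eps must be nonnegative")
    A = np.asarray(B, dtype=float).T
    c = np.asarray(c_i, dtype=float)
    try:
        return _bpdn(A, c, float(eps_i), solver_tol), "optimal"
    except InfeasibleError:
        if eps_i == 0:
            raise InfeasibleError("inconsistent system with eps=0", row=row)
        try:
            s = _bpdn(A, c, 1.1 * float(eps_i), solver_tol)
            return s, "infeasible-relaxed"
        except InfeasibleError as exc:
            raise InfeasibleError(str(exc), row=row) from exc


def solve_matrix(
    form: LinearSystemForm,
    bounds: BoundEstimate,
    solver_tol: float = 1e-9,
    zero_diagonal: bool = False,
) -> SolveResult:
    """Row-wise sparse recovery of the full direct-influence matrix.

    Rows are independent problems (any execution order gives the same
    result). ``zero_diagonal`` removes the self-influence variable before
    solving, the convention when (B, C) come from deconvolution.
    """
    n = form.n
    eps = np.broadcast_to(bounds.eps, (n,))
    S = np.zeros((n, n))
    residuals = np.zeros(n)
    status: list[str] = []
    for i in range(n):
        if zero_diagonal:
            keep = np.arange(n) != i
            A = form.B.T[:, keep]
            s_red, st = _solve_general(A, form.C[i], float(eps[i]), solver_tol, i)
            s = np.zeros(n)
            s[keep] = s_red
        else:
            s, st = solve_row(form.B, form.C[i], float(eps[i]), solver_tol, row=i)
        S[i] = s
        residuals[i] = np.linalg.norm(s @ form.B - form.C[i])
        status.append(st)
    return SolveResult(DirectInfluence(S), residuals, status)


def _solve_general(
    A: np.ndarray, c: np.ndarray, eps: float, tol: float, row: int
) -> tuple[np.ndarray, str]:
    try:
        return _bpdn(A, np.asarray(c, dtype=float), eps, tol), "optimal"
    except InfeasibleError:
        if eps == 0:
            raise
        s = _bpdn(A, np.asarray(c, dtype=float), 1.1 * eps, tol)
        return s, "infeasible-relaxed"


def true_bound(S0: DirectInfluence, form: LinearSystemForm) -> BoundEstimate:
    """Oracle budget: eps_i is the realized residual of the true matrix."""
    eps = np.linalg.norm(S0.S @ form.B - form.C, axis=1)
    return BoundEstimate(eps=eps, kind="true")


def approx_bound(
    G: TotalInfluence,
    dG: np.ndarray,
    S_ref: DirectInfluence | None = None,
) -> BoundEstimate:
    """Noise-based budget from the residual identity, without ground truth.

    The true matrix's residual against the noisy system is exactly
    ``(S0 dG - dG)_i`` row-wise; substituting a reference estimate for S0
    (default: the closed-form deconvolution of the noisy G, whose error
    enters only at second order in the noise) gives the operational budget

        eps_i = ||(S_ref dG - dG)_i||_2.

    ``gamma``, the largest eigenvalue magnitude of the noise matrix (about
    sigma*sqrt(n) for i.i.d. noise, by the circular law), is attached as the
    spectral diagnostic; the looser triangle-inequality form
    ``||dG_i|| + gamma ||S_ref_i||`` is what :func:`upper_bound` tightens to
    the Frobenius level.
    """
    dG = np.asarray(dG, dtype=float)
    if S_ref is None:
        S_ref = nd_closed_form(G)
    gamma = float(np.max(np.abs(np.linalg.eigvals(dG)))) if dG.any() else 0.0
    eps = np.linalg.norm(S_ref.S @ dG - dG, axis=1)
    return BoundEstimate(eps=eps, gamma=gamma, kind="approx")


def upper_bound(G: TotalInfluence, dG: np.ndarray) -> BoundEstimate:
    """Loose Frobenius budget, valid for every row simultaneously."""
    dG = np.asarray(dG, dtype=float)
    nF = float(np.linalg.norm(dG))
    val = nF * (1.0 + float(np.linalg.norm(nd_closed_form(G).S)))
    gamma = float(np.linalg.svd(dG, compute_uv=False)[0]) if dG.any() else 0.0
    return BoundEstimate(eps=np.full(G.n, val), gamma=gamma, kind="upper")


def bound_from_noise_spec(
    G: TotalInfluence, spec: NoiseSpec, S_ref: DirectInfluence | None = None
) -> BoundEstimate:
    """Expected-norm budget when the noise matrix itself is unobserved.

    Uses E||dG_i||_2 ~ sigma * sqrt(n) * scale_i and gamma ~ sigma sqrt(n),
    the circular-law spectral radius of i.i.d. noise (times the RMS |G|
    scale in the proportional mode).
    """
    n = G.n
    if S_ref is None:
        S_ref = nd_closed_form(G)
    if spec.mode == "independent":
        row_norm = spec.sigma * np.sqrt(n) * np.ones(n)
        gamma = spec.sigma * np.sqrt(n)
    else:
        scale_i = np.sqrt(np.mean(G.G**2, axis=1))
        row_norm = spec.sigma * np.sqrt(n) * scale_i
        gamma = spec.sigma * np.sqrt(n) * float(np.sqrt(np.mean(G.G**2)))
    eps = row_norm + gamma * np.linalg.norm(S_ref.S, axis=1)
    return BoundEstimate(eps=eps, gamma=gamma, kind="approx")


def ric_error_bound(delta_2K: float, eps_i: float) -> float:
    """Worst-case recovery-error bound under a restricted isometry constant.

    ||s_hat - s0||_2 <= 4 sqrt(1 + d) / (1 - (1 + sqrt(2)) d) * eps, valid
    for d = delta_2K < sqrt(2) - 1. Diagnostic only: the constant is NP-hard
    to compute, so callers pass an assumed value.
    """
    if not 0 <= delta_2K < np.sqrt(2) - 1:
        raise ValueError("delta_2K must lie in [0, sqrt(2)-1)")
    return 4.0 * np.sqrt(1.0 + delta_2K) / (1.0 - (1.0 + np.sqrt(2)) * delta_2K) * eps_i


def hoyer(S: np.ndarray) -> float:
    """Hoyer sparsity of a matrix, in [0, 1] (1 = one nonzero, 0 = flat)."""
    v = np.asarray(S, dtype=float).ravel()
    m = v.size
    l2 = np.linalg.norm(v)
    if l2 == 0:
        return 1.0  # convention: the zero matrix is maximally sparse
    return float((np.sqrt(m) - np.abs(v).sum() / l2) / (np.sqrt(m) - 1.0))
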