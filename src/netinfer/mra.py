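"""Modular response analysis on transient trajectories.

Each Jacobian row ``s_i`` of the underlying dynamics satisfies, to first
order in the parameter perturbations,

    s_i R = d,    R[j, k] = x_j^(k)(t) - x_j^(0)(t),
                  d[k]    = xdot_i^(k)(t) - xdot_i^(0)(t),

where run ``k`` perturbs only the degradation parameter ``p_k``. The classic
(Sontag-style) design cannot use the run k = i — ``p_i`` enters equation i
directly — so its i-th experiment carries only indirect, noise-level
responses, leaving R with a column orders of magnitude smaller than the rest
and the inversion extremely sensitive to noise. The robust design keeps the ``p_i``
run and moves the known direct term ``-x_i dp_i`` to the right-hand side
(the self term is linear in ``x_i``), restoring column balance.

Rows are then solved either by least squares (the classic baseline) or by
the constrained l1 program with a noise-calibrated residual budget.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import l1min
from .netsim import TrajectoryEnsemble


@dataclass
class ResponseSystem:
    """Response matrix and derivative responses for one Jacobian row at time t."""

    R: np.ndarray  # (node j, perturbation k) state responses
    d: np.ndarray  # derivative responses of node row_index
    row_index: int
    t: float
    corrected: bool = False  # robust self-perturbation correction applied

    @property
    def n(self) -> int:
        return self.R.shape[0]

    def condition_number(self) -> float:
        return float(np.linalg.cond(self.R))

    def column_imbalance(self) -> float:
        """max/min column norm of R: the conditioning pathology indicator."""
        norms = np.linalg.norm(self.R, axis=0)
        lo = norms.min()
        return float(np.inf) if lo == 0 else float(norms.max() / lo)


def derivative(traj: np.ndarray, times: np.ndarray, t: float) -> np.ndarray:
    """Finite-difference time derivative of a (time x node) trajectory at t.

    Central difference (exact for quadratics) at interior grid points;
    one-sided with a warning at the boundary.
    """
    times = np.asarray(times, dtype=float)
    idx = int(np.argmin(np.abs(times - t)))
    if not np.isclose(times[idx], t):
        raise ValueError(f"t={t} is not on the time grid")
    if 0 < idx < len(times) - 1:
        dt = times[idx + 1] - times[idx - 1]
        return (traj[idx + 1] - traj[idx - 1]) / dt
    warnings.warn("boundary time point: using one-sided difference", stacklevel=2)
    if idx == 0:
        return (traj[1] - traj[0]) / (times[1] - times[0])
    return (traj[-1] - traj[-2]) / (times[-1] - times[-2])


def build_response_system(
    ens: TrajectoryEnsemble,
    i: int,
    t: float,
    robust: bool = True,
    mode: str | None = None,
) -> ResponseSystem:
    """Assemble s_i R = d from a perturbation ensemble at grid time t.

    Three designs:

    - ``robust`` (default): the p_i run is used for experiment i and d[i] is
      corrected by the known direct contribution ``+ dp_i * x_i^(i)(t)``
      (the self term is linear in x_i); R is square and column-balanced.
    - ``padded``: the classic design padded to a square system with an inert
      experiment — the direct perturbation of node i is inadmissible, so its
      column holds only the noise-level responses of an unperturbed re-run.
      This reproduces the orders-of-magnitude column imbalance that makes
      the plain inversion noise-fragile.
    - ``reduced``: the classic design with only the n-1 admissible
      experiments; R is n x (n-1) and the row is solved in the least-squares
      minimum-norm sense.

    ``robust=False`` is shorthand for ``mode="padded"``.
    """
    if mode is None:
        mode = "robust" if robust else "padded"
    if mode not in ("robust", "padded", "reduced"):
        raise ValueError(f"unknown design mode {mode!r}")
    times = ens.times
    idx = int(np.argmin(np.abs(times - t)))
    if not np.isclose(times[idx], t):
        raise ValueError(f"t={t} is not on the time grid")
    if idx == 0 or idx == len(times) - 1:
        raise ValueError("t must be strictly inside the time grid")
    n = ens.n
    R = np.zeros((n, n))
    d = np.zeros(n)
    d_base = derivative(ens.baseline, times, t)
    for k, dpk in ens.design:
        R[:, k] = ens.perturbed[k][idx] - ens.baseline[idx]
        d[k] = derivative(ens.perturbed[k], times, t)[i] - d_base[i]
    corrected = False
    if mode == "robust":
        _, dpi = ens.design[i]
        d[i] += dpi * ens.perturbed[i][idx, i]
        corrected = True
    elif mode == "padded":
        if ens.null_run is None:
            raise ValueError("padded design needs a null run in the ensemble")
        R[:, i] = ens.null_run[idx] - ens.baseline[idx]
        d[i] = derivative(ens.null_run, times, t)[i] - d_base[i]
    else:  # reduced
        keep = np.arange(n) != i
        R = R[:, keep]
        d = d[keep]
    return ResponseSystem(R=R, d=d, row_index=i, t=float(times[idx]), corrected=corrected)


def sontag_solve(rs: ResponseSystem, rcond: float = 1e-12) -> np.ndarray:
    """Least-squares (pseudo-inverse) solution of s_i R = d — the classic baseline."""
    s, *_ = np.linalg.lstsq(rs.R.T, rs.d, rcond=rcond)
    return s


def l1_solve_row_mra(
    rs: ResponseSystem, eps_i: float, solver_tol: float = 1e-9
) -> np.ndarray:
    """Sparse recovery of one Jacobian row from the response system."""
    s, _ = l1min.solve_row(rs.R, rs.d, eps_i, solver_tol, row=rs.row_index)
    return s


def mra_bound(
    ens: TrajectoryEnsemble, i: int, t: float, sigma_obs: float, robust: bool = True
) -> float:
    """Residual budget eps_i from the trajectory-observation noise level.

    eps_i = ||s_pilot||_2 * ||dR||_est + ||dd||_est with
    ||dR||_est = 2 sigma sqrt(n) and ||dd||_est = 2 sqrt(2) sigma sqrt(n)/dt
    (central differencing amplifies observation noise by sqrt(2)/dt); the
    pilot row estimate comes from the least-squares solve. Linear in sigma.
    """
    if sigma_obs < 0:
        raise ValueError("sigma_obs must be nonnegative")
    if sigma_obs == 0:
        return 0.0
    n = ens.n
    dt = float(np.median(np.diff(ens.times)))
    rs = build_response_system(ens, i, t, robust=robust)
    s_pilot = sontag_solve(rs)
    dR = 2.0 * sigma_obs * np.sqrt(n)
    dd = 2.0 * np.sqrt(2.0) * sigma_obs * np.sqrt(n) / dt
    return float(np.linalg.norm(s_pilot) * dR + dd)
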