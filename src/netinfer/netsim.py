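"""Synthetic ground truths: sparse networks, influence closures, noise, dynamics.

Everything downstream (deconvolution, sparse recovery, MRA) is exercised on
networks produced here: scale-free directed graphs with weighted couplings
(the direct-influence matrix ``S``), their total-influence closure
``G = (I - S)^{-1} S``, noisy observations of ``G``, and transient
trajectories of a Michaelis-Menten-type regulatory ODE together with the
one-parameter-at-a-time perturbation ensembles that modular response
analysis consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp


class ClosureDivergenceError(ValueError):
    """Spectral radius of S is >= 1: the influence series does not converge."""


class SimulationError(RuntimeError):
    """ODE integration produced a non-finite state."""


@dataclass
class DirectInfluence:
    """Direct-coupling matrix: ``S[i, j]`` is the influence of node j on node i.

    A nonzero entry corresponds to a directed arc j -> i; the zero pattern is
    the (absence of) network structure that the inference methods try to
    recover.
    """

    S: np.ndarray

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        if self.S.ndim != 2 or self.S.shape[0] != self.S.shape[1]:
            raise ValueError("S must be a square matrix")
        if not np.all(np.isfinite(self.S)):
            raise ValueError("S must have finite entries")

    @property
    def n(self) -> int:
        return self.S.shape[0]

    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.S))))


@dataclass
class TotalInfluence:
    """Accumulated direct + indirect influence matrix ``G``."""

    G: np.ndarray
    provenance: str = "measured"  # closure | correlation-pearson | correlation-spearman | measured

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, dtype=float)
        if self.G.ndim != 2 or self.G.shape[0] != self.G.shape[1]:
            raise ValueError("G must be a square matrix")

    @property
    def n(self) -> int:
        return self.G.shape[0]


@dataclass
class NoiseSpec:
    """Observation noise on a total-influence matrix.

    ``proportional`` scales a standard-normal draw by ``sigma * |G_ij|``
    (multiplicative measurement error); ``independent`` adds
    ``sigma * z_ij`` everywhere.
    """

    mode: str = "proportional"
    sigma: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("proportional", "independent"):
            raise ValueError(f"unknown noise mode {self.mode!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")


@dataclass
class MMSystem:
    """Michaelis-Menten-type regulatory dynamics.

    dx_i/dt = -p_i x_i + sum_j S0[i, j] * x_j^h / (1 + x_j^h)

    The self term is linear in x_i (first-order degradation at rate p_i > 0);
    regulation saturates through a Hill/Michaelis-Menten nonlinearity with
    exponent ``h`` (default 1).
    """

    S0: DirectInfluence
    degradation: np.ndarray
    hill_exponent: float = 1.0
    x0: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = self.S0.n
        self.degradation = np.broadcast_to(
            np.asarray(self.degradation, dtype=float), (n,)
        ).copy()
        if np.any(self.degradation <= 0):
            raise ValueError("degradation rates must be positive")
        if self.hill_exponent <= 0:
            raise ValueError("hill exponent must be positive")
        if self.x0 is None:
            self.x0 = np.ones(n)
        self.x0 = np.asarray(self.x0, dtype=float)
        if np.any(self.x0 < 0):
            raise ValueError("initial state must be nonnegative")

    @property
    def n(self) -> int:
        return self.S0.n

    def rhs(self, t: float, x: np.ndarray, degradation: np.ndarray | None = None) -> np.ndarray:
        p = self.degradation if degradation is None else degradation
        h = self.hill_exponent
        xh = np.power(np.clip(x, 0.0, None), h)
        return -p * x + self.S0.S @ (xh / (1.0 + xh))

    def jacobian(self, x: np.ndarray) -> np.ndarray:
        """State Jacobian at x: the instantaneous direct-influence matrix."""
        h = self.hill_exponent
        xc = np.clip(x, 1e-300, None)
        xh = np.power(xc, h)
        dsat = h * np.power(xc, h - 1.0) / (1.0 + xh) ** 2
        J = self.S0.S * dsat[None, :]
        J[np.diag_indices_from(J)] -= self.degradation
        return J


@dataclass
class TrajectoryEnsemble:
    """Baseline + one-parameter-perturbed trajectories on a shared time grid.

    ``perturbed[k]`` is the observed trajectory with degradation rate ``p_k``
    scaled by ``1 + delta_frac``; ``null_run`` is an unperturbed re-observation
    (same dynamics, fresh noise) used by the non-robust response design.
    Trajectories are (time x node) arrays.
    """

    times: np.ndarray
    baseline: np.ndarray
    perturbed: list[np.ndarray]
    design: list[tuple[int, float]]  # (parameter index k, absolute delta p_k)
    noise_sigma: float = 0.0
    null_run: np.ndarray | None = None
    system: MMSystem | None = None

    @property
    def n(self) -> int:
        return self.baseline.shape[1]


def sample_scale_free(
    n: int, degree_exponent: float, edge_budget: int, seed: int
) -> np.ndarray:
    """Directed scale-free adjacency with an exact edge count and no self-loops.

    Uses the static (Goh/Chung-Lu) construction: node i gets fitness
    ``(i + 1)^(-alpha)`` with ``alpha = 1/(degree_exponent - 1)``, and edges
    are drawn with endpoint probabilities proportional to fitness, which
    yields a degree-distribution tail exponent close to ``degree_exponent``.
    """
    if n < 3:
        raise ValueError("need at least 3 nodes")
    if degree_exponent <= 1:
        raise ValueError("degree exponent must exceed 1")
    if edge_budget > n * (n - 1):
        raise ValueError("edge budget exceeds the number of possible arcs")
    rng = np.random.default_rng(seed)
    alpha = 1.0 / (degree_exponent - 1.0)
    fitness = np.arange(1, n + 1, dtype=float) ** (-alpha)
    # independent rank orders for in- and out-roles so hubs differ
    out_p = fitness[rng.permutation(n)]
    in_p = fitness[rng.permutation(n)]
    out_p /= out_p.sum()
    in_p /= in_p.sum()
    A = np.zeros((n, n), dtype=int)
    n_edges = 0
    while n_edges < edge_budget:
        src = rng.choice(n, size=edge_budget, p=out_p)
        dst = rng.choice(n, size=edge_budget, p=in_p)
        for s, d in zip(src, dst):
            if s == d or A[d, s]:
                continue
            A[d, s] = 1  # arc s -> d stored row=target
            n_edges += 1
            if n_edges == edge_budget:
                break
    return A


def assign_weights(
    adjacency: np.ndarray,
    magnitude_range: tuple[float, float] = (0.1, 1.0),
    sign_mode: str = "mixed",
    stabilize: bool = True,
    seed: int = 0,
) -> DirectInfluence:
    """Put random weights on the support of ``adjacency``.

    Magnitudes are Uniform(lo, hi); ``mixed`` flips signs with probability
    1/2. With ``stabilize`` the matrix is rescaled to spectral radius 0.9
    whenever the draw exceeds it, keeping the influence closure convergent.
    Sparse directed draws are usually far below this bound already (few
    directed cycles), so the rescale rarely triggers.
    """
    lo, hi = magnitude_range
    if lo <= 0 or hi < lo:
        raise ValueError("need 0 < lo <= hi")
    if sign_mode not in ("mixed", "positive"):
        raise ValueError(f"unknown sign mode {sign_mode!r}")
    rng = np.random.default_rng(seed)
    A = np.asarray(adjacency, dtype=float)
    W = np.zeros_like(A)
    mask = A != 0
    mags = rng.uniform(lo, hi, size=int(mask.sum()))
    if sign_mode == "mixed":
        mags *= rng.choice([-1.0, 1.0], size=mags.size)
    W[mask] = mags
    S = DirectInfluence(W)
    if stabilize and mask.any():
        rho = S.spectral_radius()
        if rho > 0.9:
            S = DirectInfluence(W * (0.9 / rho))
    return S


def total_influence_closure(S: DirectInfluence) -> TotalInfluence:
    """Accumulate direct influence over all paths: G = S + S G = (I - S)^{-1} S."""
    rho = S.spectral_radius()
    if rho >= 1.0:
        raise ClosureDivergenceError(
            f"spectral radius {rho:.4f} >= 1: total influence diverges"
        )
    n = S.n
    G = np.linalg.solve(np.eye(n) - S.S, S.S)
    return TotalInfluence(G, provenance="closure")


def add_noise(
    G0: TotalInfluence, spec: NoiseSpec
) -> tuple[TotalInfluence, np.ndarray]:
    """Contaminate a total-influence matrix; returns (noisy G, the noise dG)."""
    rng = np.random.default_rng(spec.seed)
    z = rng.standard_normal(G0.G.shape)
    if spec.mode == "proportional":
        dG = spec.sigma * np.abs(G0.G) * z
    else:
        dG = spec.sigma * z
    return TotalInfluence(G0.G + dG, provenance=G0.provenance), dG


def simulate_mm(
    system: MMSystem,
    times: np.ndarray,
    sigma_obs: float = 0.0,
    seed: int = 0,
    degradation: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> np.ndarray:
    """Integrate the MM ODE on ``times`` and add observation noise.

    Returns the observed (time x node) trajectory; with ``sigma_obs=0`` it is
    the noiseless solution to integrator tolerance.
    """
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    sol = solve_ivp(
        lambda t, x: system.rhs(t, x, degradation),
        (times[0], times[-1]),
        system.x0,
        t_eval=times,
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success or not np.all(np.isfinite(sol.y)):
        raise SimulationError(f"integration failed: {sol.message}")
    traj = sol.y.T.copy()
    if sigma_obs > 0:
        rng = np.random.default_rng(seed)
        traj = traj + sigma_obs * rng.standard_normal(traj.shape)
    return traj


def perturb_and_simulate(
    system: MMSystem,
    times: np.ndarray,
    delta_frac: float = 0.1,
    sigma_obs: float = 0.0,
    seed: int = 0,
    include_null: bool = True,
) -> TrajectoryEnsemble:
    """One-parameter-at-a-time perturbation ensemble for response analysis.

    For each node k the degradation rate ``p_k`` is scaled by
    ``1 + delta_frac`` and the system re-integrated from the same initial
    condition; an extra unperturbed run (fresh observation noise only) is
    included for the non-robust design. All runs share the time grid.
    """
    if delta_frac < 0:
        raise ValueError("delta_frac must be nonnegative")
    n = system.n
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(n + 2)
    baseline = simulate_mm(system, times, sigma_obs, int(seeds[0]))
    perturbed = []
    design = []
    for k in range(n):
        p = system.degradation.copy()
        dpk = delta_frac * p[k]
        p[k] += dpk
        perturbed.append(
            simulate_mm(system, times, sigma_obs, int(seeds[k + 1]), degradation=p)
        )
        design.append((k, dpk))
    null_run = None
    if include_null:
        null_run = simulate_mm(system, times, sigma_obs, int(seeds[n + 1]))
    return TrajectoryEnsemble(
        times=np.asarray(times, dtype=float),
        baseline=baseline,
        perturbed=perturbed,
        design=design,
        noise_sigma=sigma_obs,
        null_run=null_run,
        system=system,
    )
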