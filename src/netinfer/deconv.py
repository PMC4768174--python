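"""Network deconvolution: from total influence back to direct influence.

The closure ``G = S + S G`` gives the linear relation ``S (I + G) = G``
between the direct matrix and the accumulated (direct + indirect) matrix.
This module estimates ``G`` from sample data when it is not measured
directly, packages the relation as a generic linear system ``S B = C``, and
provides the closed-form (dense) deconvolution baseline ``S = G (I + G)^{-1}``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .netsim import DirectInfluence, TotalInfluence


class SingularSystemError(np.linalg.LinAlgError):
    pass


@dataclass
class LinearSystemForm:
    """The pair (B, C) with S B = C linking direct and total influence."""

    B: np.ndarray
    C: np.ndarray
    mapping: str = "feizi"  # 'mra' reserved for response systems

    def __post_init__(self) -> None:
        self.B = np.asarray(self.B, dtype=float)
        self.C = np.asarray(self.C, dtype=float)
        if self.B.shape != self.C.shape:
            raise ValueError("B and C must have matching shapes")

    @property
    def n(self) -> int:
        return self.B.shape[0]


def estimate_total_influence(
    samples: np.ndarray, method: str = "pearson"
) -> TotalInfluence:
    """Correlation estimate of total influence from an (observations x nodes) matrix.

    Pearson captures linear co-excitation; Spearman any monotone
    relationship. The diagonal is zeroed (self-influence is not part of the
    estimate) and constant columns get zero correlation with a warning.
    """
    X = np.asarray(samples, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("need an (m x n) sample matrix with m >= 3")
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    constant = np.std(X, axis=0) == 0
    if np.any(constant):
        warnings.warn(
            f"{int(constant.sum())} constant column(s); their correlations set to 0",
            stacklevel=2,
        )
    if method == "spearman":
        X = stats.rankdata(X, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        G = np.corrcoef(X, rowvar=False)
    G = np.where(np.isfinite(G), G, 0.0)
    G[:, constant] = 0.0
    G[constant, :] = 0.0
    np.fill_diagonal(G, 0.0)
    return TotalInfluence(G, provenance=f"correlation-{method}")


def build_linear_system(G: TotalInfluence) -> LinearSystemForm:
    """Deconvolution instantiation of S B = C: B = I + G, C = G."""
    n = G.n
    return LinearSystemForm(B=np.eye(n) + G.G, C=G.G.copy(), mapping="feizi")


def nd_closed_form(G: TotalInfluence, cond_limit: float = 1e12) -> DirectInfluence:
    """Closed-form network deconvolution S = G (I + G)^{-1}.

    Exactly inverts the influence closure in the noise-free case; with noisy
    G it is the dense least-structure baseline the sparse solver is compared
    against.
    """
    n = G.n
    B = np.eye(n) + G.G
    if np.linalg.cond(B) > cond_limit:
        raise SingularSystemError("I + G is numerically singular")
    # S = C B^{-1}  <=>  B^T S^T = C^T
    S = np.linalg.solve(B.T, G.G.T).T
    return DirectInfluence(S)
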