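"""Combining estimates across noise realizations or time points.

Entries corresponding to truly absent arcs are driven by zero-mean noise, so
the elementwise mean of N independent estimates shrinks them at the 1/sqrt(N)
rate while the true couplings survive — absence calls made on the averaged
matrix are therefore more reliable than on any single estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .netsim import DirectInfluence


@dataclass
class EstimateStack:
    estimates: list[DirectInfluence]
    source: str = "noise-realizations"  # or "time-points"

    def __post_init__(self) -> None:
        if not self.estimates:
            raise ValueError("need at least one estimate")
        shape = self.estimates[0].S.shape
        if any(e.S.shape != shape for e in self.estimates):
            raise ValueError("all estimates must share one shape")

    @property
    def N(self) -> int:
        return len(self.estimates)


def average_estimates(stack: EstimateStack) -> DirectInfluence:
    """Elementwise mean of the stack."""
    return DirectInfluence(np.mean([e.S for e in stack.estimates], axis=0))


def zero_set(S_avg: DirectInfluence, tau: float | None = None) -> np.ndarray:
    """Binary matrix of predicted absent arcs: |S_ij| <= tau.

    Default tau is 1e-3 of the largest entry magnitude; the l1 solver
    produces many exact zeros, so absence calls are insensitive to tau over
    decades.
    """
    if tau is None:
        tau = 1e-3 * np.max(np.abs(S_avg.S)) if S_avg.S.any() else 0.0
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    return (np.abs(S_avg.S) <= tau).astype(int)
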