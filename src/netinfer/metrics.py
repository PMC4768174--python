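"""Evaluation statistics for recovered influence matrices.

Two error families: the relative Frobenius inference error rho (overall
accuracy of the recovered couplings) and the absence-detection error e (the
fraction of truly absent arcs whose estimate exceeds a threshold — the
specificity-oriented quantity sparse recovery optimizes). Ranking quality
against a gold-standard edge list uses AUROC/AUPR, combined into the
DREAM-style xi score via permutation-null p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score


@dataclass
class EvalReport:
    rho: float = np.nan
    e: float = np.nan
    hoyer: float = np.nan
    auroc: float = np.nan
    aupr: float = np.nan
    xi: float = np.nan

    def to_dict(self) -> dict:
        return {k: float(v) for k, v in self.__dict__.items()}


def inference_error(S_hat: np.ndarray, S0: np.ndarray) -> float:
    """Relative Frobenius error rho = ||S_hat - S0||_F / ||S0||_F."""
    S0 = np.asarray(S0, dtype=float)
    denom = np.linalg.norm(S0)
    if denom == 0:
        raise ValueError("rho is undefined for an all-zero reference matrix")
    return float(np.linalg.norm(np.asarray(S_hat, dtype=float) - S0) / denom)


def absence_error(
    S_hat: np.ndarray,
    S0: np.ndarray,
    tau: float,
    exclude_diagonal: bool = True,
) -> float:
    """Fraction of truly absent arcs with |S_hat_ij| > tau (Heaviside count)."""
    S_hat = np.asarray(S_hat, dtype=float)
    S0 = np.asarray(S0, dtype=float)
    mask = S0 == 0
    if exclude_diagonal:
        np.fill_diagonal(mask, False)
    if not mask.any():
        raise ValueError("absence error is undefined without true zero entries")
    return float(np.mean(np.abs(S_hat[mask]) > tau))


def _offdiag_scores(S_hat: np.ndarray, gold: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = S_hat.shape[0]
    mask = ~np.eye(n, dtype=bool)
    return np.abs(S_hat[mask]), (np.asarray(gold)[mask] != 0).astype(int)


def auroc_aupr(S_hat: np.ndarray, gold: np.ndarray) -> tuple[float, float]:
    """Rank-based AUROC and AUPR of |S_hat| against a gold adjacency.

    Diagonal entries are excluded (self-influence is not part of gold
    standards); ties are handled by rank averaging.
    """
    scores, labels = _offdiag_scores(np.asarray(S_hat, dtype=float), gold)
    if labels.min() == labels.max():
        raise ValueError("gold standard must contain both present and absent arcs")
    return float(roc_auc_score(labels, scores)), float(
        average_precision_score(labels, scores)
    )


def xi_score(
    S_hat: np.ndarray,
    gold: np.ndarray,
    m: int = 1000,
    seed: int = 0,
) -> tuple[float, float, float]:
    """DREAM-style score xi = -(log10 p_AUROC + log10 p_AUPR)/2.

    P-values come from a seeded permutation null of the edge scores with an
    add-one pseudocount (so p >= 1/(m+1) and xi is finite). Returns
    (xi, p_auroc, p_aupr). Not comparable to published DREAM5 scores, which
    use the challenge's own precomputed null distributions.
    """
    if m < 100:
        raise ValueError("need at least 100 permutations")
    scores, labels = _offdiag_scores(np.asarray(S_hat, dtype=float), gold)
    if labels.min() == labels.max():
        raise ValueError("gold standard must contain both present and absent arcs")
    auroc = roc_auc_score(labels, scores)
    aupr = average_precision_score(labels, scores)
    rng = np.random.default_rng(seed)
    ge_roc = ge_pr = 0
    for _ in range(m):
        perm = rng.permutation(scores)
        if roc_auc_score(labels, perm) >= auroc:
            ge_roc += 1
        if average_precision_score(labels, perm) >= aupr:
            ge_pr += 1
    p_roc = (ge_roc + 1) / (m + 1)
    p_pr = (ge_pr + 1) / (m + 1)
    xi = -(np.log10(p_roc) + np.log10(p_pr)) / 2.0
    return float(xi), float(p_roc), float(p_pr)
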