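"""Metrics and diagnostics: value error, alignment angles, dimensionality.

The central performance measure is the mean squared value-error (MSVE): the
mean, over the labelled states from the cue timing to the reward timing
inclusive, of the squared difference between the values an agent has
developed and the oracle state values.  Feedback alignment is tracked by
the angle between the value-weight vector w and the fixed feedback vector
c; dimensionality of the learned dynamics by the contribution ratios of
the principal components of the RNN activity time series.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .core import activation

__all__ = ["msve", "vector_angle", "pca_contribution_ratios",
           "summary_statistics", "hypothetical_change_angle",
           "successive_tdrpe_product", "SummaryStats"]


def msve(learned_values: dict, true_values: dict, state_set) -> float:
    """Mean over ``state_set`` of squared (learned - true) value differences."""
    diffs = []
    for s in state_set:
        if s not in learned_values or s not in true_values:
            raise KeyError(f"state {s!r} missing from a value table")
        diffs.append(learned_values[s] - true_values[s])
    return float(np.mean(np.square(diffs)))


def vector_angle(u: np.ndarray, v: np.ndarray) -> float:
    """Angle between two vectors in degrees; NaN if either is zero."""
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        return float("nan")
    cosang = np.clip(u @ v / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def pca_contribution_ratios(X: np.ndarray, n_components: Optional[int] = None,
                            ) -> np.ndarray:
    """Eigenvalue shares of the covariance of an activity time series.

    X has shape (time, units); returns the descending, sum-to-one variance
    shares of the leading components.
    """
    X = np.asarray(X, float)
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need more time points than units")
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (X.shape[0] - 1)
    evals = np.linalg.eigvalsh(cov)[::-1]
    total = evals.sum()
    if total <= 0:
        raise ValueError("degenerate (constant) activity series")
    ratios = evals / total
    if n_components is not None:
        ratios = ratios[:n_components]
    return ratios


@dataclass
class SummaryStats:
    pearson_r: Optional[float] = None
    pearson_p: Optional[float] = None
    cohen_d: Optional[float] = None
    sem_a: Optional[float] = None
    sem_b: Optional[float] = None


def summary_statistics(a: np.ndarray, b: Optional[np.ndarray] = None,
                       ) -> SummaryStats:
    """Pearson r (paired arrays), Cohen's d with average variance, and SEM.

    Cohen's d = (mean(a) - mean(b)) / sqrt((var(a) + var(b)) / 2);
    SEM = SD / sqrt(N).  d is None when both variances vanish.
    """
    a = np.asarray(a, float)
    out = SummaryStats(sem_a=float(np.std(a, ddof=1) / np.sqrt(a.size)))
    if b is None:
        return out
    b = np.asarray(b, float)
    out.sem_b = float(np.std(b, ddof=1) / np.sqrt(b.size))
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va + vb > 0:
        out.cohen_d = float((a.mean() - b.mean()) / np.sqrt((va + vb) / 2.0))
    if a.size == b.size and a.size >= 3 and va > 0 and vb > 0:
        r, p = stats.pearsonr(a, b)
        out.pearson_r, out.pearson_p = float(r), float(p)
    return out


def hypothetical_change_angle(A: np.ndarray, B: np.ndarray,
                              A_new: np.ndarray, B_new: np.ndarray,
                              x_pre: np.ndarray, o_pre: np.ndarray,
                              delta: float, c: np.ndarray,
                              activation_kind: str = "centered") -> float:
    """Angle between sign(delta) * hypothetical activity change and c.

    The hypothetical change replays the forward pass with the updated
    connections: dx = f(A'x + B'o) - f(Ax + Bo); the returned angle (deg)
    is between sign(delta)*dx and the feedback vector.  NaN when delta = 0
    (sign undefined) or when the change vanishes.
    """
    if delta == 0.0:
        return float("nan")
    x_old = activation(A @ x_pre + B @ o_pre, activation_kind)
    x_new = activation(A_new @ x_pre + B_new @ o_pre, activation_kind)
    dx = np.sign(delta) * (x_new - x_old)
    return vector_angle(dx, c)


def successive_tdrpe_product(delta_by_trial: np.ndarray) -> np.ndarray:
    """Products of TD-RPEs at the same state in successive trials.

    Input (n_trials,) or (n_trials, n_states); positive products mean the
    TD-RPE kept its sign from one trial to the next.
    """
    d = np.asarray(delta_by_trial, float)
    return d[:-1] * d[1:]
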