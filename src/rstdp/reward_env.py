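"""Reward computation for the spike-train reproduction task.

The similarity between a produced spike train and the target is measured
with the Victor-Purpura metric ``D[q]``: the minimal cost of transforming
one train into the other, where inserting or deleting a spike costs 1 and
shifting a spike by ``dt`` costs ``q * dt``.  For ``dt > 2/q`` deleting and
re-inserting is cheaper than shifting, so ``1/q`` sets the temporal
precision of the comparison (default 20 ms).

The per-neuron reward normalizes the distance by the total spike count,

    R_j = 1 - D[q](X_out_j, X_target) / (N_out_j + N_target),

which confines ``R_j`` to ``[0, 1]``; the trial reward ``R`` is the mean of
``R_j`` over the output neurons.  The success signal is the deviation of the
trial reward from its running average, ``S = R - Rbar``, with ``Rbar``
updated as an exponential moving average with gain 1/5 per trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RewardBreakdown",
    "RewardState",
    "vp_distance",
    "trial_reward",
    "update_running_average",
    "success_signal",
]

#: EMA gain of the running-average reward: Rbar += (R - Rbar) / EMA_DIVISOR
EMA_DIVISOR = 5.0


def vp_distance(x: np.ndarray, y: np.ndarray, q: float) -> float:
    """Victor-Purpura distance between two spike trains.

    Dynamic program ``G[i][j] = min(G[i-1][j] + 1, G[i][j-1] + 1,
    G[i-1][j-1] + q*|x_i - y_j|)`` with boundary ``G[i][0] = i``,
    ``G[0][j] = j``.  ``q`` is the shift-cost rate in 1/s for spike times
    in seconds; the distance is bounded by ``len(x) + len(y)``.
    """
    if q <= 0:
        raise ValueError("q must be positive")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    if n == 0 or m == 0:
        return float(n + m)
    prev = np.arange(m + 1, dtype=float)
    cur = np.empty(m + 1)
    for i in range(1, n + 1):
        cur[0] = i
        shift = prev[:-1] + q * np.abs(x[i - 1] - y)
        for j in range(1, m + 1):
            cur[j] = min(prev[j] + 1.0, cur[j - 1] + 1.0, shift[j - 1])
        prev, cur = cur, prev
    return float(prev[m])


@dataclass
class RewardBreakdown:
    """Per-neuron decomposition of one trial's reward."""

    R_j: np.ndarray
    distances: np.ndarray
    n_out: np.ndarray
    n_target: int


def trial_reward(
    outputs: list[np.ndarray], target: np.ndarray, q: float
) -> tuple[float, RewardBreakdown]:
    """Normalized trial reward: mean over neurons of ``R_j``.

    An empty output against an empty target counts as perfect reproduction
    of silence (``R_j = 1``); an empty train against a non-empty one gives
    ``R_j = 0`` since the distance saturates its bound.
    """
    n_target = len(target)
    R_j = np.empty(len(outputs))
    D = np.empty(len(outputs))
    n_out = np.empty(len(outputs), dtype=int)
    for j, out in enumerate(outputs):
        n_out[j] = len(out)
        D[j] = vp_distance(out, target, q)
        denom = n_out[j] + n_target
        R_j[j] = 1.0 if denom == 0 else 1.0 - D[j] / denom
    return float(np.mean(R_j)), RewardBreakdown(
        R_j=R_j, distances=D, n_out=n_out, n_target=n_target
    )


def update_running_average(R_bar: float, R: float) -> float:
    """One EMA step of the running-average reward (gain 1/5)."""
    return R_bar + (R - R_bar) / EMA_DIVISOR


def success_signal(R: float, R_bar: float) -> float:
    """Success signal ``S = R - Rbar``; may be negative."""
    return R - R_bar


@dataclass
class RewardState:
    """Per-run reward bookkeeping: last R, running average, and history.

    The running average is initialized to the first trial's reward; the
    no-learning burn-in window lets it settle before updates begin.
    """

    R: float = np.nan
    R_bar: float = np.nan
    history: list[tuple[float, float, float]] = field(default_factory=list)

    def observe(self, R: float) -> float:
        """Record one trial's reward; returns the success signal ``S``.

        ``S`` is computed against the running average before it absorbs the
        new reward.
        """
        if np.isnan(self.R_bar):
            self.R_bar = R
        S = success_signal(R, self.R_bar)
        self.R = R
        self.history.append((R, self.R_bar, S))
        self.R_bar = update_running_average(self.R_bar, R)
        return S
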