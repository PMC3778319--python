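"""Spike pairing, eligibility-trace accumulation, and analog drift.

The eligibility trace is the synapse-local memory that bridges the gap
between spike-timing coincidences and the delayed, end-of-trial reward.  It
is modelled after an analog hardware synapse: two charge accumulators
``a_plus`` and ``a_minus`` collect the potentiating (pre-before-post) and
depressing (post-before-pre) STDP pair contributions

    delta_e_k = eta * |A_pm| * exp(-|dt_k| / tau_pm),

and the readout quantity is their difference ``a = a_plus - a_minus``.

Spike pairs follow the reduced symmetric nearest-neighbor scheme: in the
merged, time-ordered pre/post sequence each post spike pairs with the most
recent pre spike provided no other post spike intervenes, and each pre
spike pairs with the most recent post spike provided no other pre spike
intervenes.  The pair contribution is anchored at ``t_k``, the time of the
later spike of the pair.

Between pair events the accumulators evolve under a drift function

    phi_i(t; a0) = a0 * exp(-lambda_i t)                   for lambda_i > 0
                 = a_max - (a_max - a0) * exp(lambda_i t)  for lambda_i < 0
                 = a0                                      for lambda_i = 0

with per-accumulator inverse time constants ``lambda_i = 1/tau_e_i``.  The
ideal exponentially decaying trace is the special case ``lambda_i = 1/tau_e``
for all accumulators; drawing ``tau_e_i ~ Normal(tau_e, m_e * tau_e)``
models device mismatch, and a negative nominal ``tau_e`` models upward
drift toward the saturation value ``a_max``.  Accumulators are clamped to
``[0, a_max]`` at all times.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from numba import njit

__all__ = [
    "PlasticityParams",
    "Polarity",
    "PairEvent",
    "EligibilityState",
    "pair_spikes",
    "pair_contribution",
    "draw_drift",
    "apply_drift",
    "trace_at_trial_end",
    "trial_traces",
]


@dataclass
class PlasticityParams:
    """STDP window, learning rate, and accumulator/drift constants.

    ``A_plus``/``A_minus`` (pS) are the pair amplitudes at coincidence;
    with ``A_plus * tau_plus = -A_minus * tau_minus`` the STDP window is
    balanced, which is the default (identical magnitudes and time
    constants).  ``eta`` is a dimensionless learning-rate scale multiplying
    every pair contribution.  ``tau_e`` (s) is the nominal eligibility time
    constant; a negative value means upward drift.  ``m_e`` is the relative
    mismatch of per-accumulator time constants, and ``a_max`` (pS) the
    accumulator saturation.
    """

    A_plus: float = 32.0     # pS
    A_minus: float = -32.0   # pS
    tau_plus: float = 20.0   # ms
    tau_minus: float = 20.0  # ms
    eta: float = 5.0
    tau_e: float = 0.5       # s (signed; negative = upward drift)
    m_e: float = 0.0
    a_max: float = 1000.0    # pS

    def __post_init__(self) -> None:
        if self.tau_plus <= 0 or self.tau_minus <= 0:
            raise ValueError("STDP time constants must be positive")
        if self.a_max <= 0:
            raise ValueError("a_max must be positive")
        if self.m_e < 0:
            raise ValueError("m_e must be non-negative")
        if self.tau_e == 0:
            raise ValueError("tau_e must be non-zero")


class Polarity(Enum):
    PRE_POST = "pre-post"
    POST_PRE = "post-pre"


@dataclass
class PairEvent:
    """One STDP pair: polarity, absolute time difference, anchor time.

    ``t_k`` is the time (s) of the later spike of the pair: the post spike
    for pre-before-post pairings, the pre spike otherwise.  ``delta_t`` is
    ``|t_post - t_pre|`` in ms.
    """

    polarity: Polarity
    delta_t: float  # ms
    t_k: float      # s
    synapse_index: int = 0


@dataclass
class EligibilityState:
    """Per-synapse accumulators and their drift constants.

    ``lambda_plus`` / ``lambda_minus`` hold the per-accumulator inverse time
    constants (1/s); ``last_update_time`` tracks when each accumulator pair
    was last advanced.
    """

    a_plus: np.ndarray
    a_minus: np.ndarray
    lambda_plus: np.ndarray
    lambda_minus: np.ndarray
    last_update_time: np.ndarray

    @classmethod
    def zeros(cls, n: int, lambda_plus, lambda_minus) -> "EligibilityState":
        return cls(
            a_plus=np.zeros(n),
            a_minus=np.zeros(n),
            lambda_plus=np.broadcast_to(np.asarray(lambda_plus, float), (n,)).copy(),
            lambda_minus=np.broadcast_to(np.asarray(lambda_minus, float), (n,)).copy(),
            last_update_time=np.zeros(n),
        )

    @property
    def a(self) -> np.ndarray:
        return self.a_plus - self.a_minus


def pair_spikes(pre: np.ndarray, post: np.ndarray) -> list[PairEvent]:
    """Reduced symmetric nearest-neighbor pairing of two sorted trains.

    Simultaneous pre/post spikes are processed pre-before-post, yielding a
    pre-post pair with ``delta_t = 0``.  Times are in seconds; ``delta_t``
    of the returned events is in ms.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if np.any(np.diff(pre) < 0) or np.any(np.diff(post) < 0):
        raise ValueError("spike trains must be sorted")

    events: list[PairEvent] = []
    i = j = 0
    last_pre = last_post = None
    post_since_last_pre = True
    pre_since_last_post = True
    while i < len(pre) or j < len(post):
        # stable merge, pre first on ties
        take_pre = j >= len(post) or (i < len(pre) and pre[i] <= post[j])
        if take_pre:
            t = pre[i]
            if last_post is not None and not pre_since_last_post:
                events.append(
                    PairEvent(
                        polarity=Polarity.POST_PRE,
                        delta_t=(t - last_post) * 1000.0,
                        t_k=t,
                    )
                )
            last_pre = t
            post_since_last_pre = False
            pre_since_last_post = True
            i += 1
        else:
            t = post[j]
            if last_pre is not None and not post_since_last_pre:
                events.append(
                    PairEvent(
                        polarity=Polarity.PRE_POST,
                        delta_t=(t - last_pre) * 1000.0,
                        t_k=t,
                    )
                )
            last_post = t
            post_since_last_pre = True
            pre_since_last_post = False
            j += 1
    events.sort(key=lambda e: e.t_k)
    return events


def pair_contribution(ev: PairEvent, p: PlasticityParams) -> float:
    """Magnitude (pS) a pair adds to its accumulator.

    Pre-post pairs feed ``a_plus`` with ``eta*|A_plus|*exp(-dt/tau_plus)``;
    post-pre pairs feed ``a_minus`` with ``eta*|A_minus|*exp(-dt/tau_minus)``,
    so the difference ``a = a_plus - a_minus`` carries the signs of the
    STDP window.
    """
    if ev.polarity is Polarity.PRE_POST:
        return p.eta * abs(p.A_plus) * np.exp(-ev.delta_t / p.tau_plus)
    return p.eta * abs(p.A_minus) * np.exp(-ev.delta_t / p.tau_minus)


def draw_drift(
    p: PlasticityParams, n_accumulators: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw per-accumulator inverse time constants ``lambda_i = 1/tau_e_i``.

    ``tau_e_i ~ Normal(tau_e, m_e * |tau_e|)`` independently per
    accumulator; an exactly zero draw is redrawn.  ``m_e = 0`` returns the
    uniform value ``1/tau_e``.
    """
    if p.m_e == 0:
        return np.full(n_accumulators, 1.0 / p.tau_e)
    tau = rng.normal(p.tau_e, p.m_e * abs(p.tau_e), size=n_accumulators)
    while np.any(tau == 0.0):
        idx = tau == 0.0
        tau[idx] = rng.normal(p.tau_e, p.m_e * abs(p.tau_e), size=int(idx.sum()))
    return 1.0 / tau


def apply_drift(a0, t, lambda_i, a_max):
    """Evolve accumulator values for a duration ``t`` under drift.

    Vectorized over any broadcastable combination of ``a0`` and
    ``lambda_i``; the result is clamped to ``[0, a_max]``.
    """
    a0 = np.asarray(a0, dtype=float)
    lam = np.asarray(lambda_i, dtype=float)
    decay = a0 * np.exp(-np.abs(lam) * t)
    grow = a_max - (a_max - a0) * np.exp(-np.abs(lam) * t)
    out = np.where(lam > 0, decay, np.where(lam < 0, grow, a0))
    return np.clip(out, 0.0, a_max)


def trace_at_trial_end(
    events: list[PairEvent],
    state: EligibilityState,
    p: PlasticityParams,
    t_trial: float,
) -> np.ndarray:
    """Accumulate pair events under drift and return ``a(t_trial)``.

    For each accumulator: drift from its last update time to each event's
    ``t_k``, add the pair contribution, clamp to ``[0, a_max]``, continue;
    finally drift to ``t_trial``.  With uniform positive ``lambda`` and no
    saturation this reduces exactly to the sum of exponentially decayed
    pair contributions.

    ``state`` is updated in place and the per-synapse difference
    ``a(t_trial)`` is returned.
    """
    for ev in sorted(events, key=lambda e: e.t_k):
        s = ev.synapse_index
        dt_el = ev.t_k - state.last_update_time[s]
        state.a_plus[s] = apply_drift(
            state.a_plus[s], dt_el, state.lambda_plus[s], p.a_max
        )
        state.a_minus[s] = apply_drift(
            state.a_minus[s], dt_el, state.lambda_minus[s], p.a_max
        )
        if ev.polarity is Polarity.PRE_POST:
            state.a_plus[s] = min(state.a_plus[s] + pair_contribution(ev, p), p.a_max)
        else:
            state.a_minus[s] = min(state.a_minus[s] + pair_contribution(ev, p), p.a_max)
        state.last_update_time[s] = ev.t_k
    dt_el = t_trial - state.last_update_time
    state.a_plus = apply_drift(state.a_plus, dt_el, state.lambda_plus, p.a_max)
    state.a_minus = apply_drift(state.a_minus, dt_el, state.lambda_minus, p.a_max)
    state.last_update_time[:] = t_trial
    return state.a


@njit(cache=True)
def _phi(a0, t, lam, a_max):
    if lam > 0.0:
        a = a0 * np.exp(-lam * t)
    elif lam < 0.0:
        a = a_max - (a_max - a0) * np.exp(lam * t)
    else:
        a = a0
    if a < 0.0:
        return 0.0
    if a > a_max:
        return a_max
    return a


@njit(cache=True)
def _trial_traces_kernel(
    stim_times,    # (N_U, N_stim) s, rows sorted
    out_times,     # (N_T, max_out) s, padded
    out_counts,    # (N_T,)
    lam_plus,      # (N_U*N_T,)
    lam_minus,     # (N_U*N_T,)
    eta, A_plus_abs, A_minus_abs, tau_plus_ms, tau_minus_ms, a_max,
    t_trial,
    a_out,         # (N_U*N_T,) result a(t_trial)
    abs_parts,     # (2, N_U*N_T) a_plus(t_trial), a_minus(t_trial)
):
    N_U = stim_times.shape[0]
    N_T = out_times.shape[0]
    for i in range(N_U):
        pre = stim_times[i]
        n_pre = pre.shape[0]
        for j in range(N_T):
            syn = i * N_T + j
            n_post = out_counts[j]
            ap = 0.0
            am = 0.0
            lp = lam_plus[syn]
            lm = lam_minus[syn]
            t_last = 0.0
            # merged scan, pre before post on ties
            ii = 0
            jj = 0
            last_pre = -1.0
            last_post = -1.0
            have_pre = False
            have_post = False
            post_since_pre = True
            pre_since_post = True
            while ii < n_pre or jj < n_post:
                take_pre = jj >= n_post or (
                    ii < n_pre and pre[ii] <= out_times[j, jj]
                )
                if take_pre:
                    t = pre[ii]
                    if have_post and not pre_since_post:
                        # post-pre pair anchored at t
                        dt_ms = (t - last_post) * 1000.0
                        ap = _phi(ap, t - t_last, lp, a_max)
                        am = _phi(am, t - t_last, lm, a_max)
                        am += eta * A_minus_abs * np.exp(-dt_ms / tau_minus_ms)
                        if am > a_max:
                            am = a_max
                        t_last = t
                    last_pre = t
                    have_pre = True
                    post_since_pre = False
                    pre_since_post = True
                    ii += 1
                else:
                    t = out_times[j, jj]
                    if have_pre and not post_since_pre:
                        dt_ms = (t - last_pre) * 1000.0
                        ap = _phi(ap, t - t_last, lp, a_max)
                        am = _phi(am, t - t_last, lm, a_max)
                        ap += eta * A_plus_abs * np.exp(-dt_ms / tau_plus_ms)
                        if ap > a_max:
                            ap = a_max
                        t_last = t
                    last_post = t
                    have_post = True
                    post_since_pre = True
                    pre_since_post = False
                    jj += 1
            ap = _phi(ap, t_trial - t_last, lp, a_max)
            am = _phi(am, t_trial - t_last, lm, a_max)
            a_out[syn] = ap - am
            abs_parts[0, syn] = ap
            abs_parts[1, syn] = am


def trial_traces(
    stim_times: np.ndarray,
    outputs: list[np.ndarray],
    lam_plus: np.ndarray,
    lam_minus: np.ndarray,
    p: PlasticityParams,
    t_trial: float,
):
    """End-of-trial eligibility for every plastic synapse of one trial.

    Fast path used by the experiment loop: synapse ``(i, j)`` (flattened as
    ``i * N_T + j``) pairs input train ``i`` with output train ``j``, and
    accumulators start from zero (they are cleared after each trial's weight
    update).  Returns ``(a, a_plus, a_minus)`` at ``t_trial``, each of
    length ``N_U * N_T`` in pS.
    """
    N_T = len(outputs)
    max_out = max((len(o) for o in outputs), default=0)
    out_times = np.zeros((N_T, max_out))
    out_counts = np.zeros(N_T, dtype=np.int64)
    for j, o in enumerate(outputs):
        out_times[j, : len(o)] = o
        out_counts[j] = len(o)
    n_syn = stim_times.shape[0] * N_T
    a = np.empty(n_syn)
    parts = np.empty((2, n_syn))
    _trial_traces_kernel(
        np.ascontiguousarray(stim_times, dtype=np.float64),
        out_times,
        out_counts,
        np.ascontiguousarray(lam_plus, dtype=np.float64),
        np.ascontiguousarray(lam_minus, dtype=np.float64),
        p.eta,
        abs(p.A_plus),
        abs(p.A_minus),
        p.tau_plus,
        p.tau_minus,
        p.a_max,
        t_trial,
        a,
        parts,
    )
    return a, parts[0], parts[1]
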