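"""Weight-update backends modelling the hardware constraint variants.

The ideal (baseline) rule applies the reward-gated eligibility directly,

    w' = clamp(w + S * a(t_trial)),

with ``S`` dimensionless and ``a`` in pS (1 pS = 1e-3 nS).  The variants
model successive hardware constraints:

* **Discretized weights** — weights live on a uniform grid with step
  ``delta_r = (w_max - w_min) / (2**r - 1)`` for ``r`` bits.  Deterministic
  mode computes the exact update in floating point and rounds the result to
  the nearest grid value (ties to even), so any ``|Delta| < delta_r / 2``
  is silently discarded.  Probabilistic mode instead projects the exact
  update onto the two neighboring grid steps with probabilities chosen to
  make the mean discrete update equal the exact one (stochastic rounding).
* **Noise baseline** — continuous weights with additive noise drawn from
  the triangular density on ``(-delta_r, delta_r)``, the exact distribution
  of the stochastic-rounding error for uniformly distributed updates; this
  isolates the effect of rounding noise from that of the grid itself.
* **Thresholded readout** — the accumulators are not directly readable;
  a comparator produces one-bit outcomes ``b_pm = [+-(a_plus - a_minus) > Theta]``
  and the update becomes ``Delta = S * A * (b_plus - b_minus)``.  ``Theta``
  and ``A`` are calibrated from a no-learning precursor window:
  ``Theta* = <|a|>`` and ``A* = (N / N_p) * Theta*`` with ``N_p`` the number
  of readouts exceeding ``Theta*``, so the mean applied magnitude matches
  the mean eligibility magnitude of the ideal rule.
* **Delayed, noisy readout** — the reward arrives a delay ``D_R`` after
  trial end, during which the accumulators keep drifting; the readout is
  additionally corrupted by Gaussian noise of s.d. ``sigma_a`` and compared
  against the delay-corrected threshold ``beta * Theta`` with
  ``beta = exp(-D_R / tau_e)``.  The closed-form maximal tolerable delay
  for a required signal-to-noise ratio ``z*`` is
  ``D_max = -tau_e * ln(z* * sigma_a / a_max)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .eligibility import PlasticityParams, apply_drift

__all__ = [
    "PS_TO_NS",
    "ReadoutMode",
    "WriteMode",
    "UpdaterConfig",
    "CalibrationStats",
    "WeightState",
    "grid_step",
    "baseline_update",
    "discretize_deterministic",
    "discretize_probabilistic",
    "sample_rounding_noise",
    "evaluate_bit",
    "threshold_readout",
    "threshold_update",
    "calibrate",
    "delayed_readout",
    "max_tolerable_delay",
    "apply_update",
]

#: accumulators are bookkept in pS, weights in nS
PS_TO_NS = 1e-3


class ReadoutMode:
    DIRECT = "direct"          # Delta = S * a
    THRESHOLD = "threshold"    # Delta = S * A * (b+ - b-)


class WriteMode:
    CONTINUOUS = "continuous"
    DETERMINISTIC = "deterministic"    # round-to-nearest grid, ties to even
    PROBABILISTIC = "probabilistic"    # stochastic rounding onto the grid
    NOISE = "noise"                    # continuous + triangular noise


@dataclass
class UpdaterConfig:
    """Selects and parameterizes one weight-update backend.

    ``r`` (bits) parameterizes the weight grid for the discrete and noise
    modes.  ``Theta`` (pS) and ``A`` (nS) are the readout threshold and
    update constant; leave unset to have them calibrated from the burn-in
    window.  ``D_R`` (s, emulated time) and ``sigma_a`` (pS) activate the
    delayed noisy readout; ``z_star`` and ``alpha`` only enter the
    closed-form delay bound.
    """

    readout: str = ReadoutMode.DIRECT
    write: str = WriteMode.CONTINUOUS
    r: int = 0
    Theta: float | None = None   # pS
    A: float | None = None       # nS
    D_R: float = 0.0             # s, emulated
    sigma_a: float = 0.0         # pS
    z_star: float = 1.0
    alpha: float = 1.0e5

    def __post_init__(self) -> None:
        if self.write != WriteMode.CONTINUOUS and self.r < 1:
            raise ValueError("grid-based write modes require r >= 1")
        if self.D_R < 0 or self.sigma_a < 0:
            raise ValueError("D_R and sigma_a must be non-negative")

    @property
    def needs_calibration(self) -> bool:
        return self.readout == ReadoutMode.THRESHOLD and (
            self.Theta is None or self.A is None
        )


@dataclass
class CalibrationStats:
    """Outcome of the precursor calibration of the thresholded readout."""

    Theta_star: float  # pS
    A_star: float      # nS
    mean_abs_a: float  # pS
    N: int
    N_p: int


@dataclass
class WeightState:
    """Plastic weight vector with its resolution metadata.

    ``w`` is in nS, flattened over synapses; in discrete modes every entry
    lies exactly on the ``delta_r`` grid.
    """

    w: np.ndarray
    w_min: float
    w_max: float
    r: int = 0

    @property
    def delta_r(self) -> float | None:
        return None if self.r == 0 else grid_step(self.w_min, self.w_max, self.r)


def grid_step(w_min: float, w_max: float, r: int) -> float:
    """Weight grid step ``delta_r = (w_max - w_min) / (2**r - 1)``."""
    if r < 1:
        raise ValueError("r must be >= 1")
    return (w_max - w_min) / (2**r - 1)


def baseline_update(S: float, a, w, w_min: float, w_max: float):
    """Ideal update ``w' = clamp(w + S * a)`` with ``a`` in pS, ``w`` in nS."""
    return np.clip(w + S * np.asarray(a) * PS_TO_NS, w_min, w_max)


def discretize_deterministic(w_exact, w_min: float, w_max: float, r: int):
    """Round exact weights to the nearest grid value, ties to even index."""
    d = grid_step(w_min, w_max, r)
    idx = np.round((np.asarray(w_exact, dtype=float) - w_min) / d)  # half-to-even
    idx = np.clip(idx, 0, 2**r - 1)
    return w_min + idx * d


def discretize_probabilistic(
    delta, w, w_min: float, w_max: float, r: int, rng: np.random.Generator
):
    """Stochastically round the exact update ``delta`` onto the grid.

    With ``(k-1)*delta_r <= delta <= k*delta_r`` the applied step is
    ``k*delta_r`` with probability ``(delta - (k-1)*delta_r) / delta_r`` and
    ``(k-1)*delta_r`` otherwise, making the mean step equal ``delta``;
    negative updates are handled symmetrically.  ``w`` must lie on the grid;
    the result is clamped to the bounds (which are grid points).
    """
    d = grid_step(w_min, w_max, r)
    x = np.asarray(delta, dtype=float) / d
    lo = np.floor(x)
    p = x - lo
    shape = np.broadcast_shapes(np.shape(x), np.shape(w))
    step = (lo + (rng.random(size=shape) < p)) * d
    return np.clip(w + step, w_min, w_max)


def sample_rounding_noise(delta_r: float, rng: np.random.Generator, size=None):
    """Draw from the triangular density on ``(-delta_r, delta_r)`` peaked at 0.

    This is the distribution of the stochastic-rounding error
    ``z = Delta_d - Delta`` for updates uniformly distributed within a grid
    cell: mean 0, variance ``delta_r**2 / 6``.
    """
    if delta_r <= 0:
        raise ValueError("delta_r must be positive")
    return rng.triangular(-delta_r, 0.0, delta_r, size=size)


def evaluate_bit(a_plus, a_minus, bits, a_tl: float, a_th: float):
    """General comparator of the analog evaluation unit.

    ``bits = (e_cc, e_ca, e_ac, e_aa)`` route the accumulators onto the two
    comparator sides::

        b = [ (a_tl + e_ac*a+ + e_ca*a-) / (1 + e_ac + e_ca)
              > (a_th + e_cc*a+ + e_aa*a-) / (1 + e_cc + e_aa) ]

    The configuration ``(0, 0, 1, 1)`` reduces to
    ``a+ - a- > a_th - a_tl`` and ``(1, 1, 0, 0)`` to its mirror image.
    """
    e_cc, e_ca, e_ac, e_aa = bits
    lhs = (a_tl + e_ac * np.asarray(a_plus) + e_ca * np.asarray(a_minus)) / (
        1 + e_ac + e_ca
    )
    rhs = (a_th + e_cc * np.asarray(a_plus) + e_aa * np.asarray(a_minus)) / (
        1 + e_cc + e_aa
    )
    return (lhs > rhs).astype(np.int8)


def threshold_readout(a, Theta: float):
    """One-bit readout ``b_pm = [+-a > Theta]`` (strict inequality).

    For ``Theta >= 0`` at most one bit is set per synapse.
    """
    if Theta < 0:
        raise ValueError("Theta must be non-negative")
    a = np.asarray(a)
    return (a > Theta).astype(np.int8), (-a > Theta).astype(np.int8)


def threshold_update(S: float, b_plus, b_minus, A: float, w, w_min, w_max):
    """Thresholded-readout update ``w' = clamp(w + S * A * (b+ - b-))``."""
    return np.clip(
        w + S * A * (np.asarray(b_plus, float) - np.asarray(b_minus, float)),
        w_min,
        w_max,
    )


def calibrate(abs_a_samples: np.ndarray) -> CalibrationStats:
    """Fix ``Theta*`` and ``A*`` from precursor readout magnitudes ``|a|``.

    ``Theta* = <|a|>`` over all readouts of the no-learning precursor
    window; ``A* = (N / N_p) * Theta*`` with ``N_p`` the number of readouts
    strictly exceeding ``Theta*``.  Then the mean applied update magnitude
    ``N_p * A* / N`` equals the mean eligibility magnitude of the ideal
    rule.  Raises if no readout exceeds the threshold (degenerate
    calibration, e.g. all-zero traces).
    """
    s = np.asarray(abs_a_samples, dtype=float).ravel()
    if s.size == 0:
        raise ValueError("calibration requires a non-empty precursor sample")
    theta = float(np.mean(s))
    N = s.size
    N_p = int(np.sum(s > theta))
    if N_p == 0:
        raise ValueError("degenerate calibration: no readout exceeds Theta*")
    A_star = (N / N_p) * theta * PS_TO_NS
    return CalibrationStats(
        Theta_star=theta, A_star=A_star, mean_abs_a=theta, N=N, N_p=N_p
    )


def delayed_readout(
    a_plus,
    a_minus,
    lam_plus,
    lam_minus,
    cfg: UpdaterConfig,
    p: PlasticityParams,
    rng: np.random.Generator,
):
    """Thresholded readout a delay ``D_R`` after trial end, with noise.

    The accumulators continue to drift for ``D_R`` under their own
    per-accumulator time constants, Gaussian noise of s.d. ``sigma_a`` is
    added to the difference, and the bits are computed against the
    delay-corrected threshold ``beta * Theta``, ``beta = exp(-D_R / tau_e)``
    (nominal ``tau_e``; the delay is assumed known).  With ``D_R = 0`` and
    ``sigma_a = 0`` this is exactly the undelayed readout.
    """
    if cfg.Theta is None:
        raise ValueError("delayed_readout requires a calibrated Theta")
    ap = apply_drift(a_plus, cfg.D_R, lam_plus, p.a_max)
    am = apply_drift(a_minus, cfg.D_R, lam_minus, p.a_max)
    a = np.asarray(ap) - np.asarray(am)
    if cfg.sigma_a > 0:
        a = a + rng.normal(0.0, cfg.sigma_a, size=np.shape(a))
    beta = np.exp(-cfg.D_R / p.tau_e) if p.tau_e > 0 else 1.0
    return threshold_readout(a, beta * cfg.Theta)


def max_tolerable_delay(
    tau_e: float, z_star: float, sigma_a: float, a_max: float
) -> float:
    """Closed-form delay bound ``D_max = -tau_e * ln(z* sigma_a / a_max)``.

    Emulated-time seconds; divide by the acceleration factor ``alpha`` for
    wall-clock time.  Requires ``0 < z* * sigma_a <= a_max`` (otherwise no
    positive delay can satisfy the signal-to-noise requirement).
    """
    x = z_star * sigma_a
    if x <= 0:
        raise ValueError("z_star * sigma_a must be positive")
    if x > a_max:
        raise ValueError("z_star * sigma_a exceeds a_max: no tolerable delay")
    return -tau_e * np.log(x / a_max)


def apply_update(
    S: float,
    a: np.ndarray,
    a_plus: np.ndarray,
    a_minus: np.ndarray,
    lam_plus: np.ndarray,
    lam_minus: np.ndarray,
    weights: np.ndarray,
    cfg: UpdaterConfig,
    p: PlasticityParams,
    net,
    rng_write: np.random.Generator,
    rng_readout: np.random.Generator | None = None,
) -> np.ndarray:
    """One full per-trial weight update in the configured mode.

    Composition order: readout (direct eligibility or threshold bits, with
    optional delay and noise) -> raw update ``Delta`` -> write transform
    (rounding / stochastic rounding / additive noise) -> clamp.
    ``rng_write`` drives stochastic rounding / rounding noise,
    ``rng_readout`` the readout noise of the delayed variant; keeping them
    separate lets either component be replayed in isolation.
    """
    w_min, w_max = net.w_min, net.w_max
    if cfg.readout == ReadoutMode.THRESHOLD:
        if cfg.D_R > 0 or cfg.sigma_a > 0:
            b_plus, b_minus = delayed_readout(
                a_plus, a_minus, lam_plus, lam_minus, cfg, p,
                rng_readout if rng_readout is not None else rng_write,
            )
        else:
            b_plus, b_minus = threshold_readout(a, cfg.Theta)
        delta = S * cfg.A * (b_plus.astype(float) - b_minus.astype(float))
    else:
        delta = S * np.asarray(a) * PS_TO_NS

    if cfg.write == WriteMode.CONTINUOUS:
        return np.clip(weights + delta, w_min, w_max)
    if cfg.write == WriteMode.DETERMINISTIC:
        return discretize_deterministic(weights + delta, w_min, w_max, cfg.r)
    if cfg.write == WriteMode.PROBABILISTIC:
        return discretize_probabilistic(delta, weights, w_min, w_max, cfg.r, rng_write)
    if cfg.write == WriteMode.NOISE:
        z = sample_rounding_noise(
            grid_step(w_min, w_max, cfg.r), rng_write, size=weights.shape
        )
        return np.clip(weights + delta + z, w_min, w_max)
    raise ValueError(f"unknown write mode {cfg.write!r}")
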