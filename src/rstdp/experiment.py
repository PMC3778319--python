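"""Trial/run/sweep orchestration and reported metrics.

A *run* presents the fixed stimulus for ``n_trials`` trials.  The first
``burn_in`` trials are simulated without learning so the running-average
reward can settle (their mean reward is ``R_before``); if the thresholded
readout is active, the same window doubles as the calibration precursor for
``Theta*`` and ``A*``.  The mean reward over the final ``tail`` trials is
``R_after``.  A *batch* is several runs with independent seeds but the same
stimulus; sweeps scan drift (``tau_e`` x ``m_e``) and delay
(``D_R`` x ``sigma_a``) grids.

Seeding: one master seed per experiment.  The stimulus stream is derived
from the master seed (identical across runs); each run then derives
independent substreams for the target's background, the per-trial
background, drift constants, stochastic rounding, and readout noise, so any
component can be replayed in isolation and results are bitwise reproducible
from the seed record regardless of execution order.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sp_stats

from . import weight_updaters as wu
from .eligibility import PlasticityParams, draw_drift, trial_traces
from .lif_network import NeuronParams, simulate_trial
from .reward_env import RewardState, trial_reward
from .synthetic_inputs import (
    NetworkParams,
    StimulusSet,
    background_by_neuron,
    generate_stimulus,
    generate_target,
    random_reference_weights,
    reference_weights,
)
from .weight_updaters import CalibrationStats, ReadoutMode, UpdaterConfig

__all__ = [
    "ExperimentConfig",
    "RunResult",
    "BatchResult",
    "SweepResult",
    "run_single",
    "run_batch",
    "sweep_drift",
    "sweep_delay",
    "rms_weight_error",
    "ks_statistic",
    "success_variability",
    "DESK",
    "FULL",
]


@dataclass
class ExperimentConfig:
    """Trial counts, windows, mode flags and the VP cost parameter.

    ``q_inv`` is the shift-cost parameter of the spike metric expressed as
    a duration (s); ``q = 1 / q_inv``.
    """

    n_trials: int = 10_000
    n_runs: int = 20
    burn_in: int = 100
    tail: int = 1000
    q_inv: float = 0.020  # s
    randomize_reference_weights: bool = False
    randomize_stimulus: bool = False

    def __post_init__(self) -> None:
        if self.burn_in + self.tail > self.n_trials:
            raise ValueError("burn_in + tail must not exceed n_trials")
        if self.q_inv <= 0:
            raise ValueError("q_inv must be positive")

    @property
    def q(self) -> float:
        return 1.0 / self.q_inv


#: full-scale preset (20 runs x 10000 trials)
FULL = ExperimentConfig()
#: desk-scale preset: most of the reward improvement happens within the
#: first ~2000 trials, so 4000 trials with a 500-trial tail suffice for a
#: stable estimate at a fraction of the cost
DESK = ExperimentConfig(n_trials=4000, n_runs=5, tail=500)


@dataclass
class RunResult:
    """Everything measured in one run."""

    R: np.ndarray
    R_bar: np.ndarray
    S: np.ndarray
    R_before: float
    R_after: float
    final_weights: np.ndarray      # (N_U, N_T) nS
    initial_weights: np.ndarray
    target: np.ndarray
    calibration: CalibrationStats | None
    seed: object


@dataclass
class BatchResult:
    runs: list[RunResult]
    R_after_mean: float
    R_after_sd: float
    R_before_mean: float
    mean_Rbar_trace: np.ndarray

    @property
    def R_after_values(self) -> np.ndarray:
        return np.array([r.R_after for r in self.runs])

    @property
    def pooled_weights(self) -> np.ndarray:
        return np.concatenate([r.final_weights.ravel() for r in self.runs])

    @property
    def R_after_sem(self) -> float:
        return self.R_after_sd / np.sqrt(len(self.runs))


@dataclass
class SweepResult:
    """Grid of batch summaries from a parameter sweep."""

    rows: np.ndarray           # row parameter values
    cols: np.ndarray           # column parameter values
    row_name: str
    col_name: str
    mean: np.ndarray           # (n_rows, n_cols) mean R_after or improvement
    sd: np.ndarray
    extra: dict = field(default_factory=dict)


def _as_seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def run_single(
    net: NetworkParams,
    nparams: NeuronParams,
    plast: PlasticityParams,
    updater: UpdaterConfig,
    cfg: ExperimentConfig,
    seed,
    stim: StimulusSet | None = None,
    ref: np.ndarray | None = None,
    collect_abs_a: bool = False,
) -> RunResult:
    """Execute one run and return its result.

    ``stim``/``ref`` are normally supplied by :func:`run_batch` so that all
    runs of an experiment share them; called standalone, they are derived
    from the run's own seed.  ``collect_abs_a`` retains the burn-in
    eligibility magnitudes even when no calibration is needed.
    """
    ss = _as_seedseq(seed)
    (s_stim, s_run) = ss.spawn(2)
    s_target, s_bg, s_drift, s_round, s_readout, s_ref = s_run.spawn(6)

    if stim is None:
        stim = generate_stimulus(net, np.random.default_rng(s_stim))
    if ref is None:
        if cfg.randomize_reference_weights:
            ref = random_reference_weights(net, np.random.default_rng(s_ref))
        else:
            ref = reference_weights(net)

    n_syn = net.N_U * net.N_T
    rng_drift = np.random.default_rng(s_drift)
    lam_plus = draw_drift(plast, n_syn, rng_drift)
    lam_minus = draw_drift(plast, n_syn, rng_drift)

    target = generate_target(ref, stim, net, nparams, np.random.default_rng(s_target))

    rng_bg = np.random.default_rng(s_bg)
    rng_round = np.random.default_rng(s_round)
    rng_readout = np.random.default_rng(s_readout)

    updater = dataclasses.replace(updater)
    if updater.needs_calibration and cfg.burn_in < 1:
        raise ValueError(
            "thresholded readout without explicit Theta/A requires a burn-in "
            "window to calibrate from"
        )
    need_elig_in_burnin = updater.needs_calibration or collect_abs_a
    calibration: CalibrationStats | None = None
    abs_a: list[np.ndarray] = []

    weights = np.full((net.N_U, net.N_T), net.w_S)
    w_flat = weights.ravel().copy()
    if updater.write in (wu.WriteMode.DETERMINISTIC, wu.WriteMode.PROBABILISTIC):
        w_flat = wu.discretize_deterministic(w_flat, net.w_min, net.w_max, updater.r)

    reward = RewardState()
    S_log = np.empty(cfg.n_trials)
    q = cfg.q

    for trial in range(cfg.n_trials):
        bg = background_by_neuron(net, rng_bg)
        rec = simulate_trial(
            w_flat.reshape(net.N_U, net.N_T), stim, bg, nparams, net
        )
        R, _ = trial_reward(rec.outputs, target, q)
        S = reward.observe(R)
        S_log[trial] = S

        if trial < cfg.burn_in:
            if need_elig_in_burnin:
                a, _, _ = trial_traces(
                    stim.times, rec.outputs, lam_plus, lam_minus, plast, net.t_trial
                )
                abs_a.append(np.abs(a))
            if trial == cfg.burn_in - 1 and updater.needs_calibration:
                calibration = wu.calibrate(np.concatenate(abs_a))
                if updater.Theta is None:
                    updater.Theta = calibration.Theta_star
                if updater.A is None:
                    updater.A = calibration.A_star
            continue

        a, ap, am = trial_traces(
            stim.times, rec.outputs, lam_plus, lam_minus, plast, net.t_trial
        )
        w_flat = wu.apply_update(
            S, a, ap, am, lam_plus, lam_minus, w_flat, updater, plast, net,
            rng_write=rng_round, rng_readout=rng_readout,
        )
        # accumulators are cleared after the update (read-and-clear
        # semantics); trial_traces restarts from zero each trial

    hist = np.asarray(reward.history)
    R_trace, Rbar_trace = hist[:, 0], hist[:, 1]
    return RunResult(
        R=R_trace,
        R_bar=Rbar_trace,
        S=S_log,
        R_before=float(np.mean(R_trace[: cfg.burn_in])),
        R_after=float(np.mean(R_trace[-cfg.tail :])),
        final_weights=w_flat.reshape(net.N_U, net.N_T).copy(),
        initial_weights=weights,
        target=target,
        calibration=calibration,
        seed=ss.entropy,
    )


def run_batch(
    net: NetworkParams,
    nparams: NeuronParams,
    plast: PlasticityParams,
    updater: UpdaterConfig,
    cfg: ExperimentConfig,
    seed,
    n_runs: int | None = None,
) -> BatchResult:
    """Independent runs sharing one stimulus; aggregate statistics.

    Runs use seeds spawned from the master seed; with
    ``randomize_stimulus`` each run additionally draws its own stimulus.
    """
    n_runs = cfg.n_runs if n_runs is None else n_runs
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    ss = _as_seedseq(seed)
    s_stim, s_runs = ss.spawn(2)
    stim = generate_stimulus(net, np.random.default_rng(s_stim))
    run_seeds = s_runs.spawn(n_runs)

    runs = []
    for k in range(n_runs):
        stim_k = (
            generate_stimulus(net, np.random.default_rng(run_seeds[k].spawn(1)[0]))
            if cfg.randomize_stimulus
            else stim
        )
        runs.append(
            run_single(
                net, nparams, plast, updater, cfg, run_seeds[k], stim=stim_k
            )
        )
    R_after = np.array([r.R_after for r in runs])
    mean_trace = np.mean([r.R_bar for r in runs], axis=0)
    return BatchResult(
        runs=runs,
        R_after_mean=float(np.mean(R_after)),
        R_after_sd=float(np.std(R_after, ddof=1)) if n_runs > 1 else 0.0,
        R_before_mean=float(np.mean([r.R_before for r in runs])),
        mean_Rbar_trace=mean_trace,
    )


def sweep_drift(
    net: NetworkParams,
    nparams: NeuronParams,
    plast: PlasticityParams,
    cfg: ExperimentConfig,
    seed,
    tau_e_grid,
    m_e_grid,
    baseline_mean: float | None = None,
    baseline_sd: float | None = None,
    n_runs: int | None = None,
) -> SweepResult:
    """Drift sweep: thresholded readout, continuous weights.

    Cells report mean ``R_after``; if baseline statistics are supplied,
    ``extra['relative']`` holds ``(R_after - baseline) / baseline_sd``.
    """
    ss = _as_seedseq(seed)
    tau_e_grid = np.asarray(tau_e_grid, dtype=float)
    m_e_grid = np.asarray(m_e_grid, dtype=float)
    mean = np.empty((len(m_e_grid), len(tau_e_grid)))
    sd = np.empty_like(mean)
    cell_seeds = ss.spawn(mean.size)
    updater = UpdaterConfig(readout=ReadoutMode.THRESHOLD)
    for a, m_e in enumerate(m_e_grid):
        for b, tau_e in enumerate(tau_e_grid):
            p = dataclasses.replace(plast, tau_e=float(tau_e), m_e=float(m_e))
            batch = run_batch(
                net, nparams, p, updater, cfg,
                cell_seeds[a * len(tau_e_grid) + b], n_runs=n_runs,
            )
            mean[a, b] = batch.R_after_mean
            sd[a, b] = batch.R_after_sd
    extra = {}
    if baseline_mean is not None and baseline_sd:
        extra["relative"] = (mean - baseline_mean) / baseline_sd
    return SweepResult(
        rows=m_e_grid, cols=tau_e_grid, row_name="m_e", col_name="tau_e",
        mean=mean, sd=sd, extra=extra,
    )


def sweep_delay(
    net: NetworkParams,
    nparams: NeuronParams,
    plast: PlasticityParams,
    cfg: ExperimentConfig,
    seed,
    D_R_grid,
    sigma_a_grid,
    n_runs: int = 15,
    z_star: float = 1.0,
) -> SweepResult:
    """Delay sweep: improvement ``R_after - R_before`` per cell.

    Thresholded readout, continuous weights, no mismatch; the predicted
    maximal tolerable delay per noise level is attached as
    ``extra['D_max']``.
    """
    ss = _as_seedseq(seed)
    D_R_grid = np.asarray(D_R_grid, dtype=float)
    sigma_a_grid = np.asarray(sigma_a_grid, dtype=float)
    mean = np.empty((len(sigma_a_grid), len(D_R_grid)))
    sd = np.empty_like(mean)
    cell_seeds = ss.spawn(mean.size)
    for a, sigma_a in enumerate(sigma_a_grid):
        for b, D_R in enumerate(D_R_grid):
            updater = UpdaterConfig(
                readout=ReadoutMode.THRESHOLD,
                D_R=float(D_R),
                sigma_a=float(sigma_a),
                z_star=z_star,
            )
            batch = run_batch(
                net, nparams, plast, updater, cfg,
                cell_seeds[a * len(D_R_grid) + b], n_runs=n_runs,
            )
            improvements = [r.R_after - r.R_before for r in batch.runs]
            mean[a, b] = float(np.mean(improvements))
            sd[a, b] = (
                float(np.std(improvements, ddof=1)) if len(improvements) > 1 else 0.0
            )
    D_max = np.array(
        [
            wu.max_tolerable_delay(plast.tau_e, z_star, s, plast.a_max)
            if s > 0
            else np.inf
            for s in sigma_a_grid
        ]
    )
    return SweepResult(
        rows=sigma_a_grid, cols=D_R_grid, row_name="sigma_a", col_name="D_R",
        mean=mean, sd=sd, extra={"D_max": D_max},
    )


def rms_weight_error(w: np.ndarray, baseline_mean: np.ndarray) -> float:
    """RMS deviation of a weight vector from the mean baseline weights (nS)."""
    w = np.asarray(w, dtype=float).ravel()
    b = np.asarray(baseline_mean, dtype=float).ravel()
    if w.shape != b.shape:
        raise ValueError("weight vectors must have matching length")
    return float(np.sqrt(np.mean((w - b) ** 2)))


def ks_statistic(sample_a, sample_b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov statistic and asymptotic p-value.

    When comparing a discrete-weight result against the continuous
    baseline, round the baseline to the weight grid first (callers do this
    with :func:`weight_updaters.discretize_deterministic`).
    """
    sample_a = np.asarray(sample_a).ravel()
    sample_b = np.asarray(sample_b).ravel()
    if sample_a.size == 0 or sample_b.size == 0:
        raise ValueError("KS test requires non-empty samples")
    res = sp_stats.ks_2samp(sample_a, sample_b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def success_variability(S: np.ndarray, tail: int | None = None) -> float:
    """Sample s.d. of the success signal over the stable tail window."""
    S = np.asarray(S, dtype=float)
    if tail is not None:
        S = S[-tail:]
    return float(np.std(S, ddof=1))
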