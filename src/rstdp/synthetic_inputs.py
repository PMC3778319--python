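"""Generation of all experiment inputs.

The learning task has no external data: the stimulus, the background noise,
the reference weights and the target spike train are all produced here, from
a seeded random stream.

* **Stimulus** — each of the ``N_U`` input units fires ``N_stim`` spikes at
  times drawn uniformly on ``[0, t_trial)``.  The stimulus is drawn once per
  experiment and repeated identically on every trial of every run, so that
  runs are comparable.
* **Background** — ``N_B`` independent homogeneous Poisson sources with rate
  ``nu_B``; a fresh realization is drawn for every trial.  Background
  sources are wired 250-to-1 onto the output neurons with a strong weight,
  so every background spike makes its neuron fire: this is the source of the
  exploratory randomness required by reward-driven learning.
* **Reference weights** — a half-sine profile over the input index,
  ``W_ij = W_hat * sin(i*pi/N_U)`` for ``i <= N_U/2`` and zero above, the
  same for every output neuron.
* **Target spike train** — produced by simulating one trial of the network
  with the reference weights and fresh background noise; the train of output
  neuron 0 serves as the common target for all neurons.

All spike times are in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NetworkParams",
    "StimulusSet",
    "generate_stimulus",
    "generate_background",
    "background_by_neuron",
    "reference_weights",
    "random_reference_weights",
    "generate_target",
    "save_spike_trains",
    "load_spike_trains",
]


@dataclass
class NetworkParams:
    """Network-level sizes, rates and weight bounds.

    Defaults correspond to the study conditions: 250 input units projecting
    all-to-all onto 5 output neurons, each neuron privately stimulated by
    250 background Poisson sources.

    ``N_stim`` (spikes per input unit per trial) is a calibration knob of
    the task: together with the synaptic time constant it sets the
    stimulus-driven firing regime of the output neurons.  The default was
    fixed once by calibrating the continuous-weight simulation to its
    nominal final reward level and is not meant to be tuned per experiment.
    """

    N_U: int = 250          # input units
    N_T: int = 5            # output (target) neurons
    N_B: int = field(default=None)  # background sources; defaults to N_T * 250
    N_stim: int = 3         # stimulus spikes per input unit per trial
    nu_B: float = 0.008     # background rate per source (Hz)
    t_trial: float = 1.0    # trial duration (s)
    w_B: float = 20.0       # background synapse weight (nS)
    w_S: float = 0.21       # initial plastic weight (nS)
    w_min: float = 0.0      # lower weight bound (nS)
    w_max: float = 0.5      # upper weight bound (nS)
    W_hat: float = 0.45     # reference-weight amplitude (nS)

    def __post_init__(self) -> None:
        if self.N_B is None:
            self.N_B = self.N_T * 250
        if self.t_trial <= 0:
            raise ValueError("t_trial must be positive")
        if self.N_stim < 0:
            raise ValueError("N_stim must be non-negative")
        if self.nu_B < 0:
            raise ValueError("nu_B must be non-negative")
        if not (self.w_min < self.w_max):
            raise ValueError("w_min must be below w_max")
        if not (self.w_min <= self.w_S <= self.w_max):
            raise ValueError("w_S must lie within [w_min, w_max]")

    @property
    def sources_per_neuron(self) -> int:
        return self.N_B // self.N_T


@dataclass
class StimulusSet:
    """Fixed per-experiment input spike times, shape ``(N_U, N_stim)``.

    Rows are sorted; every time lies in ``[0, t_trial)``.
    """

    times: np.ndarray

    @property
    def n_inputs(self) -> int:
        return self.times.shape[0]

    @property
    def n_spikes(self) -> int:
        return self.times.shape[1]


def generate_stimulus(params: NetworkParams, rng: np.random.Generator) -> StimulusSet:
    """Draw the fixed stimulus: uniform spike times, sorted per input row."""
    times = rng.uniform(0.0, params.t_trial, size=(params.N_U, params.N_stim))
    times.sort(axis=1, kind="stable")
    return StimulusSet(times=times)


def generate_background(
    params: NetworkParams, rng: np.random.Generator
) -> list[np.ndarray]:
    """Draw one trial's background: ``N_B`` independent Poisson trains.

    Homogeneous Poisson realizations on ``[0, t_trial)``; counts are Poisson
    with mean ``nu_B * t_trial`` and, given the count, times are iid uniform.
    """
    counts = rng.poisson(params.nu_B * params.t_trial, size=params.N_B)
    trains = []
    for c in counts:
        t = rng.uniform(0.0, params.t_trial, size=c)
        t.sort()
        trains.append(t)
    return trains


def background_by_neuron(
    params: NetworkParams, rng: np.random.Generator
) -> list[np.ndarray]:
    """Draw one trial's background, merged per output neuron.

    Sources are wired non-overlapping (250 -> 1): source ``s`` drives neuron
    ``s // 250``.  The merged train per neuron is the superposition of its
    private sources, i.e. Poisson with rate ``250 * nu_B``.  Statistically
    identical to merging :func:`generate_background`, but draws only one
    count per neuron.
    """
    per = params.sources_per_neuron
    merged = []
    for _ in range(params.N_T):
        c = rng.poisson(params.nu_B * params.t_trial * per)
        t = rng.uniform(0.0, params.t_trial, size=c)
        t.sort()
        merged.append(t)
    return merged


def reference_weights(params: NetworkParams) -> np.ndarray:
    """Half-sine reference weight profile, shape ``(N_U, N_T)``.

    ``W_ij = W_hat * sin(i*pi/N_U)`` for ``0 <= i <= N_U/2``, zero for
    ``i > N_U/2``; no dependence on the neuron index ``j``.
    """
    i = np.arange(params.N_U, dtype=float)
    w = params.W_hat * np.sin(i * np.pi / params.N_U)
    w[i > params.N_U / 2] = 0.0
    return np.repeat(w[:, None], params.N_T, axis=1)


def random_reference_weights(
    params: NetworkParams, rng: np.random.Generator
) -> np.ndarray:
    """Per-run randomized reference weights, uniform on ``(w_min, w_max)``."""
    return rng.uniform(params.w_min, params.w_max, size=(params.N_U, params.N_T))


def generate_target(
    ref: np.ndarray,
    stim: StimulusSet,
    params: NetworkParams,
    nparams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulate one trial with the reference weights and return the target.

    The output train of reference neuron 0 is used as the common target for
    all neurons.  Background noise is fresh, so the target differs between
    runs even for identical weights and stimulation.
    """
    from .lif_network import simulate_trial

    bg = background_by_neuron(params, rng)
    rec = simulate_trial(ref, stim, bg, nparams, params)
    return rec.outputs[0]


def save_spike_trains(path, trains: list[np.ndarray]) -> None:
    """Write spike trains as two-column text: source id, time in seconds."""
    with open(path, "w") as fh:
        fh.write("# source_id\ttime_s\n")
        for i, t in enumerate(trains):
            for x in t:
                fh.write(f"{i}\t{x:.9f}\n")


def load_spike_trains(path, n_sources: int | None = None) -> list[np.ndarray]:
    """Read spike trains written by :func:`save_spike_trains`."""
    ids, times = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            a, b = line.split()
            ids.append(int(a))
            times.append(float(b))
    n = (max(ids) + 1 if ids else 0) if n_sources is None else n_sources
    out = [[] for _ in range(n)]
    for i, t in zip(ids, times):
        out[i].append(t)
    return [np.asarray(sorted(t), dtype=float) for t in out]
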