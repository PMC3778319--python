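# Methods

## The model

`rstdp` simulates a two-layer feed-forward spiking network that learns to
reproduce a target spike train by reward-modulated STDP (R-STDP), and
quantifies how the learning rule degrades under the constraints a
mixed-signal neuromorphic implementation would impose.

**Network.** `N_U = 250` input units project all-to-all onto `N_T = 5`
conductance-based leaky integrate-and-fire neurons through plastic synapses
(initial weight `w_S = 0.21 nS`, bounds `[0, 0.5] nS`). Each neuron is
additionally driven by a private, disjoint set of 250 Poisson background
sources (`nu_B = 0.008 Hz` each, i.e. 2 Hz aggregate per neuron) at a strong
fixed weight `w_B = 20 nS`, chosen so that every background spike fires its
neuron. The background is the exploration mechanism: a deterministic neuron
cannot explore alternative output spike patterns on its own.

**Neuron.** Sub-threshold dynamics
`C_m dV/dt = g_L (E_L − V) + g(t)(E_e − V)` with `C_m = 500 pF`,
`g_L = 10 nS`, `E_L = −70 mV`, `E_e = 0 mV`. A single exponential
conductance state per neuron (decay `tau_syn`) accumulates all excitatory
events; threshold `V_th = −50 mV`, reset/clamp `V_reset = −60 mV` for
`tau_ref = 10 ms`.

**Plasticity.** For every reduced-symmetric-nearest-neighbor spike pair the
increment `eta * |A_pm| * exp(−|dt|/tau_pm)` (`A_pm = ±32 pS`,
`tau_pm = 20 ms`, balanced window) is added to the potentiating or
depressing accumulator of the synapse; the eligibility is the difference
`a = a_plus − a_minus`, and the accumulators relax between events with
nominal time constant `tau_e` (drift function, below). At trial end the
reward `R` is the mean over neurons of
`R_j = 1 − D[q](X_out_j, X_target)/(N_out_j + N_target)` with the
Victor–Purpura metric at `1/q = 20 ms`, the success signal is
`S = R − Rbar` with `Rbar` an EMA of gain 1/5, and the ideal weight update
is `Delta = S * a(t_trial)` (clamped to the weight bounds). Accumulators
are cleared after each update (hardware read-and-clear semantics; without
clearing, slow `tau_e` would accumulate across trials without bound,
contradicting the per-trial update form).

**Protocol.** A run presents a fixed stimulus for `n_trials` trials; the
first 100 run without learning (`R_before`; the window doubles as the
calibration precursor for the thresholded readout) and the mean reward over
the final tail is `R_after`. Batches repeat runs with independent
background/target seeds but a shared stimulus.

## Constraint models

* **Discrete weights (`r` bits).** Grid step
  `delta_r = (w_max − w_min)/(2^r − 1)`. Deterministic: round the exact
  result to the nearest grid point (ties to even), so `|Delta| < delta_r/2`
  is lost. Probabilistic: stochastic rounding onto the two adjacent steps,
  unbiased in the mean. Noise control: continuous weights plus additive
  triangular noise on `(−delta_r, delta_r)` — the exact distribution of the
  stochastic-rounding error under a uniform update distribution — to
  separate the effect of rounding noise from that of the grid.
* **Thresholded readout.** One-bit comparison
  `b_pm = [±(a_plus − a_minus) > Theta]`, update
  `Delta = S * A * (b_plus − b_minus)`. `Theta* = <|a|>` over the
  no-learning precursor window and `A* = (N/N_p) Theta*` make the mean
  applied magnitude equal the mean eligibility magnitude of the ideal rule.
* **Analog drift / mismatch.** Between events each accumulator follows
  `phi(t; a0)`: exponential decay for `lambda > 0`, saturating growth
  toward `a_max = 1000 pS` for `lambda < 0`, identity at `lambda = 0`, with
  `1/lambda` drawn per accumulator from `Normal(tau_e, m_e |tau_e|)`.
* **Delayed, noisy reward.** The readout happens `D_R` (emulated seconds)
  after trial end with the accumulators still drifting; Gaussian noise of
  s.d. `sigma_a` corrupts the comparison, which uses the delay-corrected
  threshold `beta Theta`, `beta = exp(−D_R/tau_e)`. Closed-form bound
  `D_max = −tau_e ln(z* sigma_a / a_max)`; wall-clock via the acceleration
  factor `alpha` (default `1e5`).

## Calibrated task parameters

Three task constants are not fixed by the parameter table and were
calibrated once, then frozen:

* `tau_syn = 20 ms`. The firing gate requires a single `w_B = 20 nS` event
  to fire the neuron from rest while a single `w_S = 0.21 nS` event stays
  sub-threshold. Direct integration shows the background gate fails for
  `tau_syn < 15 ms` (peak depolarization −59.96 mV at 5 ms, −49.7 mV at
  15 ms); 20 ms is the smallest round value with a robust margin
  (peak −46.6 mV).
* `N_stim = 3` stimulus spikes per input per trial. This sets the operating
  regime: mean stimulus conductance at the initial weights is
  `~3.2 nS`, just below the ~4 nS needed to reach threshold, so initial
  firing is background-driven and sparse, while potentiated weight profiles
  can produce reliable stimulus-locked spikes. Larger `N_stim` (≥ 6 at this
  `tau_syn`) drives both the initial and the reference network into a
  stimulus-locked tonic regime in which the reward starts high and learning
  has almost no headroom; `N_stim = 1` leaves too little drive to ever fire
  the neurons from the stimulus.
* `eta = 5`. Grid-searched over seeds; smaller rates learn too slowly to
  plateau within 4000–10000 trials, larger rates destabilize the learned
  solution (weight diffusion from reward noise outpaces the correcting
  signal).

`tau_e = 0.5 s` is the nominal eligibility time constant (the value the
drift study singles out as best); the drift sweep varies it over
`±{0.1 … 1000} s`.

## Numerical choices

* Fixed integration step `dt = 0.1 ms`; conductance decay exact;
  voltage step exponential Euler (exact for `g` frozen over the step).
  Spike detection on the grid (`V(t−) < V_th ≤ V(t+)`), spike time
  recorded at the grid point after the crossing; for robustly
  supra-threshold events halving `dt` moves spike times by less than `dt`.
  Near-tangential crossings — common in the fluctuation-driven regime — are
  intrinsically step-sensitive and carry no such bound.
* Trials are independent: `V = E_L`, `g = 0` at trial start.
* Simultaneous pre/post spikes are processed pre-before-post (a
  coincidence counts as a causal pair with `dt = 0`).
* Strict inequalities in all comparator readouts; ties produce no bits.
* Accumulators are clamped to `[0, a_max]` during accumulation and drift.
* Drift between events is applied analytically (closed-form `phi`), so
  near-zero or negative time constants cause no stiffness issues; an
  exactly-zero drawn time constant is redrawn.
* Weights in nS, accumulators in pS; the conversion constant `1e-3` is a
  single module-level definition.
* RNG: one `SeedSequence` per experiment; the stimulus stream is spawned at
  the experiment level (identical across runs), each run spawns independent
  substreams for target background, trial background, drift constants,
  stochastic rounding, and readout noise. Results are bitwise reproducible
  from the seed and independent of execution order.

## What the generator emulates — and what it does not

All inputs are synthetic by design (the task defines its own data): frozen
uniform stimulus times, Poisson background, half-sine reference weights
(`W_hat sin(i pi / N_U)` on the lower half of the input index range), and a
target train produced by simulating the reference network itself (output
neuron 0 serves as the common target, regenerated once per run). There is
no trial-to-trial stimulus variability, no input correlations, and no
biological variability beyond the Poisson background; passing tests
demonstrate properties of the learning rule and constraint models under
these idealized conditions, not performance on physiological spike data.

## Problem sizes

The full protocol is 20 runs × 10 000 trials. The package's desk preset
(`rstdp.DESK`, 5 runs × 4000 trials, 500-trial tail) is used by the
acceptance script, and the test suite uses further-reduced batches
(3–4 runs × 2000–3000 trials); most of the attainable reward improvement
occurs within the first ~2000 trials, and the sweeps use coarse grids
(drift: `tau_e ∈ ±{0.5, 1000} s` × `m_e ∈ {0, 1}`; delay: noise levels
`{10, 100, 500} pS` with delays spaced around the predicted `D_max`).

## Known limitations

* With the calibrated task constants the baseline plateaus at
  `R_after ≈ 0.25–0.38` (seed-dependent) rather than the nominal `0.54`
  reference level for this protocol. Three loss mechanisms dominate:
  (i) systematic firing-time jitter of 15–25 ms relative to target times —
  comparable to the `1/q = 20 ms` cost window — caused by the learned
  conductance bump rising over the full 40 ms STDP window rather than
  peaking at the target time; (ii) double-firing bursts on wide bumps;
  (iii) the network's own background spikes, which are unmatchable by
  construction. A stochastic-threshold (escape-noise) neuron would provide
  fine-grained timing exploration that the deterministic LIF with discrete
  background kicks lacks; this is the most plausible source of the gap and
  is out of scope here.
* Per-seed `R_after` variance is large because targets carry few spikes;
  batch means over ≥ 5 runs are the meaningful quantity.
* The learned solution is metastable: single runs show reward dips lasting
  hundreds to thousands of trials, and a run can end in a collapsed state
  (`R_after ≈ 0`). Constraint variants that perturb updates (notably
  deterministic rounding) make collapse more likely at some seeds, which
  adds variant-level variance beyond what the run-to-run s.d. suggests.
* No conduction delays, inhibition, short-term plasticity, or per-synapse
  update scheduling (updates are applied simultaneously at
  `t_trial + D_R`).
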