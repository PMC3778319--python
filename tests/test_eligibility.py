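"""Spike pairing, trace accumulation, drift, and their closed forms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rstdp.eligibility import (
    EligibilityState,
    PairEvent,
    PlasticityParams,
    Polarity,
    apply_drift,
    draw_drift,
    pair_contribution,
    pair_spikes,
    trace_at_trial_end,
    trial_traces,
)

MS = 1e-3


def pairing_oracle(pre, post):
    """Independent rule-based enumeration of reduced symmetric NN pairs.

    A post spike at t pairs with the latest pre spike s <= t iff no post
    spike lies strictly between s and t; symmetrically, a pre spike at t
    pairs with the latest post spike s < t iff no pre spike lies strictly
    between s and t.  Assumes distinct times within each train.
    """
    pairs = []
    for t in post:
        cand = [s for s in pre if s <= t]
        if cand:
            s = max(cand)
            if not any(s < p < t for p in post):
                pairs.append(("pre-post", (t - s) / MS, t))
    for t in pre:
        cand = [s for s in post if s < t]
        if cand:
            s = max(cand)
            if not any(s < p < t for p in pre):
                pairs.append(("post-pre", (t - s) / MS, t))
    return sorted(pairs, key=lambda p: (p[2], p[0]))


def as_tuples(events):
    return sorted(
        ((e.polarity.value, e.delta_t, e.t_k) for e in events),
        key=lambda p: (p[2], p[0]),
    )


class TestPairSpikes:
    def test_single_pre_post_adjacency(self):
        ev = pair_spikes(np.array([0.010]), np.array([0.020]))
        assert len(ev) == 1
        assert ev[0].polarity is Polarity.PRE_POST
        assert ev[0].delta_t == pytest.approx(10.0)
        assert ev[0].t_k == pytest.approx(0.020)

    def test_post_pre_then_pre_post(self):
        ev = pair_spikes(np.array([0.010]), np.array([0.005, 0.020]))
        assert as_tuples(ev) == [
            ("post-pre", pytest.approx(5.0), pytest.approx(0.010)),
            ("pre-post", pytest.approx(10.0), pytest.approx(0.020)),
        ]

    def test_shadowed_pre_spike_yields_single_pair(self):
        # pre at 10 ms is shadowed by the pre at 15 ms
        ev = pair_spikes(np.array([0.010, 0.015]), np.array([0.020]))
        assert len(ev) == 1
        assert ev[0].polarity is Polarity.PRE_POST
        assert ev[0].delta_t == pytest.approx(5.0)

    def test_simultaneous_spikes_processed_pre_first(self):
        ev = pair_spikes(np.array([0.010]), np.array([0.010]))
        assert len(ev) == 1
        assert ev[0].polarity is Polarity.PRE_POST
        assert ev[0].delta_t == 0.0

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError):
            pair_spikes(np.array([0.02, 0.01]), np.array([0.03]))

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_enumeration_oracle_on_random_trains(self, seed):
        rng = np.random.default_rng(seed)
        pre = np.sort(rng.choice(1000, size=rng.integers(0, 8), replace=False)) / 1000
        post = np.sort(rng.choice(999, size=rng.integers(0, 8), replace=False)) / 1000 + 0.0005
        got = as_tuples(pair_spikes(pre, post))
        want = pairing_oracle(pre, post)
        assert len(got) == len(want)
        for g, w in zip(got, want):
            assert g[0] == w[0]
            assert g[1] == pytest.approx(w[1])
            assert g[2] == pytest.approx(w[2])


class TestPairContribution:
    def test_coincidence_gives_full_amplitude(self, plast):
        ev = PairEvent(Polarity.PRE_POST, delta_t=0.0, t_k=0.1)
        assert pair_contribution(ev, plast) == pytest.approx(32.0)

    def test_one_time_constant_decay(self, plast):
        ev = PairEvent(Polarity.PRE_POST, delta_t=20.0, t_k=0.1)
        assert pair_contribution(ev, plast) == pytest.approx(32.0 * np.exp(-1))

    def test_large_separation_vanishes(self, plast):
        ev = PairEvent(Polarity.POST_PRE, delta_t=1e6, t_k=0.1)
        assert pair_contribution(ev, plast) == pytest.approx(0.0, abs=1e-12)

    def test_eta_scales_linearly(self):
        p = PlasticityParams(eta=2.5)
        ev = PairEvent(Polarity.POST_PRE, delta_t=10.0, t_k=0.1)
        assert pair_contribution(ev, p) == pytest.approx(
            2.5 * 32.0 * np.exp(-0.5)
        )


class TestDrift:
    def test_uniform_when_no_mismatch(self, rng):
        p = PlasticityParams(tau_e=0.5, m_e=0.0)
        lam = draw_drift(p, 100, rng)
        assert np.all(lam == 2.0)

    def test_mismatch_statistics(self, rng):
        p = PlasticityParams(tau_e=0.5, m_e=1.0)
        lam = draw_drift(p, 100_000, rng)
        tau = 1.0 / lam
        # sample mean of tau_e_i ~ tau_e
        assert abs(tau.mean() - 0.5) < 3 * tau.std() / np.sqrt(tau.size)
        # fraction of negative time constants ~ Phi(-1)
        from scipy.stats import norm
        frac = (lam < 0).mean()
        p_neg = norm.cdf(-1.0)
        se = np.sqrt(p_neg * (1 - p_neg) / lam.size)
        assert abs(frac - p_neg) < 4 * se

    def test_decay_branch_closed_form(self):
        assert apply_drift(100.0, 0.5, 2.0, 1000.0) == pytest.approx(100 * np.exp(-1))

    def test_zero_lambda_is_identity(self):
        assert apply_drift(123.0, 7.0, 0.0, 1000.0) == 123.0

    def test_negative_lambda_saturates_at_a_max(self):
        assert apply_drift(100.0, 1e9, -2.0, 1000.0) == pytest.approx(1000.0)

    def test_negative_lambda_growth_closed_form(self):
        # a(t) = a_max - (a_max - a0) * exp(lambda * t), lambda = -1
        got = apply_drift(100.0, 0.5, -1.0, 1000.0)
        assert got == pytest.approx(1000.0 - 900.0 * np.exp(-0.5))

    def test_clamped_to_valid_range(self, rng):
        a0 = rng.uniform(0, 1000, size=200)
        lam = rng.normal(0, 5, size=200)
        out = apply_drift(a0, 0.3, lam, 1000.0)
        assert np.all(out >= 0.0) and np.all(out <= 1000.0)


def eq6_direct(events, p, t_trial):
    """Closed-form sum of exponentially decayed pair contributions."""
    e = 0.0
    for ev in events:
        sign = 1.0 if ev.polarity is Polarity.PRE_POST else -1.0
        e += sign * pair_contribution(ev, p) * np.exp(-(t_trial - ev.t_k) / p.tau_e)
    return e


class TestTraceAtTrialEnd:
    def test_single_pair_closed_form(self, plast):
        ev = [PairEvent(Polarity.PRE_POST, delta_t=0.0, t_k=0.5)]
        state = EligibilityState.zeros(1, 2.0, 2.0)
        a = trace_at_trial_end(ev, state, plast, t_trial=1.0)
        assert a[0] == pytest.approx(32.0 * np.exp(-1))

    def test_no_pairs_gives_zero(self, plast):
        state = EligibilityState.zeros(3, 2.0, 2.0)
        assert trace_at_trial_end([], state, plast, 1.0) == pytest.approx([0, 0, 0])

    def test_linearity_below_saturation(self, plast):
        ev1 = [PairEvent(Polarity.PRE_POST, 5.0, 0.2), PairEvent(Polarity.POST_PRE, 3.0, 0.6)]
        ev2 = [PairEvent(Polarity.PRE_POST, 1.0, 0.4)]
        a_union = trace_at_trial_end(
            ev1 + ev2, EligibilityState.zeros(1, 2.0, 2.0), plast, 1.0
        )
        a1 = trace_at_trial_end(ev1, EligibilityState.zeros(1, 2.0, 2.0), plast, 1.0)
        a2 = trace_at_trial_end(ev2, EligibilityState.zeros(1, 2.0, 2.0), plast, 1.0)
        assert a_union[0] == pytest.approx(a1[0] + a2[0])

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=20, deadline=None)
    def test_equals_exponential_sum_without_drift_generalization(self, seed):
        """With uniform positive lambda and no saturation the generalized
        accumulator reduces exactly to the decayed-sum closed form."""
        rng = np.random.default_rng(seed)
        p = PlasticityParams(tau_e=0.5, a_max=1e12)
        n_ev = rng.integers(1, 12)
        events = [
            PairEvent(
                polarity=Polarity.PRE_POST if rng.random() < 0.5 else Polarity.POST_PRE,
                delta_t=float(rng.uniform(0, 60)),
                t_k=float(rng.uniform(0, 1)),
            )
            for _ in range(n_ev)
        ]
        state = EligibilityState.zeros(1, 1 / p.tau_e, 1 / p.tau_e)
        a = trace_at_trial_end(sorted(events, key=lambda e: e.t_k), state, p, 1.0)
        want = eq6_direct(events, p, 1.0)
        assert a[0] == pytest.approx(want, rel=1e-12, abs=1e-12)

    def test_saturation_bounds_respected(self):
        p = PlasticityParams(a_max=50.0)
        events = [PairEvent(Polarity.PRE_POST, 0.0, 0.01 * k) for k in range(1, 60)]
        state = EligibilityState.zeros(1, 2.0, 2.0)
        trace_at_trial_end(events, state, p, 1.0)
        assert 0.0 <= state.a_plus[0] <= 50.0
        assert 0.0 <= state.a_minus[0] <= 50.0

    def test_balanced_window_has_near_zero_mean_trace(self, plast, rng):
        """Symmetric dt ensembles: potentiation and depression cancel."""
        vals = []
        for _ in range(400):
            n = rng.integers(1, 6)
            events = [
                PairEvent(
                    polarity=Polarity.PRE_POST if rng.random() < 0.5 else Polarity.POST_PRE,
                    delta_t=float(rng.exponential(20.0)),
                    t_k=float(rng.uniform(0, 1)),
                )
                for _ in range(n)
            ]
            state = EligibilityState.zeros(1, 2.0, 2.0)
            vals.append(
                trace_at_trial_end(sorted(events, key=lambda e: e.t_k), state, plast, 1.0)[0]
            )
        vals = np.asarray(vals)
        assert abs(vals.mean()) < 3 * vals.std() / np.sqrt(vals.size)


class TestTrialTracesFastPath:
    """The vectorized per-trial kernel must agree with the generic path."""

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_generic_accumulator(self, seed, plast):
        rng = np.random.default_rng(seed)
        n_in, n_out_neurons = 6, 3
        stim = np.sort(rng.uniform(0, 1, size=(n_in, 4)), axis=1)
        outputs = [
            np.sort(rng.uniform(0, 1, size=rng.integers(0, 7)))
            for _ in range(n_out_neurons)
        ]
        lam_p = rng.uniform(0.5, 4.0, size=n_in * n_out_neurons)
        lam_m = rng.uniform(0.5, 4.0, size=n_in * n_out_neurons)
        a_fast, ap_fast, am_fast = trial_traces(stim, outputs, lam_p, lam_m, plast, 1.0)
        for i in range(n_in):
            for j in range(n_out_neurons):
                syn = i * n_out_neurons + j
                events = pair_spikes(stim[i], outputs[j])
                state = EligibilityState.zeros(1, lam_p[syn], lam_m[syn])
                a_ref = trace_at_trial_end(events, state, plast, 1.0)[0]
                assert a_fast[syn] == pytest.approx(a_ref, rel=1e-10, abs=1e-10)
                assert ap_fast[syn] == pytest.approx(state.a_plus[0], rel=1e-10, abs=1e-10)
                assert am_fast[syn] == pytest.approx(state.a_minus[0], rel=1e-10, abs=1e-10)

    def test_accumulators_stay_in_bounds_under_saturation(self, rng):
        p = PlasticityParams(a_max=40.0)
        stim = np.sort(rng.uniform(0, 1, size=(4, 30)), axis=1)
        outputs = [np.sort(rng.uniform(0, 1, size=25))]
        _, ap, am = trial_traces(stim, outputs, np.full(4, 2.0), np.full(4, 2.0), p, 1.0)
        assert np.all(ap <= 40.0) and np.all(ap >= 0.0)
        assert np.all(am <= 40.0) and np.all(am >= 0.0)
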