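"""Spike-train generator: drive shapes (rectification, adaptation, wind-up),
point-process contracts (refractoriness, seed determinism), class structure
and cohort generation."""

import numpy as np
import pytest
from dataclasses import replace

from wdrtherm.protocols import make_iterative, make_single_stim
from wdrtherm.thermal import solve_skin_temperature
from wdrtherm.wdr_model import (
    CohortSpec,
    NegativeDriveError,
    NeuronParams,
    class_params,
    expected_per_stimulus_rates,
    generate_cohort,
    generate_spike_train,
    simulate_recording,
    transduction_drive,
)


class TestParamsInvariants:
    def test_cold_delay_must_not_exceed_heat_delay(self):
        with pytest.raises(ValueError):
            NeuronParams(conduction_delay_cold=0.05, conduction_delay_heat=0.01)

    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError):
            NeuronParams(cold_threshold=35.0)

    def test_refractory_must_be_positive(self):
        with pytest.raises(ValueError):
            NeuronParams(refractory=0.0)

    def test_jittered_params_preserve_orderings(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = class_params("MHC", rng=rng)
            assert p.cold_threshold < 30.0 < p.heat_threshold
            assert p.conduction_delay_cold <= p.conduction_delay_heat


class TestTransductionDrive:
    def test_subthreshold_heat_drive_is_zero(self, mhc_params):
        t = np.arange(0, 2, 1e-3)
        trace = np.full_like(t, 40.0)  # below the 43 °C heat threshold
        drive = transduction_drive(t, trace, mhc_params, "hot")
        np.testing.assert_array_equal(drive, 0.0)

    def test_cold_plateau_drive_adapts_toward_static_floor(self, mhc_params):
        t = np.arange(0, 5, 1e-3)
        trace = np.full_like(t, 10.0)
        trace[:200] = np.linspace(30.0, 10.0, 200)  # cooling transient
        drive = transduction_drive(t, trace, mhc_params, "cold")
        peak = drive.max()
        late = drive[-500:].mean()
        assert late < peak / 3
        assert late > 0  # static floor persists

    def test_hot_plateau_counts_exceed_cold_plateau_counts(self, mhc_params):
        t = np.arange(0, 5, 1e-3)
        hot_trace = np.full_like(t, 50.0)
        cold_trace = np.full_like(t, 2.0)
        cold_trace[:200] = np.linspace(30.0, 2.0, 200)
        hot = transduction_drive(t, hot_trace, mhc_params, "hot")
        cold = transduction_drive(t, cold_trace, mhc_params, "cold")
        assert np.trapezoid(hot, t) > 100.0 > np.trapezoid(cold, t)

    def test_neutral_modality_gives_zero_drive(self, mhc_params):
        t = np.arange(0, 1, 1e-3)
        drive = transduction_drive(t, np.full_like(t, 30.0), mhc_params, "neutral")
        np.testing.assert_array_equal(drive, 0.0)


class TestSpikeGeneration:
    def test_zero_drive_zero_baseline_gives_empty_train(self):
        p = NeuronParams(baseline_rate=0.0)
        t = np.arange(0, 5, 1e-3)
        spikes = generate_spike_train(t, np.zeros_like(t), p, seed=3)
        assert spikes.size == 0

    def test_fixed_seed_reproducibility(self, mhc_params):
        t = np.arange(0, 3, 1e-3)
        drive = 20.0 * np.exp(-((t - 1.0) ** 2) / 0.1)
        a = generate_spike_train(t, drive, mhc_params, seed=11)
        b = generate_spike_train(t, drive, mhc_params, seed=11)
        np.testing.assert_array_equal(a, b)
        c = generate_spike_train(t, drive, mhc_params, seed=12)
        assert a.size != c.size or not np.allclose(a, c)

    def test_refractory_period_respected(self, mhc_params):
        t = np.arange(0, 4, 1e-3)
        drive = np.full_like(t, 140.0)  # near max_rate
        for seed in range(20):
            spikes = generate_spike_train(t, drive, mhc_params, seed=seed)
            assert np.all(np.diff(spikes) >= mhc_params.refractory - 1e-12)

    def test_negative_drive_rejected(self, mhc_params):
        t = np.arange(0, 1, 1e-3)
        with pytest.raises(NegativeDriveError):
            generate_spike_train(t, np.full_like(t, -1.0), mhc_params, seed=0)

    def test_deterministic_mode_is_noise_free_and_repeatable(self, mhc_params):
        t = np.arange(0, 3, 1e-3)
        drive = np.where(t > 1.0, 30.0, 0.0)
        a = generate_spike_train(t, drive, mhc_params, seed=1, deterministic=True)
        b = generate_spike_train(t, drive, mhc_params, seed=999, deterministic=True)
        np.testing.assert_array_equal(a, b)
        assert a[0] == pytest.approx(t[t > 1.0][0])


class TestSimulatedSessions:
    def test_mechano_only_neuron_silent_under_heat(self, hot_protocol, skin, hot_field):
        m = class_params("M")
        sess = simulate_recording(hot_protocol, m, skin, seed=5, field_=hot_field)
        t0 = sess.protocol_start
        evoked = np.sum((sess.spike_times >= t0) & (sess.spike_times < t0 + 2.0))
        # nothing beyond spontaneous activity (0.1 Hz baseline)
        assert evoked <= 2

    def test_non_nociceptive_neuron_silent_under_heat(self, hot_protocol, skin, hot_field):
        nn = class_params("non_nociceptive")
        sess = simulate_recording(hot_protocol, nn, skin, seed=5, field_=hot_field)
        t0 = sess.protocol_start
        assert np.sum(sess.spike_times >= t0) <= 2

    def test_session_times_sorted_and_baseline_precedes_onset(
            self, hot_protocol, mhc_params, skin, hot_field):
        sess = simulate_recording(hot_protocol, mhc_params, skin, seed=8, field_=hot_field)
        assert np.all(np.diff(sess.spike_times) > 0)
        assert sess.baseline_epoch[1] <= sess.onsets[0]


class TestWindupShapes:
    def test_hot_expected_rates_rise_then_decay(self, mhc_params, skin):
        p = make_iterative(make_single_stim("hot", 1.0), 30, 1.0)
        rates = expected_per_stimulus_rates(p, mhc_params, skin)
        peak = int(np.argmax(rates))
        assert 1 <= peak <= 4                      # facilitation over stimuli 2-5
        assert rates[peak] > 1.5 * rates[0]        # wind-up-like rise
        assert rates[-1] < 0.3 * rates[peak]       # slow adaptation dominates late

    def test_cold_expected_rates_non_increasing(self, mhc_params, skin):
        p = make_iterative(make_single_stim("cold", 1.0), 30, 1.0)
        rates = expected_per_stimulus_rates(p, mhc_params, skin)
        assert np.all(np.diff(rates) <= 0.35)       # no facilitation; small floor drift
        assert rates[0] == rates.max()


class TestCohort:
    def test_fixture_counts(self, fixture_cohort):
        assert len(fixture_cohort) == 37
        wdr = [r for r in fixture_cohort if r.true_class in ("M", "MH", "MHC")]
        assert len(wdr) == 30

    def test_empty_spec_gives_empty_cohort(self, skin):
        spec = CohortSpec(0, 0, 0, 0, 0)
        assert generate_cohort(spec, battery={}, seed=1, sp=skin) == []

    def test_no_cold_only_wdr_generated(self, fixture_cohort):
        """Every cold-sensitive neuron is also heat-sensitive (MHC ⊆ MH)."""
        for r in fixture_cohort:
            if r.params.cold_static_gain > 0 or r.params.cold_dynamic_gain > 0:
                assert r.params.heat_gain > 0

    def test_mechanical_flags_follow_class(self, fixture_cohort):
        for r in fixture_cohort:
            flags = r.mechanical_flags
            if r.true_class == "non_nociceptive":
                assert flags["brush"] and not flags["pinch"]
            elif r.true_class == "NS":
                assert flags["pinch"] and not flags["brush"]
            else:
                assert flags["pinch"] and flags["brush"]

    def test_cohort_generation_is_seed_deterministic(self, skin):
        spec = CohortSpec(1, 0, 1, 1, 1)
        battery = {"single-hot-1000ms": make_single_stim("hot", 1.0)}
        a = generate_cohort(spec, battery=battery, seed=123, sp=skin)
        b = generate_cohort(spec, battery=battery, seed=123, sp=skin)
        for ra, rb in zip(a, b):
            assert ra.params == rb.params
            np.testing.assert_array_equal(
                ra.sessions["single-hot-1000ms"].spike_times,
                rb.sessions["single-hot-1000ms"].spike_times)
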