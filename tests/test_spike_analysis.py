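"""Spike-train measurements: latency, windowed rates, ramp thresholds,
wind-up profiles and decay fits, response curves, PSTHs and classification."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wdrtherm.protocols import make_response_curve, make_single_stim, make_slow_ramp
from wdrtherm.spike_analysis import (
    DetectionCriterion,
    IncompleteBatteryError,
    classify_neuron,
    cohort_summary,
    evoked_rate,
    filter_wdr,
    first_spike_latency,
    fit_exponential_decay,
    iterative_profile,
    psth,
    ramp_threshold,
    response_curve,
    windup_index,
)
from wdrtherm.wdr_model import NeuronParams, NeuronRecord, RecordingSession, class_params, simulate_recording

BASELINE = 5.0


def make_session(spike_times, protocol=None, baseline=BASELINE, params=None):
    """A session from literal spike times (absolute session clock)."""
    protocol = protocol or make_single_stim("hot", 1.0)
    return RecordingSession(
        neuron_id="test", params=params or NeuronParams(),
        protocol=protocol, baseline_epoch=(0.0, baseline),
        spike_times=np.asarray(spike_times, dtype=float), seed=0,
    )


class TestFirstSpikeLatency:
    def test_latency_from_onset(self):
        s = make_session([BASELINE + 0.490, BASELINE + 0.6])
        res = first_spike_latency(s, BASELINE)
        assert res.defined and res.latency == pytest.approx(0.490)

    def test_spikes_only_before_onset_are_ignored(self):
        s = make_session([1.0, 2.0, 4.9])
        assert not first_spike_latency(s, BASELINE).defined

    def test_empty_train_is_undefined_not_an_exception(self):
        assert not first_spike_latency(make_session([]), BASELINE).defined

    def test_onset_outside_session_rejected(self):
        with pytest.raises(ValueError):
            first_spike_latency(make_session([6.0]), 1e6)

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_matches_brute_force_scan(self, seed):
        rng = np.random.default_rng(seed)
        times = np.unique(np.round(rng.uniform(0, 8.0, 40), 3))
        times = times[np.insert(np.diff(times) >= 0.002, 0, True)]
        s = make_session(times)
        onset = float(rng.uniform(0, 7.5))
        res = first_spike_latency(s, onset)
        after = [t for t in times if t > onset]  # brute-force linear scan
        if after:
            assert res.defined and res.latency == pytest.approx(after[0] - onset)
        else:
            assert not res.defined


class TestEvokedRate:
    def test_two_second_window_rate(self):
        spikes = BASELINE + np.linspace(0.05, 1.95, 34)
        res = evoked_rate(make_session(spikes), BASELINE)
        assert res.raw_rate == pytest.approx(17.0)
        assert res.evoked_rate == pytest.approx(17.0)  # silent baseline

    def test_baseline_subtraction(self):
        baseline_spikes = np.linspace(0.1, 4.9, 10)       # 2 Hz for 5 s
        evoked_spikes = BASELINE + np.linspace(0.05, 1.95, 24)
        res = evoked_rate(make_session(np.concatenate([baseline_spikes, evoked_spikes])),
                          BASELINE)
        assert res.baseline_rate == pytest.approx(2.0)
        assert res.evoked_rate == pytest.approx(12.0 - 2.0)

    def test_empty_window_with_silent_baseline(self):
        res = evoked_rate(make_session([]), BASELINE)
        assert res.raw_rate == 0.0 and res.evoked_rate == 0.0

    def test_zero_length_window_rejected(self):
        with pytest.raises(ValueError):
            evoked_rate(make_session([]), BASELINE, window_len=0.0)

    def test_zero_baseline_identity(self):
        spikes = BASELINE + np.linspace(0.1, 1.9, 7)
        res = evoked_rate(make_session(spikes), BASELINE)
        assert res.evoked_rate == res.raw_rate


class TestRampThreshold:
    def test_heat_ramp_threshold_arithmetic(self):
        p = make_slow_ramp("hot")  # 3 °C/s from 30 °C
        s = make_session([BASELINE + 4.4667], protocol=p)
        est = ramp_threshold(s)
        assert est.threshold_temp == pytest.approx(43.4, abs=0.01)

    def test_cold_ramp_threshold_arithmetic(self):
        p = make_slow_ramp("cold")  # 4 °C/s from 30 °C
        s = make_session([BASELINE + 2.55], protocol=p)
        est = ramp_threshold(s)
        assert est.threshold_temp == pytest.approx(19.8, abs=0.01)
        assert est.modality == "cold"

    def test_first_spike_at_onset_returns_baseline_temp(self):
        p = make_slow_ramp("hot")
        s = make_session([BASELINE + 1e-4], protocol=p)
        assert ramp_threshold(s).threshold_temp == pytest.approx(30.0, abs=0.01)

    def test_silent_trial_gives_undefined_threshold(self):
        assert not ramp_threshold(make_session([], protocol=make_slow_ramp("hot"))).defined

    def test_estimate_biased_above_depth_threshold_under_heating(self, skin, mhc_params):
        """Thermal lag: the probe reads hotter than the nociceptor when the
        depth threshold is crossed, so the ramp estimate is an upper bound."""
        s = simulate_recording(make_slow_ramp("hot"), mhc_params, skin,
                               seed=0, deterministic=True)
        est = ramp_threshold(s)
        assert est.threshold_temp >= mhc_params.heat_threshold


class TestWindupIndexAndDecayFit:
    def test_published_series_index(self):
        # rise from 9.5 Hz (stim 1) to a 23.1 Hz peak within the first three
        rates = [9.5, 14.0, 23.1, 20.0, 15.0]
        assert windup_index(rates) == pytest.approx(23.1 / 9.5, rel=1e-12)

    def test_constant_series_index_is_one(self):
        assert windup_index([5.0, 5.0, 5.0]) == 1.0

    def test_nonpositive_first_rate_is_undefined(self):
        assert math.isnan(windup_index([0.0, 3.0, 4.0]))

    def test_noiseless_fit_recovers_four_significant_digits(self):
        t = np.arange(28.0)
        a_true, tau_true, c_true = 19.4, 8.12, 3.7
        y = a_true * np.exp(-t / tau_true) + c_true
        a, tau, c = fit_exponential_decay(t, y)
        assert a == pytest.approx(a_true, rel=1e-4)
        assert tau == pytest.approx(tau_true, rel=1e-4)
        assert c == pytest.approx(c_true, rel=1e-4)

    def test_noisy_fit_recovers_within_ten_percent(self):
        rng = np.random.default_rng(2024)
        t = np.arange(28.0)
        a_true, tau_true, c_true = 19.4, 8.12, 3.7
        y = a_true * np.exp(-t / tau_true) + c_true + rng.normal(0, 0.1, t.size)
        a, tau, c = fit_exponential_decay(t, y)
        assert a == pytest.approx(a_true, rel=0.10)
        assert tau == pytest.approx(tau_true, rel=0.10)
        assert c == pytest.approx(c_true, rel=0.10)

    def test_constant_series_reports_asymptote_only(self):
        t = np.arange(20.0)
        a, tau, c = fit_exponential_decay(t, np.full_like(t, 6.0), max_tau=300.0)
        if math.isnan(tau):          # degenerate-fit contract
            assert c == pytest.approx(6.0)
        else:                        # or an exact fit with no amplitude
            assert abs(a) < 1e-6 and c == pytest.approx(6.0, abs=1e-6)


class TestIterativeProfile:
    @staticmethod
    def _train_session(counts, modality="hot"):
        """Session whose k-th 1-s window holds `counts[k]` evenly spaced spikes."""
        from wdrtherm.protocols import make_iterative
        p = make_iterative(make_single_stim(modality, 1.0), len(counts), 1.0)
        spikes = []
        for k, n in enumerate(counts):
            if n:
                spikes.extend(BASELINE + k + np.linspace(0.1, 0.9, n))
        return make_session(np.asarray(spikes), protocol=p)

    def test_per_stimulus_rates_and_index(self):
        counts = [10, 16, 23, 21, 18, 15, 13, 11, 10, 9]
        prof = iterative_profile(self._train_session(counts))
        np.testing.assert_allclose(prof.per_stimulus_rate, counts, atol=1e-9)
        assert prof.windup_index == pytest.approx(2.3)
        assert prof.fit_start == 2  # decay fitted from the stimulus-3 peak

    def test_exponential_series_tau_recovered_through_profile(self):
        t = np.arange(30)
        counts = np.round(3.0 + 20.0 * np.exp(-t / 8.12)).astype(int)
        prof = iterative_profile(self._train_session(list(counts)))
        assert prof.fit_tau == pytest.approx(8.12, rel=0.15)  # integer rounding noise

    def test_single_onset_protocol_rejected(self):
        with pytest.raises(ValueError):
            iterative_profile(make_session([6.0]))


class TestResponseCurve:
    @staticmethod
    def _battery_sessions(counts_by_temp, modality="cold"):
        sessions = []
        for temp, n in counts_by_temp.items():
            p = make_single_stim(modality, 5.0, target=float(temp),
                                 name=f"curve-{modality}-{temp}C")
            spikes = BASELINE + np.linspace(0.2, 4.8, n) if n else []
            sessions.append(make_session(spikes, protocol=p))
        return sessions

    def test_counts_ordered_by_temperature(self):
        curve = response_curve(self._battery_sessions({20: 2, 15: 24, 10: 25, 5: 26, 0: 25}))
        np.testing.assert_array_equal(curve.temperatures, [0, 5, 10, 15, 20])
        np.testing.assert_allclose(curve.ap_counts, [25, 26, 25, 24, 2])

    def test_neutral_stimulus_counts_zero(self):
        curve = response_curve(self._battery_sessions({30: 0}, modality="hot"))
        assert curve.ap_counts[0] == 0.0

    def test_missing_temperature_raises(self):
        sessions = self._battery_sessions({20: 5, 15: 6})
        with pytest.raises(IncompleteBatteryError):
            response_curve(sessions, temperatures=[20, 15, 10])


class TestPsth:
    def test_empty_train_all_zero(self):
        counts = psth(make_session([]))
        assert counts.sum() == 0

    def test_single_loaded_bin(self):
        s = make_session(2.0 + np.arange(5) * 0.003)
        counts = psth(s)
        assert counts.max() == 5 and counts.sum() == 5

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_histogram_conserves_spike_count(self, seed):
        rng = np.random.default_rng(seed)
        times = np.unique(np.round(rng.uniform(0, 8.0, 60), 3))
        times = times[np.insert(np.diff(times) >= 0.002, 0, True)]
        s = make_session(times)
        assert psth(s).sum() == times.size


class TestClassification:
    @staticmethod
    def _record(cls, heat_spikes=0, cold_spikes=0):
        params = class_params(cls)
        sessions = {}
        for modality, n in (("hot", heat_spikes), ("cold", cold_spikes)):
            target = 52.0 if modality == "hot" else 0.0
            p = make_single_stim(modality, 5.0, target=target,
                                 name=f"curve-{modality}-{target:g}C")
            spikes = BASELINE + np.linspace(0.3, 4.7, n) if n else []
            sessions[p.name] = make_session(spikes, protocol=p, params=params)
        return NeuronRecord(neuron_id="u", true_class=cls, params=params,
                            sessions=sessions)

    def test_full_convergent_unit_is_wdr_mhc(self):
        label = classify_neuron(self._record("MHC", heat_spikes=60, cold_spikes=40))
        assert label.primary == "WDR" and label.thermal == "MHC"

    def test_mechanical_only_unit_is_wdr_m(self):
        label = classify_neuron(self._record("M"))
        assert label.primary == "WDR" and label.thermal == "M"

    def test_brush_only_unit_excluded_as_non_nociceptive(self):
        label = classify_neuron(self._record("non_nociceptive"))
        assert label.primary == "non_nociceptive" and label.thermal is None

    def test_pinch_only_unit_is_nociceptive_specific(self):
        label = classify_neuron(self._record("NS", heat_spikes=50))
        assert label.primary == "nociceptive_specific"

    def test_heat_only_unit_is_mh(self):
        label = classify_neuron(self._record("MH", heat_spikes=60, cold_spikes=0))
        assert label.thermal == "MH"

    def test_detection_criterion_floor(self):
        # 3 spikes in 5 s (0.6 Hz) stays below the 2-Hz floor
        label = classify_neuron(self._record("MH", heat_spikes=3))
        assert label.thermal == "M"

    def test_filter_wdr_drops_excluded_units(self):
        records = [self._record("non_nociceptive"), self._record("NS"),
                   self._record("MHC", 60, 40)]
        labels = [classify_neuron(r) for r in records]
        kept = filter_wdr(records, labels)
        assert [r.true_class for r in kept] == ["MHC"]

    def test_cohort_summary_percentages(self):
        records = [self._record("M"), self._record("MH", 60),
                   self._record("MHC", 60, 40), self._record("non_nociceptive")]
        labels = [classify_neuron(r) for r in records]
        table = cohort_summary(records, labels)
        rows = dict(zip(table["group"], table["percent"]))
        assert rows["heat_responsive_of_WDR"] == pytest.approx(100 * 2 / 3)
        assert rows["heat_and_cold_of_WDR"] == pytest.approx(100 * 1 / 3)
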