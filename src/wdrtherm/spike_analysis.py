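"""Spike-train measurements for thermode-stimulation experiments.

Implements every quantity reported for wide-dynamic-range neurons:

* first-spike latency from stimulus onset;
* windowed firing rate (default 2-s window, the span of the stereotypical
  bursting discharge) with baseline-rate subtraction;
* activation-threshold estimation from slow ramps (probe temperature at the
  first evoked spike);
* per-stimulus rate profiles of iterative 1-Hz trains, with an exponential
  decay fit and a wind-up index;
* response curves (spike count per 5-s graded plateau);
* peristimulus time histograms (200-ms bins);
* neuron classification from mechanical response flags and thermal evoked
  rates (non-nociceptive / nociceptive-specific / WDR, with M/MH/MHC thermal
  sub-labels), plus the exclusion filter that retains only WDR units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .protocols import ThermalProtocol
from .wdr_model import NeuronRecord, RecordingSession, WDR_CLASSES

__all__ = [
    "LatencyResult",
    "RateResult",
    "ThresholdEstimate",
    "IterativeProfile",
    "ResponseCurve",
    "NeuronLabel",
    "DetectionCriterion",
    "first_spike_latency",
    "evoked_rate",
    "baseline_stats",
    "ramp_threshold",
    "iterative_profile",
    "fit_exponential_decay",
    "windup_index",
    "response_curve",
    "psth",
    "classify_neuron",
    "classify_cohort",
    "filter_wdr",
    "cohort_summary",
]

EVOKED_WINDOW = 2.0  # s, span of the stereotypical bursting discharge
PSTH_BIN = 0.2       # s


# -- result containers ----------------------------------------------------

@dataclass(frozen=True)
class LatencyResult:
    latency: float      # s from onset to the first evoked spike (NaN if none)
    onset: float        # s, stimulus onset on the session time axis
    defined: bool


@dataclass(frozen=True)
class RateResult:
    window: tuple[float, float]
    raw_rate: float
    baseline_rate: float
    evoked_rate: float  # raw - baseline


@dataclass(frozen=True)
class ThresholdEstimate:
    threshold_temp: float  # °C, probe temperature at the first evoked spike
    first_spike_time: float  # s from stimulus onset
    modality: str
    defined: bool = True


@dataclass(frozen=True)
class IterativeProfile:
    per_stimulus_rate: np.ndarray  # Hz, baseline-subtracted, one per stimulus
    fit_amplitude: float
    fit_tau: float
    fit_asymptote: float
    windup_index: float
    fit_start: int  # index of the first stimulus included in the decay fit


@dataclass(frozen=True)
class ResponseCurve:
    temperatures: np.ndarray
    ap_counts: np.ndarray  # baseline-corrected counts over the stimulus, >= 0


@dataclass(frozen=True)
class NeuronLabel:
    primary: str          # non_nociceptive | nociceptive_specific | WDR
    thermal: str | None   # M | MH | MHC (WDR only)


@dataclass(frozen=True)
class DetectionCriterion:
    """A unit counts as thermally responsive when its evoked rate exceeds
    max(min_rate, baseline + n_sd * SE(baseline rate))."""

    min_rate: float = 2.0
    n_sd: float = 3.0

    def threshold(self, baseline_rate: float, baseline_se: float) -> float:
        return max(self.min_rate, baseline_rate + self.n_sd * baseline_se)


# -- elementary measurements ----------------------------------------------

def baseline_stats(s: RecordingSession) -> tuple[float, float]:
    """Baseline rate (Hz) and the Poisson standard error of that estimate."""
    b0, b1 = s.baseline_epoch
    span = b1 - b0
    if span <= 0:
        raise ValueError("empty baseline epoch")
    n = int(np.sum((s.spike_times >= b0) & (s.spike_times < b1)))
    return n / span, math.sqrt(n) / span if n > 0 else 1.0 / span


def first_spike_latency(s: RecordingSession, onset: float) -> LatencyResult:
    """Latency to the first spike strictly after ``onset``; spikes in the
    baseline epoch never count, and a silent trial is defined=False."""
    if not 0 <= onset <= s.duration:
        raise ValueError("onset outside the session time range")
    after = s.spike_times[s.spike_times > onset]
    if after.size == 0:
        return LatencyResult(latency=math.nan, onset=onset, defined=False)
    return LatencyResult(latency=float(after[0] - onset), onset=onset, defined=True)


def evoked_rate(
    s: RecordingSession, onset: float, window_len: float = EVOKED_WINDOW
) -> RateResult:
    """Firing rate in [onset, onset + window_len) minus the mean baseline rate."""
    if window_len <= 0:
        raise ValueError("window length must be positive")
    n = int(np.sum((s.spike_times >= onset) & (s.spike_times < onset + window_len)))
    raw = n / window_len
    base, _ = baseline_stats(s)
    return RateResult(window=(onset, onset + window_len), raw_rate=raw,
                      baseline_rate=base, evoked_rate=raw - base)


def ramp_threshold(s: RecordingSession, p: ThermalProtocol | None = None) -> ThresholdEstimate:
    """Activation threshold from a slow ramp: the probe temperature at the
    moment of the first evoked spike."""
    p = p or s.protocol
    onset = float(s.onsets[0])
    lat = first_spike_latency(s, onset)
    modality = p.modality
    if not lat.defined or lat.latency > p.total_duration:
        return ThresholdEstimate(math.nan, math.nan, modality, defined=False)
    temp = p.temperature(min(lat.latency, p.total_duration))
    return ThresholdEstimate(threshold_temp=float(temp),
                             first_spike_time=lat.latency, modality=modality)


# -- iterative (wind-up) protocol -----------------------------------------

def windup_index(per_stimulus_rate: Sequence[float]) -> float:
    """max(rate over stimuli 1..3) / rate of stimulus 1; >= 1 by construction,
    NaN when the first-stimulus rate is not positive."""
    r = np.asarray(per_stimulus_rate, dtype=float)
    if r.size < 1 or r[0] <= 0:
        return math.nan
    return float(np.max(r[: min(3, r.size)]) / r[0])


def fit_exponential_decay(
    t: np.ndarray, y: np.ndarray, *, max_tau: float | None = None
) -> tuple[float, float, float]:
    """Least-squares fit of y = A * exp(-t/tau) + c.

    Returns (A, tau, c); (NaN, NaN, mean) when the fit fails or when tau is
    degenerate (beyond ``max_tau``, i.e. no meaningful decay on this span).
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size < 3:
        return math.nan, math.nan, float(np.mean(y))

    def model(tt, a, tau, c):
        return a * np.exp(-tt / tau) + c

    a0 = max(y[0] - y[-1], 1e-3)
    tau0 = max((t[-1] - t[0]) / 3.0, 1e-3)
    try:
        popt, _ = curve_fit(
            model, t - t[0], y, p0=(a0, tau0, max(y[-1], 0.0)),
            bounds=([-np.inf, 1e-9, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
    except Exception:
        return math.nan, math.nan, float(np.mean(y))
    a, tau, c = (float(v) for v in popt)
    if max_tau is not None and tau > max_tau:
        return math.nan, math.nan, float(np.mean(y))
    return a, tau, c


def iterative_profile(s: RecordingSession, p: ThermalProtocol | None = None) -> IterativeProfile:
    """Per-stimulus baseline-subtracted rates of an iterative train, the
    wind-up index, and an exponential decay fit of the post-peak portion
    (hot; facilitation first) or of the whole series (cold; no facilitation)."""
    p = p or s.protocol
    onsets = s.onsets
    if onsets.size < 2:
        raise ValueError("iterative protocol needs at least 2 onsets")
    period = float(onsets[1] - onsets[0])
    base, _ = baseline_stats(s)
    rates = np.array([
        np.sum((s.spike_times >= o) & (s.spike_times < o + period)) / period - base
        for o in onsets
    ])
    wi = windup_index(rates)
    start = int(np.argmax(rates[: min(5, rates.size)])) if p.modality == "hot" else 0
    t_rel = (onsets[start:] - onsets[0]).astype(float)
    a, tau, c = fit_exponential_decay(
        t_rel - t_rel[0], rates[start:], max_tau=10.0 * p.total_duration)
    return IterativeProfile(per_stimulus_rate=rates, fit_amplitude=a, fit_tau=tau,
                            fit_asymptote=c, windup_index=wi, fit_start=start)


# -- response curve --------------------------------------------------------

class IncompleteBatteryError(ValueError):
    """A response-curve temperature has no matching session."""


def response_curve(
    sessions: Iterable[RecordingSession], temperatures: Sequence[float] | None = None
) -> ResponseCurve:
    """Baseline-corrected spike count (floored at 0) within each 5-s graded
    plateau, ordered by the battery temperature."""
    by_temp: dict[float, RecordingSession] = {}
    for s in sessions:
        stim = s.protocol.segments[0]
        by_temp[float(stim.target_temp)] = s
    if temperatures is None:
        temperatures = sorted(by_temp)
    counts = []
    for temp in temperatures:
        if float(temp) not in by_temp:
            raise IncompleteBatteryError(f"no session at {temp} °C")
        s = by_temp[float(temp)]
        onset = float(s.onsets[0])
        stim = s.protocol.segments[0]
        duration = abs(stim.target_temp - s.protocol.baseline_temp) / stim.ramp_rate \
            + stim.hold_duration
        n = int(np.sum((s.spike_times >= onset) & (s.spike_times < onset + duration)))
        base, _ = baseline_stats(s)
        counts.append(max(n - base * duration, 0.0))
    return ResponseCurve(temperatures=np.asarray(temperatures, dtype=float),
                         ap_counts=np.asarray(counts))


def psth(s: RecordingSession, bin: float = PSTH_BIN) -> np.ndarray:
    """Spike counts in left-closed bins of ``bin`` seconds over the whole
    session; the final bin is closed on the right so the histogram conserves
    the total spike count."""
    if bin <= 0:
        raise ValueError("bin must be positive")
    n_bins = max(1, int(math.ceil(s.duration / bin - 1e-9)))
    edges = np.arange(n_bins + 1) * bin
    counts, _ = np.histogram(s.spike_times, bins=edges)
    return counts


# -- classification --------------------------------------------------------

class ClassificationError(ValueError):
    """Missing information required for classification."""


def _thermal_response(
    record: NeuronRecord, modality: str, criterion: DetectionCriterion
) -> bool:
    """Thermal responsiveness judged on the strongest stimulus available for
    the modality (the 52 °C / 0 °C 5-s plateau when present, else the longest
    single stimulus), over the full stimulus duration."""
    extreme = 52.0 if modality == "hot" else 0.0
    candidates: list[tuple[float, RecordingSession]] = []
    for s in record.sessions.values():
        if s.protocol.modality != modality or s.onsets.size != 1:
            continue
        stim = s.protocol.segments[0]
        # judge responsiveness on fast-onset noxious stimuli; slow threshold
        # ramps spread the adapted cold response too thin for rate detection
        if abs(stim.target_temp - extreme) > 1e-9 or stim.ramp_rate < 100.0:
            continue
        duration = abs(stim.target_temp - s.protocol.baseline_temp) / stim.ramp_rate \
            + stim.hold_duration
        candidates.append((duration, s))
    if not candidates:
        return False
    duration, s = max(candidates, key=lambda pair: pair[0])
    window = max(EVOKED_WINDOW, duration)
    rr = evoked_rate(s, float(s.onsets[0]), window)
    base, base_se = baseline_stats(s)
    return rr.evoked_rate > criterion.threshold(base, base_se)


def classify_neuron(
    record: NeuronRecord, criterion: DetectionCriterion | None = None
) -> NeuronLabel:
    """Classify one unit from its mechanical flags and thermal responses.

    Innocuous-only responders are non-nociceptive; pinch-only responders are
    nociceptive-specific; units responding to both are wide-dynamic-range and
    receive an M/MH/MHC thermal sub-label from their evoked responses at the
    extreme hot (52 °C) and cold (0 °C) stimuli.
    """
    criterion = criterion or DetectionCriterion()
    flags = record.mechanical_flags
    if flags is None or any(k not in flags for k in ("brush", "pressure", "pinch")):
        raise ClassificationError("mechanical response flags missing")
    innocuous = flags["brush"] or flags["pressure"]
    noxious = flags["pinch"]
    if innocuous and not noxious:
        return NeuronLabel(primary="non_nociceptive", thermal=None)
    if noxious and not innocuous:
        return NeuronLabel(primary="nociceptive_specific", thermal=None)
    if not innocuous and not noxious:
        raise ClassificationError("unit responds to no mechanical stimulus")
    heat = _thermal_response(record, "hot", criterion)
    cold = _thermal_response(record, "cold", criterion)
    if heat and cold:
        thermal = "MHC"
    elif heat:
        thermal = "MH"
    else:
        # cold-without-heat is not a recognised WDR thermal profile; a unit
        # with neither (or cold only) is mechano-only
        thermal = "M"
    return NeuronLabel(primary="WDR", thermal=thermal)


def classify_cohort(
    records: Sequence[NeuronRecord], criterion: DetectionCriterion | None = None
) -> list[NeuronLabel]:
    return [classify_neuron(r, criterion) for r in records]


def filter_wdr(
    records: Sequence[NeuronRecord], labels: Sequence[NeuronLabel]
) -> list[NeuronRecord]:
    """Exclusion filter: drop non-nociceptive and nociceptive-specific units,
    keeping the wide-dynamic-range population the thermal analysis uses."""
    return [r for r, lab in zip(records, labels) if lab.primary == "WDR"]


def cohort_summary(
    records: Sequence[NeuronRecord], labels: Sequence[NeuronLabel]
) -> pd.DataFrame:
    """Cohort-level classification table: counts and percentages of recorded,
    WDR, heat-responsive (MH+MHC) and heat-and-cold (MHC) units."""
    n_total = len(records)
    wdr = [lab for lab in labels if lab.primary == "WDR"]
    n_wdr = len(wdr)
    n_heat = sum(1 for lab in wdr if lab.thermal in ("MH", "MHC"))
    n_mhc = sum(1 for lab in wdr if lab.thermal == "MHC")
    rows = [
        ("recorded", n_total, 100.0),
        ("excluded", n_total - n_wdr, 100.0 * (n_total - n_wdr) / max(n_total, 1)),
        ("WDR", n_wdr, 100.0 * n_wdr / max(n_total, 1)),
        ("heat_responsive_of_WDR", n_heat, 100.0 * n_heat / max(n_wdr, 1)),
        ("heat_and_cold_of_WDR", n_mhc, 100.0 * n_mhc / max(n_wdr, 1)),
    ]
    return pd.DataFrame(rows, columns=["group", "count", "percent"])
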