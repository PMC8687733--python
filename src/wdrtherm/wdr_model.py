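"""Phenomenological spike-train generator for spinal wide-dynamic-range neurons.

The generator stands in for in vivo recordings: it maps the temperature
history at nociceptor depth (from :mod:`wdrtherm.thermal`) to an instantaneous
firing-rate drive, and realises spike trains as an inhomogeneous Poisson
process with an absolute refractory period.  It is an explicitly descriptive
rate model — no channel biophysics — whose defaults are calibrated against
summary statistics of WDR responses to thermode stimulation:

* heat drive: threshold-linear in temperature above ~43 °C (TRPV1-like,
  absolute coding), an onset burst at the first threshold crossing (the
  stereotypical bursting discharge that sets the ~490 ms first-spike latency),
  slow wind-up-like facilitation with accumulated suprathreshold exposure,
  slow exponential adaptation (τ ≈ 8 s), and a post-discharge envelope that
  lets firing outlast the stimulus (C-fibre-like);
* cold drive: dominated by the rate of temperature change (relative coding),
  gated below a ~20 °C cold threshold, with a static component saturating at a
  low ceiling and fast adaptation (Aδ-like), no post-discharge;
* conduction delays: cold (Aδ) shorter than heat (C).

Cohorts reproduce the observed class structure — mechano-only (M),
mechano-heat (MH), mechano-heat-cold (MHC) wide-dynamic-range neurons plus
non-nociceptive and nociceptive-specific units — with seeded log-normal
parameter jitter, and carry ground-truth labels for recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .protocols import ThermalProtocol, table1_battery
from .thermal import SkinThermalParams, TemperatureField, solve_skin_temperature

__all__ = [
    "NeuronParams",
    "RecordingSession",
    "CohortSpec",
    "NeuronRecord",
    "class_params",
    "transduction_drive",
    "generate_spike_train",
    "simulate_recording",
    "generate_cohort",
    "expected_per_stimulus_rates",
    "CLASS_PRESETS",
    "WDR_CLASSES",
    "HOT_LATENCY_TARGET",
    "COLD_LATENCY_TARGET",
]

#: calibration targets for mean first-spike latency of the default MHC neuron
#: under the 1000-ms single stimulus (see analysis/02_calibrate_neuron.py).
HOT_LATENCY_TARGET = 0.490
COLD_LATENCY_TARGET = 0.212

WDR_CLASSES = ("M", "MH", "MHC")
ALL_CLASSES = ("non_nociceptive", "NS", "M", "MH", "MHC")


@dataclass(frozen=True)
class NeuronParams:
    """Transduction and dynamics parameters of one model neuron.

    Rates are in Hz, temperatures in °C, times in seconds.  Gains of zero
    switch a modality off (class structure).  ``*_burst_*`` parameters shape
    the onset discharge; facilitation/adaptation act on accumulated
    suprathreshold exposure, so they carry over between 1-Hz repetitions.
    """

    neuron_class: str = "MHC"
    # heat pathway (C-fibre-like)
    heat_threshold: float = 43.0
    heat_gain: float = 2.2            # Hz per °C above threshold
    heat_burst_rate: float = 80.0     # Hz, onset burst amplitude
    heat_burst_tau: float = 0.125     # s, onset burst decay
    facilitation_gain: float = 2.2    # dimensionless wind-up amplitude
    facilitation_tau: float = 0.6     # s of suprathreshold exposure
    adaptation_tau_heat: float = 8.12  # s, slow heat adaptation
    adaptation_floor_heat: float = 0.05
    postdischarge_tau: float = 1.2    # s, post-stimulus envelope (0 disables)
    conduction_delay_heat: float = 0.017  # s (C-fibre-like, slower)
    # cold pathway (Aδ-like)
    cold_threshold: float = 19.8
    cold_static_gain: float = 0.9     # Hz per °C below threshold
    cold_dynamic_gain: float = 2.5    # Hz per °C/s of cooling
    cold_drive_ceiling: float = 55.0  # Hz, saturation of the cold drive
    adaptation_tau_cold: float = 0.55  # s, fast cold adaptation
    adaptation_floor_cold: float = 0.15
    conduction_delay_cold: float = 0.004  # s (Aδ-like, faster)
    # spiking
    refractory: float = 0.002
    baseline_rate: float = 0.1
    max_rate: float = 150.0
    # class-determined mechanical response flags
    responds_brush: bool = True
    responds_pressure: bool = True
    responds_pinch: bool = True

    def __post_init__(self) -> None:
        for name in ("heat_gain", "cold_static_gain", "cold_dynamic_gain",
                     "facilitation_gain", "facilitation_tau", "adaptation_tau_heat",
                     "adaptation_tau_cold", "conduction_delay_heat",
                     "conduction_delay_cold", "postdischarge_tau", "baseline_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.refractory <= 0:
            raise ValueError("refractory must be positive")
        if not self.cold_threshold < 30.0 < self.heat_threshold:
            raise ValueError("need cold_threshold < 30 < heat_threshold")
        if self.conduction_delay_cold > self.conduction_delay_heat:
            raise ValueError("Aδ (cold) delay must not exceed C (heat) delay")


#: per-class parameter overrides; gains of zero remove a modality.
CLASS_PRESETS: dict[str, dict] = {
    "MHC": {},
    "MH": {"cold_static_gain": 0.0, "cold_dynamic_gain": 0.0},
    "M": {"heat_gain": 0.0, "heat_burst_rate": 0.0,
          "cold_static_gain": 0.0, "cold_dynamic_gain": 0.0},
    # nociceptive-specific units respond to pinch (and heat) but not to touch
    "NS": {"cold_static_gain": 0.0, "cold_dynamic_gain": 0.0,
           "responds_brush": False, "responds_pressure": False},
    "non_nociceptive": {"heat_gain": 0.0, "heat_burst_rate": 0.0,
                        "cold_static_gain": 0.0, "cold_dynamic_gain": 0.0,
                        "responds_pinch": False},
}

#: positive parameters subject to cohort jitter
_JITTERED = (
    "heat_gain", "heat_burst_rate", "heat_burst_tau", "facilitation_gain",
    "facilitation_tau", "adaptation_tau_heat", "postdischarge_tau",
    "cold_static_gain", "cold_dynamic_gain", "cold_drive_ceiling",
    "adaptation_tau_cold",
)


def class_params(
    neuron_class: str,
    rng: np.random.Generator | None = None,
    jitter_cv: float = 0.10,
) -> NeuronParams:
    """Default parameters for a neuron class, optionally with seeded log-normal
    jitter (mean-preserving, ``jitter_cv`` coefficient of variation) on gains,
    time constants and threshold excursions."""
    if neuron_class not in ALL_CLASSES:
        raise ValueError(f"unknown neuron class {neuron_class!r}")
    params = NeuronParams(neuron_class=neuron_class, **CLASS_PRESETS[neuron_class])
    if rng is None or jitter_cv <= 0:
        return params
    sigma = math.sqrt(math.log(1.0 + jitter_cv**2))
    mu = -0.5 * sigma**2  # mean-preserving log-normal

    def jit(value: float) -> float:
        return value * float(rng.lognormal(mu, sigma))

    overrides = {name: jit(getattr(params, name))
                 for name in _JITTERED if getattr(params, name) > 0}
    # jitter the threshold excursions from the 30 °C neutral point so that the
    # ordering cold_threshold < 30 < heat_threshold is preserved
    overrides["heat_threshold"] = 30.0 + jit(params.heat_threshold - 30.0)
    overrides["cold_threshold"] = 30.0 - jit(30.0 - params.cold_threshold)
    return replace(params, **overrides)


# -- drive ----------------------------------------------------------------

def _decaying_running_max(x: np.ndarray, dt: float, tau: float) -> np.ndarray:
    """env[i] = max(x[i], env[i-1] * exp(-dt/tau)) — exponential-forgetting
    running maximum, the post-discharge envelope."""
    if tau <= 0:
        return x
    out = np.empty_like(x)
    decay = math.exp(-dt / tau)
    # chunked log-domain trick: within a chunk,
    # env = max_acc(x * e^{t/tau}) * e^{-t/tau}, with carry between chunks
    n = x.size
    chunk = max(16, int(200.0 * tau / dt))  # e^{±200} stays in float range
    carry = 0.0
    for s in range(0, n, chunk):
        e = min(s + chunk, n)
        t_loc = np.arange(e - s) * dt
        grow = np.exp(t_loc / tau)
        seeded = np.maximum(x[s:e] * grow, carry * decay * grow)
        env = np.maximum.accumulate(seeded) / grow
        out[s:e] = env
        carry = env[-1]
    return out


def transduction_drive(
    time_grid: np.ndarray,
    depth_trace: np.ndarray,
    np_: NeuronParams,
    modality: str,
) -> np.ndarray:
    """Instantaneous rate drive (Hz) from the temperature at nociceptor depth.

    Heat: threshold-linear drive with exposure-dependent facilitation and slow
    adaptation, an onset burst per suprathreshold episode, and a post-discharge
    envelope.  Cold: change-of-temperature-dominated drive gated below the cold
    threshold, saturating at a low ceiling, with fast adaptation and no
    post-discharge.  ``modality='neutral'`` returns zeros.
    """
    T = np.asarray(depth_trace, dtype=float)
    t = np.asarray(time_grid, dtype=float)
    if T.shape != t.shape:
        raise ValueError("time_grid and depth_trace must have the same shape")
    if modality == "neutral":
        return np.zeros_like(T)
    if t.size < 2:
        return np.zeros_like(T)
    dt = float(t[1] - t[0])

    if modality == "hot":
        supra = np.maximum(T - np_.heat_threshold, 0.0)
        active = supra > 0
        exposure = np.cumsum(active) * dt
        w_fac = 1.0 + np_.facilitation_gain * (
            1.0 - np.exp(-exposure / max(np_.facilitation_tau, 1e-12)))
        w_ad = (np_.adaptation_floor_heat
                + (1.0 - np_.adaptation_floor_heat)
                * np.exp(-exposure / max(np_.adaptation_tau_heat, 1e-12)))
        sustained = np_.heat_gain * supra * w_fac * w_ad
        # post-discharge: the sustained discharge outlasts the stimulus
        drive = _decaying_running_max(sustained, dt, np_.postdischarge_tau)
        if np_.heat_burst_rate > 0 and np_.heat_burst_tau > 0:
            starts = np.flatnonzero(active & ~np.roll(active, 1))
            if active.size and active[0]:
                starts = np.union1d(starts, [0])
            for i0 in starts:
                tail = t[i0:] - t[i0]
                amp = np_.heat_burst_rate * w_fac[i0] * w_ad[i0]
                drive[i0:] += amp * np.exp(-tail / np_.heat_burst_tau)
        return drive

    if modality == "cold":
        deficit = np.maximum(np_.cold_threshold - T, 0.0)
        gate = deficit > 0
        dTdt = np.gradient(T, dt)
        dyn = np_.cold_dynamic_gain * np.maximum(-dTdt, 0.0) * gate
        static = np_.cold_static_gain * deficit
        exposure = np.cumsum(gate) * dt
        w_ad = (np_.adaptation_floor_cold
                + (1.0 - np_.adaptation_floor_cold)
                * np.exp(-exposure / max(np_.adaptation_tau_cold, 1e-12)))
        return w_ad * np.minimum(static + dyn, np_.cold_drive_ceiling)

    raise ValueError(f"modality must be 'hot', 'cold' or 'neutral', got {modality!r}")


# -- spiking --------------------------------------------------------------

class NegativeDriveError(ValueError):
    """The rate drive must be non-negative everywhere."""


def generate_spike_train(
    time_grid: np.ndarray,
    drive: np.ndarray,
    np_: NeuronParams,
    seed: int,
    *,
    deterministic: bool = False,
) -> np.ndarray:
    """Realise spike times from a rate drive on ``time_grid``.

    Stochastic mode: inhomogeneous-Poisson thinning of
    rate(t) = min(baseline_rate + drive(t), max_rate) with an absolute
    refractory period; identical seeds give identical trains.

    Deterministic mode (the noiseless high-gain limit used for estimator
    validation): the first spike is placed at the first instant of non-zero
    drive, later spikes at unit crossings of the integrated rate; the baseline
    process is silenced.
    """
    t = np.asarray(time_grid, dtype=float)
    drive = np.asarray(drive, dtype=float)
    if np.any(drive < 0):
        raise NegativeDriveError("drive must be >= 0 everywhere")
    rate = np.minimum(np_.baseline_rate + drive, np_.max_rate)

    if deterministic:
        nz = np.flatnonzero(drive > 1e-12)
        if nz.size == 0:
            return np.empty(0)
        i0 = nz[0]
        spikes = [t[i0]]
        dt = t[1] - t[0] if t.size > 1 else 0.0
        cum = np.concatenate([[0.0], np.cumsum(np.minimum(drive, np_.max_rate)[i0:]) * dt])
        k, last = 1, t[i0]
        for j in range(1, cum.size):
            while cum[j] >= k:
                frac = (k - cum[j - 1]) / (cum[j] - cum[j - 1])
                s = t[i0] + (j - 1 + frac) * dt
                if s - last >= np_.refractory:
                    spikes.append(s)
                    last = s
                k += 1
        return np.asarray(spikes)

    rng = np.random.default_rng(seed)
    t0, t1 = t[0], t[-1]
    rmax = float(rate.max())
    if rmax <= 0:
        return np.empty(0)
    n_cand = rng.poisson(rmax * (t1 - t0))
    cand = np.sort(rng.uniform(t0, t1, n_cand))
    accept = rng.uniform(0.0, rmax, n_cand) < np.interp(cand, t, rate)
    cand = cand[accept]
    if cand.size == 0:
        return cand
    spikes = [cand[0]]
    for s in cand[1:]:
        if s - spikes[-1] >= np_.refractory:
            spikes.append(s)
    return np.asarray(spikes)


# -- sessions -------------------------------------------------------------

@dataclass(frozen=True)
class RecordingSession:
    """Sorted single-unit spike times for one neuron under one protocol.

    The session time axis starts at 0 with a spontaneous-activity baseline
    epoch; the protocol program starts at ``protocol_start``.
    """

    neuron_id: str
    params: NeuronParams
    protocol: ThermalProtocol
    baseline_epoch: tuple[float, float]
    spike_times: np.ndarray
    seed: int
    trial_id: int = 0

    def __post_init__(self) -> None:
        st = np.asarray(self.spike_times, dtype=float)
        if st.size > 1:
            isi = np.diff(st)
            if np.any(isi <= 0):
                raise ValueError("spike_times must be strictly increasing")
            if np.any(isi < self.params.refractory - 1e-9):
                raise ValueError("inter-spike interval below the refractory period")
        object.__setattr__(self, "spike_times", st)
        if self.baseline_epoch[1] > self.protocol_start + 1e-9:
            raise ValueError("baseline epoch must precede the first stimulus onset")

    @property
    def protocol_start(self) -> float:
        return self.baseline_epoch[1]

    @property
    def onsets(self) -> np.ndarray:
        """Stimulus onsets on the session time axis."""
        return self.protocol_start + np.asarray(self.protocol.stimulus_onsets)

    @property
    def duration(self) -> float:
        return self.protocol_start + self.protocol.total_duration


def _session_drive(
    protocol: ThermalProtocol,
    np_: NeuronParams,
    field_: TemperatureField,
    depth: float,
    baseline_duration: float,
    dt: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Session time grid and conduction-delayed evoked drive."""
    modality = protocol.modality
    trace = field_.depth_trace(depth)
    drive = transduction_drive(field_.time_grid, trace, np_, modality)
    delay = (np_.conduction_delay_heat if modality == "hot"
             else np_.conduction_delay_cold if modality == "cold" else 0.0)
    n_total = int(round((baseline_duration + protocol.total_duration) / dt)) + 1
    t_sess = np.arange(n_total) * dt
    shifted = np.interp(t_sess - baseline_duration - delay,
                        field_.time_grid, drive, left=0.0, right=0.0)
    return t_sess, shifted


def simulate_recording(
    p: ThermalProtocol,
    np_: NeuronParams,
    sp: SkinThermalParams | None = None,
    seed: int = 0,
    *,
    baseline_duration: float = 5.0,
    dt: float = 1e-3,
    dx: float = 10e-6,
    field_: TemperatureField | None = None,
    neuron_id: str = "n0",
    trial_id: int = 0,
    deterministic: bool = False,
) -> RecordingSession:
    """Full chain: solve skin temperature → transduction drive → spike train,
    with a pre-stimulus baseline epoch of spontaneous activity."""
    sp = sp or SkinThermalParams()
    if field_ is None:
        field_ = solve_skin_temperature(p, sp, dt=dt, dx=dx)
    t_sess, drive = _session_drive(p, np_, field_, sp.nociceptor_depth,
                                   baseline_duration, dt)
    spikes = generate_spike_train(t_sess, drive, np_, seed, deterministic=deterministic)
    return RecordingSession(
        neuron_id=neuron_id,
        params=np_,
        protocol=p,
        baseline_epoch=(0.0, baseline_duration),
        spike_times=spikes,
        seed=seed,
        trial_id=trial_id,
    )


def expected_per_stimulus_rates(
    p: ThermalProtocol,
    np_: NeuronParams,
    sp: SkinThermalParams | None = None,
    dt: float = 1e-3,
    field_: TemperatureField | None = None,
) -> np.ndarray:
    """Noise-free mean evoked rate (Hz) in each per-stimulus window of an
    iterative protocol — the expectation the Poisson realisation fluctuates
    around; used for adaptation/facilitation shape checks."""
    sp = sp or SkinThermalParams()
    if field_ is None:
        field_ = solve_skin_temperature(p, sp, dt=dt)
    onsets = np.asarray(p.stimulus_onsets)
    if onsets.size < 2:
        raise ValueError("iterative protocol required")
    period = float(onsets[1] - onsets[0])
    t_sess, drive = _session_drive(p, np_, field_, sp.nociceptor_depth, 0.0, dt)
    rates = []
    for onset in onsets:
        m = (t_sess >= onset) & (t_sess < onset + period)
        rates.append(float(drive[m].mean()))
    return np.asarray(rates)


# -- cohorts --------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Class composition of a simulated cohort.  The default fixture matches
    the recorded population: 37 units, of which 30 are wide-dynamic-range
    (5 M, 8 MH-only, 17 MHC), plus 5 non-nociceptive and 2 nociceptive-specific
    units that the analysis excludes."""

    non_nociceptive: int = 5
    nociceptive_specific: int = 2
    m_only: int = 5
    mh_only: int = 8
    mhc: int = 17
    seed: int = 7

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name != "seed" and getattr(self, f.name) < 0:
                raise ValueError("class counts must be >= 0")

    @property
    def total(self) -> int:
        return (self.non_nociceptive + self.nociceptive_specific
                + self.m_only + self.mh_only + self.mhc)

    def class_counts(self) -> list[tuple[str, int]]:
        return [
            ("non_nociceptive", self.non_nociceptive),
            ("NS", self.nociceptive_specific),
            ("M", self.m_only),
            ("MH", self.mh_only),
            ("MHC", self.mhc),
        ]


@dataclass(frozen=True)
class NeuronRecord:
    """One simulated neuron: ground-truth class, parameters, and its sessions
    across the protocol battery (keyed by protocol name)."""

    neuron_id: str
    true_class: str
    params: NeuronParams
    sessions: Mapping[str, RecordingSession]

    @property
    def mechanical_flags(self) -> dict[str, bool]:
        return {
            "brush": self.params.responds_brush,
            "pressure": self.params.responds_pressure,
            "pinch": self.params.responds_pinch,
        }


def generate_cohort(
    cs: CohortSpec,
    battery: Mapping[str, ThermalProtocol] | None = None,
    seed: int | None = None,
    sp: SkinThermalParams | None = None,
    *,
    jitter_cv: float = 0.10,
    dt: float = 1e-3,
    dx: float = 10e-6,
    baseline_duration: float = 5.0,
) -> list[NeuronRecord]:
    """Simulate every neuron of ``cs`` through the protocol battery.

    Temperature fields are solved once per protocol and shared across neurons
    (transduction depth is a skin property, not a neuron property).  Each
    neuron receives seeded, jittered class parameters; ground-truth labels are
    kept for classification-recovery tests.
    """
    sp = sp or SkinThermalParams()
    if battery is None:
        battery = table1_battery()
    if seed is None:
        seed = cs.seed
    rng = np.random.default_rng(seed)
    fields_cache = {
        name: solve_skin_temperature(proto, sp, dt=dt, dx=dx)
        for name, proto in battery.items()
    }
    records: list[NeuronRecord] = []
    idx = 0
    for cls, count in cs.class_counts():
        for _ in range(count):
            idx += 1
            neuron_id = f"{cls.lower()}-{idx:02d}"
            params = class_params(cls, rng=rng, jitter_cv=jitter_cv)
            sessions: dict[str, RecordingSession] = {}
            for name, proto in battery.items():
                trial_seed = int(rng.integers(0, 2**31 - 1))
                sessions[name] = simulate_recording(
                    proto, params, sp, trial_seed,
                    baseline_duration=baseline_duration, dt=dt, dx=dx,
                    field_=fields_cache[name], neuron_id=neuron_id,
                )
            records.append(NeuronRecord(neuron_id=neuron_id, true_class=cls,
                                        params=params, sessions=sessions))
    return records
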