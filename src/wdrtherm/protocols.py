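"""Contact-thermode stimulation protocols as piecewise-linear setpoint programs.

A protocol describes the surface temperature imposed by a Peltier thermode as a
sequence of ramp-and-hold segments starting from a neutral baseline (30 °C).
Four protocol families are provided, mirroring the stimulation battery used for
characterising spinal wide-dynamic-range (WDR) neurons:

* single stimulus — 300 °C/s ramp to 52 °C (hot) or 0 °C (cold), held for
  0.25–1 s, then returned to baseline;
* slow ramp — 3 °C/s heating or 4 °C/s cooling toward the same extremes, used
  for activation-threshold estimation (max 7.5 s);
* iterative (wind-up) train — n repetitions of a single stimulus at a fixed
  rate, classically 30 × 1 Hz;
* response curve — a series of 5-s plateaus at graded temperatures.

Time is in seconds with t = 0 at protocol start; a stimulus onset is the start
of the away-from-baseline ramp.  Device limits (0–60 °C, ramp rates up to
300 °C/s) are enforced at construction.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Segment",
    "ThermalProtocol",
    "InvalidProtocolError",
    "make_single_stim",
    "make_slow_ramp",
    "make_iterative",
    "make_response_curve",
    "protocol_temperature",
    "table1_battery",
    "BASELINE_TEMP",
    "HOT_TARGET",
    "COLD_TARGET",
    "FAST_RAMP_RATE",
    "HOT_CURVE_TEMPS",
    "COLD_CURVE_TEMPS",
    "FIVE_DEGREE_GRID",
]

BASELINE_TEMP = 30.0
HOT_TARGET = 52.0
COLD_TARGET = 0.0
FAST_RAMP_RATE = 300.0
HEAT_SLOW_RAMP_RATE = 3.0
COLD_SLOW_RAMP_RATE = 4.0  # Table value of 3 °C/s is inconsistent with the
# 30 °C excursion completing in 7.5 s; 4 °C/s is the documented cooling speed.
SLOW_RAMP_MAX_DURATION = 7.5
DEVICE_TEMP_RANGE = (0.0, 60.0)
DEVICE_MAX_RATE = 300.0
SINGLE_STIM_DURATIONS = (0.25, 0.5, 0.75, 1.0)
HOT_CURVE_TEMPS = (30.0, 35.0, 40.0, 45.0, 52.0)
COLD_CURVE_TEMPS = (20.0, 15.0, 10.0, 5.0, 0.0)
FIVE_DEGREE_GRID = tuple(float(t) for t in range(0, 51, 5)) + (52.0,)

#: observation tail appended after the return-to-baseline ramp so that
#: post-stimulus analysis windows (2-s evoked window, post-discharge) fit
#: inside the protocol's time span.
POST_STIMULUS_WINDOW = 2.0


class InvalidProtocolError(ValueError):
    """Raised when a requested protocol violates device or timing constraints."""


@dataclass(frozen=True)
class Segment:
    """One ramp-and-hold step: at ``start_time`` ramp from the current setpoint
    toward ``target_temp`` at ``ramp_rate`` (°C/s, magnitude), then hold for
    ``hold_duration`` seconds."""

    start_time: float
    target_temp: float
    ramp_rate: float
    hold_duration: float


@dataclass(frozen=True)
class ThermalProtocol:
    """A surface-temperature setpoint waveform for one stimulation episode or train."""

    name: str
    baseline_temp: float
    segments: tuple[Segment, ...]
    total_duration: float
    stimulus_onsets: tuple[float, ...]
    #: metadata only — stimulated skin area of one thermode zone (m²)
    stimulated_area_mm2: float = 8.0
    _breakpoints: tuple[np.ndarray, np.ndarray] = field(
        init=False, repr=False, compare=False, default=None
    )

    def __post_init__(self) -> None:
        self._validate()
        object.__setattr__(self, "_breakpoints", self._build_breakpoints())
        # waveform must start at baseline and stay continuous by construction
        if abs(self.temperature(0.0) - self.baseline_temp) > 1e-9:
            raise InvalidProtocolError("waveform at t=0 must equal baseline_temp")

    # -- construction -----------------------------------------------------
    def _validate(self) -> None:
        lo, hi = DEVICE_TEMP_RANGE
        if not lo <= self.baseline_temp <= hi:
            raise InvalidProtocolError(f"baseline {self.baseline_temp} outside device range")
        if self.total_duration <= 0:
            raise InvalidProtocolError("total_duration must be positive")
        prev_end = 0.0
        for seg in self.segments:
            if not lo <= seg.target_temp <= hi:
                raise InvalidProtocolError(f"target {seg.target_temp} outside device range")
            if not 0.0 < seg.ramp_rate <= DEVICE_MAX_RATE:
                raise InvalidProtocolError(f"ramp rate {seg.ramp_rate} outside (0, 300]")
            if seg.hold_duration < 0:
                raise InvalidProtocolError("negative hold duration")
            if seg.start_time < prev_end - 1e-9:
                raise InvalidProtocolError("segments overlap or are out of order")
            prev_end = seg.start_time  # ramp/hold extent checked while building

    def _build_breakpoints(self) -> tuple[np.ndarray, np.ndarray]:
        times = [0.0]
        temps = [self.baseline_temp]
        for seg in self.segments:
            t0, temp0 = times[-1], temps[-1]
            if seg.start_time < t0 - 1e-9:
                raise InvalidProtocolError("segment starts inside the previous one")
            if seg.start_time > t0 + 1e-12:
                times.append(seg.start_time)
                temps.append(temp0)  # hold between segments
            ramp_time = abs(seg.target_temp - temps[-1]) / seg.ramp_rate
            if ramp_time > 0:
                times.append(times[-1] + ramp_time)
                temps.append(seg.target_temp)
            if seg.hold_duration > 0:
                times.append(times[-1] + seg.hold_duration)
                temps.append(seg.target_temp)
        if times[-1] > self.total_duration + 1e-9:
            raise InvalidProtocolError(
                f"segments extend to {times[-1]:.4f}s beyond total_duration "
                f"{self.total_duration:.4f}s"
            )
        if times[-1] < self.total_duration:
            times.append(self.total_duration)
            temps.append(temps[-1])
        return np.asarray(times), np.asarray(temps)

    # -- evaluation -------------------------------------------------------
    def temperature(self, t):
        """Exact piecewise-linear evaluation of the setpoint at time(s) ``t``."""
        t = np.asarray(t, dtype=float)
        if np.any(t < -1e-12) or np.any(t > self.total_duration + 1e-12):
            raise ValueError(f"time outside [0, {self.total_duration}] s")
        bp_t, bp_T = self._breakpoints
        out = np.interp(t, bp_t, bp_T)
        return float(out) if out.ndim == 0 else out

    def breakpoints(self) -> tuple[np.ndarray, np.ndarray]:
        bp_t, bp_T = self._breakpoints
        return bp_t.copy(), bp_T.copy()

    @property
    def modality(self) -> str:
        """'hot', 'cold' or 'neutral' judged from the waveform excursion."""
        _, bp_T = self._breakpoints
        if bp_T.max() > self.baseline_temp + 1e-9:
            return "hot"
        if bp_T.min() < self.baseline_temp - 1e-9:
            return "cold"
        return "neutral"

    # -- serialization ----------------------------------------------------
    def to_text(self) -> str:
        buf = io.StringIO()
        buf.write("# wdrtherm protocol v1\n")
        buf.write(f"name: {self.name}\n")
        buf.write(f"baseline_temp: {self.baseline_temp!r}\n")
        buf.write(f"total_duration: {self.total_duration!r}\n")
        buf.write("stimulus_onsets: " + " ".join(repr(t) for t in self.stimulus_onsets) + "\n")
        buf.write(f"stimulated_area_mm2: {self.stimulated_area_mm2!r}\n")
        for seg in self.segments:
            buf.write(
                f"segment: {seg.start_time!r} {seg.target_temp!r} "
                f"{seg.ramp_rate!r} {seg.hold_duration!r}\n"
            )
        return buf.getvalue()

    @classmethod
    def from_text(cls, text: str) -> "ThermalProtocol":
        fields: dict[str, str] = {}
        segments: list[Segment] = []
        for ln, raw in enumerate(text.splitlines(), start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if ":" not in line:
                raise InvalidProtocolError(f"line {ln}: expected 'key: value'")
            key, value = (part.strip() for part in line.split(":", 1))
            if key == "segment":
                parts = value.split()
                if len(parts) != 4:
                    raise InvalidProtocolError(f"line {ln}: segment needs 4 numbers")
                segments.append(Segment(*(float(p) for p in parts)))
            else:
                fields[key] = value
        try:
            return cls(
                name=fields["name"],
                baseline_temp=float(fields["baseline_temp"]),
                segments=tuple(segments),
                total_duration=float(fields["total_duration"]),
                stimulus_onsets=tuple(float(t) for t in fields["stimulus_onsets"].split()),
                stimulated_area_mm2=float(fields.get("stimulated_area_mm2", 8.0)),
            )
        except KeyError as exc:  # pragma: no cover - format error path
            raise InvalidProtocolError(f"missing field {exc}") from exc

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_text())

    @classmethod
    def load(cls, path) -> "ThermalProtocol":
        with open(path) as fh:
            return cls.from_text(fh.read())


# -- builders -------------------------------------------------------------

def _target_for(modality: str) -> float:
    if modality == "hot":
        return HOT_TARGET
    if modality == "cold":
        return COLD_TARGET
    raise InvalidProtocolError(f"modality must be 'hot' or 'cold', got {modality!r}")


def make_single_stim(
    modality: str,
    duration: float = 1.0,
    *,
    baseline: float = BASELINE_TEMP,
    ramp_rate: float = FAST_RAMP_RATE,
    target: float | None = None,
    post_window: float = POST_STIMULUS_WINDOW,
    name: str | None = None,
) -> ThermalProtocol:
    """Single fast stimulus: ramp to the noxious target, hold until
    ``onset + duration``, then return to baseline at the same rate."""
    if duration <= 0:
        raise InvalidProtocolError("duration must be positive")
    if target is None:
        target = _target_for(modality)
    ramp_time = abs(target - baseline) / ramp_rate
    if ramp_time > duration:
        raise InvalidProtocolError("duration shorter than the ramp itself")
    segments = (
        Segment(0.0, target, ramp_rate, duration - ramp_time),
        Segment(duration, baseline, ramp_rate, post_window),
    )
    total = duration + ramp_time + post_window
    return ThermalProtocol(
        name=name or f"single-{modality}-{int(round(duration * 1000))}ms",
        baseline_temp=baseline,
        segments=segments,
        total_duration=total,
        stimulus_onsets=(0.0,),
    )


def make_slow_ramp(
    modality: str,
    *,
    baseline: float = BASELINE_TEMP,
    heat_rate: float = HEAT_SLOW_RAMP_RATE,
    cold_rate: float = COLD_SLOW_RAMP_RATE,
    max_duration: float = SLOW_RAMP_MAX_DURATION,
    post_window: float = POST_STIMULUS_WINDOW,
) -> ThermalProtocol:
    """Slow threshold-hunting ramp: 3 °C/s heating to 52 °C or 4 °C/s cooling
    to 0 °C, stimulus capped at ``max_duration`` (7.5 s), then back to baseline."""
    target = _target_for(modality)
    rate = heat_rate if modality == "hot" else cold_rate
    ramp_time = abs(target - baseline) / rate
    if ramp_time > max_duration + 1e-9:
        raise InvalidProtocolError("ramp does not reach target within max_duration")
    segments = (
        Segment(0.0, target, rate, max_duration - ramp_time),
        Segment(max_duration, baseline, FAST_RAMP_RATE, post_window),
    )
    total = max_duration + abs(target - baseline) / FAST_RAMP_RATE + post_window
    return ThermalProtocol(
        name=f"slow-ramp-{modality}",
        baseline_temp=baseline,
        segments=segments,
        total_duration=total,
        stimulus_onsets=(0.0,),
    )


def make_iterative(base: ThermalProtocol, n: int, rate: float) -> ThermalProtocol:
    """Repeat a single-stimulus protocol ``n`` times with onsets 1/rate apart.

    When the base stimulus duration equals the period (1000 ms at 1 Hz) the
    waveform degenerates into one continuous plateau with n bookkeeping onsets.
    """
    if n < 1:
        raise InvalidProtocolError("n must be >= 1")
    if rate <= 0:
        raise InvalidProtocolError("rate must be positive")
    if len(base.stimulus_onsets) != 1:
        raise InvalidProtocolError("base must be a single-stimulus protocol")
    if n == 1:
        return base
    period = 1.0 / rate
    stim = base.segments[0]
    ramp_time = abs(stim.target_temp - base.baseline_temp) / stim.ramp_rate
    duration = ramp_time + stim.hold_duration  # onset -> start of return ramp
    return_time = abs(stim.target_temp - base.baseline_temp) / base.segments[1].ramp_rate
    post_window = base.segments[1].hold_duration
    if duration > period + 1e-9:
        raise InvalidProtocolError("episodes would overlap: base duration > 1/rate")
    continuous = abs(duration - period) <= 1e-9
    if not continuous and duration + return_time > period + 1e-9:
        raise InvalidProtocolError("return ramp would overlap the next onset")
    onsets = tuple(k * period for k in range(n))
    segments: list[Segment] = []
    if continuous:
        plateau_hold = n * period - ramp_time
        segments.append(Segment(0.0, stim.target_temp, stim.ramp_rate, plateau_hold))
        segments.append(
            Segment(n * period, base.baseline_temp, base.segments[1].ramp_rate, post_window)
        )
        total = n * period + return_time + post_window
    else:
        for k, onset in enumerate(onsets):
            segments.append(Segment(onset, stim.target_temp, stim.ramp_rate, stim.hold_duration))
            hold_back = (period - duration - return_time) if k < n - 1 else post_window
            segments.append(
                Segment(onset + duration, base.baseline_temp, base.segments[1].ramp_rate, hold_back)
            )
        total = onsets[-1] + duration + return_time + post_window
    return ThermalProtocol(
        name=f"iterative-{base.name}-n{n}-{rate:g}Hz",
        baseline_temp=base.baseline_temp,
        segments=tuple(segments),
        total_duration=total,
        stimulus_onsets=onsets,
    )


def make_response_curve(
    modality: str,
    *,
    temps: Sequence[float] | None = None,
    duration: float = 5.0,
    baseline: float = BASELINE_TEMP,
    grid: str = "table1",
) -> list[ThermalProtocol]:
    """One 5-s constant-plateau protocol per test temperature.

    ``grid='table1'`` uses the published per-modality temperature lists;
    ``grid='5C'`` uses the 0–52 °C 5-degree-increment preset.
    """
    if temps is None:
        if grid == "table1":
            temps = HOT_CURVE_TEMPS if modality == "hot" else COLD_CURVE_TEMPS
        elif grid == "5C":
            temps = FIVE_DEGREE_GRID
        else:
            raise InvalidProtocolError(f"unknown grid {grid!r}")
    protocols = []
    for temp in temps:
        protocols.append(
            make_single_stim(
                modality,
                duration,
                baseline=baseline,
                target=float(temp),
                name=f"curve-{modality}-{temp:g}C",
            )
        )
    return protocols


def protocol_temperature(p: ThermalProtocol, t) -> float:
    """Setpoint temperature of protocol ``p`` at time ``t`` (0 <= t <= total)."""
    return p.temperature(t)


def table1_battery(*, windup_duration: float = 1.0, windup_n: int = 30) -> dict[str, ThermalProtocol]:
    """The full published stimulation battery, keyed by protocol name.

    Eight single stimuli (4 durations x hot/cold), two slow ramps, two 30 x 1 Hz
    iterative trains, and the ten response-curve plateaus.
    """
    battery: dict[str, ThermalProtocol] = {}
    for modality in ("hot", "cold"):
        for duration in SINGLE_STIM_DURATIONS:
            p = make_single_stim(modality, duration)
            battery[p.name] = p
        p = make_slow_ramp(modality)
        battery[p.name] = p
        base = make_single_stim(modality, windup_duration)
        p = make_iterative(base, windup_n, 1.0)
        battery[p.name] = p
        for p in make_response_curve(modality):
            battery[p.name] = p
    return battery
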