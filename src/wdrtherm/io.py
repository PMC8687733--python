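"""File formats, configuration and the one-shot reproduction report.

All I/O is delimited text for auditability: spike-event tables are TSV with
columns ``neuron_id, trial_id, protocol_name, spike_time_s`` plus ``#``-prefixed
metadata header lines (version, seed, config hash); protocols use the
key–value format of :mod:`wdrtherm.protocols`; run configuration is YAML.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
import logging
import math
import sys
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .protocols import ThermalProtocol, make_single_stim, table1_battery
from .thermal import (SkinThermalParams, solve_skin_temperature,
                      threshold_crossing_latency)
from .spike_analysis import (DetectionCriterion, classify_cohort, cohort_summary,
                             filter_wdr, first_spike_latency)
from .wdr_model import (CohortSpec, NeuronParams, NeuronRecord, RecordingSession,
                        class_params, generate_cohort, simulate_recording,
                        HOT_LATENCY_TARGET, COLD_LATENCY_TARGET)

__all__ = [
    "RunConfig",
    "SpikeTableFormatError",
    "write_spike_table",
    "read_spike_table",
    "write_field",
    "reproduce",
]

log = logging.getLogger("wdrtherm")

SPIKE_COLUMNS = ["neuron_id", "trial_id", "protocol_name", "spike_time_s"]


class SpikeTableFormatError(ValueError):
    pass


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full pipeline run; identical config + seed gives
    byte-identical summary tables."""

    seed: int = 7
    skin: SkinThermalParams = field(default_factory=SkinThermalParams)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    battery: str = "table1"
    out_dir: str = "results"
    log_level: str = "INFO"

    def config_hash(self) -> str:
        payload = json.dumps(
            {"seed": self.seed, "skin": asdict(self.skin),
             "cohort": asdict(self.cohort), "battery": self.battery},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def to_yaml(self, path) -> None:
        data = {"seed": self.seed, "skin": asdict(self.skin),
                "cohort": asdict(self.cohort), "battery": self.battery,
                "out_dir": self.out_dir, "log_level": self.log_level}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        skin = SkinThermalParams(**data.pop("skin", {}))
        cohort = CohortSpec(**data.pop("cohort", {}))
        return cls(skin=skin, cohort=cohort, **data)


def _metadata_header(seed: int | None, extra: Mapping[str, str] | None = None) -> str:
    lines = [f"# wdrtherm v{__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    for key, value in (extra or {}).items():
        lines.append(f"# {key}: {value}")
    return "\n".join(lines) + "\n"


# -- spike tables ----------------------------------------------------------

def write_spike_table(
    records: Sequence[NeuronRecord] | Sequence[RecordingSession],
    path,
    seed: int | None = None,
) -> None:
    """Write sessions as a delimited spike-event table (one row per spike)."""
    sessions: list[RecordingSession] = []
    for item in records:
        if isinstance(item, NeuronRecord):
            sessions.extend(item.sessions.values())
        else:
            sessions.append(item)
    rows = []
    for s in sessions:
        for t in s.spike_times:
            rows.append((s.neuron_id, s.trial_id, s.protocol.name, float(t)))
        if s.spike_times.size == 0:
            # silent sessions keep a presence row so reading recovers them
            rows.append((s.neuron_id, s.trial_id, s.protocol.name, math.nan))
    frame = pd.DataFrame(rows, columns=SPIKE_COLUMNS)
    with open(path, "w") as fh:
        fh.write(_metadata_header(seed))
        frame.to_csv(fh, sep="\t", index=False, float_format="%.6f")


def read_spike_table(path) -> list[dict]:
    """Read a spike-event table back into per-(neuron, trial, protocol) groups.

    Returns a list of dicts with keys ``neuron_id, trial_id, protocol_name,
    spike_times`` (sorted array).  Malformed rows are reported with their line
    numbers; unsorted times are sorted with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    header_lines = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                header_lines += 1
            else:
                break
    frame = pd.read_csv(path, sep="\t", skiprows=header_lines)
    missing = [c for c in SPIKE_COLUMNS if c not in frame.columns]
    if missing:
        raise SpikeTableFormatError(f"missing column(s): {', '.join(missing)}")
    numeric = pd.to_numeric(frame["spike_time_s"], errors="coerce")
    malformed = frame.index[numeric.isna() & frame["spike_time_s"].notna()]
    for idx in malformed:
        log.warning("line %d: malformed spike time %r — dropped",
                    idx + header_lines + 2, frame.loc[idx, "spike_time_s"])
    frame["spike_time_s"] = numeric
    groups = []
    for (nid, trial, proto), sub in frame.groupby(
            ["neuron_id", "trial_id", "protocol_name"], sort=False):
        times = sub["spike_time_s"].dropna().to_numpy(dtype=float)
        if times.size > 1 and np.any(np.diff(times) < 0):
            warnings.warn(f"unsorted spike times for {nid}/{trial}/{proto}; sorting")
            times = np.sort(times)
        groups.append({"neuron_id": nid, "trial_id": int(trial),
                       "protocol_name": proto, "spike_times": times})
    return groups


def write_field(field_, path, seed: int | None = None) -> None:
    """Export a temperature field as a delimited matrix (time rows × depth
    columns) with a metadata header."""
    with open(path, "w") as fh:
        fh.write(_metadata_header(seed, {"protocol": field_.protocol.name}))
        frame = pd.DataFrame(
            field_.temperatures,
            index=pd.Index(field_.time_grid, name="time_s"),
            columns=[f"{d * 1e6:.0f}um" for d in field_.depth_grid],
        )
        frame.to_csv(fh, sep="\t", float_format="%.4f")


# -- reproduction report ---------------------------------------------------

#: reference values the report juxtaposes with computed ones
_REFERENCE = {
    "thermal_hot_latency_ms": 470.0,
    "thermal_cold_latency_ms": 270.0,
    "recorded_neurons": 37,
    "wdr_retained": 30,
    "heat_responsive_pct": 83.0,
    "heat_and_cold_pct": 57.0,
    "hot_first_spike_ms": 490.0,
    "cold_first_spike_ms": 212.0,
}


def reproduce(config: RunConfig | None = None, n_latency_trials: int = 100) -> pd.DataFrame:
    """Run the full pipeline and juxtapose computed quantities with their
    reference values: thermal threshold-crossing predictions, the fixture
    cohort classification, and Monte-Carlo first-spike latencies."""
    config = config or RunConfig()
    rows: list[dict] = []

    def add(name, computed, reference, tol_pct):
        ok = (abs(computed - reference) <= tol_pct / 100.0 * abs(reference)
              if not math.isnan(computed) else False)
        rows.append({"quantity": name, "computed": round(float(computed), 3),
                     "reference": reference, "tol_pct": tol_pct,
                     "pass": bool(ok)})

    # thermal predictions
    try:
        hot = make_single_stim("hot", 1.0)
        cold = make_single_stim("cold", 1.0)
        f_hot = solve_skin_temperature(hot, config.skin)
        f_cold = solve_skin_temperature(cold, config.skin)
        add("thermal_hot_latency_ms",
            1e3 * threshold_crossing_latency(f_hot, config.skin.nociceptor_depth,
                                             43.0, "heating"),
            _REFERENCE["thermal_hot_latency_ms"], 10.0)
        add("thermal_cold_latency_ms",
            1e3 * threshold_crossing_latency(f_cold, config.skin.nociceptor_depth,
                                             18.0, "cooling"),
            _REFERENCE["thermal_cold_latency_ms"], 15.0)
    except Exception as exc:  # stage-level error entry, partial report
        rows.append({"quantity": "thermal", "computed": math.nan,
                     "reference": math.nan, "tol_pct": math.nan, "pass": False,
                     "error": str(exc)})
        f_hot = f_cold = None

    # cohort classification
    if config.cohort.total > 0:
        try:
            records = generate_cohort(config.cohort, seed=config.seed, sp=config.skin)
            labels = classify_cohort(records)
            summary = cohort_summary(records, labels)
            by = dict(zip(summary["group"], summary["count"]))
            pct = dict(zip(summary["group"], summary["percent"]))
            add("recorded_neurons", by["recorded"], _REFERENCE["recorded_neurons"], 0.0)
            add("wdr_retained", by["WDR"], _REFERENCE["wdr_retained"], 0.0)
            add("heat_responsive_pct", round(pct["heat_responsive_of_WDR"]),
                _REFERENCE["heat_responsive_pct"], 2.0)
            add("heat_and_cold_pct", round(pct["heat_and_cold_of_WDR"]),
                _REFERENCE["heat_and_cold_pct"], 2.0)
        except Exception as exc:
            rows.append({"quantity": "cohort", "computed": math.nan,
                         "reference": math.nan, "tol_pct": math.nan,
                         "pass": False, "error": str(exc)})

    # Monte-Carlo first-spike latencies of the default MHC neuron
    if n_latency_trials > 0 and f_hot is not None:
        params = class_params("MHC")
        rng = np.random.default_rng(config.seed)
        for name, proto, field_, ref in [
            ("hot_first_spike_ms", hot, f_hot, _REFERENCE["hot_first_spike_ms"]),
            ("cold_first_spike_ms", cold, f_cold, _REFERENCE["cold_first_spike_ms"]),
        ]:
            lats = []
            for _ in range(n_latency_trials):
                s = simulate_recording(proto, params, config.skin,
                                       int(rng.integers(0, 2**31 - 1)), field_=field_)
                ev = s.spike_times[s.spike_times > s.protocol_start]
                if ev.size:
                    lats.append(1e3 * (ev[0] - s.protocol_start))
            add(name, float(np.mean(lats)) if lats else math.nan, ref, 10.0)

    return pd.DataFrame(rows)


def write_report(report: pd.DataFrame, config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        fh.write(_metadata_header(config.seed, {"config": config.config_hash()}))
        report.to_csv(fh, sep="\t", index=False)
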