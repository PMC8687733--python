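#!/usr/bin/env python
"""Verify the spike-generator calibration against its summary-statistic targets.

Monte-Carlo estimates (default MHC parameters, fixed base seed) of:
  * mean first-spike latency, hot and cold 1000-ms single stimuli
    (targets 490 / 212 ms);
  * 2-s evoked rate for both modalities (reference 17.2 / 12.4 Hz — the hot
    figure is only partially attainable, see docs/methods.md);
  * 5-s plateau spike counts (hot 52 °C > 100; cold ≤ 15 °C plateau near 25);
  * the expected per-stimulus wind-up profile (rise over stimuli 1→3, slow
    decay toward a few Hz).

Writes results/neuron_calibration.json.
"""

import json
from pathlib import Path

import numpy as np

from wdrtherm.protocols import make_iterative, make_single_stim
from wdrtherm.thermal import SkinThermalParams, solve_skin_temperature
from wdrtherm.wdr_model import (class_params, expected_per_stimulus_rates,
                                simulate_recording)

OUT = Path(__file__).resolve().parents[1] / "results"
N_TRIALS = 500
BASE_SEED = 90000


def mc_latency_and_rate(proto, params, sp, field_):
    lats, rates = [], []
    for k in range(N_TRIALS):
        s = simulate_recording(proto, params, sp, BASE_SEED + k, field_=field_)
        t0 = s.protocol_start
        ev = s.spike_times[s.spike_times > t0]
        if ev.size:
            lats.append(ev[0] - t0)
        rates.append(np.sum((s.spike_times >= t0) & (s.spike_times < t0 + 2.0)) / 2.0)
    lats = np.asarray(lats)
    return (float(lats.mean()), float(lats.std(ddof=1) / np.sqrt(lats.size)),
            float(np.mean(rates)))


def plateau_count(proto, params, sp, n=200):
    field_ = solve_skin_temperature(proto, sp)
    counts = []
    for k in range(n):
        s = simulate_recording(proto, params, sp, BASE_SEED + k, field_=field_)
        t0 = s.protocol_start
        counts.append(np.sum((s.spike_times >= t0) & (s.spike_times < t0 + 5.0)))
    return float(np.mean(counts))


def main() -> None:
    sp = SkinThermalParams()
    params = class_params("MHC")
    payload = {}

    for modality, target in (("hot", 0.490), ("cold", 0.212)):
        proto = make_single_stim(modality, 1.0)
        field_ = solve_skin_temperature(proto, sp)
        mean, sem, rate = mc_latency_and_rate(proto, params, sp, field_)
        print(f"{modality:4s} latency {mean * 1e3:6.1f} ± {sem * 1e3:.1f} ms "
              f"(target {target * 1e3:.0f});  2-s evoked rate {rate:5.1f} Hz")
        payload[f"{modality}_latency_ms"] = round(mean * 1e3, 1)
        payload[f"{modality}_latency_sem_ms"] = round(sem * 1e3, 2)
        payload[f"{modality}_rate_2s_hz"] = round(rate, 1)

    c52 = plateau_count(make_single_stim("hot", 5.0, target=52.0, name="c52"),
                        params, sp)
    c0 = plateau_count(make_single_stim("cold", 5.0, target=0.0, name="c0"),
                       params, sp)
    print(f"5-s plateau counts: 52 °C → {c52:.0f} AP (>100 expected); "
          f"0 °C → {c0:.0f} AP (low saturating response)")
    payload["count_52C_5s"] = round(c52, 1)
    payload["count_0C_5s"] = round(c0, 1)

    for modality in ("hot", "cold"):
        proto = make_iterative(make_single_stim(modality, 1.0), 30, 1.0)
        rates = expected_per_stimulus_rates(proto, params, sp)
        peak = int(np.argmax(rates))
        print(f"{modality:4s} wind-up: stim1 {rates[0]:.1f} Hz, "
              f"peak {rates[peak]:.1f} Hz at stim {peak + 1}, "
              f"end {rates[-1]:.1f} Hz")
        payload[f"{modality}_windup_stim1_hz"] = round(float(rates[0]), 2)
        payload[f"{modality}_windup_peak_hz"] = round(float(rates[peak]), 2)
        payload[f"{modality}_windup_end_hz"] = round(float(rates[-1]), 2)

    OUT.mkdir(exist_ok=True)
    (OUT / "neuron_calibration.json").write_text(json.dumps(payload, indent=2) + "\n")
    print(f"wrote {OUT / 'neuron_calibration.json'}")


if __name__ == "__main__":
    main()
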