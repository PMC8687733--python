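# Methods

`wdrtherm` models the chain from a programmed contact-thermode waveform to
the spike discharge of a spinal wide-dynamic-range (WDR) neuron, and
implements the complete quantification pipeline for such recordings. This
note documents the models, their assumptions, the calibrated parameters, and
the limits of what the synthetic data can show.

## 1. Stimulation protocols

Protocols are ideal piecewise-linear setpoint programs (no overshoot or
device lag is modelled): ramp-and-hold segments from a 30 °C neutral
baseline, constrained to the device envelope (0–60 °C, ramp rates up to
300 °C/s). Four families cover the standard battery:

| family | program | purpose |
|---|---|---|
| single stimulus | 300 °C/s to 52 °C (hot) or 0 °C (cold), held 0.25–1 s | latency, 2-s discharge rate |
| slow ramp | 3 °C/s heating / 4 °C/s cooling, max 7.5 s | activation threshold |
| iterative train | 30 × single stimulus at 1 Hz | facilitation / adaptation |
| response curve | 5-s plateaus at 30/35/40/45/52 °C or 20/15/10/5/0 °C | stimulus–response curve |

Conventions: t = 0 at protocol start; a stimulus onset is the start of the
away-from-baseline ramp; the return ramp is symmetric at 300 °C/s (the
device's capability — nothing measured inside the analysis windows depends
on it); builders append a 2-s post-stimulus observation tail so evoked
windows fit inside the protocol span. The cooling slow-ramp speed is 4 °C/s
(the value consistent with a 30 °C excursion completing in 7.5 s);
it is configurable. A 5-°C-increment response-curve grid is available as a
preset alongside the default per-modality lists.

## 2. Skin heat conduction

The skin is a homogeneous half-space obeying ∂T/∂t = α ∂²T/∂x², with
Dirichlet surface boundary equal to the thermode setpoint (perfect thermal
contact), uniform 30 °C initial condition, and a fixed 30 °C far boundary at
5 mm. This is the simplest model consistent with a surface trace that equals
the programmed waveform and a single "nociceptor depth" parameter (default
150 µm; a 100 µm preset exists). Layering, contact resistance and perfusion
are deliberately omitted — no parameters are available to constrain them —
but the solver accepts arbitrary `SkinThermalParams`, which is the extension
point.

**Numerics.** Crank–Nicolson time stepping (unconditionally stable, second
order), dx = 10 µm, dt = 1 ms, with the constant tridiagonal system factored
once (banded Cholesky). Threshold crossings are refined by linear
interpolation between time samples; a never-crossed threshold returns NaN
rather than raising. Halving dt and dx moves the headline crossing latencies
by < 1 ms; the solver agrees with the closed-form erfc/Duhamel ramp-and-hold
solution to < 0.01 °C on the default grid (tested at < 0.1 °C).

**Calibration.** α is the model's only free scalar. It is fitted by
root-finding on the solver itself so that the hot protocol's 43 °C crossing
at 150 µm is 470 ms, giving α = 9.0008 × 10⁻⁸ m²/s — inside the epidermal
literature range (order 10⁻⁷ m²/s). The cold prediction is then parameter
free: 18 °C at 150 µm is reached at 229 ms.

**The cold crossing is structurally capped.** For a fixed threshold
fraction, step/ramp crossing times scale as 1/α, so the hot/cold crossing
ratio of any shared-diffusivity conduction model is fixed by the threshold
fractions alone — here (43−30)/(52−30) = 0.59 and (30−18)/30 = 0.40, giving
a ratio of 2.05. A reference pair of 470 ms and 270 ms implies a ratio of
1.74, which no choice of α can produce; 270 ms corresponds to a 16.5 °C
crossing (and an "equivalent delta" of 13 °C below baseline, i.e. a 17 °C
target, yields 256 ms). We keep 18 °C as the stated cold target and report
the 229 ms the model actually produces. `analysis/01_calibrate_thermal.py`
prints this decomposition.

## 3. The WDR spike-train generator

The generator is explicitly phenomenological: a rate model calibrated to
summary statistics, not a biophysical one. Temperature at nociceptor depth
T(t) (shared with the thermal model, depth 150 µm) maps to an instantaneous
drive r(t), realised as an inhomogeneous Poisson process.

**Heat pathway (C-fibre-like, absolute coding).** With exposure
a(t) = ∫1[T>θ_h]dt (suprathreshold time, so it accumulates across 1-Hz
repetitions):

    r_hot = PD[ g_h·(T−θ_h)₊ · w_fac(a) · w_ad(a) ] + B·w_fac·w_ad·e^(−(t−t_x)/τ_B)

- θ_h = 43 °C (TRPV1-like); g_h = 2.2 Hz/°C.
- w_fac = 1 + 2.2·(1−e^(−a/0.6 s)): wind-up-like facilitation, saturating
  within a few seconds of suprathreshold exposure.
- w_ad = 0.05 + 0.95·e^(−a/8.12 s): slow adaptation; its time constant is the
  decay constant fitted to the published iterative-train profile, read in
  seconds (the printed millisecond unit is inconsistent with a 30-s decay).
- B·e^(−(t−t_x)/τ_B), B = 80 Hz, τ_B = 0.125 s, at each threshold-crossing
  instant t_x: the stereotypical onset burst. It is forced by the printed
  numbers — a first-spike latency only ~20 ms after the 470-ms thermal
  crossing requires ≳50 Hz of instantaneous rate at crossing, which a pure
  threshold-linear drive (rising from zero) cannot supply.
- PD[·] is a post-discharge envelope: an exponential-forgetting running
  maximum with τ_pd = 1.2 s, letting the sustained discharge outlast the
  stimulus (firing after 52 °C offsets, none after cold).

**Cold pathway (Aδ-like, change-of-temperature coding).** With cold exposure
a_c = ∫1[T<θ_c]dt:

    r_cold = w_adc(a_c) · min( g_s·(θ_c−T)₊ + g_d·(−dT/dt)₊·1[T<θ_c], r_ceil )

- θ_c = 19.8 °C; g_s = 0.9 Hz/°C (static), g_d = 2.5 Hz/(°C/s) (dynamic,
  dominant), r_ceil = 55 Hz.
- The dynamic term is gated below θ_c. Ungated, the cooling rate at depth
  would trigger spikes ~100 ms into any cooling ramp regardless of absolute
  temperature, i.e. the slow-ramp threshold estimate would sit near 29 °C —
  incompatible with a ~20 °C cold threshold. Gating encodes that the
  transducer must be in its active range before rate sensitivity matters.
- w_adc = 0.15 + 0.85·e^(−a_c/0.55 s): fast adaptation (≪ the heat constant),
  leaving a small static floor. The ceiling plus fast adaptation produce the
  low saturating cold response (≈25–30 spikes per 5-s plateau at ≤5 °C)
  against >100 spikes for 52 °C heat.

**Spiking.** rate = min(baseline + drive(t − delay), 150 Hz), thinned from a
homogeneous Poisson proposal, with a 2-ms absolute refractory period; fixed
seeds give identical trains. Conduction delays: heat 17 ms, cold 4 ms
(cold < heat, the Aδ-vs-C ordering; both are "effective" delays absorbing
spike initiation, so they are shorter than literal conduction times).
Baseline rate 0.1 Hz ("little to no" spontaneous activity). A deterministic
mode — first spike at drive onset, then unit crossings of the integrated
rate — is the noiseless high-gain limit used to validate estimators
independently of Poisson scatter.

**Calibration results** (Monte-Carlo, `analysis/02_calibrate_neuron.py`):
mean first-spike latency 491 ± 3 ms hot and 213 ± 1 ms cold (targets
490/212); 5-s counts 112 (52 °C) vs 30 (0 °C); hot iterative profile rising
13 → 28 Hz over stimuli 1–4 then decaying to 4.2 Hz with a fitted group-mean
τ of ≈8.2 s; cold iterative profile non-increasing from 19 Hz.

**What is deliberately not matched.** The reference statistics overdetermine
a single rate model: a 1000-ms hot stimulus reported at 9.5 Hz in its first
second (iterative stim 1) but 17.2 Hz over a 2-s window (34 spikes) places
more spikes after the stimulus than during it, while the 490-ms latency
pins a high onset rate. The calibration prioritises (i) latencies,
(ii) wind-up asymmetry and decay shape, (iii) hot-vs-cold count ratios; the
absolute hot 2-s rate lands at ~11 Hz and iterative stim 1 at ~13 Hz,
between the two incompatible anchors.

**Classes and cohorts.** Class presets zero out pathways: M (mechano-only)
has no thermal gain, MH no cold gains, MHC all; non-nociceptive and
nociceptive-specific units differ in their mechanical flags
(brush/pressure without pinch, and pinch-only, respectively — NS units keep
the heat pathway). The fixture cohort is {5 non-nociceptive, 2 NS, 5 M,
8 MH, 17 MHC} = 37 units, 30 of them WDR, 25/30 heat-responsive (83%),
17/30 heat-and-cold (57%), with no cold-only units by construction. Cohort
parameters are jittered with seeded mean-preserving log-normal noise
(10% CV) on gains, time constants and threshold excursions (jittering the
excursion from 30 °C preserves θ_c < 30 < θ_h). Temperature fields are
solved once per protocol and shared across neurons — transduction depth is
a skin property, not a neuron property.

## 4. Measurements

- **First-spike latency**: first spike strictly after onset; baseline spikes
  never count; silent trials are "undefined", not errors. Spontaneous spikes
  falling between onset and the evoked response do contaminate the
  measurement — as they would in a real recording — which is why the
  generator's delay constants were calibrated against the *measured* mean.
- **Evoked rate**: spike count in [onset, onset+2 s) divided by the window,
  minus the mean baseline rate (left-closed/right-open, no double counting).
- **Ramp threshold**: probe temperature at the first evoked spike of a slow
  ramp. Under the calibrated diffusivity the 150-µm thermal lag on a 3 °C/s
  ramp is ≈3.6 °C (the deficit at depth grows with elapsed time in a
  half-space), so estimates are biased beyond the true transduction
  threshold — above it when heating, below when cooling. The estimator
  itself is validated to <1 °C in the shallow-transduction noiseless limit
  (20 µm, deterministic spikes), and the 150-µm bias is asserted as an
  invariant (estimate ≥ depth threshold under heating).
- **Iterative profile**: per-stimulus baseline-subtracted rates in 1/f-rate
  windows; wind-up index = max(rate of stimuli 1–3)/rate(stim 1), undefined
  for a non-positive first rate; exponential decay A·e^(−t/τ)+c fitted by
  least squares from the profile peak (hot) or stimulus 1 (cold). A fitted τ
  exceeding 10× the protocol duration is reported as asymptote-only. The τ
  of a single 27-point noisy series is identifiable to 10% only for noise up
  to ~1% of the peak rate; the recovery tests state their claims in that
  regime.
- **Response curve**: baseline-corrected spike count (floored at 0) over the
  full 5-s stimulus — the curve uses the whole-stimulus count, not the 2-s
  window.
- **PSTH**: 200-ms left-closed bins over the session; the final bin closes
  on the right so the histogram conserves the spike count.
- **Classification**: mechanical flags decide the primary label
  (innocuous-only → non-nociceptive; pinch-only → nociceptive-specific;
  both → WDR); thermal sub-labels come from evoked responses at the extreme
  fast-onset stimuli (52 °C and 0 °C; the 5-s plateau when available). A
  unit is "responsive" when its evoked rate exceeds
  max(2 Hz, baseline + 3·SE(baseline)) — configurable, since no explicit
  criterion is published. Slow ramps are excluded from detection: fast
  cold adaptation spreads their response too thin for a rate criterion.
- **Statistics**: D'Agostino–Pearson normality gate (α = 0.05) selecting a
  pooled-variance t-test (the printed integer dof n₁+n₂−2 identifies pooled,
  not Welch) or Mann–Whitney; one-way ANOVA with Tukey HSD. Samples below
  the omnibus test's minimum (n < 8) go nonparametric.

## 5. What the synthetic data can and cannot show

The generator reproduces the statistical *structure* the pipeline assumes —
latency scales and their hot/cold asymmetry, facilitation-then-adaptation
under repetition, cold saturation, class composition, Poisson trial
variability with realistic cross-neuron parameter spread. It does not
emulate bursty non-Poisson ISI statistics, receptive-field or
between-animal effects, electrode drift, or spike-sorting errors; passing
recovery tests therefore validates the estimators and the pipeline plumbing,
not the biological fidelity of any parameter value. Real-recording means
and p-values are not reproducible from summaries alone; the pipeline's
statistics are exercised on simulated cohorts of the same group sizes
instead.

## 6. Problem sizes

Default grids (dx = 10 µm over 5 mm, dt = 1 ms) solve a 1-s stimulus in
~0.1 s and the 31-s iterative train in ~1 s; the full 37-neuron × 22-protocol
fixture cohort simulates in ~15 s on one core. Monte-Carlo checks use
200–500 trials per condition; analysis drivers use the recorded group sizes
(21/13 single-stimulus, 14/11 ramps, 10/6 trains, 7 response curves).
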