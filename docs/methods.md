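# Methods

## The instrument being emulated

The target device is a custom electronic nose: seven partially selective MOS
gas sensors in a flow chamber, a pump that alternates clean air and sample
headspace, a microcontroller that extracts scalar features on-board and logs
them to a small EEPROM, and PC-side multivariate statistics on the resulting
"smellprints". A measurement cycle has three phases — baseline purge
(clean-air flush), sampling (odor exposure), purge (recovery) — with the
characterization default of 100 s / 35 s / 100 s at a 15 Hz acquisition rate,
giving 3525 samples per sensor per cycle.

The package replaces the hardware with a simulator and emulates everything
downstream of the sensing element faithfully enough that the full analysis
chain (features → smellprints → PCA/LDA/MANOVA) can be exercised and tested
end to end.

## Response-curve model

A MOS sensor's conductance responds to reducing volatiles roughly as a power
law of concentration and relaxes with first-order kinetics. The simulator
uses the simplest model with those signatures:

* plateau amplitude per sensor:
  `A = Σ_chem s(sensor, chem) · log10(1 + c_chem / LDL_sensor)` volts, where
  `LDL` is the sensor's datasheet lower detection limit (ppm). The log term
  compresses concentration the way MOS sensors do while staying linear near
  zero, and pins the concentration scale to a documented datasheet constant.
* sampling phase: `v(t) = baseline + A·(1 − e^(−t/τ_rise))`;
  purge phase: exponential decay toward baseline with `τ_decay`.
* additive white Gaussian noise (`noise_sd_v`, default 0.02 V), linear drift
  (`drift_v_per_s`, default 2·10⁻⁴ V/s in the onion preset — a slow aging
  term), hard clipping to the 0–5 V supply rails.
* time constants default to τ_rise = 8 s, τ_decay = 15 s. The source device's
  transients were shown but never parametrized; these values put the 35 s
  sampling window at ~98% of plateau, matching the qualitative curve shape.
  They are free parameters of the model.

**Replicate variability.** Real onion bulbs differ in how much volatile they
emit; without that, group separation after area integration would be
trivially perfect and any classification benchmark vacuous. Each simulated
measurement therefore draws one lognormal amplitude factor
(`sample_scale_sigma`, default σ = 0.25) shared by all seven sensors. This
couples the channels (as a common headspace-strength factor does) and puts
the default study's validation accuracy in a realistic ~85–100% band instead
of a degenerate 100%.

**Presets.** The healthy-onion preset carries a background volatile mix; the
sour-skin preset adds the two disease markers (methyl propyl disulfide at
196 ppm, 2-nonanone at 145 ppm — the levels of the 0.5 μL characterization
aliquots). Sensitivities are back-computed from target healthy amplitudes
(0.25–0.8 V, with TGS 826 and SB-AQ8 highest and TGS 813 lowest, mirroring
the observed sensor ranking) so that diseased plateaus are 2.4× healthy on
every sensor, consistent with diseased responses being "more than twice"
healthy ones.

**Randomness.** All randomness derives from one caller seed through
`SeedSequence([seed, stream, sensor_id])` substreams: curves are bit-stable
individually, measurements get independent noise, and a whole experiment is
reproducible from a single integer.

What the simulator deliberately does not model: sensor heater physics,
temperature and humidity response, cross-replicate drift correlation,
chamber fluid dynamics, saturation kinetics beyond first order. Passing
tests therefore demonstrate that the *pipeline* is correct and that the
statistics behave as designed under known conditions — not that a physical
array would achieve any particular accuracy.

## Feature extraction

Per curve: minimum over baseline + sampling (the pre-exposure level, which
is where the minimum falls on a well-behaved curve), maximum and
time-to-maximum over the sampling phase (ties → earliest sample). Features:

* **area** — trapezoid sum `Σ ½[f(t) + f(t+1)]·Δt` over the sampling phase.
  Two grids are supported. `dt_s = 1.0` (default, the firmware's grid):
  f(t) is the native sample at each whole second — a point sample, keeping
  the trapezoid rule's O(Δt²) accuracy — with the final grid point clamped
  to the phase's last sample so an n-second phase contributes exactly n
  intervals (a constant c integrates to c·n). `dt_s = 1/15 s`: plain
  trapezoid over the raw samples, exact for piecewise-linear signals.
* **slope** — `(max − min)/t_max`; a flat curve has slope 0; a rise with
  t_max = 0 is contradictory and raises.
* **relative response** — `(max − min)/min`, undefined for min ≤ 0.

`featurize` computes all three for a measurement. Two paths exist: the
firmware path works on raw signals; the analysis path first applies
**differential baseline correction** (subtract the mean of the last 5 s of
the baseline phase from the whole curve), which removes sensor-to-sensor
offsets before smellprint analysis. After correction the pre-exposure
minimum is ~0, so the relative response is always computed from the
*uncorrected* extrema, and two guards keep the quotients defined on
degraded signals: a raw minimum clipped to 0 V is floored to one A/D count
(5/1023 V — an integer firmware never divides by zero counts), and a noisy
maximum landing on the first sampling sample gets t_max floored to one
sample interval. The standalone `slope`/`relative_response` functions keep
their strict error contracts; the guards live only in the measurement path.

## Firmware emulation choices

The historical device documents totals, not layouts; the following layouts
are this package's own consistent choices.

* **Command string** (12 digits): 1–3 baseline purge s, 4–6 sampling s,
  7–9 purge s, 10 pump speed (0/1), 11 feature code (1 = area,
  2 = relative, 3 = slope, 4 = all), 12 command type (1 record, 2 download,
  3 erase, 4 autorun, 5 forced sampling, 6 forced purging). This covers
  every documented command within 12 digits and round-trips exactly.
* **24-byte record** (little-endian): uint16 serial + 6-byte timestamp
  (year−2000, month, day, hour, minute, second — 1 s resolution, as a
  DS1302 RTC provides) + 1-byte feature code + 7 × uint16 quantized feature
  values + 1-byte additive checksum. Since 21 floats cannot fit in
  24 bytes, an "all features" measurement writes three records (one per
  feature, same timestamp, consecutive serials). The capacity arithmetic is
  independent of the layout: ⌊1 048 576 bits / 8 / 24 B⌋ = 5461 records.
* **Feature quantization**: uint16 with fixed full-scale ranges — area
  0–5·sampling_s V·s (a rail-level signal for the whole phase), slope
  0–5 V/s, relative response 0–50. Deterministic, documented, ≤½ LSB error.
* **State machine**: a recording cycle always runs baseline purge →
  sampling → purge; forced-sampling and forced-purging commands are the
  only phase overrides. The CLI constructs a fresh controller per
  invocation — the record-store file is the only persistent state,
  mirroring the EEPROM being the device's only non-volatile memory.

## Headspace concentrations

`C [ppm] = 10⁶ · V_m·V_l·D / (V_c·MW)` assumes the aliquot evaporates
completely (no vapor-pressure saturation check, no temperature correction)
with V_m = 24.45 L/mol at 25 °C / 1 atm. Constants shipped (MW g/mol,
D kg/L): ethanol 46.07 / 0.789, acetone 58.08 / 0.791, ethyl acetate
88.106 / 0.897, acetonitrile 41.05 / 0.786, methyl propyl disulfide
122.25 / 0.982, 2-nonanone 142.24 / 0.821. These are standard reference
values and reproduce the published characterization concentrations to the
printed integer ppm — except 2-nonanone, whose printed values (145 /
1452 ppm) would require D ≈ 0.845 kg/L, inconsistent with reference
densities (~0.82); the package keeps the reference constant (yielding
141 / 1411 ppm) and documents the discrepancy rather than fitting a
constant to the printed table.

## Statistics

Implemented from definitions (so oracle tests are meaningful), with scipy
providing only the t and F distribution functions; scikit-learn serves as a
secondary cross-check in the test suite, never as the implementation.

* **Smellprints**: sensor-major vectors; 7 values for a single feature, 21
  for all three (per-sensor triples ordered area, slope, relative).
* **PCA**: covariance of mean-centered data (no autoscaling by default —
  an `autoscale` flag exists; the feature scales here are commensurate),
  `eigh` decomposition, eigenvalue-descending order, sign fixed by making
  each component's largest-magnitude loading positive.
* **LDA** (two classes): `w = Σ̂⁻¹(μ₁ − μ₀)` with the pooled within-class
  covariance `Σ̂ = S_w/(n−2)`; threshold `½·wᵀ(μ₀ + μ₁) + log(π₀/π₁)` with
  priors from training proportions. If `Σ̂` is singular or has condition
  number > 10¹², a ridge `10⁻⁸·tr(Σ̂)/p` is added (21 features against 48
  training points can be ill-conditioned).
* **Wilks' Λ** = det(E)/det(E+H) from within-/between-group cross-product
  matrices; Rao's F approximation for (df₁, df₂) and the p-value; for
  p = 1, two groups it reduces exactly to Λ = 1/(1 + t²/(n−2)). A singular
  E raises with guidance to reduce the number of variables. One-way MANOVA
  on group labels only — no factorial designs.
* **Two-sample t**: pooled variance, two-sided; no multiple-testing
  correction (tests are reported individually).
* **Rounding**: all rates kept unrounded internally; the report layer
  rounds to one decimal, half away from zero (so 89.583 prints as 89.6).
  Note 2/48 = 4.1667% prints as 4.2%.

## Default study conditions

The synthetic disease study mirrors the proof-of-concept design: 2 groups ×
8 bulbs × 3 measurements/day × 2 days = 96 measurements, characterization
cycle (100/35/100 s), differential baseline correction, area smellprints
(area is the feature the original analysis used; the others are
selectable), a seeded random half/half train–validation split (48/48), LDA,
and a validation confusion table. With the default presets this achieves
>80% validation accuracy for every seed tested and degrades monotonically
(on average) as sensor noise grows — the pipeline-level sanity checks in
the test suite.

## Known limitations

* The simulator is qualitative: amplitudes, time constants and noise are
  plausible, not calibrated to any physical sensor.
* The published classification result on real onions cannot be reproduced —
  no raw data exists in the public record; the package reproduces the
  confusion-table arithmetic and demonstrates the pipeline on synthetic
  data instead.
* The 24-byte record and 12-digit command layouts are reconstructions
  consistent with the documented totals, not byte-level copies of the
  original firmware.
* MANOVA is one-way only; LDA is strictly two-class.
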