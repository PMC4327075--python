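# enose

Emulation and analysis toolkit for a seven-sensor metal-oxide (MOS) gas-sensor
array — an "electronic nose" — built to detect sour skin (*Burkholderia
cepacia*) infection in stored onions from the volatiles in their headspace.

The package is aimed at people developing or teaching e-nose signal-processing
pipelines who do not have the hardware on the bench: it re-creates the whole
measurement chain in software, from the three-phase sampling cycle down to the
instrument's 24-byte storage records, and carries the smellprint statistics
through to a classification result.

## What it implements

**Sensor array & cycle** (`enose.device`): the seven-sensor array (five Figaro
TGS-series SnO2 sensors, an FIS SB-11A and a WO3 SB-AQ8) with their datasheet
detection limits, 15 Hz acquisition on a 0–5 V / 10-bit circuit, and the
baseline-purge → sampling → purge cycle (characterization default:
100 s / 35 s / 100 s, high pump speed).

**Simulator** (`enose.simulator`): synthetic response curves with a
first-order transient — during sampling the deterministic signal is
`baseline + A·(1 − e^(−t/τ_rise))` with plateau amplitude
`A = Σ_chem s·log10(1 + c/LDL)`, exponential recovery during the purge, plus
white noise, linear drift, a per-measurement lognormal amplitude factor
(replicate variability) and clipping to the 0–5 V rails. Presets model
healthy and sour-skin-infected onion headspace (diseased responses 2.4×
healthy) and the 2 groups × 8 bulbs × 3 sessions/day × 2 days = 96-measurement
study design.

**Firmware emulation** (`enose.controller`): the 12-digit command protocol,
the cycle state machine with forced-sampling/forced-purging overrides, and the
1024 Kbit record store holding 5461 records of 24 bytes each (serial,
1 s-resolution timestamp, one quantized feature per sensor, checksum).

**Feature extraction** (`enose.features`): per-curve minimum, maximum and
time-to-maximum; area under the sampling phase by the trapezoidal rule
`A(i) = Σ_t ½[f_i(t) + f_i(t+1)]·Δt` (Δt = 1 s by default, native 1/15 s
optionally); slope `[max(i) − min(i)]/t`; relative response
`R(i) = [max(i) − min(i)]/min(i)`; and differential baseline correction
(subtracting the pre-exposure baseline mean from the whole curve).

**Headspace chemistry** (`enose.headspace`): theoretical concentration of a
fully evaporated liquid aliquot, `C [ppm] = 10⁶·V_m·V_l·D/(V_c·MW)` with
V_m = 24.45 L/mol at 25 °C, and a constants table for ethanol, acetone, ethyl
acetate, acetonitrile, methyl propyl disulfide and 2-nonanone.

**Statistics** (`enose.analysis`): smellprint assembly (sensor-major feature
vectors), covariance PCA, two-class Fisher LDA with a pooled-covariance
discriminant and log-prior threshold, random half/half train–validation
splits, confusion-table rates, one-way MANOVA via Wilks' Λ = det(E)/det(E+H)
with Rao's F approximation, and pooled two-sample t-tests. All implemented
from their definitions and cross-checked against independent oracles in the
test suite.

**CLI** (`enose`): `record`, `download`, `erase`, `autorun`, `force-sample`,
`force-purge`, `conc`, `pca`, `lda`, `manova`, `simulate` — a command-line
replacement for the instrument's GUI. Every stochastic command takes
`--seed` and is bit-reproducible.

## Worked example

Theoretical headspace concentration of 20 μL ethanol evaporated in a 0.5 L
jar:

```console
$ enose conc ethanol 20e-6 0.5
ethanol: 16749 ppm
```

(10⁶ × 24.45 L/mol × 20·10⁻⁶ L × 789 g/L / (0.5 L × 46.07 g/mol) ≈ 16 749
parts per million by mole.)

Full synthetic disease-detection study — simulate 96 measurements (48
healthy, 48 sour-skin), baseline-correct, build area smellprints, split
half/half, fit LDA on the training half and score the validation half:

```console
$ enose simulate --seed 1
measurements: 96 (train 48, validation 48)
PC1+PC2 explained variance: 100.0%
                      actual  healthy  actual sour_skin
   predicted healthy               22                1
 predicted sour_skin                2               23
correct classification rate: 93.8%
false positive rate: 4.2%
false negative rate: 2.1%
```

The confusion table counts validation measurements (rows = predicted class,
columns = actual class); the three rates are percentages of the 48
validation samples and sum to 100%. Accuracy varies a few points with the
seed because each virtual onion carries its own headspace strength.

Driving the virtual instrument itself:

```console
$ enose record --store demo.store --seed 1   # one 235 s cycle, 3 records
$ enose download --store demo.store         # tab-delimited txt log
$ enose erase --store demo.store
```

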