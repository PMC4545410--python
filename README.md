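# growthspec

Spectral and regularity analysis of growth-increment time series from
bioarcheological remains.

Bone, teeth and hair grow incrementally, and each increment records the
state of the organism's metabolism: hair-scale repeat intervals, enamel
striae spacings, growth lines in bone, and isotope ratios (e.g. δD)
measured at fixed steps along a hair shaft all form time series indexed
along the growth axis. `growthspec` is a toolkit for the time-series
statistics such records support — aimed at bioarcheologists, forensic
anthropologists and sclerochronologists who want periodicities, growth
rates, frequency-band power comparisons and regularity measures from a
single column of equally spaced measurements.

## What it computes

**Preprocessing.** A record `Y_1..Y_N` with physical step Δt is
detrended by OLS (`Y ≈ b + m·t`) and divided by its sample SD, giving a
zero-mean, unit-variance series whose spectral shape is dimensionless.
Gap-separated segments are pooled end to end.

**Growth rate.** An annual cycle fitted along the growth axis at
frequency `f` cycles per physical unit (from the trend + sinusoid model
`y = b + m·x + A·sin(ωx + φ)`, `f = ω/2π`) pins the growth rate:

    growth rate = 1 / (f · period)            [units per year]

A spectral peak at `f_p` cycles/observation then has period

    period = Δt / (f_p · g_w)   weeks,   g_w = growth rate per week,

and the Nyquist folding frequency `ω_N = 0.5/Δt` bounds what is
observable; peaks near aliases `λ + 2kω_N` of the daily cycle are
flagged rather than trusted.

**Spectral estimation.** The periodogram on the Fourier grid
`λ_j = 2πj/N`,

    I(λ_j) = |Σ_t Y(t) e^{-iλ_j t}|² / (2πN),

smoothed by a symmetric unit-sum window (Daniell by default) into the
consistent density estimate `f̂(λ)`, with effective degrees of freedom
`r = 2/Σw²` per ordinate.

**Band power inference.** For a band `[λ_lo, λ_hi)`,

    AUC = Σ 2 f̂(λ_j) Δλ,    Var = Σ 4 f̂²(λ_j) Δλ²,    Δλ = 2π/N,

modelled as `AUC ≈ c·χ²_R` by moment matching (`c = Var/2E`,
`R = 2E²/Var`): chi-square confidence intervals, an F-test of the LF/HF
ratio (`F_{R₂,R₃}` with non-integer df), bandwidth bias adjustment, and
a normal-reference t-test between two records' band powers.

**Quiescence (telogen) model.** Hair dormancy of AQ weeks per 52-week
year reduces observed annual growth G to

    G′ = (52 − AQ)/(52 − Q) · G,   AQ = 52 − (G′/G)(52 − Q),

so a measured growth-rate reduction converts into an inferred augmented
quiescence (reference human values: G = 16 cm/yr, Q = 13 weeks). A
masked-sinusoid simulator produces the weekly record such dormancy
leaves behind.

**Approximate entropy.** Pincus ApEn(m, r, N) with self-matches,
Chebyshev distance and SD-relative tolerance — small values flag
pathologically regular dynamics.

## Worked example

Simulate a mammoth-hair-like δD record (trend + annual sinusoid + noise,
sampled every 0.3 cm) and run the full pipeline:

```sh
growthspec simulate --kind mammoth_like --n 100 --delta-t 0.3 \
    --noise-sd 2.0 --seed 7 --out hair.csv
growthspec pipeline hair.csv --delta-t 0.3
```

Selected report fields (seed 7):

```json
"sinusoid_fit": {"slope": -0.804178, "amplitude": 8.17666,
                 "angular_freq": 0.205029,
                 "freq_cycles_per_unit": 0.0326313},
"growth_rate": {"per_year": 30.6454, "per_week": 0.589335},
"band_power": {"lf": {"auc": 0.383822,
                      "ci": {"sided": "two", "lower": 0.231555,
                             "upper": 0.57394}}},
"lf_hf": {"ratio": 0.792219, "p_two": 0.466865},
"apen": {"value": 0.0793485, "n": 100, "m": 2, "r_fraction": 0.7}
```

Reading it: the fitted annual cycle at 0.0326 cycles/cm implies
1/0.0326 ≈ 30.6 cm of growth per year (the generator's true model,
ω = 0.196 rad/cm, corresponds to 32.1 cm/yr; this noisy draw lands 4%
low). The low-frequency band 0.07–0.27 cycles/obs carries an estimated
38% of the standardized record's variance, with a 95% chi-square CI of
[0.23, 0.57]; the LF/HF ratio does not differ detectably from 1
(p = 0.47). ApEn ≈ 0.08 is small because a noiseless sinusoid+trend
backbone dominates this synthetic record — real hair records score much
higher.

Every stage is also available separately (`growthspec preprocess`,
`spectrum`, `bandpower`, `growth`, `quiescence`, `apen`), and the same
functionality is importable:

```python
import growthspec as gs
gs.augmented_quiescence(16, 12, 13)   # 22.75 weeks of dormancy
res = gs.SpectralModel(series).fit()  # periodogram + Daniell smoothing
res.band_power(0.07, 0.27).ci()
```

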