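# Methods

This note documents the statistical model behind `growthspec`, the
defaults and numerical choices, what the synthetic generators do and do
not emulate, and the known limits of the approximations.

## The data model

The unit of analysis is a single column of measurements at equal steps
along a growth axis (`ForensicSeries`): isotope ratios per fixed length
of hair, repeat intervals between growth marks, enamel-line spacings.
Two time scales coexist: the *observation* index `t = 1..N` (the
spectral axis) and the *physical* coordinate `x = t·Δt`. Intrinsically
discrete records (one value per growth line) use Δt = 1.

Spectral analysis assumes the series is stationary and Gaussian after
preprocessing. Preprocessing removes an OLS line on the observation
index and divides by the sample SD (N−1 denominator; conventional for
the inferential statistics downstream — the choice only rescales the
spectrum by (N−1)/N). When an annual cycle visibly dominates, the
trend + sinusoid model is fitted first and its residuals are
standardized, so the annual line does not leak across the whole
spectrum. Records broken by missing stretches are pooled end to end
with no taper at the joins; a warning is logged when over 20% of the
length sits in segments shorter than 10 observations, where join
artifacts become appreciable. Detrending is applied to the pooled
series, not per segment.

## Trend + annual sinusoid

`y = b + m·x + A·sin(ωx + φ)` is linear in `(b, m, A cos φ, A sin φ)`
for fixed ω, so the fit profiles ω over a 200-point geometric grid from
one cycle per four record lengths up to the angular Nyquist π/Δt,
solves the linear subproblem at each, and polishes the five best
candidates with Levenberg–Marquardt. The sign ambiguities
`(A, ω, φ) ↔ (−A, ω, φ+π) ↔ (A, −ω, π−φ)` are canonicalized to
`A ≥ 0, ω > 0, φ ∈ [0, 2π)`; a fit whose RSS exceeds the trend-only RSS
is rejected as non-converged (the best partial fit is attached to the
error).

Identifiability depends on how many cycles the record spans. With ~3
cycles in view (N = 100, Δt = 1, ω ≈ 0.2) all parameters are recovered
within 5% per realization at noise SD equal to 10% of the amplitude.
With a sub-cycle span (N = 100, Δt = 0.3, period ≈ 32 length units) the
trend and sinusoid are nearly collinear: the asymptotic relative SE of
the slope alone is ~5%, so single-fit scatter necessarily exceeds a 5%
band, while the estimator remains unbiased (mean over 20 seeds within
0.5% of truth). The tests distinguish these two regimes explicitly.

## Spectral estimation

Periodogram on the Fourier grid `λ_j = 2πj/N`, `j = 1..⌊N/2⌋`
(cycles/observation axis `j/N`; the zero frequency — the mean — is
excluded). Computed by FFT; the unit shift from `t = 0..N−1` to
`1..N` changes only the phase. With the Nyquist ordinate (even N)
weighted 1 instead of 2, the factor-2 sum over the grid equals the
population variance of the zero-mean input exactly (discrete Parseval),
and this identity is tested at 1e-9.

The density estimate is a symmetric unit-sum moving average of the
periodogram. Default window: Daniell with half-width `⌈√N/4⌉` — the
simplest window with an exact EDF formula (`r = 2(2h+1)`), wide enough
to grow with N for consistency, narrow enough that adjacent smoothed
ordinates stay nearly independent. A modified Daniell (half-weighted
endpoints) is also provided. Edges are handled by half-sample symmetric
reflection of the periodogram at both grid ends: this preserves
constants and conserves the plain factor-2 sum exactly, which is what
"smoothing does not create or destroy power" means on this finite grid.
Whole-sample reflection about the Nyquist ordinate would match the
underlying spectral symmetry slightly better but does not conserve
area; conservation was preferred because band powers are the
inferential currency.

Peak detection reports local maxima of the density above a prominence
threshold (fraction of the maximum), ordered by height; the first grid
ordinate is excluded unless it dominates the spectrum outright.

## Band-power inference

For a half-open band `[λ_lo, λ_hi)` on the cyclic grid:
`AUC = Σ 2 f̂ Δλ`, `Var = Σ 4 f̂² Δλ²` with `Δλ = 2π/N`. The variance
formula is evaluated on the smoothed density, and treats ordinates as
independent — an approximation whose limits are listed below. The AUC,
a weighted sum of chi-squares, is modelled as a single `c·χ²_R` by
matching its first two moments: `c = Var/(2E)`, `R = 2E²/Var` (df
non-integer; all chi-square and F tail functions are evaluated
continuously).

Confidence intervals are equal-tail chi-square intervals
`[c·q_{α/2}, c·q_{1−α/2}]`. For a standardized series total power is
exactly 1, so when the two-sided upper limit exceeds 1 the interval
switches to the one-sided `[c·q_α, 1]` — an upper bound beyond the
physical maximum carries no information.

The LF/HF ratio of two disjoint bands is distributed as
`(c₂R₂/c₃R₃)·F_{R₂,R₃}`; under the null of equal band power that scale
is 1, so the observed ratio is referred directly to `F_{R₂,R₃}` and the
two-sided p doubles the smaller tail. Comparing bands of unequal width
biases the wider band; the adjustment multiplies AUC by
`target_width/actual_width` (variance by its square). Two records'
band powers are compared by `t = ΔAUC/√(SE₁²+SE₂²)` against the
standard normal, the asymptotic reference for these SEs.

Calibration of the F approximation was checked by simulation: with two
bands of equal Fourier-ordinate count, separated by more than the
smoothing span and clear of the folding ordinate at 0.5 (which is χ²₁,
not χ²₂), one-sided null p-values from 2,000 white-noise replicates at
N = 1024 are uniform by Kolmogorov–Smirnov. The approximation visibly
degrades when the two bands share an edge (the window straddles the
boundary and correlates the AUCs), when band ordinate counts are
unequal (the expected ratio shifts from 1), or when a band touches the
Nyquist ordinate; users comparing such bands should treat borderline
p-values with caution.

## Quiescence (telogen) model

Assumptions: growth while growing is constant and unaffected by the
preceding dormancy; metabolism continues through dormancy but leaves no
record in the hair. Then observed annual growth scales with the number
of growing weeks, giving `G′ = (52−AQ)/(52−Q)·G` and its exact inverse
`AQ = 52 − (G′/G)(52−Q)`. Defaults: G = 16 cm/yr, Q = 13 weeks (normal
human scalp hair); the year is exactly 52 weeks throughout the package.
The formulas are exact algebra and are property-tested as inverses at
1e-9. The model deliberately does not couple dormancy to a reduced
instantaneous growth rate — that would require a different model.

The simulator builds 52 weekly increments `mean·(1 + a·cos)` (mean =
nominal rate/52, amplitude fraction `a ≤ 1` so increments stay
nonnegative) and masks one contiguous block of quiescent weeks, by
default centred on the trough (dormancy in the slow-growth season). The
observed record is the gap-free concatenation of growing weeks: 52−Q
values whose periodic extension has fundamental period 52−Q — periodic
but visibly not a sinusoid. With a flat profile a 20 cm/yr hair with 13
dormant weeks shows 20·39/52 = 15 cm; observing ~16 cm requires a
nonzero seasonal amplitude, so the amplitude is exposed as a parameter
with a bisection calibrator (`calibrate_amplitude`) rather than a
hard-coded value (a ≈ 0.22 reproduces 16.0). Block placement at the
start of the year is available as the alternative framing of dormancy
split across the year.

## Approximate entropy

Classic Pincus estimator: `Φ^m − Φ^{m+1}` with
`Φ^m = (N−m+1)^{-1} Σ_i log C_i^m(r)`, counts including the self-match
(all logs finite on short records), Chebyshev distance between embedded
vectors, natural log. Tolerance is a fraction of the whole-series
sample SD computed before embedding, which makes the statistic exactly
invariant under affine rescaling. Defaults m = 2 and r = 0.7·SD — the
midpoint of the 0.6–0.8 range in routine use; the sweep helper
evaluates a tolerance grid for discrimination tuning. Constant series
(zero peak-to-peak range) are defined as ApEn = 0 with a warning. The
implementation is vectorized O(N²m) and tested for exact agreement with
a literal loop oracle for N ≤ 30.

## Synthetic generators

`synthetic` fixtures exist because no real accession of this data type
is publicly deposited. Defaults are the documented study conditions:

* `mammoth_like` — `−158 − 0.727x + 8.69·sin(−0.196x + 3.98)` plus
  Gaussian noise (default SD 2.0 ‰, roughly a quarter of the seasonal
  amplitude), the published δD model along a mammoth hair at Δt =
  0.3 cm. The printed negative angular frequency is kept verbatim in
  the generator; the fitter reports its magnitude with the phase
  canonicalized.
* `ar1` — stationary AR(1), closed-form spectrum
  `σ²/(2π(1−2φcosλ+φ²))`, initialized from the stationary marginal
  plus a 200-step burn-in.
* `two_tone` — sinusoids at 0.15 and 0.42 cycles/obs, amplitude ratio
  2:1 (power ratio 4:1), small additive noise.
* `regularity_pair` — a unit-variance sampled sine and white noise of
  matched length for ApEn ordering tests.
* `masked_growth` — the quiescent-hair weekly record.

Every generator returns a ground-truth sidecar and is bit-reproducible
from its seed. What these fixtures do *not* emulate: measurement-error
autocorrelation, nonstationary seasonal amplitude, irregular sampling,
diagenesis of the chemical signal, or the integer-day quantization of
real repeat intervals — passing tests demonstrate the estimators work
under the stated model, not that real archived hair satisfies it.

## Problem sizes and test design

Stochastic checks use sizes at which the targeted property is
informative while the whole suite stays interactive: Parseval and
DFT-oracle equivalence at N ≤ 500; F-null calibration at N = 1024 ×
2,000 replicates; ApEn ordering over 50 seeded replicate pairs at
N = 200 (pass requires ≥ 95%); CI coverage over 4,000 chi-square draws.
All random tests are seeded; hypothesis properties run derandomized.

## Known limitations

* The band-power variance treats smoothed ordinates as independent;
  cross-covariance from overlapping smoothing spans is not corrected.
* No tapering, prewhitening, multitaper or autoregressive spectral
  estimation; no irregular-sampling (Lomb–Scargle) support; records
  must be equally spaced with gaps encoded as segments.
* The alias report flags candidates (e.g. whether a ~1.2-week peak
  could be a folded daily cycle); it cannot decide between a real peak
  and its alias from one record.
* Fuzzy ApEn, sample entropy and Hilbert–Huang decompositions are out
  of scope.
* The quiescence model is algebraic; it infers dormancy only relative
  to an assumed reference growth rate and quiescence.
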