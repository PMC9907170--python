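# Methods

## Scope and model of the data

`phenoplate` analyzes micro-cultivation growth screens: yeast cultures in
96-well plates (~200 µl per well) read by a plate reader at 650 nm on a
fixed cycle (default 250 cycles × 10 min, ~42 h). The analysis chain is

1. blank correction (per-cycle mean of medium-only wells),
2. detector-nonlinearity calibration to true 1-cm-path OD,
3. smoothing (running-median despike, then centered moving average),
4. log-ratio transform `L(t) = ln(OD_t / OD_i)`,
5. trait extraction (λ, μ, κ) and the dynamic measuring point ф,
6. cumulative-growth statistics AUC, ΔAUC, and empty-vector
   standardization,
7. comparison statistics (Fisher's LSD vs control, Tukey HSD letters).

## OD calibration

Plate readers undercount dense cultures: the mapping from recorded to
true OD is nonlinear and instrument-specific. We model it as a
zero-intercept quartic `y = c4·x⁴ + c3·x³ + c2·x² + c1·x` fitted by
ordinary least squares on the monomial basis to a dilution series whose
"true" ODs follow from the dilution factors (the least-concentrated
point is the anchor, assumed in the linear regime; its true OD is
user-supplied because it cannot be inferred from the series itself).
The zero intercept is structural — a blank-corrected reading of zero
must map to zero. Degree 4 is fixed; no automatic degree selection.
The fitted polynomial must be strictly increasing on its domain
(checked on a 2001-point grid) or the fit is rejected, since inversion
and the simulator both rely on monotonicity. Readings above the fitted
domain are extrapolated with a recorded warning rather than rejected,
because growth curves can slightly exceed the calibration series.
Inversion uses Brent root finding on the monotone domain (tolerance
1e-10); `apply ∘ invert` and `invert ∘ apply` are identities to better
than 1e-8 over the valid range.

A published quartic for one instrument (`PUBLISHED_CALIBRATION`) is
packaged both as a usable default and as the reference for regression
tests. Calibrations carry an `instrument_id`; mixing instruments
requires an explicit override.

## Smoothing and the log-ratio transform

Micro-cultures aggregate and sediment, producing isolated spikes in
individual readings. The filter chain is a running median (window 5)
followed by a centered moving average (window 3), both configurable,
with shrunken symmetric windows at the ends so output length equals
input length. Constants and interior points of linear ramps pass
through unchanged, which keeps the filters near-idempotent on smooth
data.

`OD_i` is the mean of the first 3 corrected readings (configurable),
floored at 1e-4 OD; the same floor applies to every reading before
division so blank-level noise cannot produce −∞. An all-floor series is
flagged degenerate and carries `L ≡ 0`.

## Traits and the dynamic measuring point

The traits are nonparametric: μ is the maximum sliding-window OLS slope
of `L(t)` (default window 5 points; earliest window on ties; floored at
0), κ the maximum smoothed corrected OD, and λ the tangent construction —
the time where the maximal-slope tangent crosses `L = 0`, floored at 0.
No growth model is fitted to the data; the Gompertz form lives only in
the simulator.

ф is computed once per genotype on the mean curve of that genotype's
reference condition (untreated for toxic compounds, maximal
supplementation for growth-requiring nutrients): scanning window slopes
after the time of maximal rate, ф is the first time — linearly
interpolated between adjacent window centers — where the slope falls
below 5% of μ (fraction configurable). If the rate never falls below
threshold within the observation window, ф snaps to the last time with
`reached = False` and a warning row. An additive shift ф₊ₜ (capped at
the end of the window) recovers slow-growing cultures at the cost of
underestimating ΔAUC, since the control contributes little once
plateaued. A global-ф mode (control genotype's ф for all lines) exists
for sensitivity analysis.

On a noiseless logistic reference (N₀ = 0.05, K = 5, r = 0.01/min,
10-min sampling), the per-capita rate at the detected ф is 4.97% of μ
and density is 95.1% of K — the analytic consequence of the 5% rule for
a logistic with N₀ ≪ K is density at 95% of K, and the windowed slope
estimator crosses the threshold slightly after the instantaneous slope
does, so the rule is satisfied conservatively.

AUC is the trapezoidal integral of `L(t)` on [0, ф], final partial
interval interpolated linearly, negative log-ratios clipped to 0 by
default (cumulative growth cannot be negative in this readout;
configurable off). ΔAUC = AUC_treated / AUC_control at the same ф;
rel_auc_vs_empty standardizes each condition's mean ΔAUC to the
empty-vector control's. A control AUC below 1e-6·ф raises rather than
returning an unstable ratio.

## Dose–response and concentration selection

Per-concentration means of ΔAUC form the dose–response table (anchored
at ΔAUC = 1 for the untreated control; promoting series renormalized to
the maximal supplementation). The 4PL
`ΔAUC(c) = bottom + (top − bottom)/(1 + (c/ec50)^hill)` is fitted in
untransformed concentration (no log(c) singularity at c = 0; the zero
dose evaluates to the limit), with ec50 and hill estimated on the log
scale for positivity, multi-start over hill ∈ {0.5, 1, 2, 4} × a
5-point geometric ec50 grid, best RSS wins, iteration cap 500. Fewer
than 4 distinct doses fixes top = 1 (3-parameter fit). A span
|top − bottom| < 0.05 is a flat response: flagged, no EC50.

"Commencement of pronounced growth inhibition" is operationalized as
the tested doses whose fitted response is nearest 0.75 and 0.5
(configurable targets): these sit on the upper shoulder / linear range
of the curve, where resolution between lines is highest. Duplicate
picks nudge to the adjacent tested dose; if everything tested is
already saturating (fitted response < 0.1), the two smallest tested
doses are returned. Recommendations are invariant to unit rescaling.

## Spheroplast bursting kinetics

Osmotic-shock traces (ΔOD650, 0–5 s at 0.1 s) are fitted with
`y(t) = A1·e^(−t/τ1) + A2·e^(−t/τ2)`, unconstrained Levenberg–Marquardt
with multi-start (τ1 ∈ {0.05, 0.1, 0.2, 0.5} s; τ2 ∈ {1, 3, 10, −10} s;
amplitudes by linear solve at fixed taus). The slow term may have
negative amplitude and/or a negative time constant (a slow drift, as in
the packaged empty-vector benchmark); the fast phase must not. After
convergence, the term with the smallest positive time constant is
labeled (A1, τ1) — this operational rule makes the permeability ranking
deterministic — except that a vanishing-amplitude term (|A| ≤ 1e-6 of
the larger amplitude) cannot claim the label, which keeps the nested
single-exponential case well-posed. Ranking is by descending A1, ties
toward smaller τ1. Traces are assumed pre-baselined; an optional flag
subtracts the final 0.5 s mean.

## Comparison statistics

One-way ANOVA supplies the pooled MSE. Fisher's LSD compares each
genotype only against the designated control (as screen bar charts are
drawn), two-sided on N − k df, marks `*` (P < 0.05) and `**`
(P < 0.01). Tukey HSD covers all pairs through the studentized-range
distribution with the Tukey–Kramer standard error for unbalanced
groups; the compact letter display uses insert-and-absorb (start from
one letter containing all groups, split every letter containing a
significant pair, absorb subset letters), which guarantees that two
groups share a letter iff their pairwise Tukey p ≥ α. Experimental runs
are pooled, not blocked. Under a 2000-instance null simulation the LSD
per-comparison type-I error at α = 0.05 falls inside [0.04, 0.06].

## The synthetic plate generator

The generator emulates the study conditions end to end so the pipeline
is testable without instrument data. True curves follow the Zwietering
parameterization of the Gompertz model,
`L(t) = A·exp(−exp((μ·e/A)(λ − t) + 1))`, chosen because its parameters
are exactly the tangent-construction lag, the maximal log-ratio slope,
and the asymptotic log-ratio — generator parameters double as the
ground truth for recovery tests. Defaults: od_init 0.05, λ 300 min,
μ 0.01/min, A 4 (κ ≈ 2.7 OD), 10-min cycles × 250, replicate-level
trait jitter CV 2%, recorded-OD noise SD 0.003, blank offset 0.08,
sedimentation spikes with probability 0.002 per reading — values chosen
as typical for shaken yeast micro-cultures where no published value
exists.

Recorded readings are built by pushing true OD through the *inverse*
calibration polynomial and adding blank offset plus Gaussian noise on
the recorded scale (detector noise lives there, not on the true scale) —
exactly the compression the analysis is meant to undo. Treatments act
phenomenologically on traits (toxic: Hill-saturating lag extension and
rate/yield suppression; nutrient: saturating recovery of rate and
yield; freeze–thaw: survivorship sⁿ scales the viable inoculum, traits
untouched, so the apparent lag extends emergently by ≈ ln(1/sⁿ)/μ for
detection thresholds inside the exponential window). Everything is
deterministic given a seed.

One analytic subtlety: the Gompertz log-ratio is not exactly zero at
t = 0, and the observed curve is normalized by the initial OD, so the
tangent lag of the *observed* curve is exactly λ + L(0)/μ
(`WellSimSpec.effective_lag`). For realistic parameters the correction
is negligible; for short-lag/slow-rate corners of parameter space it is
a property of the log-ratio definition, not estimator error, and
recovery tests compare against the effective lag.

What the generator does not emulate: plate-position effects, drift in
the blank, diauxie and death phases, well-to-well optical cross-talk,
and run-level batch structure. Passing recovery tests therefore
demonstrates correctness of the estimators under the stated noise
model, not robustness to every artifact of real instruments.

## Numerical and problem-size choices

Trait-recovery grid tests sample at 2-min resolution so the 5-point
slope window resolves the fastest configured curves (A = 1 with
μ = 0.03/min rises in ~30 min; 10-min cycles cannot resolve that for
any estimator); end-to-end tests use the default 10-min cycles with
realistic yeast parameters. κ recovery is asserted only over horizons
that reach the plateau (λ + 8A/μ). Simulated screens in the test suite
use 2–3 genotypes × 2–3 doses × 3 replicates, which keeps the whole
suite under a minute while exercising every pipeline branch; the
2000-instance LSD null simulation dominates the statistics tests and
runs in a few seconds.

## Known limitations

- The ф crossing interpolates between window centers; an instrument
  that snaps to cycle boundaries would differ by at most one cycle.
- The LSD is intentionally unadjusted for multiplicity (its historical
  definition); the Tukey letters are the multiplicity-safe view.
- Dose–response targets {0.75, 0.5} are an operationalization of a
  qualitative criterion and are labeled as such in output.
- No correction for plate-position effects is attempted.
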