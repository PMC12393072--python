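# Methods

This note records the models behind `durinose`, the defaults that matter,
and the design decisions taken where the measurement procedure left choices
open.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Sensor signal model

Each MOS channel is simulated as

```
y(t) = baseline + drift·t + β_T (T(t) − T_ref) + β_H (RH(t) − H_ref)
       + odor(t) + warmup(t) + ε(t),     ε ~ N(0, σ²) i.i.d. per second
```

* **Odor** during a sampling phase is a linear concentration ramp, so the
  noise-free reading slope equals the configured per-sensor emission rate
  (a.u./s) — the quantity the pipeline estimates.  A saturating response
  is deliberately not modelled: the slope is the statistic of interest and
  a linear ramp makes its ground truth exact.
* **Warm-up transient**: prototype sampling phases carry an additive
  `A·exp(−t/τ)` term with defaults τ = 20 s, A = 5 a.u., sized so the first
  ~70 s are visibly contaminated.  This is the rationale for the device's
  discard-70/keep-30 trimming rule; τ and A are modelling choices, not
  measured values.
* **Rest phases** relax the accumulated odor signal back to baseline with a
  fixed 30-s time constant (cosmetic; nothing downstream uses rest data).
* **Environment**: the default profile is a sinusoidal diel cycle,
  T = 25 ± 5 °C and RH = 60 ± 15 %, with humidity lagging temperature by
  2 h.  The lag matters: a perfectly anti-phase RH would be collinear with
  T and the calibration regression would be unidentifiable.
* **Seeding**: one integer seed feeds a `numpy` `SeedSequence`; all
  sub-streams derive from it, so identical seed + configuration gives
  bit-identical output.

### Noise scales

Survey-array read noise defaults to 5·10⁻⁴ a.u. per second.  This is set by
self-consistency, not by a datasheet: catalogued net slopes are of order
10⁻⁴ a.u./s (10⁻² a.u. total excursion over a 100-s phase), and a device
that resolves them must have median/OLS slope noise (≈ 4·10⁻³ × σ per
phase) well below the between-fruit slope spread.  The prototype array uses
0.3 a.u. noise on ~100 a.u. baselines (0.3%), typical for MOS modules.

### Group effect sizes

The survey simulator draws each fruit's per-sensor net slope from
`Normal(mean, SD)` with the group means/SDs catalogued from the original
13-sensor sensitivity survey (`catalog.SURVEY_GROUP_SLOPES`).  Only the
first two moments of those distributions are known, so Gaussian is the
default; a deterministic `quantile` mode places the n fruits of a group at
the (i+½)/n normal quantiles instead, giving a reproducible, spread-faithful
"noise-free" draw.

A documented limitation follows from this: the catalogued mean ± SD pairs
cannot encode the rank structure of the original measurements.  Under any
moment-matched symmetric model the standardized separation of MQ9 exceeds
that of MQ7, so a simulated survey flags a different sensor subset than the
original one did; reproducing the original flag set would require
distributional shape information (skewness, outliers) that a mean ± SD
summary does not carry.  The screening machinery itself is exact — its
relative-effect estimator is verified against O(n²) pair enumeration and an
independent reference implementation — and the characteristic small-n
statistics (−8.13, −4.48) are reproduced from synthetic data realizing the
same rank configurations.

### Outdoor and indoor designs

The outdoor experiment is simulated at the reading level (corrected,
normalized channel values), since that is the unit entering ANOSIM/LDA:
readings = class mean + per-fruit random effect (SD 0.5) + noise (SD 1).
Defaults put the air class ~1.7 combined-SD from the durian classes and the
two durian classes ~0.4 SD apart — a clearly detectable air signal with
heavily overlapping infested/uninfested clouds, the regime the device
operates in outdoors.  Training set: 5+5 fruits × 3 measurements × 30
readings + 3 air measurements (990 rows); test set: 10 further fruits × 30
readings (300 rows).

The indoor design gives each fruit a latent daily trajectory in channel
space: before the cracking day the daily mean advances along a random unit
direction **u**; from the day after cracking it departs along an orthogonal
direction **v**.  Mealybug-inoculated fruits take 1.5× larger daily steps
(stress-accelerated odor change).  Defaults — step 1.0, reading noise
SD 0.35, 30 readings/day, 7 days, cracking day 4 — produce per-fruit
ANOSIM-by-day R values in the high 0.8s to 0.9s and day clouds whose 95%
ellipses overlap only near the cracking day.

What the simulator does **not** emulate: sensor cross-sensitivity
structure, non-Gaussian slope distributions (above), autocorrelated
environmental noise, long-term sensor aging beyond linear drift, and any
chemistry (no Langmuir/R₀-Rs response curves).  Passing tests therefore
demonstrate the correctness of the processing and inference chain under its
stated assumptions, not field performance.

## Acquisition

* Slope regression uses window midpoints **in seconds** (5, 15, …, 95 for
  100 s / 10 s windows) so slopes are a.u./s.  Regressing on window index
  instead would scale slopes by 10; comparisons against externally computed
  slopes must check this convention.
* Windows are half-open `[k·w, (k+1)·w)` over the 0-based sample index;
  even-count windows use the mean of the two central order statistics.
* Up to 5% of a phase's seconds may be missing (serial links drop lines);
  they are linearly interpolated on the 1-s grid.  More is an error, as is
  any phase-label sequence that does not follow the schedule grammar.
* Survey mode (room air 100 s → sample air 100 s) and prototype mode
  (reset 300 s → sampling 100 s → rest 200 s) are two presets of one code
  path.

## Environmental calibration and normalization

The calibration is one **joint** OLS of each sensor's control-air reading
on T and RH (not two marginal fits — T and RH covary diurnally and marginal
slopes would be confounded), with the calibration means as reference point
and at least 100 samples required.  Correction subtracts the fitted
environmental component:
`corrected = raw − β_T(T − T_ref) − β_H(RH − H_ref)`; a divide-style
correction was considered and rejected because the additive model matches
the simulator's (and plausibly the sensors') response form.  By OLS
orthogonality, corrected control air is exactly uncorrelated with T and RH
on the calibration data.

Slow drift is deliberately not a calibration covariate: over a single diel
period drift is partially collinear with T, so a T/RH-only calibration
absorbs some drift into β_T.  This is harmless downstream — the slope
features difference drift out, and the correction residuals stay
environment-free — but fitted coefficients should not be read as pure
physical response constants when drift is present.

Normalization is two steps: divide the sampling phase by its **anchor**
(first retained reading after trimming — chosen over the pre-trim first
reading because the warm-up transient sits there), then subtract 1, giving
the relative fluctuation about 0.  A `log` variant (log-ratio) is available
behind a switch.  Output is dimensionless and scale-invariant.

## Inference

* **Brunner–Munzel**: midranks for ties; Welch–Satterthwaite-type df;
  two-sided p from the t distribution (sidedness chosen two-sided since the
  screen looks for effects in either direction).  Complete separation of
  two samples (zero rank variance, p̂ ∈ {0,1}) yields ±∞ with p = 0 rather
  than an error — the direction is certain even though the magnitude is
  unbounded; only the fully-tied case (p̂ = 0.5, zero variance) errors out.
  No multiple-testing correction is applied across the 13 sensors; the
  screen reports raw p-values and this is a documented caveat.
* **ANOSIM**: Euclidean distances on corrected, normalized values by
  default (Bray–Curtis available behind the metric switch); R uses the
  standard rank-based form with divisor n(n−1)/4; permutation p-values are
  `(#{R* ≥ R} + 1)/(B + 1)` with B = 9999 by default, switching to exact
  enumeration of all distinct relabelings when there are ≤ 20,000.
* **PCA** is computed on centered, unit-variance-scaled channels: channels
  share units but differ widely in dynamic range, and unscaled components
  would be dominated by the loudest channel.
* **Ripeness staging** operationalizes "day overlaps the cracking day" as
  intersection of 95% coverage ellipses (per-day mean and covariance,
  Mahalanobis radius χ²₀.₉₅ with 2 df) in PC1–PC2.  Intersection is tested
  by mutual center containment plus 256 boundary points per ellipse —
  adequate at the resolution of the plotted ellipses the rule mimics.  Days
  with fewer than 3 readings are `unassigned`.
* **LDA** solves the generalized symmetric eigenproblem `S_b v = λ S_w v`
  with `scipy.linalg.eigh`; axes are S_w-orthonormal, so pooled
  within-class covariance is whitened in discriminant space and
  nearest-class-mean with a log-prior offset is the Gaussian
  equal-covariance rule on that subspace.  Axis sign is canonicalized
  (largest-magnitude coefficient positive); comparisons against externally
  stored coefficient vectors should be made after sign canonicalization and
  L2 normalization, since LDA scale/sign is implementation-dependent.  A
  near-singular S_w (condition > 10¹⁰) receives a logged ridge of
  `10⁻⁸·tr(S_w)/p`.
* **Confusion matrices** use predicted-rows / true-columns orientation;
  per-class accuracy is the diagonal over the true-class column total, and
  classes absent from the test set keep zero column totals.

## Numerical and testing notes

* Problem sizes in the test suite and acceptance script (e.g. 5,000 null
  simulations for test size, 2,000 for p-value uniformity, 4,500 replicate
  cycles for slope unbiasedness, 100 seeds × 6 fruits for staging) are
  chosen so Monte-Carlo error is well below each assertion's tolerance.
* Exact-arithmetic claims (slope recovery, relative-effect enumeration,
  distance matrices) are tested against independent closed-form or
  brute-force oracles; stochastic claims against their own sampling error.
* Reference implementations (`scipy.stats.brunnermunzel`, scikit-bio's
  ANOSIM, scikit-learn's LDA) serve as cross-checks in tests only; the
  pipeline's statistics are computed by this package.
* Pipeline outputs embed the tool version and a hash of the scientific
  configuration (output paths excluded), and re-running with the same
  configuration and seed reproduces artifacts byte for byte.
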