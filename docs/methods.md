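# Methods

## Problem setting

A marathon field over a 42.195 km course timed every 5 km yields a runner ×
section matrix of durations: eight 5 km sections plus the final 2.195 km.
Non-finishers leave a contiguous missing tail, starting after their last
recorded checkpoint (20, 25, 30, 35 or 40 km; runners lost before half-way
are excluded from the analysis population, as are finishers under four
hours, whose pacing differs sharply from the rest of the field). The task
is to predict each non-finisher's remaining time — equivalently to complete
the matrix — and, for live-tracking uses, to attach an honest uncertainty
band.

All arithmetic is in floating-point seconds; `h:mm:ss` rendering rounds
half-up at the last step only. Records store per-section durations;
cumulative checkpoint times are derived prefix sums, so monotonicity is
structural rather than asserted.

## Data preparation

Cohort CSVs carry cumulative `h:mm:ss` checkpoint times, empty cell =
unrecorded, matching what timing systems emit. An interior unrecorded
checkpoint (chip misread) is filled by linear interpolation of cumulative
time against distance between the flanking recorded checkpoints; trailing
gaps are the prediction target and stay missing.

The validation harness masks a complete cohort into synthetic
non-finishers: exactly `round(0.257·N)` runners are drawn uniformly
(seeded) and truncated at dropout checkpoints allocated by
largest-remainder (Hamilton) apportionment of the weights
(93, 39, 459, 533, 4505) over 20/25/30/35/40 km — the observed dropout
counts of a stopped race, normalized by their sum; ties in the remainder
go to the earlier checkpoint. The hidden tails are retained so masking is
exactly invertible. Allocation is deterministic given (seed, N): at
N = 10,000, the 40 km point receives 2,057 of 2,570 masked runners (80.0%).

## Predictors

**Constant pace** uses the exact distance ratio, finish = T_m·42.195/km_m,
not a per-mile pace rounded to whole seconds; the exact ratio reproduces
the method's published worked answers to the second.

**Britt** multiplies cumulative time by 1.06 (40 km) or 1.23 (35 km) and
deliberately raises an error earlier — the rule has no earlier form. Since
1.23 > 42.195/35 ≈ 1.2056 and 1.06 > 42.195/40 ≈ 1.0549, Britt always
predicts slower than constant pace where both apply.

**Split-ratio** constants are estimated as the direct mean over training
runners of (remaining time)/(last 5 km section time), per gender and
checkpoint — the quantity the prediction rule consumes — rather than as
chained products of consecutive-section mean ratios; the two readings
agree to printed precision on reference data and cannot be distinguished
there, so the direct form was chosen for coherence with the predictor. A
published reference table is shipped as the default.

**Linear regression** fits one OLS model per dropout checkpoint of the
remaining-time sum on the observed sections, with an intercept by default
(a flag disables it) and optional age/gender covariates (off by default;
they add little). On fading populations the fitted weights of the first
two sections are negative — runners who start relatively slow finish
relatively fast — and the test suite asserts this on the generator's fader
regime.

**Two-way log-ANOVA.** Log section times follow μ + α_i + β_j with
Σβ_j = 0, fitted by least squares within 32 subgroups; for complete
subgroup data the solution is closed-form (grand mean and column-mean
deviations). Subgroups cross octiles of variable (a), the half-way time,
with quartiles of variable (b), the scaled second-half slow-down. Two
operationalizations were open:

- (a) is the cumulative 20 km time — the nearest recorded checkpoint to
  half-way on a 5 km-gridded course; (b) = (T₄₀ − T₂₀)/T₂₀.
- classifying a runner who never reached 40 km: the analogous partial
  slow-down (T_L − T₂₀)/T₂₀ over their longest observed stretch is
  compared against quartile breaks of that same partial statistic
  recomputed on the training cohort (stored at fit time for L = 25, 30,
  35 km), preserving the equal-mass semantics on exactly the information
  available. A runner observed only to 20 km carries no slow-down
  information and takes the quartile containing the training median.

Prediction re-estimates α_i as the mean residual over the observed
sections and exponentiates; no σ²/2 lognormal bias correction is applied
(none is specified by the method, and the within-subgroup residual
variance is small). In a field truncated at four hours, a very fast
half-way time entails fading, so the (fastest, least-fading) corner cell
is thinly populated; fitting therefore requires a few thousand runners,
and an empty cell raises an error suggesting a larger cohort.

**SVD completion** factors the raw, uncentered training matrix (the
dominant component is the overall-speed pattern; centering is not part of
the method). Completion solves x_obs = (V_obs D)u for the minimum-norm u
via the pseudo-inverse — exact for any record consistent with the rank-k
model, whatever tail is missing. The rank is chosen by 5-fold
cross-validation in which held-out runners are truncated at random
dropout checkpoints and ranks scored by MSE of predicted remaining time;
ties prefer the smaller rank. During scoring a poor candidate rank may
project a negative remaining time; it simply scores badly rather than
erroring.

**KNN local regression** (K = 200). Distances are Euclidean on 5 km
*section* vectors (a flag switches to cumulative vectors for sensitivity
checks). The kd-tree (scipy `cKDTree`) is an acceleration detail with an
exactness contract: a candidate set is over-queried and re-ranked by true
distance with ties broken by reference order, so results are identical to
an exhaustive scan — property-tested, including duplicated references.
The local model is OLS with intercept of neighbors' remaining sums on
their sections, tolerant of level offsets between query and references; a
singular local design falls back (logged) to the neighbor mean. A query
present in the reference set is excluded from its own neighborhood.

**Rescaled KNN** (K = 100) multiplies each neighbor's profile by
T_m(query)/T_m(neighbor) — after which every neighbor agrees with the
query at the sampling point exactly — and reads off per-future-checkpoint
medians and 5th/95th percentiles of the rescaled cumulative times.
Percentiles interpolate linearly between order statistics (numpy's
default, type-7); the choice is configurable and affects bounds by a
fraction of a second at K = 100.

## Evaluation

Errors are (predicted − true) finish in minutes: MAE, MSE (minutes²), and
within-k proportions for k ∈ {1,2,3,4,5,10}, with optional stratification
(gender; age ≤ 45; finish ≤ 265 min; last recorded split). Interval
coverage is the fraction of true finishes inside their 90% band.

Cross-method agreement is summarized by Pearson correlations of projected
*remaining* times (not total finishes, which share the observed cumulative
term) computed within each dropout checkpoint and pooled by
count-weighted average; Britt-involving entries pool over 35/40 km only.
The pooled matrix is reported as the raw weighted average without
re-normalization. Within one checkpoint both Britt and constant pace are
scalar multiples of cumulative time, so their pooled correlation is
identically 1 — an analytic identity the suite asserts and the acceptance
script recomputes. Points with fewer than two runners, or zero-variance
methods within a point, are excluded from pooling with a warning.

## Synthetic cohort generator

The generator emulates the analysis population — an over-four-hour field
with heterogeneous pacing:

| parameter | default | meaning |
|---|---|---|
| `base_pace_log_mean/sd` | ln 355, 0.08 | lognormal first-half pace, s/km (median ≈ 355 → ~4:10 base finish) |
| `section_difficulty` | 1.00, 0.99, 0.99, 1.00, 1.01, 1.03, 1.04, 1.01, 1.02 | per-section course multiplier; 25–35 km hills bumped a few percent |
| `fade_mix` | 0.50 / 0.40 / 0.10 | steady / fader / negative-split mixture |
| `fade_range` | 1.02–1.08 | fader's per-section geometric slow-down beyond 20 km |
| `negative_range` | 0.96–0.995 | negative-splitter's per-section speed-up |
| `noise_sd` | 0.02 | per-section multiplicative lognormal sigma |
| `gender_split` | 0.45 | fraction female |

Section time = pace × section km × difficulty × fade^(sections past 20 km)
× noise, rounded to whole seconds (as chip timing records). Noise is
multiplicative throughout, consistent with running times composing
multiplicatively. The four-hour floor is enforced by seeded rejection
resampling — sub-threshold runners are redrawn (pacing type kept) — which
models a truncated population without piling probability mass at the
boundary. Fader heterogeneity makes section-time variance grow with
distance, the qualitative signature of real fields.

What the generator does **not** emulate: weather shocks, start-wave
congestion, chip dropout noise correlated across checkpoints, repeat
participants, and real course-specific split distributions. Passing tests
therefore certify the algorithms and their contracts on a structurally
realistic population, not predictive accuracy on any particular race's
data; the harness accepts real cohort CSVs by path for that purpose.

`generate_fixture` produces *model-exact* cohorts for recovery tests: an
exact linear remaining-time model (zero-sum jitter inside the tail keeps
the remaining sum exactly linear while breaking collinearity of individual
tail sections), an exact multiplicative two-way model, and an exact rank-k
factor model (dominant positive speed component plus orthonormal
polynomial section patterns, singular values decaying 1, 0.1, 0.02, …
so every component clears small noise).

## Numerical choices and test scale

OLS via `numpy.linalg.lstsq` with explicit rank checks; normal-equation
solves appear only as independent oracles in tests. Recovery tolerances on
noiseless fixtures are 1e-8 absolute (closed-form identities hold to
machine precision). Default test scale: cohorts of 500–5,000 runners;
interval-coverage calibration uses 4,000 reference runners and 2,000
exchangeable queries at K = 100, allocated across dropout points like the
observed field, and expects empirical coverage of the nominal 90% band in
[0.86, 0.94] (finite-K order statistics bias coverage slightly below
nominal; Monte-Carlo tolerance on 2,000 queries).

## Limitations

- ANOVA subgroup classification of early dropouts is one defensible
  reading of an under-determined design point; alternatives (e.g.
  projecting a provisional slow-down) are plausible and untested.
- No SOFT-IMPUTE-style regularized completion or Bayesian two-stage
  regression variants.
- The pooled correlation matrix, as a weighted average of correlation
  matrices, is not guaranteed positive semi-definite; it is reported raw.
- Prediction intervals are empirical percentile bands; they carry no
  parametric coverage guarantee for runners whose pacing departs from all
  of their neighbors (late collapse), and such failures are expected for
  early sampling points.
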