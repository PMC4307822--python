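# Methods

`vrdot` implements an analysis pipeline for performance-based assessment
of activities of daily living (ADL) from event logs of a simulated
fire-evacuation drill (a "day-out task" administered in virtual reality).
This note documents the models, the choices made where the design was
genuinely open, and the limits of what the bundled synthetic data can
show.

## Session scoring

A session is a timestamped sequence of activity performances recorded
against a protocol: the canonical ordered list of activities a fully
competent participant would complete (the default protocol has eight
steps — size up the fire, call for help, alert neighbours, gather
essentials, close doors, avoid smoke, locate the exit, evacuate).  The
concrete activity list is configurable; eight steps give the order-error
metric room to vary.

Two quantities are derived per session:

* **Efficacy ratio** `REff ∈ [0, 1]`: time spent performing protocol
  activities divided by total session time.  Overlapping intervals of
  the same activity are unioned before summing.
* **Functional index** `FI ∈ [0, 100]`:

      FI = 100 · REff / (1 + k₁O + k₂R + k₃W + k₄A)

  where the four error counts are **O** omissions (protocol activities
  never completed), **R** repetitions (completed performances beyond the
  first, per activity), **W** order errors, and **A** extra attempts
  (attempts beyond the first on each activity's first completion —
  retries inside later repetitions are already penalised through R).
  Higher FI means better function.

The rational-penalty form was chosen because it (a) reduces to the pure
efficacy ratio at zero errors, (b) is bounded in [0, 100] so cutoff
magnitudes in the 0–100 range are representable, and (c) is monotone
decreasing in every error count and weight, which the calibration
procedure requires.  It is implemented as a single replaceable strategy
function (`scoring.penalised_index`).

**Order errors** are the longest-increasing-subsequence (LIS) deficit of
the first-completion order mapped onto protocol indices: the minimum
number of activities that must be deleted from the performed order to
restore protocol order.  This is deterministic, permutation-principled
(W = 0 iff first completions appear in protocol order), and insensitive
to repetitions appended after first completions.

A deliberate convention: the index *rises* with better function, so it
correlates positively with MMSE and negatively with informant disability
scales (Bristol/Blessed, where higher = more impaired).  Published
correlation tables for comparable instruments are ambiguous on the sign
convention; this package fixes one and states it everywhere a direction
is needed.

## Calibration of the penalty weights

The four weights are fitted in two steps on a pilot cohort, mimicking a
discrete candidate-set evaluation rather than continuous optimisation
(exactly reproducible, no local-minimum concerns):

1. every candidate `(k₁,k₂,k₃,k₄)` on a regular grid (default 0–1 by
   0.05, 21⁴ candidates) is scored by the Spearman correlation of the
   resulting baseline FI with MMSE (`ρ₊`) and with an IADL scale
   (`ρ₋`; Bristol by default, Blessed selectable);
2. candidates with `ρ₊ ≥ ρ_mmse_min` and `ρ₋ ≤ ρ_iadl_max` are accepted
   and the componentwise mean of the accepted set is the final weight
   vector.

"Strongly correlated" has no canonical number; the thresholds default to
|ρ| ≥ 0.6 (a conventional "strong" for Spearman) and are configuration,
never hard-coded.  The grid evaluation is vectorised (the index for all
candidates is `100·r/(1 + X·k)` for fixed per-subject `r`, counts `X`),
so the full default grid runs in seconds.

For parameter-recovery experiments the package ships a dedicated
synthetic pilot (`make_recovery_pilot`) whose MMSE/Bristol scores are
noisy monotone functions of FI computed with known true weights.  Its
design matters: because `log(1 + c·u)` is a monotone transform of
`u = k·x` for any scale `c`, ranks of the index are nearly invariant to
scaling the weight vector unless the efficacy ratio varies comparably.
The fixture therefore draws counts Poisson(1) (penalty term mostly
below 1, the near-linear regime) and REff uniform on (0.35, 0.95), which
makes rank correlations decay symmetrically in the log-scale of the
weights; recovery runs should use tight thresholds (|ρ| ≥ 0.99).  Under
those conditions a coarse 0.1 grid recovers each component of
(0.3, 0.2, 0.4, 0.1) within 0.15 across seeds.

## Psychomotor metrics

Gait speed = 4.6 m / walk time; stride length = 4.6 m / steps; tapping
rate = taps / 15 s; grip = best of up to three dynamometer attempts
(kg, dominant hand).  Gait speed and stride length can be normalised to
a 50-cm knee-heel (lower-leg) length by multiplicative scaling
`value · 50/kh`, chosen over regression-residual adjustment for
transparency and invertibility (identity at 50 cm, scale-equivariant).
A pipeline flag (`apply`/`auto`/`skip`) controls whether the adjustment
is applied; `auto` tests the knee-heel covariate against gait speed at
the 10% level.  Adjusted values *replace* the raw ones in downstream
models by default; both columns are emitted.

## Longitudinal rates of change

The working model for measure *y* of subject *i* at time *t* (years
since baseline, 0/1/2) is a random-intercept/random-slope line

    y_it = (b₀ + u₀ᵢ) + (b₁ + u₁ᵢ)·t + e_it.

It is estimated by a transparent two-stage procedure: per-subject OLS
(with 2–3 visits the within-subject fit is saturated or nearly so),
then pooling — the mean slope with its empirical SE overall and per
group, plus empirical-Bayes-style shrinkage of each subject slope toward
its group mean with weight `τ²/(τ² + se_i²)`, where `τ²` is the moment
estimate of between-subject slope variance (floored at 0).  With
balanced visits the two-stage mean equals the mixed-model GLS estimate;
the closed forms make the estimator testable against hand computation,
and shrinkage provably never moves a slope past its group mean.  A REML
fit (statsmodels `MixedLM`) can be substituted for unbalanced designs.
Missing visits are handled by fitting on available points (≥ 2); no
imputation.  Prediction features use raw slopes by default; shrunken
slopes are available (`slopes="shrunken"`).

## Screening battery

* **Spearman correlation**: mid-ranks for ties, two-sided p from the
  t-approximation (n−2 df).  **Partial Spearman**: rank-transform all
  variables, residualise x and y on the ranked covariates by OLS,
  correlate residuals; p uses n−2−q df.  Matches `pingouin.partial_corr`
  (method="spearman"), which serves as the independent cross-check in
  the tests.
* **ROC**: sensitivity/specificity at every distinct score value
  (inclusive in the positive direction); AUC is the Mann–Whitney
  probability with ties half-credited, verified against exhaustive
  pairwise enumeration.  Direction (higher- vs lower-is-positive) is
  explicit per measure, never inferred: for impairment screening MMSE
  and FI are lower-is-positive, informant ADL scales
  higher-is-positive.
* **AUC confidence intervals**: stratified percentile bootstrap (2000
  replicates by default, resampling within class, seeded).  DeLong-type
  analytic intervals were considered but the bootstrap keeps one code
  path for all statistics.
* **Cutoffs**: Youden's J maximised over observed thresholds, ties
  broken toward higher specificity (a screening-friendly convention);
  PPV/NPV from the sample 2×2 table, reported as NaN when a predicted
  cell is empty.

## Conversion prediction

Binary logistic regression (maximum likelihood via statsmodels Logit,
Newton–Raphson) with Wald SEs, `exp(b ± 1.96·SE)` odds-ratio intervals,
Nagelkerke's rescaled R² `[1 − (L₀/L₁)^{2/n}] / [1 − L₀^{2/n}]`, and
percent correctly classified at probability 0.5.  Backward stepwise
elimination repeatedly drops the predictor with the largest Wald
p ≥ 0.10 (interpreting the retention criterion of a backward procedure;
ties to the later column; forced-in covariates exempt), deterministically
given column order.  Quasi-complete separation is flagged on the result
rather than raised, and an optional Firth-style Jeffreys-penalised fit
keeps estimates finite — relevant because published sensitivities near
100% imply near-separation in realistic data.  In the pipeline the
conversion models are fitted on the aMCI group with rate-of-change
predictors standardised to 1 SD and oriented so larger values mean
faster deterioration.

## Synthetic cohort generator

The generator emulates the study conditions the pipeline assumes: three
groups (72 controls / 65 aMCI / 68 mild AD completers), three annual
visits, 11.6% baseline-only dropout (realised as deterministic counts,
so 232 enrolled / 27 dropouts / 205 completers exactly), and group
means/SDs for MMSE, RAVLT delayed recall, GDS, FAQ, TMT-A/B, digit
symbol, Bristol and Blessed ADL, gait speed and tapping anchored to the
published cohort description.  Scales are drawn from truncated normals
at instrument bounds (several published SDs sit close to a bound, where
an unbounded normal would generate invalid scores), then decline
linearly with per-subject random slopes plus small visit noise —
matching the longitudinal module's model so slope recovery is a fair
test.

Sessions are generated *counts-first*: the four error counts are drawn
(Poisson rates ordered control < aMCI < mild AD, growing with visit
year) and the event log is constructed to score back to them exactly —
omitted activities are never performed; the performed activities are
sequenced as the W largest protocol indices in decreasing order followed
by the rest ascending (a permutation with LIS deficit exactly W);
repetitions and extra attempts are layered on without disturbing
first-completion order.  The target efficacy ratio is realised exactly
by sizing idle time; activity durations are log-normal.  This makes the
scorer's correctness testable end-to-end (generator ∘ scorer =
identity).

Two defaults are anchored to the published screening results rather than
the demographics table: the control error rates are low enough that the
functional index separates controls from aMCI more strongly than MMSE
does (the instrument's headline property), and the aMCI conversion
label follows a logistic in the subject's true efficacy-ratio slope
(intercept −5.7, slope coefficient −140) so the conversion association
is of the reported magnitude (Nagelkerke R² around 0.5 at n=65).
Conversion depends only on the efficacy-ratio slope by default; other
dependencies are config hooks.

What the generator does **not** emulate: realistic joint dependence
between scales beyond shared group membership and shared decline,
non-linear trajectories, practice effects, informant-rating noise
structure, missing-not-at-random dropout, or any real subject-level
data.  Passing tests therefore demonstrate the *estimators* recover the
structure they assume, and that the pipeline is internally consistent —
not that the instrument performs as published on clinical data.

## Numerical and procedural choices

* Timestamps are seconds from session start with millisecond precision;
  visits are indexed 1–3; slopes are per year with time coded 0/1/2.
* I/O is lossless and deterministic: repeated writes of the same cohort
  are byte-identical (JSON with sorted keys; CSV bundle of
  subjects/visits/sessions/events joined by ids).
* Logistic fits iterate Newton to tolerance 1e-10 (≤ 100 iterations),
  falling back to BFGS under separation; Firth iterations stop at score
  norm < 1e-8.
* All randomness flows through `numpy.random.default_rng` seeds; the
  bootstrap, the generator and the pipeline stamp their seed into every
  artifact.
* Problem sizes used by the test suite and the acceptance script (1000
  oracle sessions, 200 ROC instances, a 75-subject recovery pilot on a
  0.1 grid, 60 subjects × 500 replicates for slope recovery, n=500
  logistic recovery, 20 seeds for the separation check) are the
  package's chosen defaults: large enough for the Monte-Carlo tolerances
  quoted, small enough to run on a laptop in minutes.

## Known limitations

* The penalty form of the functional index is a principled choice, not
  a reproduction of any particular instrument's internal formula.
* The two-stage slope estimator equals GLS only under balanced designs;
  heavily unbalanced data should use the REML hook.
* The calibration accepted-set mean is sensitive to the threshold when
  correlations decay slowly across the grid; diagnostics (per-candidate
  correlations) are returned so users can inspect the acceptance region.
* Bootstrap CIs are percentile-based and degenerate ([1, 1]) under
  perfect separation; no continuity correction is applied.
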