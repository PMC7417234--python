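# Methods

This note records the statistical models `aircount` implements, the
assumptions and defaults behind them, what the synthetic-data generator
does and does not emulate, and the numerical choices that matter for
reproducing its output.

## Data model

An **observation table** holds one row per object in a surveyed site that
was either flagged by an automated detector in drone thermal imagery or
known from ground truthing to have been missed. Each row carries a
four-level fate `klass`:

| klass | meaning | algorithm output? |
|---|---|---|
| `unique_detection` | first verified record of a real animal | yes |
| `duplicate` | repeat record of an already-detected animal | yes |
| `false_positive` | object misidentified as the target species | yes |
| `missed` | animal present (ground-truthed) but not detected | no |

plus covariates: ambient temperature (°C), wind speed (km/h), distance to
habitat edge (m; larger = deeper into forest core), distance to nearest
other detection (m) and time since the previous detection (s) — the last
two undefined for misses — and the perpendicular distance to the transect
line (m, strictly inside the 75 m half-strip). The validator enforces
these invariants and reports (never enforces) the fate composition.
Binary responses for the three probability models are *derived views* of
`klass`, never stored:

- detection model: rows with `klass ∈ {unique_detection, missed}`,
  response Y = 1 for a detection;
- false-detection model: rows with `klass ≠ missed`, response W = 1 for a
  false positive;
- duplicate model: rows with `klass ∈ {unique_detection, duplicate}`,
  response Z = 1 for a duplicate.

A **transect count array** holds `y[t, v, b]`: detections on transect *t*
during visit *v* in perpendicular-distance bin *b*. Bins are half-open
`[lo, hi)` over the five 15 m classes 0–75 m; a distance at or beyond the
outer edge is rejected rather than assigned to a bin, so the boundary
convention is observable only at interior edges (15.0 m falls in the
second bin).

## Modified Horvitz–Thompson estimator

For a survey with `C` algorithm-identified objects,

```
N̂ = Σ_{i=1}^{C} (1 − d̂_i − f̂_i) / p̂_i .
```

Each detected object is down-weighted by its probability of being a
duplicate or a false positive and inflated by its inverse detection
probability. Two clamps keep single objects from dominating or flipping
sign: the numerator is floored at 0 (possible when `f̂ + d̂ > 1`) and `p̂`
is floored at 1e-3; the count of clamped objects is reported with every
estimate so truncation is never silent.

Interval construction is by plug-in limit substitution: per-object Wald
limits `invlogit(η̂ ± z·SE(η̂))` are computed for each of the three
probabilities on the link scale (z = 1.96 at the default 95% level), and
the *lower* limits of p, f and d give the *upper* abundance limit
(abundance is largest when detection was unlikely but the records are
believed real and unique), the upper limits the lower abundance limit.
This ordering is monotone through the clamps and asserted at run time.
Delta-method or design-based variance formulas are deliberately not used.

Two documented judgment calls: estimates are reported rounded to whole
animals with the raw values retained; and `d̂` is predicted for every
detected object including probable false positives, even though the
duplicate model is trained only on verified animals — this mirrors how
the estimator must be applied to raw algorithm output, where the truth of
each record is unknown.

## Detection / false / duplicate probability models

Each role is a Bernoulli GLM with logit link fitted by maximum likelihood
(IRLS, gradient tolerance 1e-10 at the scale of statsmodels' convergence
check; standard errors from the inverse observed information). Perfect
separation raises an error naming the separating covariate — silently
returning divergent coefficients would poison the downstream division by
`p̂`. Rank-deficient designs are rejected. McFadden's pseudo-R²
`1 − ℓ/ℓ₀` summarizes explained variance.

**Stepwise selection.** Stage 1 fits the null model and every univariate
GLM, ranking all of them by AIC alongside p-values and residual-deviance
reductions; covariates with Wald p < α (default α = 0.05) advance. Stage 2
fits every subset of the advanced covariates. Stage 3 fits a penalized
additive variant of the best linear model, adopted only when it lowers
that model's AIC by more than 2 points. The final choice is the lowest
AIC among the null, the advanced singletons, their combinations and (when
adopted) the additive fit, with ties broken toward fewer parameters. The
ranking table reports all three stage-1 criteria even where they
disagree; AIC is the operative selector. When no candidate beats the
null, the null model is selected — that is a result, not an error.

**Additive fits.** One cubic B-spline smooth per covariate (six basis
functions by default), smoothing penalty chosen by generalized
cross-validation `n·D/(n − edf)²` over a log-spaced grid shared across
smooths. The curvature penalty's null space is the linear predictor, so an
infinite penalty reproduces the linear fit exactly rather than flattening
the smooth. Effective degrees of freedom (trace of the penalized hat
matrix) enter the AIC, and the penalized covariance drives prediction
intervals. Additive fits are not serialized to the YAML fit format —
only coefficients and covariance of linear fits are, which is all the
CLI's estimation-from-saved-fits path needs; additive models are refitted
from data instead.

## Generalized N-mixture model

Hierarchy per transect *t*, visit *v*:

- `M_t ~ NegBin(mean λ_t, dispersion α)`, `log λ_t = x_tᵀ θ_λ`
  (transect land-cover percentages), variance `λ + λ²/α`, `α` estimated
  on the log scale; a Poisson option drops `α`;
- availability `N_tv ~ Binomial(M_t, φ_v)`, `logit φ_v = w_vᵀ θ_φ`
  (visit weather). The visit-level formula is interpreted as availability,
  one of the two readings the hierarchy admits;
- distance cells: `π_b = ∫_bin g(x) dx / W` with W = 75 m and `g`
  uniform (`Σπ_b = 1`) or half-normal with scale σ, optionally
  `log σ_t = s_tᵀ θ_σ` in transect covariates. The half-normal integral
  uses the Gaussian error function.

Because each of the `M_t` animals is observed in bin *b* of visit *v*
independently with probability `φ_v π_b`, the availability layer is
marginalized analytically and each visit contributes a multinomial over
the five bins plus an unobserved remainder `1 − φ_v Σπ_b`; the latent
`M_t` is then summed out numerically up to a truncation bound `K`
(default: maximum observed transect total + 100). The implementation is
checked in tests against brute-force enumeration over both latent layers
(agreement to 1e-8 on small instances), and every fit records the
log-likelihood change when `K` is doubled (reported as `K_check_`,
typically below 1e-6).

Fitting is quasi-Newton (L-BFGS-B with numerical gradients, Nelder–Mead
polish) from moment-based starts — the lambda formula is initialized by
regressing `log(mean count / 0.5 + 0.5)` on its design — with standard
errors from the numerical Hessian; a non-invertible Hessian flags the SEs
unavailable rather than failing the fit. Under a uniform key with
negative-binomial abundance, `φ` and `λ` are only weakly identified;
`fix_phi` pins availability (e.g. at 1) for that situation. Site-level
abundance is reported as `Σ_t λ̂_t` — the *expected* total, not an
empirical-Bayes realized total, a deliberate convention.

**Goodness of fit.** Freeman–Tukey discrepancy
`T = Σ (√y − √ŷ)²` with `ŷ_tvb = λ̂_t φ̂_v π̂_b`, and a parametric
bootstrap p-value `P(T* ≥ T)` over datasets simulated from the fit. The
default fast mode evaluates `T*` at the generating estimates; `refit=True`
refits every simulated dataset (the textbook bootstrap, ~100× slower).
The fast mode is what the calibration checks exercise: under the
generating model its p-values are approximately uniform (Kolmogorov
distance ≈ 0.07 over 100 runs in the shipped acceptance run).

## Synthetic survey generator

The generator emulates the campaign structure the estimators are designed
for, with defaults at a realistic scale for a two-site koala survey:

| dial | default | rationale |
|---|---|---|
| surveys | 11 (5 north + 6 south), Feb–Aug 2018; the 4 July dates are the test set | campaign scale; train/test split by date |
| true animals per survey | Poisson, mean 15 | ~250 training rows with the fate mix below |
| detection `p_coefs` | (6.5, −0.1879 temp, −0.0233 edge) | ≈ 0.79 detection at mean covariates, falling with temperature and edge distance |
| false positives | Poisson(11.5)/survey; edge profile tilted by (1.0, −0.0324) | ~1 false per true detection, concentrated near habitat edges |
| duplicates | spawn probability `invlogit(0 − 0.0228·dist_nearest)`; position jitter ≤ 30 m | ~0.3 duplicates per detection, arising between nearby records |
| covariates | temperature U(5, 25) °C, wind U(0, 20) km/h, edge distance U(0, 200) m | plausible ranges; the generator documents rather than infers them |
| transect counts | 9 transects × 5 visits; `log λ = 3.4 − 0.0985·road% − 0.0308·grass%`, α = 3, φ = invlogit(0.847) ≈ 0.7, uniform key | ~40–100 animals per site array |

Animals are placed uniformly in a 300 m × 300 m site with two flight
lines 150 m apart (perpendicular distances < 75 m); duplicate spawning
uses nearest-neighbour distances among the realized first-pass
detections, and the recorded `dist_nearest` covariate is recomputed *post
hoc* over all detected objects — duplicates included — exactly as it
would be from real algorithm output.

**What the generator does not guarantee.** Detection is exactly
logit-linear by construction, so `β` recovery is exact in distribution.
The false-positive and duplicate mechanisms, however, are *generative*
(class counts plus covariate profiles), and the logistic models fitted to
their output are discriminative summaries: the fitted `γ` and `κ` are
close to, but not exactly, the generating dials (the post-hoc
`dist_nearest` recomputation and the finite covariate ranges both
contribute). Coefficient-level recovery checks therefore draw `(y, X)`
directly from the Bernoulli models (`simulate_bernoulli_design`), while
the full campaign generator backs the end-to-end checks that do not
depend on that identity — above all interval coverage of the true count.
Passing tests consequently demonstrate correctness of the estimation
machinery and calibration under the assumed error structure, not
robustness to real-world deviations from it (animal movement, weather
time-series, spatially clustered false positives, image artefacts —
none of which are modelled).

## Experiment sizes and numerical conventions

- End-to-end coverage: 50 simulated campaigns × 4 test surveys = 200
  surveys; 95% intervals cover the true count in ≈ 93–95% of surveys,
  while the raw count carries a mean bias of ≈ +10 animals against a
  truth of ~15 and the corrected estimator ≈ −1.5.
- Parameter recovery: logistic at n = 5000; N-mixture at 120–200
  transects (half-normal at 150), all within 3 SE of truth.
- Oracle agreements: logistic MLE vs direct numerical maximization to
  1e-4 over 50 small datasets; N-mixture likelihood vs enumeration to
  1e-8 on instances with K ≤ 6.
- GOF calibration: 100 simulated datasets, 100 bootstrap draws each,
  fast mode.
- Boundary conventions: interval coverage is boundary-inclusive; AIC ties
  break toward fewer parameters; seeds derive from one master seed by
  fixed offsets and are recorded in outputs.
- The test-date layout mirrors a temporal hold-out (all July surveys), so
  training and testing never share a survey date.

## Known limitations

- The false-model intercept is a function of class balance, not a free
  generator dial; only its slope is a meaningful recovery target.
- The N-mixture availability/detection split is conventionally resolved
  in favour of availability; data of this shape cannot distinguish the
  two readings.
- Fit serialization covers linear logistic fits only.
- The two data products in `run_comparison` are simulated from one master
  seed but separate latent populations; each estimator is scored against
  its own product's truth. A single spatially explicit population shared
  by both products is out of scope.
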