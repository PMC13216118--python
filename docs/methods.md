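# Methods

## Data model

The unit of analysis is a binary **presence matrix**: N_article × N_theme
cells, cell (i, j) = 1 iff article i's text addresses theme j. Themes are
split into two categories, device *utilities* and operational *issues*,
and every temporal analysis runs per category. The embedded reference
corpus covers 19 early da Vinci studies (2001/05–2004/09) and 16 themes
(7 utilities, 9 issues), encoded from the published per-theme study lists;
its per-theme column sums match the published count rows exactly
(utilities 16, 7, 12, 2, 5, 5, 3; issues 16, 9, 4, 1, 12, 6, 2, 6, 6), and
the observation window runs from the day after FDA clearance (2000-07-12)
to the day before the first in-scope RCT (2004-10-24).

Publication *months* are the finest date information available, so a
day-of-month convention resolves them to calendar dates: `mid` (day 15,
the default — unbiased placement within the month), `first`, or `last`.
Switching conventions moves every elapsed time by at most ±0.5 month and
the fitted time constants by well under their CI widths (≈ ±0.2 months on
the reference corpus). Elapsed time uses a fixed month of 365.25/12 =
30.4375 days, so the axis is calendar-independent. Same-date articles
keep their table-row order; each article increments the publication-count
axis by one.

## Agreement

Coding reliability is assessed on the pooled cells of two coders'
matrices (two raters, two categories): observed agreement p_o, chance
agreement p_e = pA(1)pB(1) + pA(0)pB(0) from each coder's own marginals,
and κ = (p_o − p_e)/(1 − p_e), interpreted on the Landis–Koch scale. The
printed scale's two-decimal interval bounds leave gaps (e.g. 0.205), so
bands are implemented half-open on the upper bound: κ < 0 poor, [0, 0.21)
slight, [0.21, 0.41) fair, [0.41, 0.61) moderate, [0.61, 0.81)
substantial, [0.81, 1] almost perfect. When both coders use a single
category, p_e = 1 and κ is 0/0; it is reported as *undefined* rather than
silently substituted, because that degeneracy usually signals a coding
pathology. Threshold verdicts mirror the study protocol: agreement rate
strictly above 0.90, κ at least 0.80. Per-theme κ is available as a
diagnostic but is not the headline statistic (n per column is small).

## Emergence series

Under the first-occurrence rule a theme contributes once, at the earliest
article mentioning it (date order, row order on ties). The series has one
event per article — including articles contributing zero new themes,
which form the flat segments of the curve and are genuine observations on
both axes. The outcome is the cumulative occurrence proportion,
100·T_sum,n / T_sum,End, normalized by the number of distinct themes
observed by the final article (7 utilities, 9 issues in the reference
corpus); the final event is therefore exactly 100%.

## Saturation models and fitting

Two candidate curves, both increasing and saturating at 100%:

- exponential plateau f(t) = 100(1 − e^(−t/T_c)); one parameter, passes
  through the origin; T_c is the time at which 63.2% of themes have
  emerged;
- logistic f(t) = 100/(1 + a·e^(−bt)); two parameters, f(0) = 100/(1+a).

Fits are unweighted nonlinear least squares (scipy's trust-region
reflective variant of Levenberg–Marquardt, parameters bounded positive,
tolerances 1e-12; deterministic initial values T_c0 = max(x)/3,
b0 = 1/T_c0, a0 from the first point). Standard errors come from the
Jacobian-based covariance scaled by rss/(n − p); 95% parameter CIs are
Wald intervals with Student-t quantiles on n − p degrees of freedom.

**Origin anchoring.** By default the point (0, 0) is prepended to the
series before fitting: at the window anchor no article exists, so the
cumulative proportion is zero by construction, and the anchored fit makes
the goodness-of-fit statistics describe the full trajectory from device
clearance rather than only the tail where most proportions already exceed
70%. This is also what makes the model comparison decisive: the
exponential passes through the origin analytically (so its T_c estimate
is *identical* with or without the anchor), whereas the logistic cannot
reach zero, and with the anchor the exponential wins on AICc, adjusted R²
and RMSE on all four reference series (e.g. utilities/months: adjusted R²
0.973 vs 0.932, RMSE 3.6 vs 5.5). Without the anchor the comparison
statistics describe only the 19 high-proportion points and the ranking
can flip; `include_origin=False` exposes that variant.

**Selection statistics.** R² is computed against the mean-only model and
adjusted as 1 − (1 − R²)(n − 1)/(n − p − 1); RMSE = √(rss/n); AICc uses
the Gaussian concentrated likelihood without the 2π constant,
AICc = n·ln(rss/n) + 2k + 2k(k+1)/(n − k − 1) with k = p + 1 (the error
variance counts as a parameter). Absolute AICc values are
convention-dependent (additive constants in the likelihood, whether n or
rss is inside the log); only differences between candidates at fixed n
are meaningful, and model selection relies solely on those. A perfect fit
(rss = 0) drives AICc to −∞; it is reported as undefined and ranks first.

## Threshold estimation

The fitted curve is inverted for target proportions (defaults 50%, 80%,
and 99.9% — the saturation proxy; 100% is never reached by either model):
exponential t = −T_c·ln(1 − q), logistic t = (ln a − ln(1/q − 1))/b. A
logistic target at or below f(0) is reached before the origin and maps to
0 with a warning. Confidence intervals:

- **transform** (default, exponential only): the inversion is a monotone
  scalar map of T_c, so mapping the T_c interval endpoints is exact;
- **delta**: first-order propagation through the inversion gradient and
  the parameter covariance (coincides with transform for the exponential,
  required for the two-parameter logistic);
- **bootstrap**: residual resampling with refitting (default 2000
  replicates, seeded), percentile interval; the cross-check route.

For the exponential model t(99.9)/t(50) = ln 1000 / ln 2 ≈ 9.966 for any
T_c, a useful internal-consistency identity. Estimates beyond twice the
observed axis range are extrapolations of the fitted law (the 99.9%
thresholds on the reference corpus are ~57 and ~112 months against a
51-month window) and inherit its assumptions.

## Synthetic corpora and parameter recovery

The generator matches the analysis's generative assumption exactly:
articles follow a fixed schedule (explicit, or constant-rate across the
window); each theme draws an emergence time E ~ Exponential(mean T_c);
the earliest article at or after E carries the first mention; each later
article mentions the theme independently with probability
`recurrence_prob` (default 0.5 — recurrence affects per-theme mention
counts but not the first-occurrence series). The expected cumulative
proportion at time t is exactly 100(1 − e^(−t/T_c)), so recovery error
measures the estimator, not misspecification; a logistic emergence law is
available for misspecification and model-selection power experiments.
Defaults mirror the reference design: 19 articles, 7 themes, T_c = 8.2
months, 51-month window. Themes emerging after the window are absent from
the matrix and excluded from the normalizing denominator, as in real
corpora. All randomness flows from a single seed; recovery replicates use
seeds spawned deterministically from it.

What the simulations do *not* emulate: clustered publication bursts,
theme-to-theme correlation within an article, coder error, and corpus
growth that feeds back on itself; passing recovery tests therefore
demonstrates estimator correctness under the model, not robustness of the
model for any particular real corpus.

## Known limitations

- **The estimator's information floor.** T_c information comes from the
  theme emergence times alone — n_themes draws — so no estimator can beat
  a relative error of ~1/√n_themes (≈ 14% at 50 themes, ≈ 38% at 7). The
  least-squares pipeline essentially attains this floor (measured
  relative RMSE 14.3% at 100 articles × 50 themes); adding articles
  refines the time resolution but adds no draws.
- **Wald CIs undercover on cumulative data.** The residuals of a
  cumulative curve are strongly autocorrelated, while the Wald covariance
  assumes i.i.d. errors; the nominal 95% intervals' measured coverage of
  the true T_c is far below nominal (~0.1–0.3 in simulation). The
  intervals are reported because they are the field's convention for this
  analysis, but they describe curve-fit uncertainty, not sampling
  uncertainty of the emergence process; the recovery harness quantifies
  the gap, and a theme-level (nonparametric) bootstrap would be the
  remedy if calibrated intervals are needed.
- Exact publication days are unknown; all dates are month-resolved by
  convention (sensitivity ≈ ±0.5 month on elapsed times).
- The 99.9% thresholds extrapolate the fitted law well beyond the
  observation window.

## Problem sizes used in the test suite

Unit and property tests run on the 19-article reference corpus and on
simulated designs up to 100 articles × 50 themes with 500 recovery
replicates (a few seconds each); the bootstrap cross-check uses 600
replicates. These sizes make the stochastic assertions stable at the
stated tolerances while keeping the suite fast.
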