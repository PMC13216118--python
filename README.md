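# themesat

Quantitative modelling of how descriptive evidence **themes** — device
utilities and operational issues coded from clinical articles — emerge and
saturate in an early-adoption literature corpus.

When a new medical device enters clinical use, the first wave of
publications is descriptive: surgeons report what the device makes easier
and what gets in the way, long before randomized trials exist. If those
observations are coded into a binary article × theme presence matrix, the
cumulative number of *distinct* themes observed over time traces a
saturation curve: new themes appear quickly at first, then the corpus runs
out of new things to say. `themesat` implements that analysis end to end:

- **corpus** — article × theme presence matrices (wide/long CSV I/O, JSON
  codebooks), publication-month date resolution, an elapsed-time axis with
  a fixed 30.4375-day month, and an embedded reference dataset: 19 studies
  of early da Vinci surgical-robot adoption (2001–2004, 7 utility themes +
  9 issue themes, observation window anchored the day after FDA clearance,
  2000-07-12).
- **agreement** — inter-rater reliability of the coding: agreement rate
  p_o, Cohen's κ = (p_o − p_e)/(1 − p_e) with p_e from each coder's
  marginals, Landis–Koch interpretation bands, and the a-priori
  thresholds (p_o > 0.90, κ ≥ 0.80).
- **emergence** — cumulative emergence series under the first-occurrence
  rule: T_sum,n = Σ_{i≤n} T_new,i, proportion = 100·T_sum,n / T_sum,End,
  on either explanatory axis (months since clearance, or publication
  count).
- **saturation** — nonlinear least-squares fits of two candidate curves,
  the exponential plateau f(t) = 100(1 − e^(−t/T_c)) and the logistic
  f(t) = 100/(1 + a·e^(−bt)), compared by small-sample AICc, adjusted R²
  and RMSE, with Wald parameter CIs.
- **thresholds** — inversion of the fitted curve for the time (or number
  of publications) to reach 50%, 80% and 99.9% (the saturation proxy),
  with transform / delta / bootstrap confidence intervals.
- **simulate** — a synthetic corpus generator whose emergence law matches
  the fitted model exactly (theme emergence times ~ Exponential(T_c)),
  plus a parameter-recovery harness reporting bias, relative RMSE and CI
  coverage.

## Worked example

```python
from themesat import (davinci_fixture, resolve_dates, emergence_series,
                      fit_series, compare_series, threshold_ci)

matrix, window = davinci_fixture()          # 19 articles x 16 themes
matrix = resolve_dates(matrix, "mid", window=window)

series = emergence_series(matrix, window, "utility", "months")
comp = compare_series(series)               # exponential vs logistic
fit = comp.fits[comp.selected]
print(comp.selected.value,
      round(fit.model.params["Tc"], 2),
      round(fit.r2_adj, 3), round(fit.rmse, 2))

t50 = threshold_ci(fit, 50.0, method="transform", axis="months")
print(round(t50.estimate, 1), [round(v, 1) for v in t50.ci95])
```

prints

```
exponential 8.26 0.973 3.61
5.7 [5.1, 6.3]
```

i.e. the exponential model is selected (AICc), the utility-theme time
constant is ≈ 8.3 months — about 63.2% of all utility themes had emerged
8.3 months after device clearance — and half of the themes had emerged by
5.7 months (95% CI 5.1–6.3). Issue themes saturate roughly twice as
slowly (T_c ≈ 16.3 months).

The same pipeline is available from the shell:

```bash
themesat fit --fixture --outdir out/       # series CSVs, fit/compare JSON,
                                           # threshold table, report figure
themesat agree coder_a.csv coder_b.csv     # agreement rate, kappa, verdicts
themesat simulate --tc-true 8.2 --n-reps 500 --seed 1
```

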