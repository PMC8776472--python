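# scalefit

Benchmarking missing-data imputation for ordinal questionnaire (Likert
scale) data under the three classical missingness mechanisms.

Clinical self-rating scales — the motivating case is the 20-item, 4-level
Zung Self-rating Depression Scale in a 507-patient post-stroke depression
cohort — routinely come back with unanswered items, and the right way to
fill the holes depends on *why* the data are missing (MCAR / MAR / MNAR)
and *how much* is missing. `scalefit` provides the full simulation
apparatus to study that question:

- **synthetic cohorts**: a one-factor latent-severity generator producing
  complete, positively inter-correlated ordinal item matrices with a
  realistic sex split and a calibrated item-2 severity grouping;
- **amputation**: exact-count cell deletion at overall rates 5–40% under
  MCAR (uniform), MAR (deletion rate depends on sex) and MNAR (depends on
  the true item-2 score), with the closed-form group-rate solver
  `r = (R·(n_fixed + n_free) − r_fixed·n_fixed) / n_free` that balances a
  fixed 10% reference-group rate to the overall target `R`;
- **imputers**: mean substitution (MS), predictive mean matching by
  chained equations (PMM, m = 20 completions, 5 sweeps, 5-donor pools,
  Bayesian coefficient draws), and missForest-style iterative random-forest
  regression (RFR, 50 trees per forest, stop when the normalised squared
  change of the imputed cells increases);
- **evaluation** on the normalised total score `T = Σ items / 80`: RMSE,
  the full width of the paired-t 95% CI of the mean difference
  `2·t₀.₉₇₅,ₙ₋₁·sd(d)/√n`, and the Spearman rank correlation (SCC);
- an **experiment runner** crossing mechanism × rate × method with
  replication (all methods see the identical mask per cell) and a
  recommendation table: published decision rules or data-driven argmin-RMSE.

## Worked example

```python
import scalefit as sf

cohort = sf.generate_cohort(sf.default_spec(), seed=1)
masked = sf.ampute(cohort, sf.MissingnessSpec("MCAR", overall_rate=0.20, seed=2))
for method in ("MS", "PMM", "RFR"):
    fitted = sf.impute(masked, sf.ImputerConfig(method=method, seed=3))
    rec = sf.evaluate_fit(cohort, fitted)
    print(method, round(rec.rmse, 4), round(rec.ci_width, 5), round(rec.scc, 4))
```

prints (see `examples/03_impute_and_score.py`):

```
method     rmse  ci_width     scc
MS       0.0362   0.00632  0.9868
PMM      0.0289   0.00503  0.9779
RFR      0.0210   0.00366  0.9886
```

At 20% MCAR the forest imputer tracks the true total scores most closely
(lowest RMSE, narrowest CI) while all three preserve the subject ranking
almost perfectly (SCC ≈ 0.98–0.99). The `examples/` directory holds one
short narrative script per capability: cohort generation and calibration,
amputation and missing-item tabulation, imputation and scoring, and a
reduced benchmark grid with the recommendation table. A thin CLI mirrors
the pipeline stages (`scalefit generate | ampute | impute | evaluate |
run-grid | recommend`).

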