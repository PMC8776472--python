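"""Fit one masked dataset with all three imputers and score the fits.

Amputes the cohort at 20% under MCAR, imputes with mean substitution,
predictive mean matching (20 completions) and iterative random-forest
regression, and evaluates each against the complete truth on the
normalised total-score scale (raw total / 80).
"""

import scalefit as sf

cohort = sf.generate_cohort(sf.default_spec(), seed=1)
masked = sf.ampute(cohort, sf.MissingnessSpec("MCAR", overall_rate=0.20, seed=2))

print(f"{'method':6} {'rmse':>8} {'ci_width':>9} {'scc':>7}")
for method in ("MS", "PMM", "RFR"):
    fitted = sf.impute(masked, sf.ImputerConfig(method=method, seed=3))
    rec = sf.evaluate_fit(cohort, fitted, mechanism="MCAR", overall_rate=0.20)
    print(f"{method:6} {rec.rmse:8.4f} {rec.ci_width:9.5f} {rec.scc:7.4f}")

# Lower RMSE and CI width mean a more accurate/precise fit of the total
# scores; SCC near 1 means subject ranking is preserved.  PMM reports the
# metric averaged over its 20 completions; its imputed values are always
# observed levels (donor copies), while MS/RFR may be fractional.
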