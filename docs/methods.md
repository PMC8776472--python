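# Methods

## The problem

Self-rating questionnaires in clinical research — here the 20-item, 4-level
Zung Self-rating Depression Scale (SDS) as used in a post-stroke depression
cohort — routinely come back with unanswered items. Whether a missing cell
can be filled in credibly, and by which algorithm, depends on two things:
the *mechanism* that produced the hole (completely at random, dependent on
an observed covariate, or dependent on the unobserved value itself) and the
*overall rate* of missingness. `scalefit` implements the full simulation
apparatus needed to answer that question for ordinal scale data: a complete
synthetic cohort, controlled amputation, three imputation algorithms, and
three fitting-quality metrics, orchestrated over a mechanism x rate x method
grid.

## Synthetic cohort model

Real patient data of this kind is not publicly deposited, so the package
generates complete cohorts from a one-factor graded-response-style model:

- Subject *i* has a latent depression severity
  `theta_i ~ Normal(mu_sex(i), sigma_theta)`.
- Item *j*'s continuous response is `y_ij = lambda_j * theta_i + eps_ij`,
  `eps_ij ~ Normal(0, sigma_eps)`.
- `y_ij` is cut into levels 1..4 by three ordered thresholds per item.

Defaults (frozen before any benchmark was run, and not revisited):

| parameter | default | rationale |
|---|---|---|
| n (male / female) | 507 (313 / 194) | the reference cohort's size and sex split |
| items x levels | 20 x 4 | the SDS layout |
| `mu_male`, `mu_female` | 0.0, 0.2 z-units | small female excess in depressive symptom scores, a robust epidemiological regularity; the benchmark is insensitive to the exact value because sex enters the pipeline only through deletion rates |
| `sigma_theta`, `sigma_eps` | 1.0, 1.0 | one common factor explaining half the latent item variance; after discretisation this yields mean pairwise inter-item Spearman correlations around 0.3–0.4, i.e. "well-correlated items" without being degenerate |
| `lambda_j` | 1 for all items | items treated symmetrically; reverse-scored item semantics are out of scope |
| shared thresholds | mixture-CDF quantiles at cumulative probs (0.15, 0.50, 0.85) | a moderately severe, roughly symmetric level distribution |
| item-2 thresholds | quantiles at (0.08, 108/507, 0.60) | calibrates P(item2 <= 2) to exactly 108/507 = 0.213 in expectation, reproducing the low/high severity split that drives the MNAR mechanism |
| age | Normal(60.11, 9.55) M / Normal(62.94, 8.77) F, years | the reference cohort's means; the +/- values reported there are read as standard errors of the mean and converted to SDs (0.54·sqrt(313), 0.63·sqrt(194)), since an age SD of half a year is implausible. Age is descriptive only — no downstream stage uses it |

Thresholds are *exact* quantiles of the marginal distribution of `y_ij`
(a two-component normal mixture over the sexes), computed by root-finding
on its closed-form CDF (`latent_cutpoints`), so the item-2 calibration
holds analytically, not just by Monte Carlo.

What the generator does **not** emulate: multi-factor structure,
reverse-keyed items, differential item functioning by sex or age, response
styles (straight-lining, extreme responding), or any fit to the real
cohort's unreported inter-item correlations. Passing benchmarks on this
cohort therefore demonstrate correctness of the pipeline and the *relative*
behaviour of the imputers under a realistic one-factor correlation
structure; absolute metric values on real SDS data may differ.

## Amputation

Deletion is cell-wise over the item matrix (covariates are never deleted)
and uses exact-count sampling: each group loses exactly
`round(rate * group_cells)` cells drawn uniformly without replacement, so
the realised rate is a set property of every mask (within one cell of the
target). The binomial closed form is the distributional oracle used in
tests: at MCAR rate q the expected share of subjects with zero missing
items is `(1-q)^20`.

- **MCAR**: one pool of all cells at the overall rate.
- **MAR**: female cells at a fixed 10%, male cells at the closed-form
  balancing rate `r = (R(n_f + n_m) - 0.10 n_f) / n_m` so the overall rate
  is `R` (solver: `solve_group_rate`; infeasible combinations raise an
  error stating the attainable overall-rate range).
- **MNAR**: same algebra with groups defined by the *true* item-2 score
  (1–2 vs 3–4). The grouping uses the pre-deletion value, and item 2 itself
  is deletable — self-masking is precisely what makes the mechanism
  not-at-random. Group sizes are whatever the generated cohort produced
  (about 108/399 in expectation), not hard-coded counts.

Whether the original study deleted by exact count or by independent
Bernoulli draws is not stated; exact-count was chosen because the published
per-set rates are presented as exact properties, and at n = 10 140 cells the
two schemes agree in distribution to well within every tolerance used here.

## Imputation algorithms

All three treat items as continuous for regression purposes. Mean
substitution and forest outputs remain fractional (clipped to [1, 4]) —
rounding to levels would discard information before the total-score metrics.

**Mean substitution (MS).** Each deleted cell gets the arithmetic mean of
its column's observed values. Deterministic, single completion.

**Predictive mean matching (PMM).** `m = 20` independent chained-equation
chains, 5 sweeps each, 5-donor pools. Each chain initialises missing cells
with random draws from the column's observed values, then visits incomplete
columns in ascending-missingness order. Per column: a linear regression of
the observed values on all other columns' current values; residual variance
and coefficients drawn from the standard normal–inverse-gamma posterior
under a noninformative prior; predicted means for observed rows under the
posterior-mean coefficients and for missing rows under the drawn
coefficients; each missing cell copies the observed value of one of the 5
donors with nearest predicted mean, chosen uniformly. Imputed values are
therefore always observed levels (integers 1–4). A singular cross-product
falls back to a ridge-stabilised fit (diagonal inflation 1e-5 of the mean
diagonal), recorded in the diagnostics rather than raised; donor pools
smaller than 5 shrink with a diagnostic count. Donor count, visit order and
initialisation follow the conventional chained-equations defaults; the
sweep count of 5 is a study condition, kept even though more sweeps might
favour PMM.

**Iterative random-forest regression (RFR).** The missForest procedure:
initialise missing cells with column means; per sweep, refit a
random-forest regression for each incomplete column (ascending-missingness
order) on all other columns' current values and re-predict its missing
cells; after each sweep compute the normalised squared change
`delta = sum((X_new - X_old)^2) / sum(X_new^2)` over imputed cells; stop
when delta first increases (returning the previous sweep's matrix) or after
10 sweeps. Forests use 50 trees, bootstrap sampling, CART base learners
with `mtry = floor(sqrt(p))` feature subsampling and a minimum leaf size of
5 — the defaults of the R randomForest regression mode that the missForest
procedure is defined around. The forest itself comes from scikit-learn;
the iteration loop, ordering and stopping rule are implemented here.

A single integer seed deterministically derives every per-chain and
per-forest substream (`SeedSequence`-based, 31-bit), so all three methods
and the whole grid are pure functions of their configs.

## Evaluation metrics

All metrics operate on the **normalised total score**: the per-subject item
total divided by its maximum (80 for 20 x 4), so values lie in (0.25, 1].
The published metric ranges (RMSE up to 0.2, CI widths of 0.005–0.035)
are only consistent with this unit-normalised scale, which is why it is the
package default; raw-total-scale output is a one-line rescale (x80). Per
fitted set:

- **RMSE** = root mean square of the per-subject normalised-total
  differences, over *all* subjects (also those with no missing items).
- **95% CI width** = `2 * t_{0.975, n-1} * sd(d) / sqrt(n)`, the full width
  of the two-sided Student interval for the mean paired difference `d`.
- **SCC** = Spearman rank correlation of the two normalised-total vectors,
  midranks for ties.

For PMM's 20 completions each metric is computed per completion and
arithmetically averaged — pooling the metric rather than averaging the
completed data, which would artificially smooth the imputations. A
cell-level RMSE (over deleted cells only) exists as a debug quantity in the
test helpers but is not a reported metric.

## The benchmark grid and recommendation

`run_grid` crosses {MCAR, MAR, MNAR} x {5…40%} x {MS, PMM, RFR} with
replication (default 10; the acceptance runs use 5). Per replicate a fresh
cohort is drawn; per (mechanism, rate) one mask is built and **shared by
all methods**, so methods compete on identical inputs. Failed cells are
logged and skipped, not fatal. Cells are labelled `C10M`-style
(mechanism code + percent + method code).

`recommend_path` emits the best-method table either by the published
decision rules — MS below 20% under MCAR, below 35% under MAR, RFR
otherwise and always under MNAR, with strict "<" at the boundary as the
conclusions phrase it (the source's abstract and discussion are in slight
tension about the MAR cutoff; the conclusions wording is followed) — or
data-driven: lowest mean RMSE per cell, ties broken by highest SCC, then
lowest CI width.

## Numerical and scale choices

- Exact-count rounding uses `round()`; realised overall rates are within
  one cell of the target by construction.
- Solved group rates are used at full precision in masks and rounded to two
  decimals only for display.
- Identical total-score vectors short-circuit the Spearman computation to
  exactly 1.0 (avoiding 1 - 2e-16 from the generic path).
- Acceptance-scale runs use the full 507-subject cohort, all 24 grid cells
  and 5 replicates; mechanics-oriented unit tests use a scaled-down cohort
  (60 subjects, 8 items) where the contract under test is size-independent.

## Known limitations

- One-factor cohorts cannot expose imputer behaviour that depends on
  multi-factor or nonlinear item structure (where forests would plausibly
  gain more ground over linear PMM).
- PMM is run at 5 sweeps as specified; its relative underperformance here
  partially reflects that condition and the metric-level pooling.
- The MNAR design is a group-rate construction (severity group determines
  the deletion rate); smooth value-dependent missingness (e.g. logistic in
  the latent severity) is out of scope.
- The recommendation table's published-rules mode encodes the source
  study's conclusions; the data-driven mode on synthetic cohorts tends to
  prefer RFR nearly everywhere, which is itself an informative discrepancy
  but says nothing about the real cohort.
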