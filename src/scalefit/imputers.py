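"""The three missing-value fitting algorithms.

* Mean substitution (MS): each deleted cell receives the arithmetic mean of
  its column's observed values (kept fractional).
* Predictive mean matching (PMM): chained equations producing ``pmm_m``
  completed datasets.  Each chain initialises missing cells with random
  observed draws, then sweeps the columns in ascending-missingness order:
  a Bayesian linear regression of the column on all others (noninformative
  normal-inverse-gamma posterior), predicted means for observed rows under
  the posterior-mean coefficients and for missing rows under the drawn
  coefficients, and each missing cell copies the value of one of the
  ``pmm_donors`` observed rows with the nearest predicted mean.  Imputed
  values are therefore always values observed somewhere in the same column.
* Iterative random-forest regression (RFR): the missForest procedure —
  mean-initialise, then refit a random-forest regression per incomplete
  column and re-predict its missing cells, sweeping until the normalised
  squared change of the imputed cells stops decreasing, and returning the
  matrix from the sweep before the increase.

All three preserve observed cells exactly and are deterministic given the
config seed.  Items are treated as continuous in the regressions; MS and
RFR outputs stay fractional (clipped to the level range), PMM outputs are
donor copies and hence integer levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from sklearn.ensemble import RandomForestRegressor

from ._errors import UnimputableColumnError, ValidationError
from .amputation import MaskedDataset

__all__ = [
    "METHODS",
    "ImputedSet",
    "ImputerConfig",
    "impute",
    "impute_mean",
    "impute_pmm",
    "impute_rfr",
]

METHODS = ("MS", "PMM", "RFR")

# ridge fraction added to the cross-product diagonal when it is singular;
# matches the magnitude conventionally used to stabilise chained equations
_RIDGE = 1e-5


@dataclass(frozen=True)
class ImputerConfig:
    """Algorithm choice and parameters.

    Defaults follow the study conditions: 20 PMM completions with 5 sweeps
    and a 5-donor pool, 50 trees per forest with a 10-sweep safety cap.
    A single integer seed deterministically derives every per-chain and
    per-forest substream.
    """

    method: str = "RFR"
    pmm_m: int = 20
    pmm_maxit: int = 5
    pmm_donors: int = 5
    rfr_ntree: int = 50
    rfr_max_iter: int = 10
    seed: int = 0
    clip: bool = True

    def validate(self) -> None:
        if self.method not in METHODS:
            raise ValidationError(
                f"unknown method {self.method!r}; expected one of {METHODS}",
                field="method",
            )
        for name in ("pmm_m", "pmm_maxit", "pmm_donors", "rfr_ntree", "rfr_max_iter"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1", field=name)
        if self.seed < 0:
            raise ValidationError("seed must be a non-negative integer", field="seed")


@dataclass
class ImputedSet:
    """One completed matrix (MS, RFR) or several (PMM), plus diagnostics."""

    completions: list[np.ndarray]
    method: str
    diagnostics: dict = field(default_factory=dict)

    @property
    def m(self) -> int:
        return len(self.completions)


def _observed_view(masked: MaskedDataset) -> tuple[np.ndarray, np.ndarray]:
    x = masked.observed_items()
    return x, ~np.isnan(x)


def _check_columns_observed(observed: np.ndarray) -> None:
    empty = np.where(~observed.any(axis=0))[0]
    if empty.size:
        j = int(empty[0])
        raise UnimputableColumnError(
            f"column item_{j + 1} has no observed values to impute from",
            column=f"item_{j + 1}",
        )


def _sub_seed(seed: int, *tags: int) -> int:
    """Derive a deterministic 31-bit substream seed from a global seed."""
    return int(
        np.random.SeedSequence([int(seed), *map(int, tags)]).generate_state(1)[0]
        % (2**31)
    )


def impute_mean(masked: MaskedDataset) -> ImputedSet:
    """Mean substitution: column-mean fill, one completion, no randomness."""
    x, observed = _observed_view(masked)
    _check_columns_observed(observed)
    out = x.copy()
    for j in range(x.shape[1]):
        miss = ~observed[:, j]
        if miss.any():
            out[miss, j] = x[observed[:, j], j].mean()
    n_levels = masked.base.n_levels
    np.clip(out, 1.0, float(n_levels), out=out)
    return ImputedSet(
        completions=[out],
        method="MS",
        diagnostics={"n_imputed": int((~observed).sum())},
    )


def _bayes_draw(
    X: np.ndarray, y: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Posterior-mean and posterior-draw coefficients for y ~ X.

    Noninformative prior: sigma^2 drawn scaled-inverse-chi-square from the
    residual sum of squares, beta drawn N(beta_hat, sigma^2 (X'X)^-1).
    Returns (beta_hat, beta_draw, ridged) where ridged flags a
    ridge-stabilised fit after a singular cross-product.
    """
    n, p = X.shape
    xtx = X.T @ X
    xty = X.T @ y
    ridged = False
    try:
        chol = cho_factor(xtx, lower=False)
    except np.linalg.LinAlgError:
        ridged = True
        xtx = xtx + _RIDGE * np.trace(xtx) / p * np.eye(p)
        chol = cho_factor(xtx, lower=False)
    beta_hat = cho_solve(chol, xty)
    resid = y - X @ beta_hat
    df = max(n - p, 1)
    sigma2 = float(resid @ resid) / rng.chisquare(df)
    # beta_draw = beta_hat + sigma * R^{-1} z with X'X = R'R
    z = rng.standard_normal(p)
    upper = np.triu(chol[0])
    w = np.linalg.solve(upper, z)
    beta_draw = beta_hat + np.sqrt(sigma2) * w
    return beta_hat, beta_draw, ridged


def impute_pmm(masked: MaskedDataset, config: ImputerConfig) -> ImputedSet:
    """Predictive mean matching via chained equations, ``pmm_m`` chains."""
    config.validate()
    x, observed = _observed_view(masked)
    _check_columns_observed(observed)
    n, p = x.shape
    miss_counts = (~observed).sum(axis=0)
    # visit incomplete columns from least to most missing (ties by index)
    visit = [j for j in np.argsort(miss_counts, kind="stable") if miss_counts[j] > 0]

    shrunk_pools = 0
    ridged_fits = 0
    completions: list[np.ndarray] = []
    for chain in range(config.pmm_m):
        rng = np.random.default_rng(_sub_seed(config.seed, chain))
        cur = x.copy()
        # initialise missing cells with random draws from observed values
        for j in visit:
            obs_vals = x[observed[:, j], j]
            k = int(miss_counts[j])
            cur[~observed[:, j], j] = rng.choice(obs_vals, size=k, replace=True)
        if visit:
            for _ in range(config.pmm_maxit):
                for j in visit:
                    obs_j = observed[:, j]
                    mis_j = ~obs_j
                    others = np.delete(np.arange(p), j)
                    design = np.c_[np.ones(n), cur[:, others]]
                    beta_hat, beta_draw, ridged = _bayes_draw(
                        design[obs_j], x[obs_j, j], rng
                    )
                    ridged_fits += int(ridged)
                    yhat_obs = design[obs_j] @ beta_hat
                    yhat_mis = design[mis_j] @ beta_draw
                    donors = min(config.pmm_donors, int(obs_j.sum()))
                    if donors < config.pmm_donors:
                        shrunk_pools += 1
                    obs_vals = x[obs_j, j]
                    # nearest-|predicted mean| donor pools, one row per missing cell
                    dist = np.abs(yhat_obs[None, :] - yhat_mis[:, None])
                    pools = np.argpartition(dist, donors - 1, axis=1)[:, :donors]
                    picks = rng.integers(donors, size=yhat_mis.size)
                    cur[mis_j, j] = obs_vals[pools[np.arange(yhat_mis.size), picks]]
        completions.append(cur)

    return ImputedSet(
        completions=completions,
        method="PMM",
        diagnostics={
            "chains": config.pmm_m,
            "sweeps": config.pmm_maxit if visit else 0,
            "ridged_fits": ridged_fits,
            "shrunk_donor_pools": shrunk_pools,
        },
    )


def impute_rfr(masked: MaskedDataset, config: ImputerConfig) -> ImputedSet:
    """Iterative random-forest imputation with the missForest stopping rule."""
    config.validate()
    x, observed = _observed_view(masked)
    _check_columns_observed(observed)
    n, p = x.shape
    n_levels = masked.base.n_levels
    miss_counts = (~observed).sum(axis=0)
    visit = [j for j in np.argsort(miss_counts, kind="stable") if miss_counts[j] > 0]

    cur = x.copy()
    for j in visit:
        cur[~observed[:, j], j] = x[observed[:, j], j].mean()

    deltas: list[float] = []
    if not visit:
        return ImputedSet(
            completions=[cur], method="RFR", diagnostics={"iterations": 0, "deltas": []}
        )

    imputed_mask = ~observed
    prev_delta = np.inf
    iterations = 0
    for it in range(1, config.rfr_max_iter + 1):
        before = cur.copy()
        for j in visit:
            obs_j = observed[:, j]
            others = np.delete(np.arange(p), j)
            forest = RandomForestRegressor(
                n_estimators=config.rfr_ntree,
                max_features="sqrt",
                min_samples_leaf=5,
                bootstrap=True,
                random_state=_sub_seed(config.seed, it, j),
            )
            forest.fit(cur[obs_j][:, others], x[obs_j, j])
            cur[~obs_j, j] = forest.predict(cur[~obs_j][:, others])
        num = float(((cur - before)[imputed_mask] ** 2).sum())
        den = float((cur[imputed_mask] ** 2).sum())
        delta = num / den if den > 0 else 0.0
        deltas.append(delta)
        iterations = it
        if delta > prev_delta:
            cur = before  # revert to the sweep with the smaller change
            break
        prev_delta = delta

    np.clip(cur, 1.0, float(n_levels), out=cur)
    return ImputedSet(
        completions=[cur],
        method="RFR",
        diagnostics={"iterations": iterations, "deltas": deltas},
    )


def impute(masked: MaskedDataset, config: ImputerConfig) -> ImputedSet:
    """Dispatch on ``config.method``."""
    config.validate()
    if config.method == "MS":
        return impute_mean(masked)
    if config.method == "PMM":
        return impute_pmm(masked, config)
    return impute_rfr(masked, config)
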