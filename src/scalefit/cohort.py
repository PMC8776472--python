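"""Synthetic questionnaire cohorts with a single latent severity factor.

The generator emulates a depression-scale cohort: each subject carries a
latent severity drawn from a sex-specific normal distribution, each item is
a noisy linear read-out of that severity, and the continuous read-out is
discretised through ordered cutpoints into Likert levels ``1..n_levels``.
One common factor is enough to give the positively inter-correlated items
that regression-based imputation exploits.

Scores follow the Zung Self-rating Depression Scale layout by default:
20 items, 4 levels, 507 subjects (313 male / 194 female).  Item 2 (diurnal
variation, the severity marker used for value-dependent missingness
downstream) gets its own cutpoints, calibrated so that the probability of
scoring 1–2 equals 108/507 under the default population mixture.
"""

from __future__ import annotations

import numbers
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.stats import norm

from ._errors import FormatError, ParseError, ValidationError

__all__ = [
    "CohortSpec",
    "ScaleDataset",
    "default_spec",
    "generate_cohort",
    "latent_cutpoints",
    "read_dataset",
    "write_dataset",
    "spec_from_yaml",
    "spec_to_yaml",
]

#: fraction of subjects in the reference cohort scoring 1-2 on item 2
ITEM2_LOW_TARGET = 108 / 507

# cumulative level probabilities used to place the default cutpoints:
# shared items get a symmetric-ish spread, item 2 is anchored at the
# low-group fraction above (second cutpoint = P(score <= 2)).
_SHARED_CUM_PROBS = (0.15, 0.50, 0.85)
_ITEM2_CUM_PROBS = (0.08, ITEM2_LOW_TARGET, 0.60)

_ITEM2_INDEX = 1  # zero-based column of "item_2"


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the synthetic cohort generator.

    Severity means are on the latent z-scale; ``item_loadings`` weight the
    latent severity per item and ``item_thresholds`` (shape
    ``(n_items, n_levels - 1)``, strictly increasing per row) cut the latent
    item response into ordinal levels.  Ages are descriptive covariates in
    years, never used by amputation or imputation.
    """

    n_total: int = 507
    n_male: int = 313
    n_female: int = 194
    n_items: int = 20
    n_levels: int = 4
    severity_mean_male: float = 0.0
    severity_mean_female: float = 0.2
    severity_sd: float = 1.0
    item_loadings: np.ndarray = field(default=None)  # type: ignore[assignment]
    item_thresholds: np.ndarray = field(default=None)  # type: ignore[assignment]
    noise_sd: float = 1.0
    age_mean_male: float = 60.11
    age_sd_male: float = 9.55
    age_mean_female: float = 62.94
    age_sd_female: float = 8.77

    def __post_init__(self):
        if self.item_loadings is not None:
            object.__setattr__(
                self, "item_loadings", np.asarray(self.item_loadings, dtype=float)
            )
        if self.item_thresholds is not None:
            object.__setattr__(
                self, "item_thresholds", np.asarray(self.item_thresholds, dtype=float)
            )

    def validate(self) -> None:
        if self.n_male + self.n_female != self.n_total:
            raise ValidationError(
                f"n_male + n_female = {self.n_male + self.n_female} "
                f"!= n_total = {self.n_total}",
                field="n_total",
            )
        if self.n_items < 1:
            raise ValidationError("n_items must be >= 1", field="n_items")
        if self.n_levels < 2:
            raise ValidationError("n_levels must be >= 2", field="n_levels")
        if not self.severity_sd > 0:
            raise ValidationError("severity_sd must be > 0", field="severity_sd")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0", field="noise_sd")
        for name in ("age_sd_male", "age_sd_female"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0", field=name)
        if self.item_loadings is None or self.item_thresholds is None:
            raise ValidationError(
                "item_loadings and item_thresholds must be set "
                "(use default_spec() for calibrated defaults)",
                field="item_loadings" if self.item_loadings is None else "item_thresholds",
            )
        if self.item_loadings.shape != (self.n_items,):
            raise ValidationError(
                f"item_loadings has shape {self.item_loadings.shape}, "
                f"expected ({self.n_items},)",
                field="item_loadings",
            )
        expect = (self.n_items, self.n_levels - 1)
        if self.item_thresholds.shape != expect:
            raise ValidationError(
                f"item_thresholds has shape {self.item_thresholds.shape}, "
                f"expected {expect}",
                field="item_thresholds",
            )
        if not np.all(np.diff(self.item_thresholds, axis=1) > 0):
            bad = int(np.where(~np.all(np.diff(self.item_thresholds, axis=1) > 0, axis=1))[0][0])
            raise ValidationError(
                f"item_thresholds must be strictly increasing per item "
                f"(violated at item {bad + 1})",
                field="item_thresholds",
            )


def latent_cutpoints(
    cum_probs,
    loading: float = 1.0,
    *,
    n_male: int = 313,
    n_female: int = 194,
    severity_mean_male: float = 0.0,
    severity_mean_female: float = 0.2,
    severity_sd: float = 1.0,
    noise_sd: float = 1.0,
) -> np.ndarray:
    """Cutpoints on the latent item scale hitting given cumulative probabilities.

    The latent item response is ``loading * theta + noise`` where ``theta``
    comes from the two-sex normal mixture, so its marginal CDF is a mixture
    of two normal CDFs; each cutpoint is the exact quantile of that mixture.
    This is how the default thresholds (including the item-2 calibration to
    the 108/507 low-scorer fraction) are derived.
    """
    w_m = n_male / (n_male + n_female)
    w_f = 1.0 - w_m
    sd = float(np.hypot(loading * severity_sd, noise_sd))
    mu_m = loading * severity_mean_male
    mu_f = loading * severity_mean_female

    def cdf(t: float) -> float:
        return w_m * norm.cdf((t - mu_m) / sd) + w_f * norm.cdf((t - mu_f) / sd)

    lo = min(mu_m, mu_f) - 10 * sd
    hi = max(mu_m, mu_f) + 10 * sd
    cuts = [brentq(lambda t, p=p: cdf(t) - p, lo, hi) for p in cum_probs]
    out = np.asarray(cuts, dtype=float)
    if not np.all(np.diff(out) > 0):
        raise ValidationError("cum_probs must be strictly increasing")
    return out


def default_spec() -> CohortSpec:
    """The reference cohort: 507 subjects, 20 four-level items, unit loadings.

    Item-2 cutpoints are placed so the expected fraction of subjects scoring
    1-2 on item 2 equals 108/507 (the low-severity group of the
    value-dependent missingness mechanism); all other items share one set of
    cutpoints at cumulative probabilities (0.15, 0.50, 0.85).
    """
    base = CohortSpec()
    kw = dict(
        n_male=base.n_male,
        n_female=base.n_female,
        severity_mean_male=base.severity_mean_male,
        severity_mean_female=base.severity_mean_female,
        severity_sd=base.severity_sd,
        noise_sd=base.noise_sd,
    )
    shared = latent_cutpoints(_SHARED_CUM_PROBS, 1.0, **kw)
    item2 = latent_cutpoints(_ITEM2_CUM_PROBS, 1.0, **kw)
    thresholds = np.tile(shared, (base.n_items, 1))
    thresholds[_ITEM2_INDEX] = item2
    spec = replace(
        base,
        item_loadings=np.ones(base.n_items),
        item_thresholds=thresholds,
    )
    spec.validate()
    return spec


@dataclass
class ScaleDataset:
    """A complete subjects-by-items matrix of ordinal scores plus covariates."""

    subject_id: np.ndarray
    sex: np.ndarray  # 'M' / 'F'
    age: np.ndarray
    items: np.ndarray  # int matrix, values in 1..n_levels
    n_levels: int = 4

    def __post_init__(self):
        self.subject_id = np.asarray(self.subject_id)
        self.sex = np.asarray(self.sex)
        self.age = np.asarray(self.age, dtype=float)
        self.items = np.asarray(self.items)
        n = self.items.shape[0]
        if not (len(self.subject_id) == len(self.sex) == len(self.age) == n):
            raise ValidationError("covariate lengths do not match the item matrix")

    @property
    def n_subjects(self) -> int:
        return self.items.shape[0]

    @property
    def n_items(self) -> int:
        return self.items.shape[1]

    @property
    def item2_group(self) -> np.ndarray:
        """'low' where item 2 is 1-2, 'high' where it is 3 or more."""
        return np.where(self.items[:, _ITEM2_INDEX] <= 2, "low", "high")

    def total_scores(self) -> np.ndarray:
        return self.items.sum(axis=1)

    def item_columns(self) -> list[str]:
        return [f"item_{j + 1}" for j in range(self.n_items)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"subject_id": self.subject_id, "sex": self.sex, "age": self.age}
        )
        for j, col in enumerate(self.item_columns()):
            df[col] = self.items[:, j]
        return df

    def __eq__(self, other) -> bool:  # type: ignore[override]
        if not isinstance(other, ScaleDataset):
            return NotImplemented
        return (
            self.n_levels == other.n_levels
            and np.array_equal(self.subject_id, other.subject_id)
            and np.array_equal(self.sex, other.sex)
            and np.allclose(self.age, other.age)
            and np.array_equal(self.items, other.items)
        )


def generate_cohort(spec: CohortSpec, seed: int) -> ScaleDataset:
    """Draw a complete cohort from the latent-severity model.

    Males come first in row order (ids 1..n_male), then females.  The same
    ``(spec, seed)`` pair always yields the identical dataset.
    """
    spec.validate()
    if not isinstance(seed, numbers.Integral) or seed < 0:
        raise ValidationError("seed must be a non-negative integer", field="seed")
    rng = np.random.default_rng(int(seed))

    sex = np.array(["M"] * spec.n_male + ["F"] * spec.n_female)
    sev_mean = np.where(
        sex == "M", spec.severity_mean_male, spec.severity_mean_female
    )
    theta = rng.normal(sev_mean, spec.severity_sd)

    eps = rng.normal(0.0, spec.noise_sd, size=(spec.n_total, spec.n_items))
    latent = theta[:, None] * spec.item_loadings[None, :] + eps

    items = np.empty((spec.n_total, spec.n_items), dtype=np.int64)
    for j in range(spec.n_items):
        # level = 1 + number of cutpoints strictly below the latent response
        items[:, j] = 1 + np.searchsorted(
            spec.item_thresholds[j], latent[:, j], side="left"
        )

    age_mean = np.where(sex == "M", spec.age_mean_male, spec.age_mean_female)
    age_sd = np.where(sex == "M", spec.age_sd_male, spec.age_sd_female)
    age = np.round(rng.normal(age_mean, age_sd), 1)

    return ScaleDataset(
        subject_id=np.arange(1, spec.n_total + 1),
        sex=sex,
        age=age,
        items=items,
        n_levels=spec.n_levels,
    )


def write_dataset(dataset: ScaleDataset, path) -> None:
    """Write a complete cohort as CSV (header subject_id,sex,age,item_*)."""
    dataset.to_frame().to_csv(path, index=False)


def read_dataset(path, n_levels: int = 4) -> ScaleDataset:
    """Read a complete cohort CSV; items must be integers in 1..n_levels.

    Blank item cells are rejected here — incomplete data belongs to the
    masked-dataset format (see :mod:`scalefit.amputation`).
    """
    df = pd.read_csv(path, dtype={"sex": str})
    required = {"subject_id", "sex", "age"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"missing header column(s) {sorted(required - set(df.columns))}; "
            "expected subject_id,sex,age,item_1,...,item_N"
        )
    item_cols = [c for c in df.columns if c.startswith("item_")]
    if not item_cols:
        raise FormatError("no item_* columns found")
    item_cols = sorted(item_cols, key=lambda c: int(c.split("_")[1]))

    items = np.empty((len(df), len(item_cols)), dtype=np.int64)
    for j, col in enumerate(item_cols):
        vals = df[col]
        if vals.isna().any():
            row = int(vals.index[vals.isna()][0])
            raise ParseError(
                f"blank cell at row {row}, column {col}: complete-dataset CSV "
                "cannot contain missing values (use the masked-dataset format "
                "for incomplete data)",
                row=row,
                column=col,
            )
        as_float = vals.astype(float)
        if not np.all(as_float == np.round(as_float)):
            row = int(np.where(as_float != np.round(as_float))[0][0])
            raise ParseError(
                f"non-integer item value at row {row}, column {col}",
                row=row,
                column=col,
            )
        as_int = as_float.astype(np.int64)
        bad = (as_int < 1) | (as_int > n_levels)
        if bad.any():
            row = int(np.where(bad)[0][0])
            raise ParseError(
                f"item value {as_int[row]} out of range 1..{n_levels} "
                f"at row {row}, column {col}",
                row=row,
                column=col,
            )
        items[:, j] = as_int

    bad_sex = ~df["sex"].isin(["M", "F"])
    if bad_sex.any():
        row = int(np.where(bad_sex)[0][0])
        raise ParseError(f"sex must be 'M' or 'F' at row {row}", row=row, column="sex")

    return ScaleDataset(
        subject_id=df["subject_id"].to_numpy(),
        sex=df["sex"].to_numpy(),
        age=df["age"].to_numpy(dtype=float),
        items=items,
        n_levels=n_levels,
    )


_SPEC_SCALARS = {
    "n_total": int,
    "n_male": int,
    "n_female": int,
    "n_items": int,
    "n_levels": int,
    "severity_mean_male": float,
    "severity_mean_female": float,
    "severity_sd": float,
    "noise_sd": float,
    "age_mean_male": float,
    "age_sd_male": float,
    "age_mean_female": float,
    "age_sd_female": float,
}
_SPEC_ARRAYS = ("item_loadings", "item_thresholds")


def spec_from_yaml(path) -> CohortSpec:
    """Load a CohortSpec from a flat YAML mapping; unknown keys are rejected.

    Keys not present fall back to the calibrated defaults of
    :func:`default_spec` (thresholds are re-derived from the mixture CDF when
    population parameters change but thresholds are not given explicitly).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise FormatError("spec file must be a flat key-value mapping")
    known = set(_SPEC_SCALARS) | set(_SPEC_ARRAYS)
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(
            f"unknown spec key(s): {sorted(unknown)}", field=sorted(unknown)[0]
        )

    kwargs = {}
    for key, cast in _SPEC_SCALARS.items():
        if key in raw:
            kwargs[key] = cast(raw[key])
    for key in _SPEC_ARRAYS:
        if key in raw:
            kwargs[key] = np.asarray(raw[key], dtype=float)

    base = CohortSpec(**kwargs)
    if base.item_loadings is None or base.item_thresholds is None:
        mix = dict(
            n_male=base.n_male,
            n_female=base.n_female,
            severity_mean_male=base.severity_mean_male,
            severity_mean_female=base.severity_mean_female,
            severity_sd=base.severity_sd,
            noise_sd=base.noise_sd,
        )
        if base.item_loadings is None:
            base = replace(base, item_loadings=np.ones(base.n_items))
        if base.item_thresholds is None:
            if base.n_levels == 4:
                shared_probs, item2_probs = _SHARED_CUM_PROBS, _ITEM2_CUM_PROBS
            else:
                shared_probs = tuple(
                    (k + 1) / base.n_levels for k in range(base.n_levels - 1)
                )
                item2_probs = shared_probs
            thresholds = np.stack(
                [
                    latent_cutpoints(
                        item2_probs if j == _ITEM2_INDEX else shared_probs,
                        float(base.item_loadings[j]),
                        **mix,
                    )
                    for j in range(base.n_items)
                ]
            )
            base = replace(base, item_thresholds=thresholds)
    base.validate()
    return base


def spec_to_yaml(spec: CohortSpec, path) -> None:
    """Write a CohortSpec as a flat YAML mapping (arrays as nested lists)."""
    out = {k: getattr(spec, k) for k in _SPEC_SCALARS}
    out["item_loadings"] = spec.item_loadings.tolist()
    out["item_thresholds"] = spec.item_thresholds.tolist()
    with open(path, "w") as fh:
        yaml.safe_dump(out, fh, sort_keys=False)
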