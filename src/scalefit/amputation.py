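"""Constructing missingness masks under MCAR, MAR, and MNAR.

Deletion is cell-wise over the item matrix only (covariates are never
deleted) and uses exact-count sampling without replacement: each group loses
exactly ``round(rate * group_cells)`` cells, so the realised rate is a set
property of every mask rather than a Bernoulli expectation.

Under MAR the groups are the sexes; females (the reference group) lose cells
at a fixed 10% while the male rate is solved in closed form so the overall
rate lands on target.  Under MNAR the groups are defined by the true item-2
score (1-2 vs 3-4) — the grouping uses the pre-deletion value even when
item 2 itself is deleted, which is exactly the self-masking that makes the
mechanism not-at-random.
"""

from __future__ import annotations

import json
import numbers
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._errors import InfeasibleRateError, ParseError, ValidationError
from .cohort import ScaleDataset

__all__ = [
    "DEFAULT_RATES",
    "MECHANISMS",
    "Mask",
    "MaskedDataset",
    "MissingItemTable",
    "MissingnessSpec",
    "ampute",
    "solve_group_rate",
    "tabulate_missing_counts",
    "read_masked",
    "write_masked",
]

MECHANISMS = ("MCAR", "MAR", "MNAR")

#: the canonical overall-rate grid of the simulation study
DEFAULT_RATES = (0.05, 0.10, 0.15, 0.20, 0.25, 0.30, 0.35, 0.40)


@dataclass(frozen=True)
class MissingnessSpec:
    """Mechanism, overall cell-deletion rate, and the fixed reference-group
    rate applied to females (MAR) or item-2 low scorers (MNAR)."""

    mechanism: str
    overall_rate: float
    fixed_group_rate: float = 0.10
    seed: int = 0

    def validate(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ValidationError(
                f"unknown mechanism {self.mechanism!r}; expected one of {MECHANISMS}",
                field="mechanism",
            )
        if not 0.0 < self.overall_rate < 1.0:
            raise ValidationError(
                f"overall_rate must be in (0, 1), got {self.overall_rate}",
                field="overall_rate",
            )
        if not 0.0 <= self.fixed_group_rate < 1.0:
            raise ValidationError(
                f"fixed_group_rate must be in [0, 1), got {self.fixed_group_rate}",
                field="fixed_group_rate",
            )
        if not isinstance(self.seed, numbers.Integral) or self.seed < 0:
            raise ValidationError("seed must be a non-negative integer", field="seed")


def solve_group_rate(
    overall_rate: float,
    n_fixed: int,
    fixed_rate: float,
    n_free: int,
    ndigits: int | None = None,
) -> float:
    """Free-group deletion rate that balances a fixed-group rate to an
    overall target.

    Solves ``(n_fixed*fixed_rate + n_free*r) / (n_fixed + n_free) =
    overall_rate`` for ``r``.  Counts may be subjects or cells — the
    solution is invariant to a common scale factor.  ``ndigits`` rounds the
    returned rate for display; masks always use full precision.
    """
    if n_fixed <= 0 or n_free <= 0:
        raise ValidationError("group sizes must be positive")
    r = (overall_rate * (n_fixed + n_free) - fixed_rate * n_fixed) / n_free
    if not 0.0 <= r <= 1.0:
        lo = fixed_rate * n_fixed / (n_fixed + n_free)
        hi = (fixed_rate * n_fixed + n_free) / (n_fixed + n_free)
        raise InfeasibleRateError(
            f"overall rate {overall_rate:.4f} is unattainable with a fixed "
            f"group rate of {fixed_rate:.4f}: the free-group rate would be "
            f"{r:.4f}; attainable overall rates are [{lo:.4f}, {hi:.4f}]"
        )
    return round(r, ndigits) if ndigits is not None else r


@dataclass
class Mask:
    """Boolean deletion pattern (True = deleted) plus realised rates."""

    pattern: np.ndarray
    realized_rate: float = field(init=False)
    per_group_rates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        self.pattern = np.asarray(self.pattern, dtype=bool)
        self.realized_rate = float(self.pattern.mean())

    @property
    def n_deleted(self) -> int:
        return int(self.pattern.sum())

    def per_subject_missing(self) -> np.ndarray:
        return self.pattern.sum(axis=1)


@dataclass
class MaskedDataset:
    """A complete dataset plus the mask applied to it.

    The base dataset is retained so any imputation can be scored against the
    truth; ``observed_items`` gives the float view with NaN at deleted cells.
    """

    base: ScaleDataset
    mask: Mask

    def __post_init__(self):
        if self.base is not None and self.mask.pattern.shape != self.base.items.shape:
            raise ValidationError("mask shape does not match the dataset")

    def observed_items(self) -> np.ndarray:
        out = self.base.items.astype(float)
        out[self.mask.pattern] = np.nan
        return out

    def restore(self) -> np.ndarray:
        """The complete truth matrix (mask undone)."""
        return self.base.items.copy()


def _exact_sample(rng: np.random.Generator, pool: np.ndarray, rate: float) -> np.ndarray:
    k = int(round(rate * pool.size))
    if k == 0:
        return pool[:0]
    return rng.choice(pool, size=k, replace=False)


def ampute(dataset: ScaleDataset, spec: MissingnessSpec) -> MaskedDataset:
    """Delete cells from a complete dataset according to the mechanism.

    The same ``(dataset, spec)`` pair always produces the identical mask.
    """
    spec.validate()
    rng = np.random.default_rng(int(spec.seed))
    n, p = dataset.items.shape
    flat = np.arange(n * p)
    pattern = np.zeros(n * p, dtype=bool)
    groups: dict[str, np.ndarray] = {}

    if spec.mechanism == "MCAR":
        pattern[_exact_sample(rng, flat, spec.overall_rate)] = True
        groups["all"] = flat
    else:
        if spec.mechanism == "MAR":
            in_fixed = dataset.sex == "F"
            fixed_name, free_name = "female", "male"
        else:  # MNAR: grouping by the true (pre-deletion) item-2 score
            in_fixed = dataset.item2_group == "low"
            free_name, fixed_name = "high", "low"
        if not in_fixed.any() or in_fixed.all():
            raise ValidationError(
                f"{spec.mechanism} grouping does not partition the subjects "
                f"(fixed group has {int(in_fixed.sum())} of {n})"
            )
        fixed_pool = flat.reshape(n, p)[in_fixed].ravel()
        free_pool = flat.reshape(n, p)[~in_fixed].ravel()
        free_rate = solve_group_rate(
            spec.overall_rate, fixed_pool.size, spec.fixed_group_rate, free_pool.size
        )
        pattern[_exact_sample(rng, fixed_pool, spec.fixed_group_rate)] = True
        pattern[_exact_sample(rng, free_pool, free_rate)] = True
        groups[fixed_name] = fixed_pool
        groups[free_name] = free_pool

    pattern = pattern.reshape(n, p)
    per_group = {
        name: float(pattern.ravel()[pool].mean()) for name, pool in groups.items()
    }
    return MaskedDataset(base=dataset, mask=Mask(pattern=pattern, per_group_rates=per_group))


@dataclass
class MissingItemTable:
    """Distribution of per-subject missing-item counts.

    One row per observed count k, with the subject count, cumulative
    percentage (one decimal), and flags at the smallest k whose cumulative
    percentage reaches 25% and 75% — mirroring how per-subject missingness
    is usually reported for questionnaire simulation sets.
    """

    table: pd.DataFrame  # columns: n_missing_items, n_subjects, cum_pct, q25, q75

    @property
    def k_at_25(self) -> int:
        return int(self.table.loc[self.table["q25"], "n_missing_items"].iloc[0])

    @property
    def k_at_75(self) -> int:
        return int(self.table.loc[self.table["q75"], "n_missing_items"].iloc[0])


def tabulate_missing_counts(masked: MaskedDataset | Mask) -> MissingItemTable:
    """Tabulate how many items each subject is missing."""
    mask = masked.mask if isinstance(masked, MaskedDataset) else masked
    per_subject = mask.per_subject_missing()
    n_total = per_subject.size
    ks, counts = np.unique(per_subject, return_counts=True)
    cum_pct = np.round(100.0 * np.cumsum(counts) / n_total, 1)
    q25 = np.zeros(len(ks), dtype=bool)
    q75 = np.zeros(len(ks), dtype=bool)
    q25[int(np.argmax(cum_pct >= 25.0))] = True
    q75[int(np.argmax(cum_pct >= 75.0))] = True
    table = pd.DataFrame(
        {
            "n_missing_items": ks.astype(int),
            "n_subjects": counts.astype(int),
            "cum_pct": cum_pct,
            "q25": q25,
            "q75": q75,
        }
    )
    return MissingItemTable(table=table)


def write_masked(masked: MaskedDataset, prefix) -> None:
    """Write the observed view, the 0/1 mask, and a metadata sidecar.

    Produces ``{prefix}.csv`` (items blank where deleted), ``{prefix}.mask.csv``
    and ``{prefix}.meta.json``.
    """
    prefix = str(prefix)
    df = masked.base.to_frame()
    obs = masked.observed_items()
    for j, col in enumerate(masked.base.item_columns()):
        vals = obs[:, j]
        df[col] = pd.array(
            [None if np.isnan(v) else int(v) for v in vals], dtype="Int64"
        )
    df.to_csv(prefix + ".csv", index=False)

    mask_df = pd.DataFrame(
        masked.mask.pattern.astype(int), columns=masked.base.item_columns()
    )
    mask_df.insert(0, "subject_id", masked.base.subject_id)
    mask_df.to_csv(prefix + ".mask.csv", index=False)

    meta = {
        "realized_rate": masked.mask.realized_rate,
        "per_group_rates": masked.mask.per_group_rates,
        "n_deleted": masked.mask.n_deleted,
    }
    with open(prefix + ".meta.json", "w") as fh:
        json.dump(meta, fh, indent=2)


def read_masked(path, n_levels: int = 4) -> tuple[pd.DataFrame, np.ndarray]:
    """Read a masked-dataset CSV (blank cells = deleted).

    Returns the covariate frame and the float item matrix with NaN at
    deleted cells.  The complete base is not recoverable from this file, so
    the result feeds imputation, not evaluation.
    """
    df = pd.read_csv(path, dtype={"sex": str})
    item_cols = sorted(
        (c for c in df.columns if c.startswith("item_")),
        key=lambda c: int(c.split("_")[1]),
    )
    if not item_cols:
        raise ParseError("no item_* columns found")
    items = df[item_cols].to_numpy(dtype=float)
    observed = ~np.isnan(items)
    vals = items[observed]
    if not np.all(vals == np.round(vals)):
        raise ParseError("non-integer observed item value")
    if vals.size and (vals.min() < 1 or vals.max() > n_levels):
        raise ParseError(f"observed item value out of range 1..{n_levels}")
    return df[["subject_id", "sex", "age"]].copy(), items
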