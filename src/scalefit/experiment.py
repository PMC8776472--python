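"""The full mechanism x rate x method benchmark grid and its summaries.

Each replicate draws a fresh complete cohort, amputes it once per
(mechanism, rate) cell, and hands the *same* masked dataset to every
imputation method, so the methods compete on identical inputs.  Cells are
labelled mechanism-code + rate + method-code (e.g. ``C10M`` = MCAR, 10%,
mean substitution).

``recommend_path`` turns a grid of evaluation records into a best-method
table per cell, either by the published decision rules (mean substitution
below a mechanism-specific rate cutoff, random-forest regression above and
under value-dependent missingness) or data-driven by the measured metrics.
"""

from __future__ import annotations

import logging
import re
import time
from dataclasses import dataclass, field, replace as dc_replace
from pathlib import Path

import numpy as np
import pandas as pd

from ._errors import ValidationError
from .amputation import DEFAULT_RATES, MECHANISMS, MissingnessSpec, ampute, tabulate_missing_counts
from .cohort import CohortSpec, default_spec, generate_cohort
from .evaluation import EvaluationRecord, evaluate_fit, records_to_frame
from .imputers import METHODS, ImputerConfig, impute

__all__ = [
    "GridConfig",
    "RecommendationTable",
    "cell_label",
    "derive_seed",
    "parse_cell_label",
    "recommend_path",
    "run_grid",
    "summarize",
]

logger = logging.getLogger("scalefit")

_MECH_CODE = {"MCAR": "C", "MAR": "A", "MNAR": "N"}
_METHOD_CODE = {"MS": "M", "PMM": "P", "RFR": "R"}
_CODE_MECH = {v: k for k, v in _MECH_CODE.items()}
_CODE_METHOD = {v: k for k, v in _METHOD_CODE.items()}


def cell_label(mechanism: str, rate: float, method: str) -> str:
    """Compact cell name, e.g. ('MCAR', 0.10, 'MS') -> 'C10M'."""
    if mechanism not in _MECH_CODE:
        raise ValidationError(f"unknown mechanism {mechanism!r}", field="mechanism")
    if method not in _METHOD_CODE:
        raise ValidationError(f"unknown method {method!r}", field="method")
    pct = 100.0 * rate
    if abs(pct - round(pct)) > 1e-9:
        raise ValidationError(f"rate {rate} is not a whole percentage", field="rate")
    return f"{_MECH_CODE[mechanism]}{int(round(pct))}{_METHOD_CODE[method]}"


def parse_cell_label(label: str) -> tuple[str, float, str]:
    """Inverse of :func:`cell_label`: 'C10M' -> ('MCAR', 0.10, 'MS')."""
    m = re.fullmatch(r"([CAN])(\d+)([MPR])", label)
    if not m:
        raise ValidationError(f"cannot parse cell label {label!r}")
    return _CODE_MECH[m.group(1)], int(m.group(2)) / 100.0, _CODE_METHOD[m.group(3)]


def derive_seed(base_seed: int, *tags: int) -> int:
    """Deterministic 31-bit substream seed from a base seed and integer tags."""
    return int(
        np.random.SeedSequence([int(base_seed), *map(int, tags)]).generate_state(1)[0]
        % (2**31)
    )


@dataclass(frozen=True)
class GridConfig:
    """Everything that defines one benchmark run.

    The whole grid is a pure function of this config: replicate cohorts,
    masks, and imputer substreams are all derived from ``base_seed``.
    """

    cohort_spec: CohortSpec | None = None
    mechanisms: tuple[str, ...] = MECHANISMS
    rates: tuple[float, ...] = DEFAULT_RATES
    methods: tuple[str, ...] = METHODS
    n_replicates: int = 10
    base_seed: int = 0
    fixed_group_rate: float = 0.10
    imputer: ImputerConfig = field(default_factory=ImputerConfig)
    output_dir: str | Path | None = None

    def validate(self) -> None:
        if not self.mechanisms or not self.rates or not self.methods:
            raise ValidationError("mechanisms, rates and methods must be non-empty")
        for mech in self.mechanisms:
            if mech not in MECHANISMS:
                raise ValidationError(f"unknown mechanism {mech!r}", field="mechanisms")
        for meth in self.methods:
            if meth not in METHODS:
                raise ValidationError(f"unknown method {meth!r}", field="methods")
        for r in self.rates:
            if not 0.0 < r < 1.0:
                raise ValidationError(f"rate {r} outside (0, 1)", field="rates")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1", field="n_replicates")


def run_grid(config: GridConfig) -> list[EvaluationRecord]:
    """Run the full grid; returns one record per (mechanism, rate, method,
    replicate).

    A failing cell is logged with its label and skipped; the failure count
    is reported at the end rather than aborting a long Monte Carlo run.
    If ``output_dir`` is set, writes ``results.csv`` plus one per-cell
    missing-item-count table.
    """
    config.validate()
    spec = config.cohort_spec if config.cohort_spec is not None else default_spec()
    out_dir = Path(config.output_dir) if config.output_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    records: list[EvaluationRecord] = []
    failures = 0
    for rep in range(config.n_replicates):
        cohort_seed = derive_seed(config.base_seed, 0, rep)
        cohort = generate_cohort(spec, cohort_seed)
        for mi, mech in enumerate(config.mechanisms):
            for ri, rate in enumerate(config.rates):
                t0 = time.perf_counter()
                mask_seed = derive_seed(config.base_seed, 1, rep, mi, ri)
                try:
                    masked = ampute(
                        cohort,
                        MissingnessSpec(
                            mechanism=mech,
                            overall_rate=rate,
                            fixed_group_rate=config.fixed_group_rate,
                            seed=mask_seed,
                        ),
                    )
                except Exception:
                    logger.exception(
                        "amputation failed: mech=%s rate=%.2f rep=%d", mech, rate, rep
                    )
                    failures += len(config.methods)
                    continue
                if out_dir is not None:
                    tab = tabulate_missing_counts(masked)
                    tab.table.to_csv(
                        out_dir
                        / f"missing_items_{_MECH_CODE[mech]}{int(round(100 * rate))}_rep{rep}.csv",
                        index=False,
                    )
                for ki, meth in enumerate(config.methods):
                    label = cell_label(mech, rate, meth)
                    imp_seed = derive_seed(config.base_seed, 2, rep, mi, ri, ki)
                    try:
                        fitted = impute(
                            masked,
                            dc_replace(config.imputer, method=meth, seed=imp_seed),
                        )
                        rec = evaluate_fit(
                            cohort,
                            fitted,
                            mechanism=mech,
                            overall_rate=rate,
                            replicate_seed=cohort_seed,
                            n_levels=spec.n_levels,
                        )
                    except Exception:
                        logger.exception("cell %s rep %d failed", label, rep)
                        failures += 1
                        continue
                    records.append(rec)
                    logger.info(
                        "cell %-5s rep %d seed %d done in %.2fs",
                        label,
                        rep,
                        imp_seed,
                        time.perf_counter() - t0,
                    )
    if failures:
        logger.warning("grid finished with %d failed cell(s)", failures)
    if out_dir is not None:
        records_to_frame(records).to_csv(out_dir / "results.csv", index=False)
    return records


def summarize(records) -> dict[str, pd.DataFrame]:
    """Per-cell mean and SD of each metric across replicates.

    Returns one wide table per metric (rows = rate, one column per
    (mechanism, method) series) for 'rmse', 'ci_width' and 'scc', plus the
    long-format table under 'long'.
    """
    df = records_to_frame(records) if not isinstance(records, pd.DataFrame) else records
    if df.empty:
        raise ValidationError("no records to summarize")
    long = (
        df.groupby(["mechanism", "overall_rate", "method"])[["rmse", "ci_width", "scc"]]
        .agg(["mean", "std"])
        .reset_index()
    )
    long.columns = [
        "_".join(c).rstrip("_") if isinstance(c, tuple) else c for c in long.columns
    ]
    long = long.fillna({f"{m}_std": 0.0 for m in ("rmse", "ci_width", "scc")})
    out: dict[str, pd.DataFrame] = {"long": long}
    for metric in ("rmse", "ci_width", "scc"):
        out[metric] = long.pivot_table(
            index="overall_rate",
            columns=["mechanism", "method"],
            values=f"{metric}_mean",
        )
    return out


@dataclass
class RecommendationTable:
    """Best method per (mechanism, rate) cell with its provenance."""

    table: pd.DataFrame  # columns: mechanism, overall_rate, method, source, ...

    def method_for(self, mechanism: str, rate: float) -> str:
        sel = self.table[
            (self.table["mechanism"] == mechanism)
            & (np.isclose(self.table["overall_rate"], rate))
        ]
        if sel.empty:
            raise ValidationError(f"no recommendation for ({mechanism}, {rate})")
        return str(sel["method"].iloc[0])


# published decision rules: MS below the cutoff, RFR at/above it;
# value-dependent missingness always goes to RFR
_RULE_CUTOFFS = {"MCAR": 0.20, "MAR": 0.35, "MNAR": 0.0}


def _paper_rule(mechanism: str, rate: float) -> str:
    return "MS" if rate < _RULE_CUTOFFS[mechanism] else "RFR"


def recommend_path(
    records=None,
    mode: str = "paper_rules",
    mechanisms=MECHANISMS,
    rates=DEFAULT_RATES,
) -> RecommendationTable:
    """Best-method table per (mechanism, rate) cell.

    ``paper_rules`` applies the published cutoffs and needs no records;
    ``data_driven`` picks the method with the lowest mean RMSE (ties broken
    by highest Spearman correlation, then lowest CI width) and requires a
    record for every requested cell.
    """
    if mode not in ("paper_rules", "data_driven"):
        raise ValidationError(f"unknown mode {mode!r}", field="mode")

    rows = []
    if mode == "paper_rules":
        for mech in mechanisms:
            for rate in rates:
                rows.append(
                    {
                        "mechanism": mech,
                        "overall_rate": rate,
                        "method": _paper_rule(mech, rate),
                        "source": "paper_rules",
                    }
                )
        return RecommendationTable(table=pd.DataFrame(rows))

    if records is None:
        raise ValidationError("data_driven mode requires evaluation records")
    df = records_to_frame(records) if not isinstance(records, pd.DataFrame) else records
    agg = (
        df.groupby(["mechanism", "overall_rate", "method"])[["rmse", "ci_width", "scc"]]
        .mean()
        .reset_index()
    )
    missing = [
        (mech, rate)
        for mech in mechanisms
        for rate in rates
        if agg[
            (agg["mechanism"] == mech) & np.isclose(agg["overall_rate"], rate)
        ].empty
    ]
    if missing:
        raise ValidationError(f"records missing for cell(s): {missing}")
    for mech in mechanisms:
        for rate in rates:
            cell = agg[
                (agg["mechanism"] == mech) & np.isclose(agg["overall_rate"], rate)
            ].copy()
            cell = cell.sort_values(
                ["rmse", "scc", "ci_width"], ascending=[True, False, True]
            )
            best = cell.iloc[0]
            rows.append(
                {
                    "mechanism": mech,
                    "overall_rate": rate,
                    "method": str(best["method"]),
                    "source": "data_driven",
                    "rmse": float(best["rmse"]),
                    "ci_width": float(best["ci_width"]),
                    "scc": float(best["scc"]),
                }
            )
    return RecommendationTable(table=pd.DataFrame(rows))
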