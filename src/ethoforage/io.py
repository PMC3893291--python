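"""CSV schemas, validated readers/writers and report tables.

Three event-table schemas (UTF-8 CSV, header row, ISO 8601 local timestamps,
categories as lowercase snake-case tokens):

* bouts:     ``deployment_id, individual_id, activity, start, duration_s``
* intervals: ``individual_id, site_year, start, exposure_h, attack_count, viable``
* attacks:   ``individual_id, site_year, time, water_position, hunting_mode,
  habitat, outcome``

Readers enforce the domain invariants at load time and report row-level
problems with file line numbers (header = line 1).  Writers emit rows in a
deterministic order so write -> read -> write is byte-stable.
"""

from __future__ import annotations

import warnings
from datetime import datetime
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from ethoforage.ethogram import (
    ActivityBudget,
    AttackRecord,
    BehaviorBout,
    BehaviorCategory,
    DielBin,
    SamplingInterval,
    parse_behavior_category,
)
from ethoforage.models import GLMFit
from ethoforage.randomization import pvalue_grid


class ValidationError(ValueError):
    """Input data failed schema or invariant validation."""

    def __init__(self, path, problems: Sequence[str]):
        self.path = str(path)
        self.problems = list(problems)
        preview = "\n  ".join(self.problems[:20])
        more = "" if len(self.problems) <= 20 else f"\n  ... {len(self.problems) - 20} more"
        super().__init__(f"{self.path}: {len(self.problems)} problem(s)\n  {preview}{more}")


_BOUT_COLUMNS = ["deployment_id", "individual_id", "activity", "start", "duration_s"]
_INTERVAL_COLUMNS = ["individual_id", "site_year", "start", "exposure_h", "attack_count", "viable"]
_ATTACK_COLUMNS = [
    "individual_id",
    "site_year",
    "time",
    "water_position",
    "hunting_mode",
    "habitat",
    "outcome",
]


def _load_csv(path, columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(path, ["file does not exist"])
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(path, [f"missing column(s): {', '.join(missing)}"])
    return df


def _parse_rows(path, df, builder) -> list:
    records, problems = [], []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        try:
            records.append(builder(row))
        except (ValueError, TypeError) as exc:
            problems.append(f"line {line}: {exc}")
    if problems:
        raise ValidationError(path, problems)
    return records


def _parse_time(value: str, column: str) -> datetime:
    try:
        return datetime.fromisoformat(value)
    except ValueError:
        raise ValueError(f"column {column}: unparseable time {value!r}") from None


def read_bout_table(path) -> list[BehaviorBout]:
    df = _load_csv(path, _BOUT_COLUMNS)

    def build(row):
        try:
            duration = int(row.duration_s)
        except ValueError:
            raise ValueError(f"column duration_s: not an integer: {row.duration_s!r}") from None
        try:
            activity = parse_behavior_category(row.activity)
        except ValueError as exc:
            raise ValueError(f"column activity: {exc}") from None
        return BehaviorBout(
            deployment_id=row.deployment_id,
            individual_id=row.individual_id,
            activity=activity,
            start=_parse_time(row.start, "start"),
            duration_s=duration,
        )

    bouts = _parse_rows(path, df, build)
    _check_bout_overlaps(path, bouts)
    return bouts


def _check_bout_overlaps(path, bouts: list[BehaviorBout]) -> None:
    problems = []
    by_dep: dict[str, list[BehaviorBout]] = {}
    for b in bouts:
        by_dep.setdefault(b.deployment_id, []).append(b)
    for dep, group in by_dep.items():
        group = sorted(group, key=lambda b: b.start)
        for a, b in zip(group, group[1:]):
            if a.end > b.start:
                problems.append(
                    f"deployment {dep}: bouts overlap at {b.start.isoformat()}"
                )
    if problems:
        raise ValidationError(path, problems)


def read_interval_table(path) -> list[SamplingInterval]:
    df = _load_csv(path, _INTERVAL_COLUMNS)

    def build(row):
        try:
            exposure = float(row.exposure_h)
            count = int(row.attack_count)
        except ValueError:
            raise ValueError(
                f"columns exposure_h/attack_count: non-numeric ({row.exposure_h!r}, {row.attack_count!r})"
            ) from None
        viable = str(row.viable).strip().lower()
        if viable not in ("true", "false", "1", "0"):
            raise ValueError(f"column viable: expected boolean, got {row.viable!r}")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # non-standard exposures warned once at fit time
            return SamplingInterval(
                individual_id=row.individual_id,
                site_year=row.site_year,
                start=_parse_time(row.start, "start"),
                exposure_h=exposure,
                attack_count=count,
                viable=viable in ("true", "1"),
            )

    return _parse_rows(path, df, build)


def read_attack_table(path) -> list[AttackRecord]:
    df = _load_csv(path, _ATTACK_COLUMNS)

    def build(row):
        return AttackRecord(
            individual_id=row.individual_id,
            site_year=row.site_year,
            time=_parse_time(row.time, "time"),
            water_position=row.water_position,
            hunting_mode=row.hunting_mode,
            habitat=row.habitat,
            outcome=row.outcome,
        )

    return _parse_rows(path, df, build)


def read_event_tables(
    bouts_path, intervals_path, attacks_path
) -> tuple[list[BehaviorBout], list[SamplingInterval], list[AttackRecord]]:
    """Load and validate the three event tables of one study."""
    return (
        read_bout_table(bouts_path),
        read_interval_table(intervals_path),
        read_attack_table(attacks_path),
    )


# ---------------------------------------------------------------------------
# writers


def write_bout_table(bouts: Iterable[BehaviorBout], path) -> None:
    rows = [
        {
            "deployment_id": b.deployment_id,
            "individual_id": b.individual_id,
            "activity": b.activity.value,
            "start": b.start.isoformat(),
            "duration_s": b.duration_s,
        }
        for b in sorted(bouts, key=lambda b: (b.deployment_id, b.start))
    ]
    pd.DataFrame(rows, columns=_BOUT_COLUMNS).to_csv(path, index=False)


def write_interval_table(intervals: Iterable[SamplingInterval], path) -> None:
    rows = [
        {
            "individual_id": iv.individual_id,
            "site_year": iv.site_year,
            "start": iv.start.isoformat(),
            "exposure_h": iv.exposure_h,
            "attack_count": iv.attack_count,
            "viable": iv.viable,
        }
        for iv in sorted(intervals, key=lambda iv: (iv.individual_id, iv.start))
    ]
    pd.DataFrame(rows, columns=_INTERVAL_COLUMNS).to_csv(path, index=False)


def write_attack_table(attacks: Iterable[AttackRecord], path) -> None:
    rows = [
        {
            "individual_id": a.individual_id,
            "site_year": a.site_year,
            "time": a.time.isoformat(),
            "water_position": a.water_position,
            "hunting_mode": a.hunting_mode,
            "habitat": a.habitat,
            "outcome": a.outcome,
        }
        for a in sorted(attacks, key=lambda a: (a.individual_id, a.time))
    ]
    pd.DataFrame(rows, columns=_ATTACK_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# report


def _budget_frame(budget: ActivityBudget) -> pd.DataFrame:
    scope = budget.scope.value if isinstance(budget.scope, DielBin) else budget.scope
    return pd.DataFrame(
        [
            {
                "scope": scope,
                "activity": cat.value,
                "proportion": budget.proportions[cat],
                "total_time_s": budget.total_time_s,
            }
            for cat in BehaviorCategory
        ]
    )


def make_report(
    out_dir,
    *,
    rate_aic=None,
    success_aic=None,
    rate_cell_fits: Optional[dict[str, GLMFit]] = None,
    success_cell_fits: Optional[dict[str, GLMFit]] = None,
    budget_overall: Optional[ActivityBudget] = None,
    budget_by_bin: Optional[dict[DielBin, ActivityBudget]] = None,
    randtest: Optional[pd.DataFrame] = None,
) -> dict[str, Path]:
    """Write report tables: AIC tables, cell means with Wald CIs, activity
    budgets and the randomization p-value grid.

    Every table is a re-parseable CSV with deterministic row order; a
    ``report.txt`` summary collects them in readable form.  Only the sections
    whose inputs are supplied are produced.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    text: list[str] = []

    def emit(key: str, frame: pd.DataFrame, title: str, float_format="%.6g"):
        p = out_dir / f"{key}.csv"
        frame.to_csv(p, index=False, float_format=float_format)
        paths[key] = p
        text.append(f"== {title} ==\n{frame.to_string(index=False)}\n")

    if rate_aic is not None:
        emit("aic_attack_rate", rate_aic.table, "Attack-rate model selection (AIC)")
    if success_aic is not None:
        emit("aic_capture_success", success_aic.table, "Capture-success model selection (AIC)")
    for fits, prefix, label in (
        (rate_cell_fits, "cells_attack_rate", "attack rate (/h)"),
        (success_cell_fits, "cells_capture_success", "P(capture success)"),
    ):
        if not fits:
            continue
        for name, fit in fits.items():
            frame = fit.cell_predictions.copy()
            emit(f"{prefix}_{name}", frame, f"{label} by {name} (mean, Wald 95% CI)")
    if budget_overall is not None:
        emit("activity_budget_overall", _budget_frame(budget_overall), "Overall activity budget")
    if budget_by_bin is not None:
        frame = pd.concat([_budget_frame(b) for b in budget_by_bin.values()], ignore_index=True)
        emit("activity_budget_by_bin", frame, "Per-bin activity budgets")
    if randtest is not None:
        emit("randtest_results", randtest, "Randomization test (long format)")
        grid = pvalue_grid(randtest).reset_index()
        emit("randtest_pvalues_grid", grid, "Randomization test p-values (bins x activities)")

    report = out_dir / "report.txt"
    report.write_text("\n".join(text), encoding="utf-8")
    paths["report"] = report
    return paths
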