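"""Longitudinal QA baselines and pass/warn/fail decisions.

Each coil set (type + bottom/top serial numbers) and series condition
(unfiltered, prescan, sum-of-squares, or one coil element) accumulates a
dated history of metric vectors.  A new measurement is compared per
metric against the baseline formed by all previously *accepted* entries:

* **sd criterion** — warn beyond 2 sample standard deviations from the
  baseline mean, fail beyond 3;
* **percent criterion** — warn beyond 5% of the baseline mean, fail
  beyond 10%; preferable for short baselines;
* **auto** — percent when the baseline holds fewer than 10 datapoints,
  sd otherwise.

Thresholds are two-sided: drops indicate coil faults, flares indicate
uniformity/stability problems.  Failed measurements are stored flagged
not-accepted so they never pollute later baselines.

The store is an append-only audit trail: one long-format CSV per
coil+condition plus a JSON index, diff-able and editable by hand.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .errors import CoilMismatchError

Status = Literal["pass", "warn", "fail", "not-evaluable"]

_STATUS_ORDER = {"pass": 0, "warn": 1, "fail": 2}

SD_WARN, SD_FAIL = 2.0, 3.0
PCT_WARN, PCT_FAIL = 5.0, 10.0
#: baselines shorter than this use the percent criterion under "auto"
AUTO_MIN_N = 10


@dataclass(frozen=True)
class QaDecision:
    metric_key: str
    status: Status
    criterion: str  # "sd" | "percent" | "none"
    deviation: float  # signed, in SD units or percent of mean
    baseline_n: int


@dataclass
class BaselineEntry:
    date: str
    values: dict[str, float]
    accepted: bool


@dataclass
class BaselineSeries:
    coil_id: str
    condition: str
    entries: list[BaselineEntry] = field(default_factory=list)

    def baseline_values(self, metric_key: str) -> np.ndarray:
        vals = [
            e.values[metric_key]
            for e in self.entries
            if e.accepted and metric_key in e.values and np.isfinite(e.values[metric_key])
        ]
        return np.asarray(vals, dtype=np.float64)


def decide(
    current_value: float,
    baseline_values: Iterable[float],
    criterion: str = "auto",
    metric_key: str = "",
) -> QaDecision:
    """Pass/warn/fail for one metric against its baseline.

    Returns status ``not-evaluable`` (distinct from pass) when the
    baseline is too short for the selected criterion: the sd criterion
    needs at least 2 values, percent at least 1.
    """
    baseline = np.asarray(list(baseline_values), dtype=np.float64)
    n = baseline.size
    if criterion == "auto":
        criterion = "sd" if n >= AUTO_MIN_N else "percent"
    if criterion not in ("sd", "percent"):
        raise ValueError(f"unknown criterion {criterion!r}")

    if (criterion == "sd" and n < 2) or n < 1:
        return QaDecision(metric_key, "not-evaluable", "none", float("nan"), n)

    mu = float(baseline.mean())
    if criterion == "sd":
        sd = float(baseline.std(ddof=1))
        if sd == 0:
            deviation = 0.0 if current_value == mu else math_inf_signed(current_value - mu)
        else:
            deviation = (current_value - mu) / sd
        warn_at, fail_at = SD_WARN, SD_FAIL
    else:
        if mu == 0:
            deviation = 0.0 if current_value == 0 else math_inf_signed(current_value)
        else:
            deviation = 100.0 * (current_value - mu) / mu
        warn_at, fail_at = PCT_WARN, PCT_FAIL

    if abs(deviation) > fail_at:
        status: Status = "fail"
    elif abs(deviation) > warn_at:
        status = "warn"
    else:
        status = "pass"
    return QaDecision(metric_key, status, criterion, float(deviation), n)


def math_inf_signed(x: float) -> float:
    return float("inf") if x > 0 else float("-inf")


# --- store -------------------------------------------------------------------

def _slug(text: str) -> str:
    return re.sub(r"[^A-Za-z0-9._-]+", "-", text)


class BaselineStore:
    """File-backed history of QA measurements.

    Layout: ``<root>/index.json`` plus one CSV per (coil_id, condition)
    with columns date, accepted, metric_key, value.
    """

    def __init__(self, root: str | Path):
        self.root = Path(root)
        self.root.mkdir(parents=True, exist_ok=True)
        self.index_path = self.root / "index.json"

    def _read_index(self) -> list[dict]:
        if self.index_path.exists():
            return json.loads(self.index_path.read_text())["series"]
        return []

    def _write_index(self, series: list[dict]) -> None:
        self.index_path.write_text(json.dumps({"series": series}, indent=2, sort_keys=True))

    def _series_file(self, coil_id: str, condition: str) -> Path:
        return self.root / f"{_slug(coil_id)}__{_slug(condition)}.csv"

    def load(self, coil_id: str, condition: str) -> BaselineSeries:
        path = self._series_file(coil_id, condition)
        series = BaselineSeries(coil_id=coil_id, condition=condition)
        if not path.exists():
            return series
        df = pd.read_csv(path)
        for (date, accepted), grp in df.groupby(["date", "accepted"], sort=True):
            series.entries.append(
                BaselineEntry(
                    date=str(date),
                    values=dict(zip(grp["metric_key"], grp["value"].astype(float))),
                    accepted=bool(accepted),
                )
            )
        series.entries.sort(key=lambda e: e.date)
        return series

    def append(
        self,
        coil_id: str,
        condition: str,
        date: str,
        values: dict[str, float],
        accepted: bool = True,
    ) -> None:
        existing = self.load(coil_id, condition)
        if any(e.date == date for e in existing.entries):
            raise CoilMismatchError(
                f"measurement dated {date} already stored for {coil_id}/{condition}"
            )
        path = self._series_file(coil_id, condition)
        df = pd.DataFrame(
            {
                "date": date,
                "accepted": accepted,
                "metric_key": list(values.keys()),
                "value": list(values.values()),
            }
        )
        df.to_csv(path, mode="a", header=not path.exists(), index=False)
        index = self._read_index()
        key = {"coil_id": coil_id, "condition": condition, "file": path.name}
        if key not in index:
            index.append(key)
            self._write_index(sorted(index, key=lambda d: (d["coil_id"], d["condition"])))


# --- evaluation --------------------------------------------------------------

@dataclass
class EvaluationResult:
    decisions: dict[str, QaDecision]
    summary: dict[str, int]
    overall: Status


def evaluate_measurement(
    store: BaselineStore,
    coil_id: str,
    condition: str,
    values: dict[str, float],
    criterion: str = "auto",
    record: bool = False,
    date: str | None = None,
    accept: str = "auto",
) -> EvaluationResult:
    """Decide every metric of a new measurement against its baseline.

    With ``record=True`` the measurement is appended to the store;
    ``accept="auto"`` stores it as accepted only when no metric failed
    (so failed runs never enter future baselines), ``accept="always"`` /
    ``"never"`` override.  Evaluation itself never mutates stored
    entries.
    """
    series = store.load(coil_id, condition)
    decisions = {
        key: decide(value, series.baseline_values(key), criterion=criterion, metric_key=key)
        for key, value in values.items()
    }
    summary = {s: 0 for s in ("pass", "warn", "fail", "not-evaluable")}
    for d in decisions.values():
        summary[d.status] += 1
    overall = overall_status(decisions.values())
    if record:
        if accept == "auto":
            accepted = summary["fail"] == 0
        elif accept in ("always", "never"):
            accepted = accept == "always"
        else:
            raise ValueError(f"accept must be auto/always/never, got {accept!r}")
        store.append(coil_id, condition, date or "undated", values, accepted=accepted)
    return EvaluationResult(decisions=decisions, summary=summary, overall=overall)


def overall_status(decisions: Iterable[QaDecision]) -> Status:
    evaluable = [d.status for d in decisions if d.status != "not-evaluable"]
    if not evaluable:
        return "not-evaluable"
    return max(evaluable, key=lambda s: _STATUS_ORDER[s])


def coil_verdict(
    combined_decisions: dict[str, dict[str, QaDecision]],
    element_decisions: dict[str, QaDecision],
    slice_fail_fraction: float = 0.5,
) -> Status:
    """Aggregate verdict for one coil run.

    Fail if any element fails, or if more than ``slice_fail_fraction`` of
    slices fail on any combined metric; otherwise the worst per-metric
    status.  ``combined_decisions`` maps metric name (e.g. "snr") to the
    per-slice decisions of that metric.
    """
    for d in element_decisions.values():
        if d.status == "fail":
            return "fail"
    worst: Status = "not-evaluable"
    all_decisions = list(element_decisions.values())
    for per_slice in combined_decisions.values():
        ds = list(per_slice.values())
        evaluable = [d for d in ds if d.status != "not-evaluable"]
        if evaluable:
            frac = sum(d.status == "fail" for d in evaluable) / len(evaluable)
            if frac > slice_fail_fraction:
                return "fail"
        all_decisions.extend(ds)
    return overall_status(all_decisions)


def compare_coils(
    candidate_values: dict[str, float],
    store: BaselineStore,
    reference_coil_id: str,
    condition: str,
    candidate_coil_id: str,
) -> pd.DataFrame:
    """Margin of a candidate coil over the reference coil's historical minima.

    Rows: metric_key, candidate, reference_min, margin (candidate minus
    minimum of the reference's accepted history), flagged (margin < 0;
    equality is acceptable).  Coil ids are "<type>_<bottomSN>_<topSN>";
    comparing different coil types is refused.
    """
    cand_type = candidate_coil_id.split("_")[0]
    ref_type = reference_coil_id.split("_")[0]
    if cand_type != ref_type:
        raise CoilMismatchError(
            f"cannot compare coil type {cand_type!r} against {ref_type!r}"
        )
    series = store.load(reference_coil_id, condition)
    rows = []
    for key in sorted(candidate_values):
        ref = series.baseline_values(key)
        ref_min = float(ref.min()) if ref.size else float("nan")
        margin = candidate_values[key] - ref_min
        rows.append(
            {
                "metric_key": key,
                "candidate": candidate_values[key],
                "reference_min": ref_min,
                "margin": margin,
                "flagged": bool(np.isfinite(margin) and margin < 0),
            }
        )
    return pd.DataFrame(rows)
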