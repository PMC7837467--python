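"""Reliability statistics for observer studies of the analysis workflow.

Agreement between observers (or repeated runs) is summarized per segment
and parameter by the single-measure intraclass correlation coefficient and
by the mean absolute difference between the two measurement series.

For a table of n subjects by k raters with two-way ANOVA mean squares
MSR (between subjects), MSC (between raters) and MSE (residual):

* two-way random, absolute agreement, single measure — ICC(2,1)::

      (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

  used for inter-observer agreement (observers are a random sample).

* two-way mixed, consistency, single measure — ICC(3,1)::

      (MSR - MSE) / (MSR + (k-1) MSE)

  used for intra-observer consistency (the observer is fixed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MeasurementTable",
    "AnovaMeanSquares",
    "anova_mean_squares",
    "icc",
    "absolute_differences",
    "observer_study",
    "reports_to_long",
]

ICC_MODELS = ("two_way_random_absolute", "two_way_mixed_consistency")


@dataclass(frozen=True)
class MeasurementTable:
    """n subjects x k raters of one parameter (mm or degrees)."""

    values: np.ndarray
    parameter: str = ""
    segment: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError(f"expected a 2D subjects-by-raters table, got shape {v.shape}")
        n, k = v.shape
        if n < 2 or k < 2:
            raise ValueError(f"need at least 2 subjects and 2 raters, got {n}x{k}")
        if not np.all(np.isfinite(v)):
            raise ValueError("table contains missing or non-finite cells")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class AnovaMeanSquares:
    """Two-way ANOVA decomposition of a subjects-by-raters table."""

    msr: float   # between-subjects, df n-1
    msc: float   # between-raters, df k-1
    mse: float   # residual, df (n-1)(k-1)


def anova_mean_squares(table: MeasurementTable) -> AnovaMeanSquares:
    v = table.values
    n, k = v.shape
    grand = v.mean()
    subject_means = v.mean(axis=1)
    rater_means = v.mean(axis=0)
    ss_rows = k * np.sum((subject_means - grand) ** 2)
    ss_cols = n * np.sum((rater_means - grand) ** 2)
    ss_total = np.sum((v - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    return AnovaMeanSquares(
        msr=float(ss_rows / (n - 1)),
        msc=float(ss_cols / (k - 1)),
        mse=float(max(ss_err, 0.0) / ((n - 1) * (k - 1))),
    )


def icc(table: MeasurementTable, model: str) -> float:
    """Single-measure intraclass correlation coefficient of ``table``.

    ``model`` is ``"two_way_random_absolute"`` (ICC(2,1)) or
    ``"two_way_mixed_consistency"`` (ICC(3,1)).  Raises on a degenerate
    table with zero total variance, where the ICC is undefined.
    """
    if model not in ICC_MODELS:
        raise ValueError(f"unknown ICC model {model!r}; choose one of {ICC_MODELS}")
    ms = anova_mean_squares(table)
    n, k = table.n, table.k
    if np.ptp(table.values) == 0:
        raise ValueError("degenerate table: zero total variance, ICC undefined")
    if model == "two_way_random_absolute":
        denom = ms.msr + (k - 1) * ms.mse + (k / n) * (ms.msc - ms.mse)
    else:
        denom = ms.msr + (k - 1) * ms.mse
    if denom == 0:
        raise ValueError("degenerate table: zero denominator, ICC undefined")
    return float((ms.msr - ms.mse) / denom)


def absolute_differences(table: MeasurementTable) -> tuple[float, float]:
    """Mean and sample SD of |rater1 - rater2| over subjects (k must be 2)."""
    if table.k != 2:
        raise ValueError(f"absolute differences require exactly 2 raters, got {table.k}")
    d = np.abs(table.values[:, 0] - table.values[:, 1])
    return float(d.mean()), float(d.std(ddof=1))


# ---------------------------------------------------------------------------
# observer study
# ---------------------------------------------------------------------------

def reports_to_long(reports: dict) -> pd.DataFrame:
    """Flatten ``{rater: {case: AccuracyReport}}`` to long format.

    One row per (case, rater, segment, parameter) holding that
    parameter's *difference* value — the quantity observers would compare.
    """
    rows = []
    for rater, cases in reports.items():
        for case, report in cases.items():
            for segment, result in report.segments.items():
                params = (("pitch", "roll", "yaw") if segment.startswith("ramus")
                          else ("t_rl", "t_ap", "t_si", "pitch", "roll", "yaw"))
                for p in params:
                    rows.append({
                        "case": case, "rater": rater, "segment": segment,
                        "parameter": p,
                        "value": getattr(result.difference, p),
                    })
    return pd.DataFrame(rows)


def observer_study(
    measurements: pd.DataFrame,
    model: str = "two_way_random_absolute",
) -> pd.DataFrame:
    """Per-(segment, parameter) reliability summary of an observer study.

    ``measurements`` is long-format with columns ``case, rater, segment,
    parameter, value`` covering >= 2 raters over a common case list (a
    nested ``{rater: {case: AccuracyReport}}`` mapping is accepted and
    flattened).  Returns one row per (segment, parameter) with the
    requested ICC and — for two raters — the mean absolute difference and
    its SD.
    """
    if isinstance(measurements, dict):
        measurements = reports_to_long(measurements)
    required = {"case", "rater", "segment", "parameter", "value"}
    missing = required - set(measurements.columns)
    if missing:
        raise ValueError(f"measurements missing columns: {sorted(missing)}")
    raters = sorted(measurements["rater"].unique())
    if len(raters) < 2:
        raise ValueError("observer study requires at least 2 raters/repeats")
    case_sets = {r: frozenset(measurements.loc[measurements["rater"] == r, "case"])
                 for r in raters}
    if len(set(case_sets.values())) != 1:
        raise ValueError(f"raters measured different case lists: {case_sets}")

    rows = []
    for (segment, parameter), grp in measurements.groupby(["segment", "parameter"],
                                                          sort=False):
        wide = grp.pivot(index="case", columns="rater", values="value")
        if wide.isna().any().any():
            raise ValueError(
                f"incomplete table for ({segment}, {parameter}): missing cells")
        table = MeasurementTable(wide.to_numpy(), parameter=parameter, segment=segment)
        row = {"segment": segment, "parameter": parameter,
               "n": table.n, "k": table.k, "icc": icc(table, model)}
        if table.k == 2:
            mean_d, sd_d = absolute_differences(table)
            row["mean_abs_diff"] = mean_d
            row["sd_abs_diff"] = sd_d
        rows.append(row)
    return pd.DataFrame(rows)
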