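"""Clinical evaluation metrics for BIS prediction.

Per prediction, the performance error relative to the predicted value

    PE = 100 * (measured - predicted) / predicted   [%]

with the per-case medians MDPE (signed bias) and MDAPE (inaccuracy) —
the standard performance measures of computer-controlled infusion pumps —
plus RMSE and MAE in raw BIS units.  Metrics are reported for the whole
case and per anesthesia phase:

* induction: the 10-minute window starting at the propofol infusion start;
* recovery: from the propofol stop to the end of the record;
* maintenance: everything between.

Cohort summaries are mean and sample standard deviation (ddof 1) across
cases.  Evaluation always uses unsmoothed BIS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PERIODS", "label_periods", "performance_error", "mdpe", "mdape",
           "rmse_mae", "case_metrics", "report"]

PERIODS = ("induction", "maintenance", "recovery")
INDUCTION_S = 600


def label_periods(t: np.ndarray, infusion_start: float, infusion_stop: float) -> np.ndarray:
    """Phase label for each timestamp.

    Induction is [start, start + 600 s); recovery is [stop, end];
    maintenance is the remainder.  If the propofol stop falls inside the
    induction window the induction period is truncated there (with a
    warning) so the phases still partition the timeline.
    """
    t = np.asarray(t, float)
    ind_end = infusion_start + INDUCTION_S
    if infusion_stop < ind_end:
        warnings.warn("propofol stop before the 10-min induction window ends; "
                      "induction truncated at the stop")
        ind_end = infusion_stop
    labels = np.full(t.shape, "maintenance", dtype=object)
    labels[(t >= infusion_start) & (t < ind_end)] = "induction"
    labels[t >= infusion_stop] = "recovery"
    return labels


def performance_error(measured: np.ndarray, predicted: np.ndarray) -> np.ndarray:
    """Signed percent error relative to the prediction."""
    measured = np.asarray(measured, float)
    predicted = np.asarray(predicted, float)
    if np.any(predicted <= 0):
        raise ValueError("performance error undefined for predictions <= 0")
    return 100.0 * (measured - predicted) / predicted


def _median(x: np.ndarray) -> float:
    if len(x) == 0:
        raise ValueError("median of an empty series")
    return float(np.median(x))  # even length: mean of the central pair


def mdpe(pe: np.ndarray) -> float:
    """Median performance error (%) — signed bias."""
    return _median(np.asarray(pe, float))


def mdape(pe: np.ndarray) -> float:
    """Median absolute performance error (%) — inaccuracy."""
    return _median(np.abs(np.asarray(pe, float)))


def rmse_mae(measured: np.ndarray, predicted: np.ndarray):
    measured = np.asarray(measured, float)
    predicted = np.asarray(predicted, float)
    if measured.shape != predicted.shape or measured.size == 0:
        raise ValueError("series must have equal nonzero length")
    err = measured - predicted
    return float(np.sqrt(np.mean(err**2))), float(np.mean(np.abs(err)))


def case_metrics(measured, predicted, labels) -> dict:
    """All/per-period RMSE, MAE, MDPE, MDAPE for one case.

    Periods with no samples are skipped (reported as NaN).
    """
    measured = np.asarray(measured, float)
    predicted = np.asarray(predicted, float)
    labels = np.asarray(labels)
    out = {}
    for period in ("All",) + PERIODS:
        mask = np.ones(len(measured), bool) if period == "All" else labels == period
        if not mask.any():
            out.update({f"{m}_{period}": np.nan for m in ("RMSE", "MAE", "MDPE", "MDAPE")})
            continue
        r, a = rmse_mae(measured[mask], predicted[mask])
        pe = performance_error(measured[mask], predicted[mask])
        out[f"RMSE_{period}"] = r
        out[f"MAE_{period}"] = a
        out[f"MDPE_{period}"] = mdpe(pe)
        out[f"MDAPE_{period}"] = mdape(pe)
    return out


def report(cases: list[dict]) -> pd.DataFrame:
    """Cohort table: metric x period with across-case mean and SD columns.

    ``cases`` holds per-case dicts with keys ``measured``, ``predicted``,
    ``labels`` (and optionally ``case_id``).  A single-case cohort reports
    SD 0 with the ``sd_undefined`` flag set.
    """
    if not cases:
        raise ValueError("report needs at least one case")
    rows = []
    for i, c in enumerate(cases):
        m = case_metrics(c["measured"], c["predicted"], c["labels"])
        m["case_id"] = c.get("case_id", f"case{i}")
        rows.append(m)
    per_case = pd.DataFrame(rows).set_index("case_id")

    records = []
    for metric in ("RMSE", "MAE", "MDPE", "MDAPE"):
        for period in ("All",) + PERIODS:
            col = per_case[f"{metric}_{period}"]
            vals = col.dropna()
            n_skip = int(col.isna().sum())
            if n_skip:
                warnings.warn(f"{n_skip} case(s) had no samples in period {period}; skipped")
            sd_undef = len(vals) < 2
            records.append({
                "metric": metric,
                "period": period,
                "mean": float(vals.mean()),
                "sd": 0.0 if sd_undef else float(vals.std(ddof=1)),
                "n_cases": int(len(vals)),
                "sd_undefined": sd_undef,
            })
    table = pd.DataFrame(records)
    table.attrs["per_case"] = per_case
    return table
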