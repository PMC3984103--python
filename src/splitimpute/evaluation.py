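"""Evaluation machinery: error metrics, interval coverage, and the pooled
cross-method correlation of projected remaining times.

Errors are reported in minutes (squared minutes for MSE) to match race
conventions.  Correlations between methods are computed within each
dropout checkpoint and pooled by a dropout-count-weighted average; entries
involving the Britt method are pooled over the 35/40 km points only, since
the rule is undefined earlier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import PredictionResult
from .knn import IntervalPrediction

__all__ = [
    "MetricsTable",
    "CorrelationReport",
    "WITHIN_K_MINUTES",
    "compute_metrics",
    "coverage_probability",
    "pooled_correlation",
]

#: Accuracy thresholds (minutes) for the within-k proportions.
WITHIN_K_MINUTES = (1, 2, 3, 4, 5, 10)

#: Dropout checkpoints at which the Britt rule applies.
_BRITT_POINTS = (35.0, 40.0)


@dataclass
class MetricsTable:
    """Per-method (and optional per-stratum) accuracy measures."""

    table: pd.DataFrame  # index (method[, stratum]); columns n, mae, mse, within_*

    def to_csv(self, path) -> None:
        self.table.to_csv(path)


def compute_metrics(
    predictions: dict[str, list[PredictionResult]],
    truth_finish_s: dict[str, float],
    strata: dict[str, str] | None = None,
) -> MetricsTable:
    """MAE, MSE and within-k proportions of predicted vs true finish times.

    ``predictions`` maps method name -> list of predictions; every
    prediction must have a truth entry.  ``strata`` optionally maps
    runner_id -> stratum label for subdivided reporting; an empty stratum
    is reported with n = 0 and blank metrics.
    """
    rows = []
    all_strata = sorted(set(strata.values())) if strata else [None]
    for method, preds in predictions.items():
        errors, labels = [], []
        for p in preds:
            if p.runner_id not in truth_finish_s:
                raise KeyError(f"no truth for runner {p.runner_id}")
            errors.append((p.finish_s - truth_finish_s[p.runner_id]) / 60.0)
            labels.append(strata[p.runner_id] if strata else None)
        err = np.asarray(errors)
        lab = np.asarray(labels, dtype=object)
        for stratum in all_strata:
            sel = err if stratum is None else err[lab == stratum]
            row = {"method": method, "stratum": stratum, "n": len(sel)}
            if len(sel):
                row["mae"] = float(np.mean(np.abs(sel)))
                row["mse"] = float(np.mean(sel**2))
                for k in WITHIN_K_MINUTES:
                    row[f"within_{k}"] = float(np.mean(np.abs(sel) <= k))
            else:
                row["mae"] = row["mse"] = np.nan
                for k in WITHIN_K_MINUTES:
                    row[f"within_{k}"] = np.nan
            rows.append(row)
    df = pd.DataFrame(rows)
    index_cols = ["method"] if strata is None else ["method", "stratum"]
    if strata is None:
        df = df.drop(columns="stratum")
    return MetricsTable(df.set_index(index_cols))


def coverage_probability(
    intervals: list[IntervalPrediction], truth_finish_s: dict[str, float]
) -> float:
    """Fraction of true finish times inside their prediction interval."""
    if not intervals:
        raise ValueError("no intervals supplied")
    hits = 0
    for iv in intervals:
        lo, hi = iv.finish_interval
        t = truth_finish_s[iv.runner_id]
        hits += int(lo <= t <= hi)
    return hits / len(intervals)


@dataclass
class CorrelationReport:
    """Per-dropout-point correlation matrices and their pooled average."""

    methods: list[str]
    per_point: dict[float, pd.DataFrame]
    counts: dict[float, int]
    pooled: pd.DataFrame

    def to_csv(self, path) -> None:
        self.pooled.to_csv(path)


def _corr_matrix(block: pd.DataFrame) -> pd.DataFrame:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return block.corr()


def pooled_correlation(
    remaining: pd.DataFrame,
    dropout_km: dict[str, float],
    britt_method: str = "britt",
) -> CorrelationReport:
    """Pool per-dropout-point Pearson correlations of projected remaining times.

    ``remaining`` holds one column per method and one row per runner
    (index = runner_id), values being each method's projected remaining
    time.  Correlations are computed within each dropout point and
    averaged weighted by the number of runners there.  Pairs involving the
    Britt method are pooled over 35/40 km only.  A zero-variance method
    within a point yields undefined entries, which are excluded from the
    pool with a warning.
    """
    methods = list(remaining.columns)
    km_series = pd.Series({rid: dropout_km[rid] for rid in remaining.index})
    per_point: dict[float, pd.DataFrame] = {}
    counts: dict[float, int] = {}
    for km in sorted(km_series.unique()):
        block = remaining.loc[km_series == km]
        if len(block) < 2:
            warnings.warn(
                f"dropout point {km} km has fewer than 2 runners; excluded from pooling",
                stacklevel=2,
            )
            continue
        per_point[km] = _corr_matrix(block)
        counts[km] = len(block)
    if not per_point:
        raise ValueError("no dropout point has at least 2 runners")

    pooled = pd.DataFrame(np.nan, index=methods, columns=methods)
    for a in methods:
        for b in methods:
            kms = [
                km
                for km in per_point
                if not (britt_method in (a, b) and km not in _BRITT_POINTS)
            ]
            num = den = 0.0
            for km in kms:
                r = per_point[km].loc[a, b]
                if np.isnan(r):
                    warnings.warn(
                        f"undefined correlation ({a}, {b}) at {km} km excluded from pooling",
                        stacklevel=2,
                    )
                    continue
                num += counts[km] * r
                den += counts[km]
            pooled.loc[a, b] = num / den if den else np.nan
    return CorrelationReport(methods=methods, per_point=per_point, counts=counts, pooled=pooled)
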