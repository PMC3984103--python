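"""Nearest-neighbor predictors: local linear regression and rescaled
interval projection.

Neighborhoods are defined by Euclidean distance between 5 km section-time
vectors up to the query's last checkpoint, found with a kd-tree.  The
kd-tree is an acceleration detail only: results are guaranteed identical
to exhaustive search, with ties broken by stable reference order.

The point predictor (K = 200 by default) fits an ordinary least-squares
regression of the neighbors' remaining times on their observed sections
and evaluates it at the query — a local linear model that tolerates level
offsets between the query and the reference population.

The rescaled projector (K = 100 by default) instead multiplies each
neighbor's whole profile by a constant so its cumulative time at the
sampling point matches the query's, then reads off per-checkpoint medians
and 5th/95th percentiles of the rescaled cumulative times: a 90%
prediction interval for the rest of the race.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .core import DEFAULT_LAYOUT, CourseLayout, PredictionResult, RunnerRecord
from .io_prepare import Cohort

__all__ = [
    "NeighborIndex",
    "IntervalPrediction",
    "build_neighbor_index",
    "find_neighbors",
    "predict_knn",
    "predict_rescaled_knn",
]

logger = logging.getLogger(__name__)


@dataclass
class NeighborIndex:
    """Reference section-time vectors organized for neighbor search.

    One index serves all dropout points: per query, distances use only the
    sections up to the query's last checkpoint.  ``use_cumulative`` switches
    the distance to cumulative-time vectors (sensitivity checks only).
    """

    runner_ids: list[str]
    sections: np.ndarray          # (n_ref, n_sections) complete section times
    layout: CourseLayout
    use_cumulative: bool = False

    def __post_init__(self) -> None:
        self._cums = np.cumsum(self.sections, axis=1)
        self._trees: dict[int, cKDTree] = {}

    def __len__(self) -> int:
        return len(self.runner_ids)

    def _features(self, m: int) -> np.ndarray:
        return self._cums[:, :m] if self.use_cumulative else self.sections[:, :m]

    def _tree(self, m: int) -> cKDTree:
        if m not in self._trees:
            self._trees[m] = cKDTree(self._features(m))
        return self._trees[m]


def build_neighbor_index(
    reference: Cohort,
    layout: CourseLayout = DEFAULT_LAYOUT,
    use_cumulative: bool = False,
) -> NeighborIndex:
    """Index a cohort of complete reference records for neighbor search."""
    ids, rows = [], []
    for r in reference:
        if not r.is_finisher(layout):
            raise ValueError(f"reference runner {r.runner_id} is incomplete")
        ids.append(r.runner_id)
        rows.append(r.section_times)
    return NeighborIndex(
        runner_ids=ids,
        sections=np.asarray(rows, dtype=float),
        layout=layout,
        use_cumulative=use_cumulative,
    )


def find_neighbors(
    query: np.ndarray,
    index: NeighborIndex,
    K: int,
    exclude_id: str | None = None,
) -> tuple[list[str], np.ndarray]:
    """The K reference records nearest to a section-time query vector.

    Exact: identical to an exhaustive Euclidean scan, ties broken by
    stable reference order.  ``exclude_id`` removes a query's own record
    from its neighborhood (leakage control during validation).
    """
    q = np.asarray(query, dtype=float)
    m = len(q)
    n_avail = len(index) - (1 if exclude_id in index.runner_ids else 0)
    if K > n_avail:
        raise ValueError(f"K={K} exceeds index size {n_avail}")
    tree = index._tree(m)
    # over-query to absorb the excluded record and boundary ties, then
    # resolve exactly against true distances
    k_ask = min(len(index), K + 2)
    dists, idxs = tree.query(q, k=k_ask)
    dists, idxs = np.atleast_1d(dists), np.atleast_1d(idxs)
    r_edge = dists[min(K, len(dists) - 1)] if len(dists) > K else dists[-1]
    cand = tree.query_ball_point(q, r=r_edge * (1 + 1e-12) + 1e-12)
    cand = sorted(set(cand) | set(idxs.tolist()))
    feats = index._features(m)[cand]
    true_d = np.sqrt(((feats - q) ** 2).sum(axis=1))
    order = sorted(range(len(cand)), key=lambda i: (true_d[i], cand[i]))
    out_ids, out_d = [], []
    for i in order:
        rid = index.runner_ids[cand[i]]
        if rid == exclude_id:
            continue
        out_ids.append(rid)
        out_d.append(true_d[i])
        if len(out_ids) == K:
            break
    return out_ids, np.asarray(out_d)


def _query_features(record: RunnerRecord, index: NeighborIndex) -> np.ndarray:
    x = np.asarray(record.section_times, dtype=float)
    return np.cumsum(x) if index.use_cumulative else x


def predict_knn(
    record: RunnerRecord,
    index: NeighborIndex,
    K: int = 200,
    exclude_self: bool = True,
) -> PredictionResult:
    """Local linear regression over the K nearest neighbors.

    OLS (with intercept) of the neighbors' remaining-time sums on their
    observed-section times, evaluated at the query.  A singular local
    design falls back to the neighbor mean of remaining times.
    """
    m = len(record.section_times)
    if K <= m + 1:
        raise ValueError(f"K={K} too small for a local regression on {m} sections")
    q = _query_features(record, index)
    ids, _ = find_neighbors(q, index, K, exclude_id=record.runner_id if exclude_self else None)
    pos = {rid: i for i, rid in enumerate(index.runner_ids)}
    rows = np.array([pos[rid] for rid in ids])
    Xn = index.sections[rows, :m]
    remaining = index.sections[rows, m:].sum(axis=1)
    design = np.column_stack([np.ones(K), Xn])
    coef, _, rank, _ = np.linalg.lstsq(design, remaining, rcond=None)
    if rank < design.shape[1]:
        logger.warning(
            "singular local design for runner %s; falling back to neighbor mean",
            record.runner_id,
        )
        pred = float(remaining.mean())
    else:
        pred = float(coef[0] + coef[1:] @ np.asarray(record.section_times, dtype=float))
    cum = record.cumulative_times()[-1]
    return PredictionResult(
        runner_id=record.runner_id, method="knn", remaining_s=pred, finish_s=cum + pred
    )


@dataclass
class IntervalPrediction:
    """Median projection with a 90% band at every future checkpoint."""

    runner_id: str
    checkpoint_km: list[float]
    lower_s: np.ndarray
    median_s: np.ndarray
    upper_s: np.ndarray

    def __post_init__(self) -> None:
        ok = (self.lower_s <= self.median_s + 1e-9) & (self.median_s <= self.upper_s + 1e-9)
        if not np.all(ok):
            raise ValueError("interval bounds must satisfy lower <= median <= upper")

    @property
    def finish_s(self) -> float:
        """Point finish prediction: the median at the final checkpoint."""
        return float(self.median_s[-1])

    @property
    def finish_interval(self) -> tuple[float, float]:
        return float(self.lower_s[-1]), float(self.upper_s[-1])


def predict_rescaled_knn(
    record: RunnerRecord,
    index: NeighborIndex,
    K: int = 100,
    exclude_self: bool = True,
    quantiles: tuple[float, float, float] = (5.0, 50.0, 95.0),
) -> IntervalPrediction:
    """Rescaled-neighbor projection with empirical prediction intervals.

    Each of the K nearest neighbors is multiplied by a constant so its
    cumulative time at the sampling point equals the query's; the rescaled
    cumulative times at every later checkpoint yield the median and the
    5th/95th percentile bounds (nominal 90% interval).  Percentiles use
    linear interpolation between order statistics.
    """
    m = len(record.section_times)
    layout = index.layout
    if m >= layout.n_sections:
        raise ValueError(f"runner {record.runner_id} already finished; nothing to project")
    q = _query_features(record, index)
    ids, _ = find_neighbors(q, index, K, exclude_id=record.runner_id if exclude_self else None)
    pos = {rid: i for i, rid in enumerate(index.runner_ids)}
    rows = np.array([pos[rid] for rid in ids])
    cum_q = record.cumulative_times()[-1]
    neighbor_cums = index._cums[rows]                     # (K, n_sections)
    scale = cum_q / neighbor_cums[:, m - 1]               # per-neighbor constant
    rescaled = neighbor_cums[:, m:] * scale[:, None]      # future checkpoints only
    lo, med, hi = (np.percentile(rescaled, p, axis=0) for p in quantiles)
    return IntervalPrediction(
        runner_id=record.runner_id,
        checkpoint_km=list(layout.checkpoint_km[m:]),
        lower_s=lo,
        median_s=med,
        upper_s=hi,
    )
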