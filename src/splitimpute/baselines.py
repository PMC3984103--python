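"""Closed-form finish-time projections: Constant Pace, Britt, Split-ratio.

Constant Pace extrapolates the runner's average pace so far over the whole
distance.  The Britt rule multiplies the cumulative time at 40 km by 1.06
(or at 35 km by 1.23) and is undefined earlier.  The Split-ratio method
multiplies the runner's *last observed 5 km section time* by a gender- and
checkpoint-specific constant to project the remaining time, leveraging the
most recent information about pace.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import DEFAULT_LAYOUT, CourseLayout, PredictionResult, RunnerRecord
from .io_prepare import Cohort

__all__ = [
    "SplitRatioTable",
    "REFERENCE_SPLIT_RATIOS",
    "BRITT_FACTORS",
    "predict_constant_pace",
    "predict_britt",
    "estimate_split_ratio_table",
    "predict_split_ratio",
]

#: Cumulative-time multipliers of the Britt rule, keyed by last checkpoint km.
BRITT_FACTORS: dict[float, float] = {40.0: 1.06, 35.0: 1.23}

#: Checkpoints at which the Split-ratio method applies (last completed 5 km
#: section ends at one of these).
_SPLIT_RATIO_POINTS = (20.0, 25.0, 30.0, 35.0, 40.0)


@dataclass(frozen=True)
class SplitRatioTable:
    """Multiplicative constants mapping the last 5 km section time to the
    projected remaining time, keyed by (gender, last checkpoint km)."""

    constants: dict[tuple[str, float], float]

    def __post_init__(self) -> None:
        for key, c in self.constants.items():
            if c <= 0:
                raise ValueError(f"non-positive split-ratio constant for {key}")

    def constant(self, gender: str, last_checkpoint_km: float) -> float:
        try:
            return self.constants[(gender, float(last_checkpoint_km))]
        except KeyError:
            raise KeyError(
                f"no split-ratio constant for gender={gender!r} at "
                f"{last_checkpoint_km} km"
            ) from None


#: Published reference constants, estimated from two prior years' finishers
#: slower than four hours; shipped as the default table.
REFERENCE_SPLIT_RATIOS = SplitRatioTable(
    constants={
        ("M", 20.0): 5.0648,
        ("M", 25.0): 3.8765,
        ("M", 30.0): 2.5761,
        ("M", 35.0): 1.4333,
        ("M", 40.0): 0.4207,
        ("F", 20.0): 4.8354,
        ("F", 25.0): 3.6965,
        ("F", 30.0): 2.4876,
        ("F", 35.0): 1.4055,
        ("F", 40.0): 0.4230,
    }
)


def predict_constant_pace(
    record: RunnerRecord, layout: CourseLayout = DEFAULT_LAYOUT
) -> PredictionResult:
    """Project the finish assuming the average pace so far continues.

    finish = cumulative time at the last checkpoint x (total km / km so far),
    computed as the exact distance ratio.
    """
    if not record.section_times:
        raise ValueError(f"runner {record.runner_id} has no recorded checkpoints")
    cum = record.cumulative_times()[-1]
    last_km = record.last_checkpoint_km(layout)
    finish = cum * layout.total_km / last_km
    return PredictionResult(
        runner_id=record.runner_id,
        method="constant_pace",
        remaining_s=finish - cum,
        finish_s=finish,
    )


def predict_britt(
    record: RunnerRecord, layout: CourseLayout = DEFAULT_LAYOUT
) -> PredictionResult:
    """Britt's extrapolation: 1.06 x cumulative at 40 km, 1.23 x at 35 km.

    No rule exists for runners who failed to reach the 35 km point; such
    records raise ``ValueError``.
    """
    last_km = record.last_checkpoint_km(layout)
    if last_km not in BRITT_FACTORS:
        raise ValueError(
            f"Britt method undefined for last checkpoint {last_km} km "
            "(no rule below 35 km)"
        )
    cum = record.cumulative_times()[-1]
    finish = cum * BRITT_FACTORS[last_km]
    return PredictionResult(
        runner_id=record.runner_id,
        method="britt",
        remaining_s=finish - cum,
        finish_s=finish,
    )


def estimate_split_ratio_table(
    training: Cohort, layout: CourseLayout = DEFAULT_LAYOUT
) -> SplitRatioTable:
    """Estimate split-ratio constants from a complete training cohort.

    For each gender and candidate last checkpoint, the constant is the mean
    over training runners of (time after that checkpoint) / (last 5 km
    section time).
    """
    constants: dict[tuple[str, float], float] = {}
    for gender in ("M", "F"):
        recs = [r for r in training if r.gender == gender]
        if not recs:
            raise ValueError(f"no training runners of gender {gender!r}")
        for km in _SPLIT_RATIO_POINTS:
            idx = layout.checkpoint_index(km)
            total = 0.0
            for r in recs:
                if not r.is_finisher(layout):
                    raise ValueError(f"training runner {r.runner_id} is incomplete")
                last_section = r.section_times[idx]
                remaining = sum(r.section_times[idx + 1 :])
                total += remaining / last_section
            constants[(gender, km)] = total / len(recs)
    return SplitRatioTable(constants)


def predict_split_ratio(
    record: RunnerRecord,
    table: SplitRatioTable = REFERENCE_SPLIT_RATIOS,
    layout: CourseLayout = DEFAULT_LAYOUT,
) -> PredictionResult:
    """Project the remaining time from the last observed 5 km section.

    remaining = last section time x table constant for (gender, checkpoint).
    """
    last_km = record.last_checkpoint_km(layout)
    c = table.constant(record.gender, last_km)
    last_section = record.section_times[-1]
    if last_section is None:
        raise ValueError(f"runner {record.runner_id} has an uninterpolated last section")
    cum = record.cumulative_times()[-1]
    remaining = last_section * c
    return PredictionResult(
        runner_id=record.runner_id,
        method="split_ratio",
        remaining_s=remaining,
        finish_s=cum + remaining,
    )
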