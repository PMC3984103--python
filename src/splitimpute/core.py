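"""Domain types, course geometry, and time arithmetic.

A marathon course is divided into checkpointed sections: eight 5 km
stretches plus the final 2.195 km.  A runner's record stores per-section
durations; cumulative checkpoint times are derived by prefix summation.
All arithmetic is carried out in floating-point seconds — rounding to
whole seconds happens only when formatting ``h:mm:ss`` strings.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace

__all__ = [
    "CourseLayout",
    "RunnerRecord",
    "PredictionResult",
    "DROPOUT_POINTS",
    "parse_hms",
    "format_hms",
    "cumulative_time",
]

#: Valid last-recorded checkpoints (km) for a non-finisher kept in the
#: analysis set; runners dropping before halfway are filtered out.
DROPOUT_POINTS: tuple[float, ...] = (20.0, 25.0, 30.0, 35.0, 40.0)

_HMS_RE = re.compile(r"^(\d+):([0-5]\d):([0-5]\d)$")


@dataclass(frozen=True)
class CourseLayout:
    """Checkpoint distances and derived section lengths of the course.

    The default is the standard marathon instrumented every 5 km:
    checkpoints at 5, 10, ..., 40 km and the finish at 42.195 km
    (26.219 miles), giving eight 5 km sections plus one 2.195 km section.
    """

    checkpoint_km: tuple[float, ...] = (5, 10, 15, 20, 25, 30, 35, 40, 42.195)

    def __post_init__(self) -> None:
        cks = tuple(float(c) for c in self.checkpoint_km)
        object.__setattr__(self, "checkpoint_km", cks)
        if any(b <= a for a, b in zip((0.0,) + cks, cks)):
            raise ValueError("checkpoint distances must be strictly increasing and positive")

    @property
    def section_km(self) -> tuple[float, ...]:
        prev = (0.0,) + self.checkpoint_km[:-1]
        return tuple(b - a for a, b in zip(prev, self.checkpoint_km))

    @property
    def total_km(self) -> float:
        return self.checkpoint_km[-1]

    @property
    def total_miles(self) -> float:
        return self.total_km / 1.609344

    @property
    def n_sections(self) -> int:
        return len(self.checkpoint_km)

    def checkpoint_index(self, checkpoint_km: float) -> int:
        """0-based index of a checkpoint distance, or raise ``KeyError``."""
        for i, c in enumerate(self.checkpoint_km):
            if math.isclose(c, checkpoint_km, rel_tol=0.0, abs_tol=1e-9):
                return i
        raise KeyError(f"{checkpoint_km} km is not a checkpoint of this course")


#: Module-level default course shared by every operation that takes a layout.
DEFAULT_LAYOUT = CourseLayout()


@dataclass
class RunnerRecord:
    """One runner's attributes plus per-section times.

    ``section_times`` is contiguous from section 1 and may be shorter than
    the course (a non-finisher truncated at a dropout checkpoint).  Interior
    entries may be ``None`` only transiently, before gap interpolation.
    """

    runner_id: str
    year: int
    gender: str
    age: int
    section_times: list[float | None] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.gender not in ("M", "F"):
            raise ValueError(f"gender must be 'M' or 'F', got {self.gender!r}")
        for t in self.section_times:
            if t is not None and t <= 0:
                raise ValueError(f"runner {self.runner_id}: non-positive section time {t}")

    @property
    def n_sections(self) -> int:
        return len(self.section_times)

    @property
    def has_gaps(self) -> bool:
        return any(t is None for t in self.section_times)

    def last_checkpoint_km(self, layout: CourseLayout = DEFAULT_LAYOUT) -> float:
        if not self.section_times:
            return 0.0
        return layout.checkpoint_km[len(self.section_times) - 1]

    def is_finisher(self, layout: CourseLayout = DEFAULT_LAYOUT) -> bool:
        return len(self.section_times) == layout.n_sections and not self.has_gaps

    @property
    def status(self) -> str:
        return "finished" if self.is_finisher() else "dnf"

    def cumulative_times(self) -> list[float]:
        """Prefix sums of the section times (requires no gaps)."""
        if self.has_gaps:
            raise ValueError(f"runner {self.runner_id} has uninterpolated gaps")
        out, acc = [], 0.0
        for t in self.section_times:
            acc += t
            out.append(acc)
        return out

    def truncated(self, n_sections: int) -> "RunnerRecord":
        """Copy of this record keeping only the first ``n_sections`` sections."""
        return replace(self, section_times=list(self.section_times[:n_sections]))


@dataclass(frozen=True)
class PredictionResult:
    """A point prediction of the time remaining from the last checkpoint.

    ``finish_s`` is the observed cumulative time plus ``remaining_s``.
    """

    runner_id: str
    method: str
    remaining_s: float
    finish_s: float

    def __post_init__(self) -> None:
        if self.remaining_s <= 0:
            raise ValueError(
                f"{self.method} produced non-positive remaining time "
                f"{self.remaining_s} for runner {self.runner_id}"
            )


def parse_hms(text: str) -> float:
    """Parse an ``h:mm:ss`` duration string into seconds.

    Hours may exceed one digit; minutes and seconds must be zero-padded
    two-digit fields below 60.
    """
    m = _HMS_RE.match(text.strip())
    if m is None:
        raise ValueError(f"malformed h:mm:ss duration: {text!r}")
    h, mm, ss = (int(g) for g in m.groups())
    return float(h * 3600 + mm * 60 + ss)


def format_hms(seconds: float) -> str:
    """Format seconds as ``h:mm:ss``, rounding half-up to the whole second."""
    if seconds < 0:
        raise ValueError(f"negative duration: {seconds}")
    total = math.floor(seconds + 0.5)  # half-up, not banker's rounding
    h, rem = divmod(total, 3600)
    mm, ss = divmod(rem, 60)
    return f"{h}:{mm:02d}:{ss:02d}"


def cumulative_time(
    record: RunnerRecord,
    checkpoint_km: float,
    layout: CourseLayout = DEFAULT_LAYOUT,
) -> float:
    """Cumulative time (s) of ``record`` at a recorded checkpoint.

    Raises ``KeyError`` if the distance is not a course checkpoint and
    ``ValueError`` if the runner was not recorded there.
    """
    idx = layout.checkpoint_index(checkpoint_km)
    if idx >= len(record.section_times):
        raise ValueError(
            f"runner {record.runner_id} has no recorded time at {checkpoint_km} km"
        )
    head = record.section_times[: idx + 1]
    if any(t is None for t in head):
        raise ValueError(
            f"runner {record.runner_id} has an uninterpolated gap before {checkpoint_km} km"
        )
    return float(sum(head))
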