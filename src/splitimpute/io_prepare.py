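"""Cohort I/O, study filters, gap interpolation, and validation masking.

Cohort CSVs store what race timing systems emit: one ``h:mm:ss``
cumulative-time column per checkpoint, with an empty cell where a runner
was not recorded.  On read these are converted to per-section durations.

A record whose interior checkpoint is unrecorded is held, pre-interpolation,
with ``None`` in place of each section inside the gap and the *combined*
duration from the last recorded checkpoint stored in the first section after
the gap — so prefix sums over recorded entries still reproduce every
recorded cumulative time exactly.  ``interpolate_isolated_gaps`` resolves
such gaps by linear interpolation of cumulative time against distance.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .core import (
    DEFAULT_LAYOUT,
    DROPOUT_POINTS,
    CourseLayout,
    PredictionResult,
    RunnerRecord,
    format_hms,
    parse_hms,
)

__all__ = [
    "Cohort",
    "ValidationSet",
    "read_cohort_csv",
    "write_cohort_csv",
    "write_predictions_csv",
    "interpolate_isolated_gaps",
    "apply_study_filters",
    "build_validation_set",
    "largest_remainder_allocation",
    "DEFAULT_DNF_FRACTION",
    "DEFAULT_DROPOUT_WEIGHTS",
]

#: Fraction of runners masked as synthetic non-finishers when building a
#: validation set: the 2013 field's observed DNF share.
DEFAULT_DNF_FRACTION = 0.257

#: Observed 2013 dropout counts at the 20/25/30/35/40 km checkpoints,
#: used (normalized) as default allocation weights.
DEFAULT_DROPOUT_WEIGHTS = (93.0, 39.0, 459.0, 533.0, 4505.0)

_META_COLS = ["runner_id", "year", "gender", "age"]


@dataclass
class Cohort:
    """A collection of runner records with unique identifiers."""

    records: list[RunnerRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.runner_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate runner_id in cohort")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def by_id(self, runner_id: str) -> RunnerRecord:
        for r in self.records:
            if r.runner_id == runner_id:
                return r
        raise KeyError(runner_id)

    def finishers(self, layout: CourseLayout = DEFAULT_LAYOUT) -> "Cohort":
        return Cohort(
            [r for r in self.records if r.is_finisher(layout)],
            provenance=f"{self.provenance} (finishers)",
        )


@dataclass
class ValidationSet:
    """A cohort with a known masking plan and the hidden true tail times.

    ``truth`` maps each masked runner to their true remaining time from the
    dropout checkpoint to the finish; ``hidden_tails`` keeps the removed
    section times so the original cohort can be reconstructed exactly.
    """

    masked: Cohort
    truth: dict[str, float]
    plan: dict[str, float]
    dnf_fraction: float
    dropout_weights: tuple[float, ...]
    seed: int
    hidden_tails: dict[str, list[float]] = field(default_factory=dict)

    def truth_finish(self, runner_id: str, layout: CourseLayout = DEFAULT_LAYOUT) -> float:
        rec = self.masked.by_id(runner_id)
        return rec.cumulative_times()[-1] + self.truth[runner_id]

    def restore(self) -> Cohort:
        """Reassemble the unmasked cohort (conservation check)."""
        out = []
        for r in self.masked:
            if r.runner_id in self.hidden_tails:
                out.append(replace(r, section_times=list(r.section_times) + list(self.hidden_tails[r.runner_id])))
            else:
                out.append(r)
        return Cohort(out, provenance=self.masked.provenance)


def _checkpoint_cols(layout: CourseLayout) -> list[str]:
    cols = [f"k{int(c)}" for c in layout.checkpoint_km[:-1]]
    return cols + ["finish"]


def read_cohort_csv(
    path,
    layout: CourseLayout = DEFAULT_LAYOUT,
    provenance: str | None = None,
) -> Cohort:
    """Read a cohort CSV of cumulative checkpoint times into section form.

    Raises ``ValueError`` naming the offending row for a missing column,
    non-monotone cumulative times, or an unparsable time field.
    """
    ck_cols = _checkpoint_cols(layout)
    records: list[RunnerRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in _META_COLS + ck_cols if c not in header]
        if missing:
            raise ValueError(f"{path}: missing mandatory column(s) {missing}")
        for lineno, row in enumerate(reader, start=2):
            rid = row["runner_id"]
            cums: list[float | None] = []
            for col in ck_cols:
                cell = (row.get(col) or "").strip()
                if not cell:
                    cums.append(None)
                    continue
                try:
                    cums.append(parse_hms(cell))
                except ValueError as exc:
                    raise ValueError(f"{path} row {lineno} (runner {rid}): {exc}") from exc
            # drop trailing unrecorded checkpoints: those are the DNF tail
            while cums and cums[-1] is None:
                cums.pop()
            known = [(i, c) for i, c in enumerate(cums) if c is not None]
            for (_, a), (_, b) in zip(known, known[1:]):
                if b <= a:
                    raise ValueError(
                        f"{path} row {lineno} (runner {rid}): cumulative times not strictly increasing"
                    )
            sections = _cumulative_to_sections(cums)
            records.append(
                RunnerRecord(
                    runner_id=rid,
                    year=int(row["year"]),
                    gender=row["gender"].strip(),
                    age=int(row["age"]),
                    section_times=sections,
                )
            )
    return Cohort(records, provenance=provenance if provenance is not None else str(path))


def _cumulative_to_sections(cums: list[float | None]) -> list[float | None]:
    sections: list[float | None] = []
    last_known = 0.0
    for c in cums:
        if c is None:
            sections.append(None)
        else:
            sections.append(c - last_known)
            last_known = c
    return sections


def write_cohort_csv(cohort: Cohort, path, layout: CourseLayout = DEFAULT_LAYOUT) -> None:
    """Write a cohort back to cumulative ``h:mm:ss`` CSV form."""
    ck_cols = _checkpoint_cols(layout)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_META_COLS + ck_cols)
        for r in cohort:
            cells = [r.runner_id, r.year, r.gender, r.age]
            acc = 0.0
            for j in range(layout.n_sections):
                if j >= len(r.section_times):
                    cells.append("")
                elif r.section_times[j] is None:
                    cells.append("")
                else:
                    acc += r.section_times[j]
                    cells.append(format_hms(acc))
            writer.writerow(cells)


def write_predictions_csv(results: list[PredictionResult], cohort: Cohort, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["runner_id", "method", "last_checkpoint_km", "predicted_finish", "predicted_finish_s"]
        )
        for res in results:
            rec = cohort.by_id(res.runner_id)
            writer.writerow(
                [
                    res.runner_id,
                    res.method,
                    rec.last_checkpoint_km(),
                    format_hms(res.finish_s),
                    f"{res.finish_s:.3f}",
                ]
            )


def interpolate_isolated_gaps(
    record: RunnerRecord, layout: CourseLayout = DEFAULT_LAYOUT
) -> RunnerRecord:
    """Fill interior unrecorded checkpoints by linear interpolation.

    Cumulative time is interpolated against distance between the flanking
    recorded checkpoints; a run of consecutive missing checkpoints is filled
    on the same line.  Trailing missing checkpoints (a DNF tail) are left
    untouched.  A record with no interior gaps is returned unchanged.
    """
    if not record.has_gaps:
        return record
    sections = list(record.section_times)
    n = len(sections)
    cums: list[float | None] = []
    acc = 0.0
    for t in sections:
        if t is None:
            cums.append(None)
        else:
            acc += t
            cums.append(acc)
    dists = layout.checkpoint_km[:n]
    i = 0
    while i < n:
        if cums[i] is not None:
            i += 1
            continue
        j = i
        while j < n and cums[j] is None:
            j += 1
        if j == n:  # trailing gap: cannot interpolate, leave as-is
            break
        left_c = cums[i - 1] if i > 0 else 0.0
        left_d = dists[i - 1] if i > 0 else 0.0
        right_c, right_d = cums[j], dists[j]
        slope = (right_c - left_c) / (right_d - left_d)
        for g in range(i, j):
            cums[g] = left_c + slope * (dists[g] - left_d)
        i = j + 1
    filled = _cumulative_to_sections(cums)
    return replace(record, section_times=filled)


def apply_study_filters(
    cohort: Cohort,
    min_finish_s: float = 14400.0,
    min_dropout_km: float = 20.0,
    layout: CourseLayout = DEFAULT_LAYOUT,
) -> Cohort:
    """Apply the study's population filters.

    Finishers faster than ``min_finish_s`` (default four hours) are removed,
    as are non-finishers whose last recorded checkpoint lies before
    ``min_dropout_km`` (default the 20 km half-way checkpoint, which itself
    is retained).
    """
    kept = []
    for r in cohort:
        if r.is_finisher(layout):
            if r.cumulative_times()[-1] >= min_finish_s:
                kept.append(r)
        else:
            if r.last_checkpoint_km(layout) >= min_dropout_km:
                kept.append(r)
    return Cohort(kept, provenance=f"{cohort.provenance} (filtered)")


def largest_remainder_allocation(total: int, weights: tuple[float, ...]) -> list[int]:
    """Apportion ``total`` units across categories proportionally to weights.

    Hamilton's method: floor the exact quotas, then hand the leftover units
    to the largest fractional remainders, ties broken by earlier category.
    """
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    quotas = total * w / w.sum()
    counts = np.floor(quotas).astype(int)
    remainder = total - int(counts.sum())
    # stable sort on (-fractional part, index): earlier category wins ties
    order = sorted(range(len(w)), key=lambda i: (-(quotas[i] - counts[i]), i))
    for i in order[:remainder]:
        counts[i] += 1
    return counts.tolist()


def build_validation_set(
    cohort: Cohort,
    dnf_fraction: float = DEFAULT_DNF_FRACTION,
    dropout_weights: tuple[float, ...] = DEFAULT_DROPOUT_WEIGHTS,
    seed: int = 0,
    layout: CourseLayout = DEFAULT_LAYOUT,
) -> ValidationSet:
    """Mask a cohort of finishers into a validation set with hidden truth.

    Exactly ``round(dnf_fraction * N)`` runners are selected uniformly at
    random (seeded) and truncated at dropout checkpoints allocated across
    20/25/30/35/40 km by largest-remainder apportionment of the weights.
    The same seed always yields the same masking plan.
    """
    for r in cohort:
        if not r.is_finisher(layout):
            raise ValueError(f"cohort must be complete; runner {r.runner_id} is not")
    n = len(cohort)
    n_mask = int(round(dnf_fraction * n))
    counts = largest_remainder_allocation(n_mask, dropout_weights)
    if any(c == 0 and w > 0 for c, w in zip(counts, dropout_weights)) and n_mask > 0:
        warnings.warn(
            "cohort too small: some dropout point with positive weight received 0 runners",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(n, size=n_mask, replace=False)
    # assignment order randomized, then dropout points dealt in checkpoint order
    points: list[float] = []
    for km, c in zip(DROPOUT_POINTS, counts):
        points.extend([km] * c)

    masked_records: list[RunnerRecord] = []
    truth: dict[str, float] = {}
    plan: dict[str, float] = {}
    tails: dict[str, list[float]] = {}
    chosen_set = {int(i): km for i, km in zip(chosen, points)}
    for i, rec in enumerate(cohort):
        if i in chosen_set:
            km = chosen_set[i]
            k = layout.checkpoint_index(km) + 1
            cums = rec.cumulative_times()
            truth[rec.runner_id] = cums[-1] - cums[k - 1]
            plan[rec.runner_id] = km
            tails[rec.runner_id] = [float(t) for t in rec.section_times[k:]]
            masked_records.append(rec.truncated(k))
        else:
            masked_records.append(rec)
    return ValidationSet(
        masked=Cohort(masked_records, provenance=f"{cohort.provenance} (masked)"),
        truth=truth,
        plan=plan,
        dnf_fraction=dnf_fraction,
        dropout_weights=tuple(dropout_weights),
        seed=seed,
        hidden_tails=tails,
    )
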