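"""Trained statistical predictors: per-dropout linear regression, two-way
log-ANOVA with 32 pacing subgroups, and low-rank SVD matrix completion.

Linear regression fits, for each dropout checkpoint, an ordinary
least-squares model of the total remaining time S_i on the runner's
available 5 km section times (optionally plus age and gender).

The ANOVA predictor models the log section time as mu + alpha_i + beta_j
(runner effect plus section effect, with the section effects summing to
zero), fitted separately within 32 subgroups formed by octiles of the
half-way cumulative time and quartiles of a scaled slow-down measure.
A new runner's alpha is estimated from their observed sections and missing
sections are imputed multiplicatively.

The SVD predictor factors the complete runner-by-section time matrix,
truncates to rank k, and completes a partially observed runner by solving
the under-determined linear system for the minimum-norm runner vector via
the Moore-Penrose pseudo-inverse.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .core import (
    DEFAULT_LAYOUT,
    DROPOUT_POINTS,
    CourseLayout,
    PredictionResult,
    RunnerRecord,
)
from .io_prepare import Cohort

__all__ = [
    "RegressionModelSet",
    "AnovaModel",
    "SvdModel",
    "fit_lm_models",
    "predict_lm",
    "fit_anova",
    "predict_anova",
    "fit_two_way_log_anova",
    "fit_svd",
    "choose_svd_rank",
    "predict_svd",
    "save_model_bundle",
    "load_model_bundle",
]


def _complete_matrix(training: Cohort, layout: CourseLayout) -> np.ndarray:
    rows = []
    for r in training:
        if not r.is_finisher(layout):
            raise ValueError(f"training runner {r.runner_id} is incomplete")
        rows.append(r.section_times)
    return np.asarray(rows, dtype=float)


# ---------------------------------------------------------------------------
# Linear regression, one model per dropout checkpoint
# ---------------------------------------------------------------------------

@dataclass
class RegressionModelSet:
    """OLS coefficients for each dropout checkpoint.

    ``models`` maps dropout km -> (intercept-first coefficient vector);
    column order is [1?, section_1 .. section_m, age?, is_female?].
    """

    models: dict[float, np.ndarray]
    include_intercept: bool
    include_demographics: bool
    n_train: int

    def to_dict(self) -> dict:
        return {
            "kind": "lm",
            "version": 1,
            "include_intercept": self.include_intercept,
            "include_demographics": self.include_demographics,
            "n_train": self.n_train,
            "models": {str(k): v.tolist() for k, v in self.models.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RegressionModelSet":
        return cls(
            models={float(k): np.asarray(v) for k, v in d["models"].items()},
            include_intercept=d["include_intercept"],
            include_demographics=d["include_demographics"],
            n_train=d["n_train"],
        )


def _lm_design(
    X_sections: np.ndarray,
    ages: np.ndarray | None,
    female: np.ndarray | None,
    include_intercept: bool,
    include_demographics: bool,
) -> np.ndarray:
    cols = []
    if include_intercept:
        cols.append(np.ones(len(X_sections)))
    cols.extend(X_sections.T)
    if include_demographics:
        cols.append(ages)
        cols.append(female)
    return np.column_stack(cols)


def fit_lm_models(
    training: Cohort,
    include_demographics: bool = False,
    include_intercept: bool = True,
    layout: CourseLayout = DEFAULT_LAYOUT,
) -> RegressionModelSet:
    """Fit, per dropout checkpoint, OLS of remaining time on available sections."""
    X = _complete_matrix(training, layout)
    ages = np.array([r.age for r in training], dtype=float)
    female = np.array([1.0 if r.gender == "F" else 0.0 for r in training])
    models: dict[float, np.ndarray] = {}
    for km in DROPOUT_POINTS:
        m = layout.checkpoint_index(km) + 1
        design = _lm_design(X[:, :m], ages, female, include_intercept, include_demographics)
        n, p = design.shape
        if n < p + 1:
            raise ValueError(
                f"dropout point {km} km: {n} training runners cannot identify {p} parameters"
            )
        target = X[:, m:].sum(axis=1)
        coef, _, rank, _ = np.linalg.lstsq(design, target, rcond=None)
        if rank < p:
            raise ValueError(f"dropout point {km} km: rank-deficient design matrix")
        models[km] = coef
    return RegressionModelSet(
        models=models,
        include_intercept=include_intercept,
        include_demographics=include_demographics,
        n_train=len(training),
    )


def predict_lm(
    record: RunnerRecord,
    models: RegressionModelSet,
    layout: CourseLayout = DEFAULT_LAYOUT,
) -> PredictionResult:
    km = record.last_checkpoint_km(layout)
    if km not in models.models:
        raise ValueError(f"no regression model fitted for dropout point {km} km")
    x = np.asarray(record.section_times, dtype=float)
    features = []
    if models.include_intercept:
        features.append(1.0)
    features.extend(x)
    if models.include_demographics:
        features.append(float(record.age))
        features.append(1.0 if record.gender == "F" else 0.0)
    remaining = float(np.dot(models.models[km], features))
    cum = record.cumulative_times()[-1]
    return PredictionResult(
        runner_id=record.runner_id, method="lm", remaining_s=remaining, finish_s=cum + remaining
    )


# ---------------------------------------------------------------------------
# Two-way log-ANOVA with pacing subgroups
# ---------------------------------------------------------------------------

def fit_two_way_log_anova(times: np.ndarray) -> tuple[float, np.ndarray]:
    """Least-squares fit of log t_ij = mu + alpha_i + beta_j, sum(beta) = 0.

    For a complete two-way layout the solution is closed form: mu is the
    grand mean of log times and beta_j the column-mean deviations.
    Returns (mu, beta); the per-runner alpha_i are not stored — they are
    re-estimated at prediction time from whatever sections are observed.
    """
    y = np.log(np.asarray(times, dtype=float))
    mu = float(y.mean())
    beta = y.mean(axis=0) - mu
    return mu, beta


@dataclass
class AnovaModel:
    """Subgroup boundaries and per-subgroup (mu, beta) effect estimates."""

    a_breaks: np.ndarray                     # 7 octile boundaries of half-way time
    b_breaks: dict[float, np.ndarray]        # per last-km: 3 quartile boundaries of slow-down
    subgroups: dict[tuple[int, int], tuple[float, np.ndarray]]
    mid_b_category: int
    n_a: int = 8
    n_b: int = 4

    def to_dict(self) -> dict:
        return {
            "kind": "anova",
            "version": 1,
            "a_breaks": self.a_breaks.tolist(),
            "b_breaks": {str(k): v.tolist() for k, v in self.b_breaks.items()},
            "subgroups": {
                f"{a},{b}": [mu, beta.tolist()] for (a, b), (mu, beta) in self.subgroups.items()
            },
            "mid_b_category": self.mid_b_category,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AnovaModel":
        subgroups = {}
        for key, (mu, beta) in d["subgroups"].items():
            a, b = (int(x) for x in key.split(","))
            subgroups[(a, b)] = (mu, np.asarray(beta))
        return cls(
            a_breaks=np.asarray(d["a_breaks"]),
            b_breaks={float(k): np.asarray(v) for k, v in d["b_breaks"].items()},
            subgroups=subgroups,
            mid_b_category=d["mid_b_category"],
        )


def _slowdown(cums: list[float], i20: int, i_last: int) -> float:
    """Scaled slow-down: (cumulative at last - cumulative at 20 km) / T20."""
    return (cums[i_last] - cums[i20]) / cums[i20]


def fit_anova(training: Cohort, layout: CourseLayout = DEFAULT_LAYOUT) -> AnovaModel:
    """Partition training runners into 32 subgroups and fit each two-way model.

    Variable (a), the half-way time, is operationalized as the cumulative
    20 km time; variable (b) is the 20-to-40 km time scaled by (a).
    (a) is cut at octiles, (b) at quartiles.  Quartile boundaries of the
    partial slow-down over each shorter stretch (20-25, 20-30, 20-35 km)
    are recorded too, so partially observed runners can be classified
    against the same population.
    """
    X = _complete_matrix(training, layout)
    n = len(X)
    if n < 32 * (layout.n_sections + 1):
        raise ValueError(f"training cohort of {n} too small for 32 subgroups")
    cums = np.cumsum(X, axis=1)
    i20 = layout.checkpoint_index(20.0)
    i40 = layout.checkpoint_index(40.0)
    a = cums[:, i20]
    b = (cums[:, i40] - cums[:, i20]) / cums[:, i20]
    a_breaks = np.quantile(a, np.arange(1, 8) / 8)
    b_breaks_full = np.quantile(b, np.arange(1, 4) / 4)
    b_breaks = {40.0: b_breaks_full}
    for km in (25.0, 30.0, 35.0):
        iL = layout.checkpoint_index(km)
        partial = (cums[:, iL] - cums[:, i20]) / cums[:, i20]
        b_breaks[km] = np.quantile(partial, np.arange(1, 4) / 4)
    ai = np.searchsorted(a_breaks, a, side="right")
    bi = np.searchsorted(b_breaks_full, b, side="right")
    subgroups: dict[tuple[int, int], tuple[float, np.ndarray]] = {}
    for gi in range(8):
        for gj in range(4):
            mask = (ai == gi) & (bi == gj)
            if not mask.any():
                raise ValueError(
                    f"empty ANOVA subgroup (octile {gi}, quartile {gj}); "
                    "use a larger training cohort"
                )
            subgroups[(gi, gj)] = fit_two_way_log_anova(X[mask])
    mid_b = int(np.searchsorted(b_breaks_full, np.median(b), side="right"))
    return AnovaModel(
        a_breaks=a_breaks, b_breaks=b_breaks, subgroups=subgroups, mid_b_category=mid_b
    )


def _assign_subgroup(
    record: RunnerRecord, model: AnovaModel, layout: CourseLayout
) -> tuple[int, int]:
    cums = record.cumulative_times()
    i20 = layout.checkpoint_index(20.0)
    if len(cums) <= i20:
        raise ValueError(
            f"runner {record.runner_id}: ANOVA subgrouping needs the 20 km checkpoint"
        )
    ai = int(np.searchsorted(model.a_breaks, cums[i20], side="right"))
    last_km = record.last_checkpoint_km(layout)
    observable = [km for km in model.b_breaks if km <= last_km]
    if not observable:
        # observed only to the half-way point: no slow-down information,
        # use the middle slow-down category
        return ai, model.mid_b_category
    km = max(observable)
    iL = layout.checkpoint_index(km)
    partial = _slowdown(cums, i20, iL)
    bi = int(np.searchsorted(model.b_breaks[km], partial, side="right"))
    return ai, bi


def predict_anova(
    record: RunnerRecord,
    model: AnovaModel,
    layout: CourseLayout = DEFAULT_LAYOUT,
) -> PredictionResult:
    """Impute missing sections multiplicatively from the subgroup effects.

    The runner effect alpha is estimated as the mean residual
    log t_j - mu - beta_j over observed sections; each missing section j is
    imputed as exp(mu + alpha + beta_j).
    """
    gi, gj = _assign_subgroup(record, model, layout)
    mu, beta = model.subgroups[(gi, gj)]
    m = len(record.section_times)
    obs = np.log(np.asarray(record.section_times, dtype=float))
    alpha = float(np.mean(obs - mu - beta[:m]))
    imputed = np.exp(mu + alpha + beta[m:])
    remaining = float(imputed.sum())
    cum = record.cumulative_times()[-1]
    return PredictionResult(
        runner_id=record.runner_id, method="anova", remaining_s=remaining, finish_s=cum + remaining
    )


# ---------------------------------------------------------------------------
# SVD matrix completion
# ---------------------------------------------------------------------------

@dataclass
class SvdModel:
    """Truncated SVD of the complete runner-by-section time matrix.

    Stores the top-k singular values and the section (right singular)
    vectors; runner vectors are solved per query via the pseudo-inverse.
    """

    singular_values: np.ndarray   # (k,), non-increasing, positive
    section_vectors: np.ndarray   # (n_sections, k), orthonormal columns
    n_train: int
    rank: int = field(init=False)

    def __post_init__(self) -> None:
        d = self.singular_values
        if np.any(d <= 0) or np.any(np.diff(d) > 0):
            raise ValueError("singular values must be positive and non-increasing")
        self.rank = len(d)

    def to_dict(self) -> dict:
        return {
            "kind": "svd",
            "version": 1,
            "singular_values": self.singular_values.tolist(),
            "section_vectors": self.section_vectors.tolist(),
            "n_train": self.n_train,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SvdModel":
        return cls(
            singular_values=np.asarray(d["singular_values"]),
            section_vectors=np.asarray(d["section_vectors"]),
            n_train=d["n_train"],
        )


def fit_svd(training: Cohort, k: int, layout: CourseLayout = DEFAULT_LAYOUT) -> SvdModel:
    """Rank-k truncated SVD of the raw (uncentered) section-time matrix."""
    X = _complete_matrix(training, layout)
    if not 1 <= k <= X.shape[1]:
        raise ValueError(f"rank {k} outside [1, {X.shape[1]}]")
    _, d, vt = np.linalg.svd(X, full_matrices=False)
    V = vt[:k].T
    # deterministic sign: each section vector summing non-negative
    signs = np.where(V.sum(axis=0) < 0, -1.0, 1.0)
    return SvdModel(singular_values=d[:k].copy(), section_vectors=V * signs, n_train=len(X))


def predict_svd(
    record: RunnerRecord,
    model: SvdModel,
    layout: CourseLayout = DEFAULT_LAYOUT,
) -> PredictionResult:
    """Complete a truncated record via the minimum-norm runner vector.

    The observed sections give an under-determined system
    x_obs = (V_obs diag(d)) u; its minimum-norm least-squares solution is
    obtained with the Moore-Penrose pseudo-inverse, and the missing
    sections are reconstructed as (V_mis diag(d)) u.
    """
    m = len(record.section_times)
    x_obs = np.asarray(record.section_times, dtype=float)
    Vd = model.section_vectors * model.singular_values  # broadcast over columns
    u = np.linalg.pinv(Vd[:m]) @ x_obs
    reconstructed_tail = Vd[m:] @ u
    remaining = float(reconstructed_tail.sum())
    cum = record.cumulative_times()[-1]
    return PredictionResult(
        runner_id=record.runner_id, method="svd", remaining_s=remaining, finish_s=cum + remaining
    )


def reconstruct_svd_row(record: RunnerRecord, model: SvdModel) -> np.ndarray:
    """Full-course reconstruction of a record's section times under the model."""
    m = len(record.section_times)
    Vd = model.section_vectors * model.singular_values
    u = np.linalg.pinv(Vd[:m]) @ np.asarray(record.section_times, dtype=float)
    return Vd @ u


def choose_svd_rank(
    training: Cohort,
    candidate_ranks=range(1, 7),
    folds: int = 5,
    seed: int = 0,
    layout: CourseLayout = DEFAULT_LAYOUT,
) -> int:
    """Pick the SVD rank by fold-wise masked-tail cross-validation.

    Each fold's held-out runners are truncated at a random dropout
    checkpoint; ranks are scored by mean squared error of the predicted
    remaining time, and the smallest rank attaining the minimum wins.
    """
    candidates = list(candidate_ranks)
    if len(candidates) == 1:
        return candidates[0]
    X = _complete_matrix(training, layout)
    n = len(X)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    dropout_idx = rng.integers(0, len(DROPOUT_POINTS), size=n)
    fold_of = np.empty(n, dtype=int)
    fold_of[perm] = np.arange(n) % folds
    records = list(training)
    scores: dict[int, float] = {k: 0.0 for k in candidates}
    for f in range(folds):
        train_mask = fold_of != f
        sub = Cohort([records[i] for i in np.nonzero(train_mask)[0]], provenance="cv")
        test_ids = np.nonzero(~train_mask)[0]
        for k in candidates:
            model = fit_svd(sub, k, layout)
            sq = 0.0
            for i in test_ids:
                km = DROPOUT_POINTS[dropout_idx[i]]
                keep = layout.checkpoint_index(km) + 1
                true_remaining = float(np.sum(X[i, keep:]))
                # raw reconstruction: a poor candidate rank may legitimately
                # project a negative remaining time and just scores badly
                Vd = model.section_vectors * model.singular_values
                u = np.linalg.pinv(Vd[:keep]) @ X[i, :keep]
                sq += (float((Vd[keep:] @ u).sum()) - true_remaining) ** 2
            scores[k] += sq / len(test_ids)
    best = min(candidates, key=lambda k: (scores[k], k))
    return best


# ---------------------------------------------------------------------------
# Model bundle serialization
# ---------------------------------------------------------------------------

_BUNDLE_KINDS = {
    "lm": RegressionModelSet,
    "anova": AnovaModel,
    "svd": SvdModel,
}


def save_model_bundle(models: dict[str, object], path) -> None:
    """Serialize fitted models to a versioned JSON bundle."""
    payload = {"bundle_version": 1, "models": {name: m.to_dict() for name, m in models.items()}}
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model_bundle(path) -> dict[str, object]:
    with open(path) as fh:
        payload = json.load(fh)
    out = {}
    for name, d in payload["models"].items():
        out[name] = _BUNDLE_KINDS[d["kind"]].from_dict(d)
    return out
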