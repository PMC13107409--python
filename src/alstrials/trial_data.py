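"""Longitudinal trial data model, CSV I/O, and per-patient outcome summaries.

The exchange object is :class:`TrialDataset`: one row of follow-up per patient
on a fixed visit schedule, with the ALSFRS-R total score (0-48, lower = more
disabled) recorded at each attended visit, plus a death time and/or a non-death
dropout time in weeks from randomization.  Death and dropout are competing:
whichever comes first truncates follow-up and the other is absent.

All times are in weeks.  Slopes are points/week throughout the library and are
converted to points/month only at the reporting layer.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

SCORE_MIN = 0.0
SCORE_MAX = 48.0

ARM_PLACEBO = "placebo"
ARM_ACTIVE = "active"

CSV_COLUMNS = [
    "patient_id",
    "arm",
    "time_weeks",
    "alsfrs_r",
    "death_time_weeks",
    "dropout_time_weeks",
]


class ValidationError(ValueError):
    """A dataset or record violates a structural invariant."""


@dataclass(frozen=True)
class VisitSchedule:
    """Scheduled assessment times in weeks from randomization.

    Times must be strictly increasing and start at 0 (baseline).
    """

    times: tuple[float, ...]

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.times)
        object.__setattr__(self, "times", times)
        if len(times) < 1 or times[0] != 0.0:
            raise ValidationError("schedule must start at week 0 (baseline)")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValidationError("schedule times must be strictly increasing")
        if any(t < 0 for t in times):
            raise ValidationError("schedule times must be non-negative")

    @property
    def horizon(self) -> float:
        return self.times[-1]

    @property
    def post_baseline(self) -> tuple[float, ...]:
        return self.times[1:]

    def __len__(self) -> int:
        return len(self.times)

    def index_of(self, time: float) -> int:
        try:
            return self.times.index(float(time))
        except ValueError:
            raise ValidationError(f"time {time} is not a scheduled visit") from None


@dataclass(frozen=True)
class Observation:
    """One scheduled assessment; ``observed=False`` marks a missed visit.

    ``imputed`` marks scores filled in by a missing-data strategy; such
    values may legitimately sit beyond the death/dropout truncation time.
    """

    patient_id: str
    time: float
    score: float | None
    observed: bool
    imputed: bool = False

    def __post_init__(self) -> None:
        if self.observed:
            if self.score is None or not (SCORE_MIN <= self.score <= SCORE_MAX):
                raise ValidationError(
                    f"patient {self.patient_id} week {self.time}: score "
                    f"{self.score} outside [{SCORE_MIN:g}, {SCORE_MAX:g}]"
                )


@dataclass
class PatientCourse:
    """All follow-up for one patient.

    ``death_time`` and ``dropout_time`` are mutually exclusive (the earlier
    event truncates follow-up; the other is cleared).
    """

    patient_id: str
    arm: str
    baseline_score: float
    observations: list[Observation]
    death_time: float | None = None
    dropout_time: float | None = None

    def __post_init__(self) -> None:
        if self.arm not in (ARM_PLACEBO, ARM_ACTIVE):
            raise ValidationError(
                f"patient {self.patient_id}: arm must be "
                f"'{ARM_PLACEBO}' or '{ARM_ACTIVE}', got {self.arm!r}"
            )
        for t in (self.death_time, self.dropout_time):
            if t is not None and t <= 0:
                raise ValidationError(
                    f"patient {self.patient_id}: event times must be > 0"
                )
        if self.death_time is not None and self.dropout_time is not None:
            raise ValidationError(
                f"patient {self.patient_id}: death and dropout are competing; "
                "only the earlier may be recorded"
            )
        trunc = self.truncation_time
        seen: set[float] = set()
        for obs in self.observations:
            if obs.time in seen:
                raise ValidationError(
                    f"patient {self.patient_id}: duplicate visit {obs.time}"
                )
            seen.add(obs.time)
            if obs.observed and not obs.imputed and trunc is not None and obs.time > trunc:
                raise ValidationError(
                    f"patient {self.patient_id}: observation at week {obs.time} "
                    f"after truncation at week {trunc}"
                )
        base = self.observation_at(0.0)
        if base is None or not base.observed:
            raise ValidationError(
                f"patient {self.patient_id}: baseline visit must be observed"
            )
        if base.score != self.baseline_score:
            raise ValidationError(
                f"patient {self.patient_id}: baseline_score "
                f"{self.baseline_score} != week-0 score {base.score}"
            )

    @property
    def truncation_time(self) -> float | None:
        if self.death_time is not None:
            return self.death_time
        return self.dropout_time

    def observation_at(self, time: float) -> Observation | None:
        for obs in self.observations:
            if obs.time == time:
                return obs
        return None

    def observed_points(self) -> tuple[np.ndarray, np.ndarray]:
        """(times, scores) of attended visits, in schedule order."""
        pts = [(o.time, o.score) for o in self.observations if o.observed]
        pts.sort()
        if not pts:
            return np.empty(0), np.empty(0)
        t, y = zip(*pts)
        return np.asarray(t, dtype=float), np.asarray(y, dtype=float)

    @property
    def last_observed_time(self) -> float:
        t, _ = self.observed_points()
        return float(t[-1]) if t.size else 0.0


@dataclass
class TrialDataset:
    """A complete trial: schedule, per-patient courses, and provenance."""

    schedule: VisitSchedule
    patients: list[PatientCourse]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            raise ValidationError("patient_id values must be unique")
        sched = set(self.schedule.times)
        for p in self.patients:
            for obs in p.observations:
                if obs.time not in sched:
                    raise ValidationError(
                        f"patient {p.patient_id}: visit {obs.time} not in schedule"
                    )

    @property
    def n(self) -> int:
        return len(self.patients)

    def arm_sizes(self) -> dict[str, int]:
        sizes = {ARM_PLACEBO: 0, ARM_ACTIVE: 0}
        for p in self.patients:
            sizes[p.arm] += 1
        return sizes

    def require_both_arms(self) -> None:
        sizes = self.arm_sizes()
        if min(sizes.values()) == 0:
            raise ValidationError("both arms must be non-empty for analysis")

    # -- array views ------------------------------------------------------

    def score_matrix(self) -> np.ndarray:
        """(n_patients, n_visits) scores with NaN at missed visits."""
        k = len(self.schedule)
        idx = {t: j for j, t in enumerate(self.schedule.times)}
        out = np.full((self.n, k), np.nan)
        for i, p in enumerate(self.patients):
            for obs in p.observations:
                if obs.observed:
                    out[i, idx[obs.time]] = obs.score
        return out

    def arm_indicator(self) -> np.ndarray:
        """1.0 for active, 0.0 for placebo, per patient."""
        return np.array([1.0 if p.arm == ARM_ACTIVE else 0.0 for p in self.patients])

    def death_times(self) -> np.ndarray:
        return np.array(
            [np.nan if p.death_time is None else p.death_time for p in self.patients]
        )

    def dropout_times(self) -> np.ndarray:
        return np.array(
            [np.nan if p.dropout_time is None else p.dropout_time for p in self.patients]
        )

    def baseline_scores(self) -> np.ndarray:
        return np.array([p.baseline_score for p in self.patients])

    def with_arms(self, arms: Sequence[str]) -> "TrialDataset":
        """A copy of the dataset with reassigned arm labels (same order)."""
        if len(arms) != self.n:
            raise ValidationError("arm vector length must equal patient count")
        patients = [
            PatientCourse(
                patient_id=p.patient_id,
                arm=a,
                baseline_score=p.baseline_score,
                observations=p.observations,
                death_time=p.death_time,
                dropout_time=p.dropout_time,
            )
            for p, a in zip(self.patients, arms)
        ]
        return TrialDataset(schedule=self.schedule, patients=patients, meta=dict(self.meta))


@dataclass(frozen=True)
class DerivedSummary:
    """One per-patient outcome value produced by a summarization.

    ``event_indicator`` is present only for time-to-event summaries.
    """

    patient_id: str
    arm: str
    value: float
    missing: bool
    event_indicator: bool | None = None


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------


def write_dataset(ds: TrialDataset, path: str | Path) -> None:
    """Write long-format CSV (one row per patient x scheduled visit) plus a
    JSON metadata sidecar at ``<path>.meta.json``."""
    path = Path(path)
    rows = []
    for p in ds.patients:
        by_time = {o.time: o for o in p.observations}
        for t in ds.schedule.times:
            obs = by_time.get(t)
            score = obs.score if obs is not None and obs.observed else None
            rows.append(
                {
                    "patient_id": p.patient_id,
                    "arm": p.arm,
                    "time_weeks": t,
                    "alsfrs_r": score,
                    "death_time_weeks": p.death_time,
                    "dropout_time_weeks": p.dropout_time,
                }
            )
    frame = pd.DataFrame(rows, columns=CSV_COLUMNS)
    frame.to_csv(path, index=False, float_format="%g")
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    with open(sidecar, "w", encoding="utf-8") as fh:
        json.dump(_jsonable(ds.meta), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_dataset(path: str | Path) -> TrialDataset:
    """Read a long-format trial CSV written by :func:`write_dataset`.

    Rows with an empty score become missed visits (``observed=False``).
    """
    path = Path(path)
    meta: dict = {}
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    if sidecar.exists():
        with open(sidecar, encoding="utf-8") as fh:
            meta = json.load(fh)
    return dataset_from_frame(pd.read_csv(path), meta=meta)


def dataset_from_frame(frame: pd.DataFrame, meta: dict | None = None) -> TrialDataset:
    """Build a validated :class:`TrialDataset` from a long-format table with
    the standard columns (one row per patient per scheduled visit)."""
    missing_cols = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing_cols:
        raise ValidationError(f"missing columns: {missing_cols}")

    times = sorted(frame["time_weeks"].unique())
    schedule = VisitSchedule(tuple(times))
    patients: list[PatientCourse] = []
    for pid, grp in frame.groupby("patient_id", sort=False):
        arms = grp["arm"].unique()
        if len(arms) != 1:
            raise ValidationError(f"patient {pid}: conflicting arm labels {arms}")
        death = _opt_float(grp["death_time_weeks"].iloc[0])
        dropout = _opt_float(grp["dropout_time_weeks"].iloc[0])
        observations = []
        seen: set[float] = set()
        for row_i, row in grp.iterrows():
            t = float(row["time_weeks"])
            if t in seen:
                raise ValidationError(
                    f"row {row_i}: duplicate visit week {t} for patient {pid}"
                )
            seen.add(t)
            score = _opt_float(row["alsfrs_r"])
            if score is not None and not (SCORE_MIN <= score <= SCORE_MAX):
                raise ValidationError(
                    f"row {row_i}: score {score} outside "
                    f"[{SCORE_MIN:g}, {SCORE_MAX:g}] for patient {pid}"
                )
            observations.append(
                Observation(
                    patient_id=str(pid),
                    time=t,
                    score=score,
                    observed=score is not None,
                )
            )
        baseline = next((o.score for o in observations if o.time == 0.0 and o.observed), None)
        if baseline is None:
            raise ValidationError(f"patient {pid}: no observed baseline score")
        patients.append(
            PatientCourse(
                patient_id=str(pid),
                arm=str(arms[0]),
                baseline_score=baseline,
                observations=observations,
                death_time=death,
                dropout_time=dropout,
            )
        )

    return TrialDataset(schedule=schedule, patients=patients, meta=dict(meta or {}))


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str) and value.strip() == "":
        return None
    return float(value)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


# ---------------------------------------------------------------------------
# Per-patient outcome summaries
# ---------------------------------------------------------------------------


def change_from_baseline(ds: TrialDataset, visit: float) -> list[DerivedSummary]:
    """Score at ``visit`` minus baseline; negative values mean decline.

    Patients without an observed score at the visit (death, dropout, or missed
    assessment) are flagged ``missing=True``; the missing-data strategy decides
    what to do with them downstream.
    """
    ds.schedule.index_of(visit)
    out = []
    for p in ds.patients:
        obs = p.observation_at(visit)
        if obs is not None and obs.observed:
            out.append(
                DerivedSummary(p.patient_id, p.arm, obs.score - p.baseline_score, False)
            )
        else:
            out.append(DerivedSummary(p.patient_id, p.arm, np.nan, True))
    return out


def per_patient_slope(ds: TrialDataset) -> list[DerivedSummary]:
    """Ordinary least-squares slope (points/week) of each patient's observed
    scores on time; patients with fewer than two attended visits are missing."""
    out = []
    for p in ds.patients:
        t, y = p.observed_points()
        if t.size < 2:
            out.append(DerivedSummary(p.patient_id, p.arm, np.nan, True))
            continue
        tc = t - t.mean()
        slope = float(tc @ y / (tc @ tc))
        out.append(DerivedSummary(p.patient_id, p.arm, slope, False))
    return out


def responder_flags(
    ds: TrialDataset, decline_threshold: float, visit: float
) -> list[DerivedSummary]:
    """Responder (1) = declined by less than ``decline_threshold`` points at
    ``visit``; non-responder (0) otherwise; missingness propagated."""
    if decline_threshold <= 0:
        raise ValidationError("decline_threshold must be > 0")
    out = []
    for summ in change_from_baseline(ds, visit):
        if summ.missing:
            out.append(summ)
        else:
            flag = 1.0 if -summ.value < decline_threshold else 0.0
            out.append(DerivedSummary(summ.patient_id, summ.arm, flag, False))
    return out


def event_times_decline_or_death(
    ds: TrialDataset, decline_threshold: float = 6.0
) -> list[DerivedSummary]:
    """Composite time to confirmed functional decline or death.

    The event time is the earlier of (a) the first scheduled visit at which the
    score has dropped by at least ``decline_threshold`` points from baseline
    and (b) death.  Patients with neither are censored at last contact: the
    later of the last attended visit and any recorded dropout time.  A decline
    crossing is dated at the visit where it is first observed (no
    interpolation between visits).
    """
    if decline_threshold <= 0:
        raise ValidationError("decline_threshold must be > 0")
    out = []
    for p in ds.patients:
        t, y = p.observed_points()
        crossing = None
        for ti, yi in zip(t, y):
            if p.baseline_score - yi >= decline_threshold:
                crossing = float(ti)
                break
        candidates = [c for c in (crossing, p.death_time) if c is not None]
        if candidates:
            out.append(
                DerivedSummary(p.patient_id, p.arm, min(candidates), False, True)
            )
        else:
            censor = p.last_observed_time
            if p.dropout_time is not None:
                censor = max(censor, p.dropout_time)
            out.append(DerivedSummary(p.patient_id, p.arm, censor, False, False))
    return out


POINTS_PER_MONTH = 4.345  # weeks per month; reporting-layer conversion factor


def slope_to_monthly(points_per_week: float) -> float:
    """Convert a slope from points/week to points/month (reporting only)."""
    return points_per_week * POINTS_PER_MONTH
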