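"""Two-visit longitudinal tables -> coupled nonnegative delta matrices.

Brain regions shrink with neurodegeneration (ventricles, filling with CSF,
grow instead), and severity-oriented task scores rise.  Change that runs
against a feature's deterioration direction is treated as measurement or
treatment artifact and clipped to zero, so every retained delta is a
nonnegative amount of deterioration.  Columns are then min-max normalized
to [0, 1] so regions measured in mm^3 and task scores on small integer
scales become commensurate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import DeltaMatrix

logger = logging.getLogger(__name__)

LOSS_IS_SIGNAL = "loss_is_signal"
GAIN_IS_SIGNAL = "gain_is_signal"


@dataclass
class FeatureDirectionMap:
    """feature name -> which direction of change counts as deterioration.

    ``loss_is_signal``: a decrease is the signal (most brain regions; MMSE
    items where higher scores mean better function).  ``gain_is_signal``: an
    increase is the signal (ventricular regions; ADAS-Cog and FAQ where
    higher scores mean worse function).
    """

    orientations: dict[str, str]
    modality: str = "region"

    def __post_init__(self) -> None:
        for feat, o in self.orientations.items():
            if o not in (LOSS_IS_SIGNAL, GAIN_IS_SIGNAL):
                raise ValueError(f"unknown orientation {o!r} for feature {feat!r}")

    def orientation(self, feature: str) -> str:
        try:
            return self.orientations[feature]
        except KeyError:
            raise KeyError(
                f"feature {feature!r} has no entry in the direction map"
            ) from None

    @classmethod
    def from_frame(cls, df: pd.DataFrame, modality: str = "region") -> "FeatureDirectionMap":
        return cls(dict(zip(df["feature"].astype(str), df["orientation"])), modality)


def default_npt_directions() -> FeatureDirectionMap:
    """Severity orientation for the standard 50-subtask battery.

    ADAS-Cog (13 items) and FAQ (10 items) score impairment, so an increase
    is deterioration (gain_is_signal); MMSE items (27) score intact
    function, so a decrease is deterioration (loss_is_signal).
    """
    d = {f"ADAS_Q{i}": GAIN_IS_SIGNAL for i in range(1, 14)}
    d.update({f"FAQ_{i}": GAIN_IS_SIGNAL for i in range(1, 11)})
    d.update({f"MMSE_{i}": LOSS_IS_SIGNAL for i in range(1, 28)})
    return FeatureDirectionMap(d, "task")


@dataclass
class PrepLog:
    """Subjects dropped during preparation, with reasons."""

    dropped: dict[str, str] = field(default_factory=dict)

    def drop(self, subject: str, reason: str) -> None:
        self.dropped[subject] = reason
        logger.info("dropping subject %s: %s", subject, reason)


def forward_fill_tasks(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Carry the last observed task value forward within each subject.

    ``records`` has columns ``subject_id, date`` plus one column per task,
    sorted by date within subject.  A value missing at time t is replaced by
    the most recent earlier observation of the same subject and task; values
    with no earlier observation stay missing and are flagged.

    Returns ``(completed, still_missing_flags)`` where the flag frame is a
    boolean mask of the same shape as the task columns.
    """
    task_cols = [c for c in records.columns if c not in ("subject_id", "date")]
    out = records.copy()
    out[task_cols] = (
        records.groupby("subject_id", sort=False)[task_cols].ffill()
    )
    flags = out[task_cols].isna()
    return out, flags


def align_visits(
    imaging_dates: pd.DataFrame,
    task_dates: pd.DataFrame,
    log: PrepLog | None = None,
) -> pd.DataFrame:
    """Pair each imaging visit with the nearest-in-time task assessment.

    ``imaging_dates``: columns ``subject_id, visit, date``.
    ``task_dates``: columns ``subject_id, date`` (one row per assessment).
    Ties in absolute day difference go to the earlier assessment.  Subjects
    with no task assessment are excluded and logged.

    Returns a frame ``subject_id, visit, imaging_date, task_date, day_diff``.
    """
    log = log or PrepLog()
    tasks_by_subject = {
        s: g["date"].sort_values().to_numpy()
        for s, g in task_dates.groupby("subject_id", sort=False)
    }
    rows = []
    for rec in imaging_dates.itertuples(index=False):
        cand = tasks_by_subject.get(rec.subject_id)
        if cand is None or len(cand) == 0:
            log.drop(str(rec.subject_id), "no task assessments")
            continue
        img = np.datetime64(rec.date)
        diffs = np.abs((cand - img) / np.timedelta64(1, "D")).astype(float)
        best = np.min(diffs)
        # earliest date among ties (candidates are date-sorted)
        pick = int(np.argmax(diffs == best))
        rows.append(
            {
                "subject_id": rec.subject_id,
                "visit": rec.visit,
                "imaging_date": rec.date,
                "task_date": cand[pick],
                "day_diff": float(best),
            }
        )
    return pd.DataFrame(rows)


def compute_delta(
    visit1: pd.DataFrame,
    visit2: pd.DataFrame,
    directions: FeatureDirectionMap,
    log: PrepLog | None = None,
) -> DeltaMatrix:
    """Direction-clipped two-visit change, one row per retained subject.

    Each visit table has ``subject_id`` plus one column per feature.  For
    ``loss_is_signal`` features the delta is ``max(0, v1 - v2)``; for
    ``gain_is_signal`` features it is ``max(0, v2 - v1)``.  Subjects missing
    either visit, or any feature value at either visit, are dropped with a
    logged reason (imaging values are never forward-filled).
    """
    log = log or PrepLog()
    features = [c for c in visit1.columns if c != "subject_id"]
    if [c for c in visit2.columns if c != "subject_id"] != features:
        raise ValueError("visit tables have different feature columns")
    for feat in features:
        directions.orientation(feat)  # hard error naming a missing feature

    v1 = visit1.set_index("subject_id")
    v2 = visit2.set_index("subject_id")
    kept: list[str] = []
    for sid in v1.index:
        if sid not in v2.index:
            log.drop(str(sid), "missing second visit")
        elif v1.loc[sid, features].isna().any() or v2.loc[sid, features].isna().any():
            log.drop(str(sid), "missing feature value at a visit")
        else:
            kept.append(sid)
    for sid in v2.index:
        if sid not in v1.index:
            log.drop(str(sid), "missing first visit")

    a = v1.loc[kept, features].to_numpy(dtype=float)
    b = v2.loc[kept, features].to_numpy(dtype=float)
    sign = np.array(
        [1.0 if directions.orientation(f) == LOSS_IS_SIGNAL else -1.0 for f in features]
    )
    delta = np.maximum(0.0, (a - b) * sign)
    return DeltaMatrix(delta, [str(s) for s in kept], features, directions.modality)


def minmax_normalize(matrix: DeltaMatrix) -> DeltaMatrix:
    """Rescale each column to [0, 1] by its own min and max across subjects.

    Constant columns (zero range) map to all-zeros: a feature with no
    variation carries no phenotype signal.  Per-column (min, max) before
    rescaling is retained on the result for reporting.
    """
    v = matrix.values
    lo = v.min(axis=0)
    hi = v.max(axis=0)
    rng = hi - lo
    safe = np.where(rng > 0, rng, 1.0)
    out = np.where(rng > 0, (v - lo) / safe, 0.0)
    stats = {
        name: (float(lo[j]), float(hi[j]))
        for j, name in enumerate(matrix.feature_names)
    }
    return DeltaMatrix(
        out, matrix.subject_ids, matrix.feature_names, matrix.modality, stats
    )


def prepare_modality(
    visit1: pd.DataFrame,
    visit2: pd.DataFrame,
    directions: FeatureDirectionMap,
    normalize: bool = True,
    log: PrepLog | None = None,
) -> DeltaMatrix:
    """compute_delta followed by min-max normalization (the full prep step)."""
    delta = compute_delta(visit1, visit2, directions, log=log)
    return minmax_normalize(delta) if normalize else delta
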