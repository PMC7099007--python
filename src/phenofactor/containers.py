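"""Shared in-memory containers for coupled-matrix phenotyping.

Two subject-aligned modalities are carried through the pipeline as
:class:`DeltaMatrix` objects (nonnegative two-visit change, one per
modality) together with a :class:`CohortTable` of diagnostic labels and
demographic covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Diagnostic stages, in severity order.
STAGES = ("AD", "MCI", "CN")

#: Demographic covariates entering the supervised heads, in column order.
DEMO_COLUMNS = ("interval_years", "sex", "age")


@dataclass
class DeltaMatrix:
    """A subjects x features matrix of nonnegative longitudinal change.

    Parameters
    ----------
    values
        Dense ``(n_subjects, n_features)`` array; every entry is a
        nonnegative "amount of deterioration" (volume loss in the region
        modality, severity increase in the task modality).
    subject_ids
        Row labels, one per subject, unique.
    feature_names
        Column labels, one per feature, unique.
    modality
        ``"region"`` or ``"task"``.
    column_stats
        Optional per-column ``(min, max)`` recorded by min-max
        normalization, for reporting and round-tripping.
    """

    values: np.ndarray
    subject_ids: list[str]
    feature_names: list[str]
    modality: str = "region"
    column_stats: dict[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.subject_ids = [str(s) for s in self.subject_ids]
        self.feature_names = [str(f) for f in self.feature_names]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        n, p = self.values.shape
        if n != len(self.subject_ids) or p != len(self.feature_names):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.subject_ids)} subjects x {len(self.feature_names)} features"
            )
        if len(set(self.subject_ids)) != n:
            raise ValueError("duplicate subject ids")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.subject_ids, name="subject_id"),
            columns=self.feature_names,
        )


@dataclass
class CohortTable:
    """Per-subject diagnostic label and demographics.

    ``table`` holds columns ``subject_id, label, interval_years, sex, age``
    with ``label`` in {AD, MCI, CN}.  ``train_mask``, when set, marks the
    subjects used to train the supervised regularizer (the held-out
    complement is the evaluation set).
    """

    table: pd.DataFrame
    train_mask: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        required = ["subject_id", "label"] + list(DEMO_COLUMNS)
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValueError(f"cohort table missing columns: {missing}")
        bad = set(self.table["label"]) - set(STAGES)
        if bad:
            raise ValueError(f"unknown diagnostic labels: {sorted(bad)}")
        if self.table["subject_id"].duplicated().any():
            dup = self.table.loc[self.table["subject_id"].duplicated(), "subject_id"]
            raise ValueError(f"duplicate subject ids in cohort: {list(dup)[:5]}")
        self.table = self.table.reset_index(drop=True)
        if self.train_mask is not None:
            self.train_mask = np.asarray(self.train_mask, dtype=bool)
            if self.train_mask.shape != (len(self.table),):
                raise ValueError("train_mask length does not match cohort size")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def subject_ids(self) -> list[str]:
        return [str(s) for s in self.table["subject_id"]]

    @property
    def labels(self) -> np.ndarray:
        return self.table["label"].to_numpy()

    @property
    def demographics(self) -> np.ndarray:
        """(n, 3) array of interval, sex, age."""
        return self.table[list(DEMO_COLUMNS)].to_numpy(dtype=float)

    def aligned_to(self, subject_ids: list[str]) -> "CohortTable":
        """Reorder rows to match ``subject_ids`` (hard error on mismatch)."""
        idx = self.table.set_index("subject_id")
        missing = [s for s in subject_ids if s not in idx.index]
        if missing:
            raise ValueError(f"cohort lacks subjects: {missing[:5]}")
        out = idx.loc[subject_ids].reset_index()
        mask = None
        if self.train_mask is not None:
            pos = {s: i for i, s in enumerate(self.table["subject_id"])}
            mask = self.train_mask[[pos[s] for s in subject_ids]]
        return CohortTable(out, mask)


def check_row_alignment(m: DeltaMatrix, x: DeltaMatrix) -> None:
    """Assert that row i of both modalities is the same subject, by id."""
    if m.subject_ids != x.subject_ids:
        raise ValueError("M and X rows are not aligned by subject id")
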