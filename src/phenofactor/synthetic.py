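"""Synthetic coupled cohorts with planted nonnegative factor structure.

The generator emulates the shape of a two-visit neurodegeneration study at
desk scale: a subjects x regions volume-loss matrix M and a subjects x tasks
severity-increase matrix X that share a low-rank nonnegative subject
membership factor V, with AD/MCI/CN labels made separable in membership
space by group-dependent mean shifts, plus demographics.  The planted
factors are retained so fits can be scored for recovery.

Factor entries are absolute Gaussians (any nonnegative generator would do;
this one is fixed for reproducibility).  Noise is added to the products
before clipping at zero and before normalization, mirroring the
measure-then-clip order of real delta matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import DeltaMatrix, CohortTable, STAGES
from .delta_prep import minmax_normalize


@dataclass
class SyntheticConfig:
    """Conditions of a synthetic cohort.

    ``label_separation`` scales group-dependent mean shifts applied to
    designated phenotype axes of V (axis r is boosted for group r mod 3), so
    labels become linearly separable in membership space as it grows.
    ``factor_sparsity`` is the fraction of entries zeroed per row of the
    region/task factors.
    """

    n_subjects: int = 300
    n_regions: int = 40
    n_tasks: int = 25
    r_true: int = 4
    group_proportions: tuple[float, float, float] = (0.3, 0.4, 0.3)  # AD, MCI, CN
    factor_sparsity: float = 0.3
    noise_sd: float = 0.05
    label_separation: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_subjects, self.n_regions, self.n_tasks, self.r_true) <= 0:
            raise ValueError("all dimensions must be positive")
        if not np.isclose(sum(self.group_proportions), 1.0):
            raise ValueError("group_proportions must sum to 1")
        if any(p <= 0 for p in self.group_proportions):
            raise ValueError("group_proportions must be positive")
        if not (0 <= self.factor_sparsity < 1):
            raise ValueError("factor_sparsity must be in [0, 1)")
        if self.noise_sd < 0 or self.label_separation < 0:
            raise ValueError("noise_sd and label_separation must be >= 0")


@dataclass
class SyntheticTruth:
    """Planted factors and generation parameters, kept for recovery scoring."""

    v_true: np.ndarray
    y_true: np.ndarray
    w_true: np.ndarray
    labels: np.ndarray
    demographics: pd.DataFrame
    config: SyntheticConfig = field(repr=False)


def _nonneg_factor(rng: np.random.Generator, rows: int, cols: int, sparsity: float) -> np.ndarray:
    f = np.abs(rng.normal(size=(rows, cols)))
    if sparsity > 0:
        n_zero = int(round(sparsity * cols))
        for r in range(rows):
            f[r, rng.choice(cols, size=n_zero, replace=False)] = 0.0
    return f


def generate(
    config: SyntheticConfig, normalize: bool = True
) -> tuple[DeltaMatrix, DeltaMatrix, CohortTable, SyntheticTruth]:
    """Draw one synthetic cohort.

    Returns ``(M, X, cohort, truth)``.  With ``noise_sd=0``,
    ``factor_sparsity=0`` and ``normalize=False``, ``M.values`` equals
    ``truth.v_true @ truth.y_true`` exactly (and likewise X with W); the
    noiseless products are scaled into [0, 1] at generation time so the
    un-normalized path still satisfies downstream range contracts.  The same
    seed gives bitwise-identical output; independent sub-streams per block
    keep added fields from shifting existing ones.
    """
    c = config
    root = np.random.default_rng(c.seed)
    # independent sub-streams so each block is stable under extension
    rng_lab, rng_v, rng_y, rng_w, rng_noise, rng_demo = (
        np.random.default_rng(s) for s in root.integers(0, 2**31 - 1, size=6)
    )

    counts = np.floor(np.asarray(c.group_proportions) * c.n_subjects).astype(int)
    counts[0] += c.n_subjects - counts.sum()
    labels = np.repeat(STAGES, counts)
    rng_lab.shuffle(labels)

    v = np.abs(rng_v.normal(size=(c.n_subjects, c.r_true)))
    # group-dependent mean shifts on designated axes: axis r favors group r mod 3
    for r in range(c.r_true):
        group = STAGES[r % len(STAGES)]
        v[labels == group, r] += c.label_separation
    y = _nonneg_factor(rng_y, c.r_true, c.n_regions, c.factor_sparsity)
    w = _nonneg_factor(rng_w, c.r_true, c.n_tasks, c.factor_sparsity)

    # scale the planted region/task factors so noiseless products lie in [0,1]
    y /= max((v @ y).max(), 1e-12)
    w /= max((v @ w).max(), 1e-12)

    m_vals = v @ y + rng_noise.normal(scale=c.noise_sd, size=(c.n_subjects, c.n_regions))
    x_vals = v @ w + rng_noise.normal(scale=c.noise_sd, size=(c.n_subjects, c.n_tasks))
    m_vals = np.maximum(0.0, m_vals)
    x_vals = np.maximum(0.0, x_vals)

    ids = [f"S{i:04d}" for i in range(c.n_subjects)]
    regions = [f"region_{j:03d}" for j in range(c.n_regions)]
    tasks = [f"task_{j:03d}" for j in range(c.n_tasks)]
    m = DeltaMatrix(m_vals, ids, regions, "region")
    x = DeltaMatrix(x_vals, ids, tasks, "task")
    if normalize:
        m = minmax_normalize(m)
        x = minmax_normalize(x)

    demo = pd.DataFrame(
        {
            "subject_id": ids,
            "label": labels,
            "interval_years": rng_demo.gamma(shape=4.0, scale=0.5, size=c.n_subjects),
            "sex": rng_demo.integers(0, 2, size=c.n_subjects).astype(float),
            "age": rng_demo.normal(73.0, 7.0, size=c.n_subjects),
        }
    )
    cohort = CohortTable(demo)
    truth = SyntheticTruth(v, y, w, labels, demo, c)
    return m, x, cohort, truth
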