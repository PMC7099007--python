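"""Discriminability and compactness metrics, and the variant comparison harness.

Discriminability is held-out AUC of the linear heads for the four stage
contrasts (AD vs MCI, MCI vs CN, AD vs CN, AD+MCI vs CN).  Compactness is
(i) sparsity — the mean Gini sparsity index of each phenotype's involvement
vector, 0 for uniform involvement and -> 1 for one dominant feature — and
(ii) overlap — the mean pairwise cosine similarity between phenotype
vectors, lower meaning more distinct phenotypes.  Reconstruction fidelity
is the per-entry mean squared error of VY against M and VW against X.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import DeltaMatrix, CohortTable
from .cnmf import (
    FactorModel, FitConfig, SvmHead, VARIANTS, fit, pair_masks, stratified_split,
)

#: The four reported contrasts; the first group codes positive.
AUC_PAIRS = (("AD", "MCI"), ("MCI", "CN"), ("AD", "CN"), ("AD+MCI", "CN"))

METRIC_COLUMNS = (
    "auc_AD_vs_MCI", "auc_MCI_vs_CN", "auc_AD_vs_CN", "auc_ADMCI_vs_CN",
    "sparsity", "overlap", "mse_M", "mse_X",
)


def auc_pair(v_test: np.ndarray, demo_test: np.ndarray, labels_test: np.ndarray,
             head: SvmHead) -> float:
    """AUC of the head's decision values by the rank statistic (ties 1/2).

    Returns NaN when the test set contains a single class.
    """
    labels_test = np.asarray(labels_test)
    pos = labels_test == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    scores = head.decision(v_test, demo_test)
    ranks = rankdata(scores)  # average ranks count ties as 1/2
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def gini_sparsity(model: FactorModel) -> float:
    """Mean Gini sparsity of phenotype involvement vectors (rows of Y and W).

    For an ascending-sorted nonnegative vector v with total s > 0,
    G = 1 - 2 * sum_k (v_(k)/s) * ((n - k + 1/2)/n): 0 for a uniform vector,
    (n-1)/n for a one-hot vector.  All-zero rows score 1 by convention.
    """
    rows = [row for mat in (model.y, model.w) for row in mat]
    return float(np.mean([gini_index(row) for row in rows]))


def gini_index(values: np.ndarray) -> float:
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    s = v.sum()
    if s <= 0:
        return 1.0
    k = np.arange(1, n + 1)
    return float(1.0 - 2.0 * np.sum((v / s) * ((n - k + 0.5) / n)))


def overlap(y: np.ndarray, w: np.ndarray, vectors: str = "phenotype") -> float:
    """Mean pairwise cosine similarity between phenotype vectors.

    Computed within Y and within W over all unordered phenotype pairs (rows),
    then the two per-matrix averages are averaged.  All-zero vectors
    contribute similarity 0.  NaN when fewer than two phenotypes.
    ``vectors="feature"`` gives the alternative reading that compares
    feature (region/task) columns instead of phenotype rows.
    """
    if vectors == "feature":
        y, w = y.T, w.T
    elif vectors != "phenotype":
        raise ValueError("vectors must be 'phenotype' or 'feature'")
    if y.shape[0] < 2:
        return float("nan")
    return float(np.mean([_mean_pairwise_cosine(y), _mean_pairwise_cosine(w)]))


def _mean_pairwise_cosine(mat: np.ndarray) -> float:
    norms = np.linalg.norm(mat, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    unit = mat / safe[:, None]
    gram = unit @ unit.T
    iu = np.triu_indices(mat.shape[0], k=1)
    return float(gram[iu].mean())


def reconstruction_mse(m: np.ndarray, x: np.ndarray,
                       model: FactorModel) -> tuple[float, float]:
    """Per-entry mean squared reconstruction error for each modality."""
    mse_m = float(np.mean((m - model.v @ model.y) ** 2))
    mse_x = float(np.mean((x - model.v @ model.w) ** 2))
    return mse_m, mse_x


def evaluate_fit(m: np.ndarray, x: np.ndarray, result, cohort: CohortTable) -> dict:
    """All eight metrics for one fitted model on its held-out subjects."""
    labels = cohort.labels
    demo = cohort.demographics
    test = ~result.train_mask
    out: dict[str, float] = {}
    for pair, col in zip(AUC_PAIRS, METRIC_COLUMNS[:4]):
        head = result.heads.get(pair)
        if head is None:
            out[col] = float("nan")
            continue
        if pair == ("AD+MCI", "CN"):
            sel = test
            pm = np.where(labels[sel] != "CN", 1, -1)
        else:
            in_pair, _ = pair_masks(labels, pair)
            sel = in_pair & test
            pm = np.where(labels[sel] == pair[0], 1, -1)
        out[col] = auc_pair(result.model.v[sel], demo[sel], pm, head)
    out["sparsity"] = gini_sparsity(result.model)
    out["overlap"] = overlap(result.model.y, result.model.w)
    out["mse_M"], out["mse_X"] = reconstruction_mse(m, x, result.model)
    return out


@dataclass
class EvalReport:
    """Per-variant, per-trial metrics with mean/sd aggregation."""

    trials: pd.DataFrame  # columns: variant, trial, seed, + METRIC_COLUMNS
    failures: list[str] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        """Variant x metric grid of mean over trials (Table-style)."""
        return self.trials.groupby("variant")[list(METRIC_COLUMNS)].mean()

    def formatted(self) -> pd.DataFrame:
        """Variant x metric grid of 'mean (sd)' strings."""
        g = self.trials.groupby("variant")[list(METRIC_COLUMNS)]
        mean, sd = g.mean(), g.std(ddof=1).fillna(0.0)
        return pd.DataFrame(
            {c: mean[c].round(4).astype(str) + " (" + sd[c].round(4).astype(str) + ")"
             for c in METRIC_COLUMNS}
        )


def run_comparison(m: DeltaMatrix | np.ndarray, x: DeltaMatrix | np.ndarray,
                   cohort: CohortTable, variants: tuple[str, ...] = VARIANTS,
                   n_trials: int = 10, base_seed: int = 0,
                   config: FitConfig | None = None) -> EvalReport:
    """Multi-trial, multi-variant comparison on resampled train/test splits.

    Each trial draws a fresh stratified 80/20 split from ``base_seed + trial``
    and every requested variant is fit on that identical split, so variant
    contrasts within a trial are paired.  Per-cell fit failures are recorded
    without aborting the other cells.
    """
    unknown = [v for v in variants if v not in VARIANTS]
    if unknown:
        raise ValueError(f"unknown variants: {unknown}")
    config = config or FitConfig()
    m_arr = m.values if isinstance(m, DeltaMatrix) else np.asarray(m, dtype=float)
    x_arr = x.values if isinstance(x, DeltaMatrix) else np.asarray(x, dtype=float)

    rows, failures = [], []
    for trial in range(n_trials):
        seed = int(base_seed + trial)
        split_rng = np.random.default_rng(seed)
        mask = stratified_split(cohort.labels, config.supervised_train_fraction,
                                split_rng)
        for variant in variants:
            vcfg = replace(config.for_variant(variant), seed=seed)
            try:
                result = fit(m_arr, x_arr, cohort, vcfg, train_mask=mask)
                metrics = evaluate_fit(m_arr, x_arr, result, cohort)
            except (ValueError, FloatingPointError) as exc:
                failures.append(f"trial {trial}, variant {variant}: {exc}")
                continue
            rows.append({"variant": variant, "trial": trial, "seed": seed, **metrics})
    return EvalReport(pd.DataFrame(rows), failures)
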