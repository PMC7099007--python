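"""Post-fit phenotype selection and characterization.

After factorization, each phenotype is profiled: its prevalence (fraction
of subjects with non-negligible membership), its top contributing regions
and tasks, whether it discriminates diagnostic stages (multivariate
logistic regression with the inter-visit interval as covariate), and
whether biomarkers change between visits among its members
(membership-weighted paired t-test).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .containers import CohortTable

#: Five cognitive areas of the 13 ADAS-Cog subtasks, used for profile plots.
ADAS_COG_AREAS = {
    "memory": ["Q1", "Q4", "Q9"],
    "visuospatial": ["Q3", "Q6"],
    "orientation": ["Q7"],
    "executive": ["Q2"],
    "language": ["Q8", "Q10", "Q11", "Q12", "Q5"],
}

COMPARISONS = ("AD_vs_MCI", "MCI_vs_CN", "ADMCI_vs_CN")


def prevalence(v: np.ndarray, threshold: float = 1e-5) -> np.ndarray:
    """Fraction of subjects with membership strictly above threshold, per phenotype."""
    v = np.asarray(v)
    return (v > threshold).mean(axis=0)


def top_features(y: np.ndarray, w: np.ndarray, feature_names_y: list[str],
                 feature_names_w: list[str], k: int = 5) -> list[dict]:
    """Per phenotype, the k regions and k tasks with largest membership.

    Zero-membership features are excluded; ties break by lexicographic
    feature name.  A k beyond the feature count yields a truncated list
    (with a warning).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > max(y.shape[1], w.shape[1]):
        warnings.warn("k exceeds feature count; lists will be truncated")

    def ranked(row: np.ndarray, names: list[str]) -> list[tuple[str, float]]:
        order = sorted(range(len(row)), key=lambda j: (-row[j], names[j]))
        return [(names[j], float(row[j])) for j in order[:k] if row[j] > 0]

    return [
        {"phenotype": f"P{r + 1}",
         "regions": ranked(y[r], feature_names_y),
         "tasks": ranked(w[r], feature_names_w)}
        for r in range(y.shape[0])
    ]


def logistic_filter(v: np.ndarray, cohort: CohortTable, comparison: str,
                    alpha: float = 0.05) -> pd.DataFrame:
    """Multivariate logistic regression of a stage contrast on memberships.

    One model: the binary contrast regressed on all phenotype membership
    columns plus the inter-visit interval (which cancels duration bias,
    since sicker subjects tend to have shorter follow-up).  Returns one row
    per phenotype with Wald coefficient, p-value, and a ``discard`` flag at
    significance level ``alpha``.  Perfect separation marks all phenotypes
    non-estimable.
    """
    if comparison not in COMPARISONS:
        raise ValueError(f"comparison must be one of {COMPARISONS}")
    labels = cohort.labels
    if comparison == "AD_vs_MCI":
        sel = np.isin(labels, ["AD", "MCI"])
        binary = (labels[sel] == "AD").astype(float)
    elif comparison == "MCI_vs_CN":
        sel = np.isin(labels, ["MCI", "CN"])
        binary = (labels[sel] == "MCI").astype(float)
    else:
        sel = np.ones(len(labels), dtype=bool)
        binary = (labels != "CN").astype(float)
    if binary.sum() < 2 or (1 - binary).sum() < 2:
        raise ValueError("need at least 2 subjects per class")

    r = v.shape[1]
    names = [f"P{i + 1}" for i in range(r)]
    design = pd.DataFrame(v[sel], columns=names)
    design["interval_years"] = cohort.demographics[sel, 0]
    design = sm.add_constant(design, has_constant="add")

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(binary, design).fit(disp=False, maxiter=200)
        coefs = res.params[names].to_numpy()
        pvals = res.pvalues[names].to_numpy()
        estimable = np.isfinite(coefs) & np.isfinite(pvals)
    except Exception:  # perfect separation or singular design
        coefs = np.full(r, np.nan)
        pvals = np.full(r, np.nan)
        estimable = np.zeros(r, dtype=bool)

    return pd.DataFrame(
        {
            "phenotype": names,
            "coef": coefs,
            "p_value": pvals,
            "estimable": estimable,
            "discard": ~estimable | (pvals > alpha),
        }
    )


@dataclass
class WeightedTTestResult:
    t: float
    p_value: float
    n_eff: float
    mean_diff: float
    significant: bool = field(default=False)  # at the p < 0.1 convention
    valid: bool = True


def weighted_ttest(values_visit1: np.ndarray, values_visit2: np.ndarray,
                   weights: np.ndarray, paired: bool = True,
                   significance_level: float = 0.1) -> WeightedTTestResult:
    """Membership-weighted paired t-test on per-subject change.

    With normalized weights w (summing to 1) over differences
    d = value2 - value1: mean d_bar = sum w_i d_i, variance
    s2 = sum w_i (d_i - d_bar)^2 / (1 - sum w_i^2), effective sample size
    n_eff = 1 / sum w_i^2, and t = d_bar / sqrt(s2 / n_eff) on n_eff - 1
    degrees of freedom.  Uniform weights reduce exactly to the ordinary
    paired t-test.  ``paired=False`` gives the weighted Welch two-sample
    variant on the two visit samples instead.

    Subjects with zero weight are ignored; fewer than 2 positive-weight
    subjects (or n_eff <= 1) yields a flagged invalid result.
    """
    w = np.asarray(weights, dtype=float)
    a = np.asarray(values_visit1, dtype=float)
    b = np.asarray(values_visit2, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    keep = w > 0
    if keep.sum() < 2 or w.sum() <= 0:
        return WeightedTTestResult(np.nan, np.nan, float(keep.sum()), np.nan,
                                   False, valid=False)
    w, a, b = w[keep], a[keep], b[keep]
    wn = w / w.sum()
    n_eff = 1.0 / np.sum(wn**2)
    if n_eff <= 1.0 + 1e-12:
        return WeightedTTestResult(np.nan, np.nan, float(n_eff), np.nan,
                                   False, valid=False)

    if paired:
        d = b - a
        mean = float(np.sum(wn * d))
        var = float(np.sum(wn * (d - mean) ** 2) / (1.0 - np.sum(wn**2)))
        if var == 0.0:
            t = 0.0
        else:
            t = mean / np.sqrt(var / n_eff)
        df = n_eff - 1.0
    else:
        m1, m2 = float(np.sum(wn * a)), float(np.sum(wn * b))
        v1 = float(np.sum(wn * (a - m1) ** 2) / (1.0 - np.sum(wn**2)))
        v2 = float(np.sum(wn * (b - m2) ** 2) / (1.0 - np.sum(wn**2)))
        mean = m2 - m1
        se2 = (v1 + v2) / n_eff
        t = 0.0 if se2 == 0 else mean / np.sqrt(se2)
        df = n_eff - 1.0
    p = float(2.0 * stats.t.sf(abs(t), df)) if df > 0 else float("nan")
    return WeightedTTestResult(float(t), p, float(n_eff), mean,
                               significant=bool(p < significance_level))


def cognitive_area_scores(adas_scores: pd.DataFrame,
                          max_scores: dict[str, float] | None = None) -> pd.DataFrame:
    """Partial sums of ADAS-Cog subtasks by cognitive area, max-normalized.

    ``adas_scores`` has one column per subtask (Q1..Q13).  Each area's score
    is the sum of its subtasks divided by the maximum attainable sum (the
    observed column maxima when ``max_scores`` is not given).
    """
    out = {}
    for area, items in ADAS_COG_AREAS.items():
        present = [q for q in items if q in adas_scores.columns]
        if not present:
            continue
        total = adas_scores[present].sum(axis=1)
        if max_scores:
            denom = sum(max_scores[q] for q in present)
        else:
            denom = adas_scores[present].max().sum()
        out[area] = total / denom if denom > 0 else total * 0.0
    return pd.DataFrame(out, index=adas_scores.index)


def profile_phenotypes(v: np.ndarray, y: np.ndarray, w: np.ndarray,
                       cohort: CohortTable, region_names: list[str],
                       task_names: list[str], alpha: float = 0.05,
                       threshold: float = 1e-5, top_k: int = 5,
                       bh_correct: bool = False) -> pd.DataFrame:
    """One row per phenotype: prevalence, top features, and the logistic filter.

    A phenotype is retained when it is significant (after optional
    Benjamini-Hochberg correction across phenotypes) in at least one of the
    three stage contrasts.  Expert curation of the retained candidates is
    left to the user.
    """
    prev = prevalence(v, threshold)
    tops = top_features(y, w, region_names, task_names, k=top_k)
    pvals = {}
    for comp in COMPARISONS:
        res = logistic_filter(v, cohort, comp, alpha=alpha)
        p = res["p_value"].to_numpy()
        if bh_correct:
            p = sm.stats.multipletests(p, alpha=alpha, method="fdr_bh")[1] \
                if np.all(np.isfinite(p)) else p
        pvals[comp] = p
    rows = []
    for r in range(v.shape[1]):
        ps = {f"p_{c}": float(pvals[c][r]) for c in COMPARISONS}
        retained = any(np.isfinite(p) and p <= alpha for p in ps.values())
        rows.append({
            "phenotype": f"P{r + 1}",
            "prevalence": float(prev[r]),
            "top_regions": tops[r]["regions"],
            "top_tasks": tops[r]["tasks"],
            **ps,
            "retained": retained,
        })
    return pd.DataFrame(rows)
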