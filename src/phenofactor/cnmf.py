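"""Supervised coupled nonnegative matrix factorization (C-NMF).

Two subject-aligned nonnegative matrices — M (subjects x regions, volume
loss) and X (subjects x tasks, severity increase) — are jointly factorized
with a shared subject-membership factor V:

    L_NMF(V, Y, W) = ||M - VY||^2 + ||X - VW||^2
                     + omega * (||V||_1 + ||Y||_1 + ||W||_1),   V, Y, W >= 0

An optional supervised regularizer pushes subject memberships apart by
diagnostic stage: three linear SVM heads (AD vs MCI, AD vs CN, MCI vs CN)
act on [V, demo] rows, and their summed hinge losses over the supervised
training subjects enter the objective,

    L_sup(V, theta) = loss_ADvsMCI + loss_ADvsCN + loss_MCIvsCN,

weighted by ``lambda_sup``.  Optimization alternates: the heads are refit
every ``svm_refit_every`` iterations; between refits V, Y, W take projected
adaptive-gradient (Adagrad) steps on the total objective with the heads held
fixed, every entry clamped to [0, inf) after each step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.svm import SVC

from .containers import DeltaMatrix, CohortTable, check_row_alignment

logger = logging.getLogger(__name__)

#: Supervised label pairs; the first stage of each pair codes +1.
PAIRS = (("AD", "MCI"), ("AD", "CN"), ("MCI", "CN"))

#: The four regularization variants of the comparison harness.
VARIANTS = ("cnmf", "cnmf-svm", "cnmf-l1", "cnmf-l1-svm")


@dataclass
class FactorModel:
    """The nonnegative factor triple (V, Y, W).

    V: subjects x R memberships of subjects to phenotypes.
    Y: R x regions memberships of brain regions to phenotypes.
    W: R x tasks memberships of cognitive tasks to phenotypes.
    """

    v: np.ndarray
    y: np.ndarray
    w: np.ndarray

    def __post_init__(self) -> None:
        if self.v.shape[1] != self.y.shape[0] or self.v.shape[1] != self.w.shape[0]:
            raise ValueError("inconsistent factor shapes")

    @property
    def rank(self) -> int:
        return self.v.shape[1]

    def copy(self) -> "FactorModel":
        return FactorModel(self.v.copy(), self.y.copy(), self.w.copy())


@dataclass
class SvmHead:
    """One linear separator over [V, demo] for one label pair.

    ``theta`` has length R + n_demo; demographics are standardized with the
    stored training-subject mean/scale before entering the decision function
    f(row) = theta . [v, demo_std] + b.
    """

    pair: tuple[str, str]
    theta: np.ndarray
    bias: float
    demo_mean: np.ndarray
    demo_scale: np.ndarray

    def decision(self, v_rows: np.ndarray, demo_rows: np.ndarray) -> np.ndarray:
        demo_std = (demo_rows - self.demo_mean) / self.demo_scale
        z = np.hstack([v_rows, demo_std])
        return z @ self.theta + self.bias


@dataclass
class FitConfig:
    """Hyperparameters of one fit.

    omega is the l1 weight (0.1 in the reference setting); lambda_sup scales
    the supervised hinge term relative to the reconstruction terms (the
    alternation schedule itself carries no explicit weight, so 1.0 is the
    neutral default).  hinge_aggregate: "mean" (per-subject hinge averaged
    within each pair, the default — keeps the supervised term from
    overwhelming the data terms as cohorts grow) or "sum".
    """

    rank: int = 30
    omega: float = 0.1
    lambda_sup: float = 1.0
    max_iters: int = 1000
    learning_rate: float = 0.05
    svm_refit_every: int = 200
    supervised_train_fraction: float = 0.8
    hinge_aggregate: str = "mean"
    svm_c: float = 1.0
    optimizer: str = "adam"
    init: str = "nndsvdar"
    early_stop_tol: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rank <= 0 or self.max_iters < 0:
            raise ValueError("rank must be positive and max_iters >= 0")
        if self.learning_rate <= 0 or self.svm_refit_every <= 0:
            raise ValueError("learning_rate and svm_refit_every must be positive")
        if not 0 < self.supervised_train_fraction < 1:
            raise ValueError("supervised_train_fraction must be in (0, 1)")
        if self.omega < 0 or self.lambda_sup < 0:
            raise ValueError("omega and lambda_sup must be >= 0")
        if self.hinge_aggregate not in ("sum", "mean"):
            raise ValueError("hinge_aggregate must be 'sum' or 'mean'")
        if self.optimizer not in ("adam", "adagrad"):
            raise ValueError("optimizer must be 'adam' or 'adagrad'")
        if self.init not in ("nndsvdar", "uniform"):
            raise ValueError("init must be 'nndsvdar' or 'uniform'")

    def for_variant(self, variant: str) -> "FitConfig":
        """The config with omega/lambda_sup set by regularization variant."""
        if variant not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}; choose from {VARIANTS}")
        omega = self.omega if "l1" in variant else 0.0
        lam = self.lambda_sup if variant.endswith("svm") else 0.0
        return replace(self, omega=omega, lambda_sup=lam)


@dataclass
class ObjectiveBreakdown:
    """The objective split into its four components."""

    recon_m: float
    recon_x: float
    l1_term: float
    sup_term: float
    lambda_sup: float

    @property
    def total(self) -> float:
        return self.recon_m + self.recon_x + self.l1_term + self.lambda_sup * self.sup_term


@dataclass
class FitResult:
    model: FactorModel
    heads: dict[tuple[str, str], SvmHead]
    trace: list[ObjectiveBreakdown] = field(repr=False)
    train_mask: np.ndarray = field(repr=False, default=None)


def project_nonnegative(model: FactorModel) -> FactorModel:
    """Clamp every negative entry of V, Y, W to zero (in place)."""
    np.maximum(model.v, 0.0, out=model.v)
    np.maximum(model.y, 0.0, out=model.y)
    np.maximum(model.w, 0.0, out=model.w)
    return model


def init_factors(
    m_shape: tuple[int, int], x_shape: tuple[int, int], rank: int,
    seed_or_rng: int | np.random.Generator, data_mean: float = 0.25,
) -> FactorModel:
    """i.i.d. uniform (0, s] entries with s = 2 * sqrt(data_mean / rank).

    E[(VY)_ij] = rank * (s/2)^2, so this scale matches the initial product
    to the data's mean entry and avoids dead-zero starts under projection.
    """
    if min(*m_shape, *x_shape, rank) <= 0:
        raise ValueError("dimensions must be positive")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    s = 2.0 * np.sqrt(max(data_mean, 1e-6) / rank)
    draw = lambda *shape: s * (1.0 - rng.random(shape))  # uniform on (0, s]
    return FactorModel(
        draw(m_shape[0], rank), draw(rank, m_shape[1]), draw(rank, x_shape[1])
    )


def nndsvdar_init(m: np.ndarray, x: np.ndarray, rank: int,
                  rng: np.random.Generator) -> FactorModel:
    """Nonnegative double-SVD initialization of the coupled factorization.

    The leading singular triplets of the stacked matrix [M | X] are split
    into their nonnegative parts (the dominant-sign half of each component
    carries most of its energy); remaining zeros are filled with small
    seeded random values so components do not start dead under projection
    and so repeated trials explore nearby basins.  Starting from this
    structured point makes paired variant comparisons reflect the
    regularizers rather than basin luck.
    """
    z = np.hstack([m, x])
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    if rank > len(s):
        raise ValueError("rank exceeds min(n_subjects, n_features)")
    v_f = np.zeros((z.shape[0], rank))
    h_f = np.zeros((rank, z.shape[1]))
    v_f[:, 0] = np.sqrt(s[0]) * np.abs(u[:, 0])
    h_f[0] = np.sqrt(s[0]) * np.abs(vt[0])
    for j in range(1, rank):
        up, un = np.maximum(u[:, j], 0), np.maximum(-u[:, j], 0)
        vp, vn = np.maximum(vt[j], 0), np.maximum(-vt[j], 0)
        npos = np.linalg.norm(up) * np.linalg.norm(vp)
        nneg = np.linalg.norm(un) * np.linalg.norm(vn)
        if npos >= nneg and npos > 0:
            v_f[:, j] = np.sqrt(s[j] * npos) * up / np.linalg.norm(up)
            h_f[j] = np.sqrt(s[j] * npos) * vp / np.linalg.norm(vp)
        elif nneg > 0:
            v_f[:, j] = np.sqrt(s[j] * nneg) * un / np.linalg.norm(un)
            h_f[j] = np.sqrt(s[j] * nneg) * vn / np.linalg.norm(vn)
    avg = z.mean()
    v_f[v_f == 0] = avg / 100 * rng.random(int((v_f == 0).sum()))
    h_f[h_f == 0] = avg / 100 * rng.random(int((h_f == 0).sum()))
    p_m = m.shape[1]
    return FactorModel(v_f, h_f[:, :p_m].copy(), h_f[:, p_m:].copy())


def hinge_loss(rows: np.ndarray, labels: np.ndarray, head: SvmHead, *,
               demo: np.ndarray | None = None, aggregate: str = "sum") -> float:
    """sum_i max{0, 1 - label_i * f(row_i)} (or the mean, if requested).

    ``rows`` are membership rows; ``demo`` the matching raw demographic rows
    (standardized inside the head).  Labels must be +/-1.
    """
    labels = np.asarray(labels)
    if not np.all(np.isin(labels, (-1, 1))):
        raise ValueError("labels must be +1 or -1")
    if demo is None:
        demo = np.zeros((len(rows), len(head.demo_mean)))
    margins = labels * head.decision(rows, demo)
    losses = np.maximum(0.0, 1.0 - margins)
    return float(losses.mean() if aggregate == "mean" else losses.sum())


def stratified_split(labels: np.ndarray, train_fraction: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Boolean train mask, stratified by label (floor per class, >=1 train)."""
    labels = np.asarray(labels)
    mask = np.zeros(len(labels), dtype=bool)
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        n_train = max(1, int(np.floor(train_fraction * len(idx))))
        mask[rng.choice(idx, size=n_train, replace=False)] = True
    return mask


def train_linear_head(pair: tuple[str, str], v_rows: np.ndarray,
                      demo_rows: np.ndarray, labels_pm: np.ndarray,
                      c: float = 1.0) -> SvmHead:
    """Soft-margin linear SVM on [V, demo_standardized] rows."""
    mean = demo_rows.mean(axis=0)
    sd = demo_rows.std(axis=0)
    scale = np.where(sd > 0, sd, 1.0)
    z = np.hstack([v_rows, (demo_rows - mean) / scale])
    clf = SVC(kernel="linear", C=c)
    clf.fit(z, labels_pm)
    return SvmHead(pair, clf.coef_.ravel().copy(), float(clf.intercept_[0]), mean, scale)


def pair_masks(labels: np.ndarray, pair: tuple[str, str]) -> tuple[np.ndarray, np.ndarray]:
    """(membership mask over all subjects, +/-1 labels over that subset)."""
    pos, neg = pair
    in_pair = np.isin(labels, [pos, neg])
    pm = np.where(labels[in_pair] == pos, 1, -1)
    return in_pair, pm


def fit_svm_heads(v: np.ndarray, cohort: CohortTable, config: FitConfig,
                  train_mask: np.ndarray) -> dict[tuple[str, str], SvmHead]:
    """One linear SVM per diagnostic pair, trained on supervised-train rows."""
    labels = cohort.labels
    demo = cohort.demographics
    heads: dict[tuple[str, str], SvmHead] = {}
    for pair in PAIRS:
        in_pair, _ = pair_masks(labels, pair)
        tr = in_pair & train_mask
        pm = np.where(labels[tr] == pair[0], 1, -1)
        if (pm == 1).sum() < 2 or (pm == -1).sum() < 2:
            raise ValueError(
                f"pair {pair[0]} vs {pair[1]}: fewer than 2 training subjects per class"
            )
        heads[pair] = train_linear_head(pair, v[tr], demo[tr], pm, config.svm_c)
    return heads


def objective(m: np.ndarray, x: np.ndarray, model: FactorModel,
              heads: dict[tuple[str, str], SvmHead] | None,
              cohort: CohortTable | None, config: FitConfig,
              train_mask: np.ndarray | None = None) -> ObjectiveBreakdown:
    """Evaluate every component of the total objective at the current model."""
    if m.shape[0] != model.v.shape[0] or m.shape[1] != model.y.shape[1]:
        raise ValueError("M shape inconsistent with factors")
    if x.shape[0] != model.v.shape[0] or x.shape[1] != model.w.shape[1]:
        raise ValueError("X shape inconsistent with factors")
    recon_m = float(np.sum((m - model.v @ model.y) ** 2))
    recon_x = float(np.sum((x - model.v @ model.w) ** 2))
    l1 = config.omega * float(
        np.sum(np.abs(model.v)) + np.sum(np.abs(model.y)) + np.sum(np.abs(model.w))
    )
    sup = 0.0
    if heads and cohort is not None and config.lambda_sup > 0:
        labels = cohort.labels
        demo = cohort.demographics
        if train_mask is None:
            train_mask = np.ones(len(labels), dtype=bool)
        for pair, head in heads.items():
            if pair == ("AD+MCI", "CN"):
                continue  # post-hoc evaluation head, not part of L_sup
            in_pair, _ = pair_masks(labels, pair)
            tr = in_pair & train_mask
            pm = np.where(labels[tr] == pair[0], 1, -1)
            sup += hinge_loss(model.v[tr], pm, head, demo=demo[tr],
                              aggregate=config.hinge_aggregate)
    return ObjectiveBreakdown(recon_m, recon_x, l1, sup, config.lambda_sup)


def _hinge_grad_v(v: np.ndarray, heads: dict, cohort: CohortTable,
                  config: FitConfig, train_mask: np.ndarray) -> np.ndarray:
    """Subgradient of L_sup w.r.t. V (flows only into supervised-train rows)."""
    grad = np.zeros_like(v)
    labels = cohort.labels
    demo = cohort.demographics
    r = v.shape[1]
    for pair, head in heads.items():
        in_pair, _ = pair_masks(labels, pair)
        tr = np.flatnonzero(in_pair & train_mask)
        pm = np.where(labels[tr] == pair[0], 1.0, -1.0)
        margins = pm * head.decision(v[tr], demo[tr])
        active = margins < 1.0  # subgradient 0 at the kink
        scale = 1.0 / len(tr) if config.hinge_aggregate == "mean" else 1.0
        grad[tr[active]] += -scale * pm[active, None] * head.theta[:r][None, :]
    return grad


class _AdaptiveOptimizer:
    """Per-coordinate adaptive-gradient updates for the three factor blocks.

    ``adam``: exponential first/second moment estimates with bias correction
    (converges within the 1000-iteration budget at desk scale).  ``adagrad``:
    cumulative squared-gradient normalization (the literal reading, offered
    for comparison; its monotonically decaying steps converge more slowly).
    """

    def __init__(self, model: FactorModel, method: str, lr: float):
        self.method = method
        self.lr = lr
        self.t = 0
        self.eps = 1e-8
        self.b1, self.b2 = 0.9, 0.999
        shapes = {"v": model.v, "y": model.y, "w": model.w}
        self.m1 = {k: np.zeros_like(a) for k, a in shapes.items()}
        self.m2 = {k: np.zeros_like(a) for k, a in shapes.items()}

    def step(self, model: FactorModel, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for key, mat in (("v", model.v), ("y", model.y), ("w", model.w)):
            g = grads[key]
            if self.method == "adam":
                self.m1[key] = self.b1 * self.m1[key] + (1 - self.b1) * g
                self.m2[key] = self.b2 * self.m2[key] + (1 - self.b2) * g * g
                m_hat = self.m1[key] / (1 - self.b1**self.t)
                v_hat = self.m2[key] / (1 - self.b2**self.t)
                mat -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
            else:  # adagrad
                self.m2[key] += g * g
                mat -= self.lr * g / (np.sqrt(self.m2[key]) + self.eps)

    def rescale(self, c: np.ndarray) -> None:
        # gradient w.r.t. V scales by c under V -> V/c (and by 1/c for Y, W rows)
        self.m1["v"] *= c
        self.m2["v"] *= c**2
        self.m1["y"] /= c[:, None]
        self.m2["y"] /= c[:, None] ** 2
        self.m1["w"] /= c[:, None]
        self.m2["w"] /= c[:, None] ** 2


def _equilibrate(model: FactorModel, optimizer: _AdaptiveOptimizer) -> None:
    """Diagonal rescale (V/c, cY, cW) minimizing the l1 term per component.

    The reconstruction VY, VW is invariant under this rescaling, and for a
    fixed product the l1 sum is minimized at c_r = sqrt(|v_r|_1 /
    (|y_r|_1 + |w_r|_1)), so this is an exact descent step along the scale
    ambiguity of the objective; without it the l1 penalty spends most of the
    iteration budget rebalancing factor scales instead of sparsifying.
    Optimizer state is rescaled consistently with the reparametrization.
    """
    lv = model.v.sum(axis=0)
    lyw = model.y.sum(axis=1) + model.w.sum(axis=1)
    ok = (lv > 0) & (lyw > 0)
    c = np.ones(model.rank)
    c[ok] = np.sqrt(lv[ok] / lyw[ok])
    model.v /= c
    model.y *= c[:, None]
    model.w *= c[:, None]
    optimizer.rescale(c)


def fit(m: DeltaMatrix | np.ndarray, x: DeltaMatrix | np.ndarray,
        cohort: CohortTable, config: FitConfig,
        train_mask: np.ndarray | None = None) -> FitResult:
    """Alternating projected-Adagrad fit of the supervised coupled NMF.

    The supervised 80/20 split is drawn once per fit from the config seed
    (stratified by label) unless ``train_mask`` is supplied.  Heads are refit
    at iteration 0 and every ``svm_refit_every`` iterations when
    ``lambda_sup > 0``; a final set of heads (including the pooled
    AD+MCI-vs-CN evaluation head) is always trained on the final V.  The
    recorded trace holds the objective breakdown at initialization and after
    every iteration.
    """
    m_arr = m.values if isinstance(m, DeltaMatrix) else np.asarray(m, dtype=float)
    x_arr = x.values if isinstance(x, DeltaMatrix) else np.asarray(x, dtype=float)
    if isinstance(m, DeltaMatrix) and isinstance(x, DeltaMatrix):
        check_row_alignment(m, x)
        cohort = cohort.aligned_to(m.subject_ids)

    rng = np.random.default_rng(config.seed)
    if train_mask is None:
        if cohort.train_mask is not None:
            train_mask = cohort.train_mask
        else:
            train_mask = stratified_split(
                cohort.labels, config.supervised_train_fraction, rng
            )
    train_mask = np.asarray(train_mask, dtype=bool)

    if config.init == "nndsvdar":
        model = nndsvdar_init(m_arr, x_arr, config.rank, rng)
    else:
        data_mean = float(np.concatenate([m_arr.ravel(), x_arr.ravel()]).mean())
        model = init_factors(m_arr.shape, x_arr.shape, config.rank, rng, data_mean)

    heads: dict[tuple[str, str], SvmHead] = {}
    if config.lambda_sup > 0 and config.max_iters > 0:
        heads = fit_svm_heads(model.v, cohort, config, train_mask)
    opt = _AdaptiveOptimizer(model, config.optimizer, config.learning_rate)
    trace = [objective(m_arr, x_arr, model, heads, cohort, config, train_mask)]

    for it in range(config.max_iters):
        if config.lambda_sup > 0 and it > 0 and it % config.svm_refit_every == 0:
            heads = fit_svm_heads(model.v, cohort, config, train_mask)

        err_m = model.v @ model.y - m_arr
        err_x = model.v @ model.w - x_arr
        g_v = 2.0 * (err_m @ model.y.T + err_x @ model.w.T) + config.omega
        g_y = 2.0 * (model.v.T @ err_m) + config.omega
        g_w = 2.0 * (model.v.T @ err_x) + config.omega
        if config.lambda_sup > 0 and heads:
            g_v += config.lambda_sup * _hinge_grad_v(
                model.v, heads, cohort, config, train_mask
            )

        opt.step(model, {"v": g_v, "y": g_y, "w": g_w})
        project_nonnegative(model)
        _equilibrate(model, opt)

        bd = objective(m_arr, x_arr, model, heads, cohort, config, train_mask)
        if not np.isfinite(bd.total):
            raise FloatingPointError(
                f"non-finite objective at iteration {it}; trace: "
                f"{[t.total for t in trace[-5:]]}"
            )
        trace.append(bd)
        if (
            config.early_stop_tol is not None
            and it > 0
            and abs(trace[-2].total - bd.total) <= config.early_stop_tol * max(trace[-2].total, 1e-12)
        ):
            logger.info("early stop at iteration %d", it)
            break

    # final heads on the final memberships, for downstream evaluation
    try:
        heads = fit_svm_heads(model.v, cohort, config, train_mask)
        labels = cohort.labels
        pooled = np.isin(labels, ["AD", "MCI", "CN"]) & train_mask
        pm = np.where(labels[pooled] != "CN", 1, -1)
        if (pm == 1).sum() >= 2 and (pm == -1).sum() >= 2:
            heads[("AD+MCI", "CN")] = train_linear_head(
                ("AD+MCI", "CN"), model.v[pooled],
                cohort.demographics[pooled], pm, config.svm_c,
            )
    except ValueError as exc:  # degenerate cohorts: keep the factor fit
        logger.warning("final head training skipped: %s", exc)

    return FitResult(model, heads, trace, train_mask)
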