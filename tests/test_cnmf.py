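"""Core factorization: objective components, hinge loss, SVM heads, fitting."""

import numpy as np
import pytest

import phenofactor as pf
from phenofactor.cnmf import PAIRS, nndsvdar_init, pair_masks, train_linear_head


def _loop_objective(m, x, v, y, w, omega):
    """Independent elementwise-loop evaluation of the unsupervised objective."""
    recon_m = sum((m[i, j] - sum(v[i, r] * y[r, j] for r in range(v.shape[1]))) ** 2
                  for i in range(m.shape[0]) for j in range(m.shape[1]))
    recon_x = sum((x[i, j] - sum(v[i, r] * w[r, j] for r in range(v.shape[1]))) ** 2
                  for i in range(x.shape[0]) for j in range(x.shape[1]))
    l1 = omega * (sum(abs(e) for e in v.ravel()) + sum(abs(e) for e in y.ravel())
                  + sum(abs(e) for e in w.ravel()))
    return recon_m, recon_x, l1


def _head(theta, bias, n_demo=3):
    return pf.SvmHead(("AD", "MCI"), np.asarray(theta, float), bias,
                      np.zeros(n_demo), np.ones(n_demo))


class TestInitFactors:
    def test_deterministic_and_shapes(self):
        a = pf.init_factors((10, 8), (10, 5), 3, seed_or_rng=11)
        b = pf.init_factors((10, 8), (10, 5), 3, seed_or_rng=11)
        assert a.v.shape == (10, 3) and a.y.shape == (3, 8) and a.w.shape == (3, 5)
        assert np.array_equal(a.v, b.v) and np.array_equal(a.y, b.y)
        assert (a.v > 0).all() and (a.y > 0).all() and (a.w > 0).all()

    def test_uniform_scale_matches_data_mean(self):
        """E[(VY)_ij] = R * (s/2)^2 with s = 2 sqrt(mean/R), so the product
        mean should approximate the requested data mean."""
        model = pf.init_factors((400, 300), (400, 10), 5, 0, data_mean=0.3)
        assert abs((model.v @ model.y).mean() - 0.3) < 0.05

    def test_nndsvd_reconstructs_better_than_random(self, small_cohort):
        m, x, _, _ = small_cohort
        rng = np.random.default_rng(0)
        svd_model = nndsvdar_init(m.values, x.values, 4, rng)
        rand_model = pf.init_factors(m.values.shape, x.values.shape, 4, 0,
                                     float(m.values.mean()))
        err = lambda mod: np.sum((m.values - mod.v @ mod.y) ** 2)
        assert err(svd_model) < err(rand_model)
        assert (svd_model.v >= 0).all() and (svd_model.y >= 0).all()


class TestObjective:
    def test_perfect_reconstruction_is_zero(self, rng):
        v = rng.random((6, 2)); y = rng.random((2, 4)); w = rng.random((2, 3))
        model = pf.FactorModel(v, y, w)
        cfg = pf.FitConfig(rank=2, omega=0.0, lambda_sup=0.0)
        bd = pf.objective(v @ y, v @ w, model, None, None, cfg)
        assert bd.total == pytest.approx(0.0, abs=1e-18)

    def test_zero_factors_closed_form(self, rng):
        m = rng.random((5, 4)); x = rng.random((5, 3))
        model = pf.FactorModel(np.zeros((5, 2)), np.zeros((2, 4)), np.zeros((2, 3)))
        bd = pf.objective(m, x, model, None, None, pf.FitConfig(rank=2, omega=0.5))
        assert bd.recon_m == pytest.approx(np.sum(m**2), rel=1e-12)
        assert bd.l1_term == 0.0

    def test_matches_loop_oracle(self, rng):
        m = rng.random((6, 4)); x = rng.random((6, 3))
        model = pf.FactorModel(rng.random((6, 2)), rng.random((2, 4)), rng.random((2, 3)))
        cfg = pf.FitConfig(rank=2, omega=0.37, lambda_sup=0.0)
        bd = pf.objective(m, x, model, None, None, cfg)
        rm, rx, l1 = _loop_objective(m, x, model.v, model.y, model.w, 0.37)
        assert bd.recon_m == pytest.approx(rm, rel=1e-12)
        assert bd.recon_x == pytest.approx(rx, rel=1e-12)
        assert bd.l1_term == pytest.approx(l1, rel=1e-12)

    def test_shape_mismatch_is_hard_error(self, rng):
        model = pf.FactorModel(rng.random((6, 2)), rng.random((2, 4)), rng.random((2, 3)))
        with pytest.raises(ValueError):
            pf.objective(rng.random((6, 5)), rng.random((6, 3)), model, None, None,
                         pf.FitConfig(rank=2))


class TestHingeLoss:
    @pytest.mark.parametrize("decision,expected", [(2.0, 0.0), (0.0, 1.0), (1.0, 0.0),
                                                   (-1.0, 2.0)])
    def test_scalar_cases(self, decision, expected):
        head = _head([1.0], 0.0, n_demo=0)
        rows = np.array([[decision]])
        assert pf.hinge_loss(rows, np.array([1]), head) == pytest.approx(expected)

    def test_matches_per_subject_loop(self, rng):
        head = _head(rng.normal(size=5), 0.3, n_demo=3)
        rows = rng.random((20, 2))
        demo = rng.normal(size=(20, 3))
        labels = rng.choice([-1, 1], 20)
        total = pf.hinge_loss(rows, labels, head, demo=demo)
        expected = sum(
            max(0.0, 1.0 - labels[i] * (head.theta @ np.r_[rows[i], demo[i]] + head.bias))
            for i in range(20))
        assert total == pytest.approx(expected, rel=1e-12)

    def test_invalid_label_rejected(self):
        with pytest.raises(ValueError, match="labels"):
            pf.hinge_loss(np.ones((1, 1)), np.array([0]), _head([1.0], 0.0, 0))


class TestProjection:
    def test_negative_entries_clamped_others_kept(self, rng):
        v = rng.normal(size=(4, 2)); y = rng.normal(size=(2, 3)); w = rng.normal(size=(2, 2))
        model = pf.project_nonnegative(pf.FactorModel(v.copy(), y.copy(), w.copy()))
        np.testing.assert_array_equal(model.v, np.maximum(v, 0))
        np.testing.assert_array_equal(model.y, np.maximum(y, 0))
        np.testing.assert_array_equal(model.w, np.maximum(w, 0))


class TestSvmHeads:
    def test_separable_clouds_reach_zero_hinge(self, rng):
        n = 40
        v = np.vstack([rng.random((n, 2)) + [3, 0], rng.random((n, 2))])
        demo = np.zeros((2 * n, 3))
        labels = np.r_[np.ones(n), -np.ones(n)].astype(int)
        head = train_linear_head(("AD", "CN"), v, demo, labels)
        preds = np.sign(head.decision(v, demo))
        assert (preds == labels).all()

    def test_determinism(self, small_cohort):
        m, x, cohort, _ = small_cohort
        rng = np.random.default_rng(5)
        v = rng.random((len(cohort), 3))
        mask = pf.stratified_split(cohort.labels, 0.8, np.random.default_rng(2))
        cfg = pf.FitConfig(rank=3)
        h1 = pf.fit_svm_heads(v, cohort, cfg, mask)
        h2 = pf.fit_svm_heads(v, cohort, cfg, mask)
        for pair in PAIRS:
            assert np.array_equal(h1[pair].theta, h2[pair].theta)
            assert h1[pair].bias == h2[pair].bias

    def test_too_few_training_subjects_names_pair(self, random_cohort_table):
        cohort = random_cohort_table(30)
        mask = np.zeros(30, dtype=bool)
        mask[np.flatnonzero(cohort.labels == "AD")[:1]] = True  # 1 AD, 0 others
        with pytest.raises(ValueError, match="AD vs MCI"):
            pf.fit_svm_heads(np.random.default_rng(0).random((30, 2)), cohort,
                             pf.FitConfig(rank=2), mask)


class TestFit:
    def test_zero_iters_returns_initialized_model(self, small_cohort):
        m, x, cohort, _ = small_cohort
        cfg = pf.FitConfig(rank=3, max_iters=0, seed=8)
        r1 = pf.fit(m, x, cohort, cfg)
        r2 = pf.fit(m, x, cohort, cfg)
        assert len(r1.trace) == 1
        assert np.array_equal(r1.model.v, r2.model.v)

    def test_deterministic_traces_and_factors(self, small_cohort):
        m, x, cohort, _ = small_cohort
        cfg = pf.FitConfig(rank=3, max_iters=150, seed=4)
        r1 = pf.fit(m, x, cohort, cfg)
        r2 = pf.fit(m, x, cohort, cfg)
        assert [b.total for b in r1.trace] == [b.total for b in r2.trace]
        assert np.array_equal(r1.model.y, r2.model.y)

    def test_nonnegativity_and_descent(self, small_cohort):
        m, x, cohort, _ = small_cohort
        cfg = pf.FitConfig(rank=3, max_iters=300, seed=4)
        res = pf.fit(m, x, cohort, cfg)
        for mat in (res.model.v, res.model.y, res.model.w):
            assert (mat >= 0).all()
        assert res.trace[-1].total <= res.trace[0].total
        assert all(np.isfinite(b.total) for b in res.trace)

    def test_unregularized_fit_reconstructs_noiseless_data(self):
        cfg_gen = pf.SyntheticConfig(n_subjects=80, n_regions=12, n_tasks=9, r_true=3,
                                     noise_sd=0.0, factor_sparsity=0.0, seed=6)
        m, x, cohort, _ = pf.generate(cfg_gen, normalize=False)
        cfg = pf.FitConfig(rank=3, omega=0.0, lambda_sup=0.0, max_iters=500, seed=1)
        res = pf.fit(m, x, cohort, cfg)
        final = res.trace[-1]
        denom = np.sum(m.values**2) + np.sum(x.values**2)
        assert (final.recon_m + final.recon_x) / denom < 1e-2

    def test_supervised_split_is_stratified_and_reused(self, small_cohort):
        m, x, cohort, _ = small_cohort
        cfg = pf.FitConfig(rank=3, max_iters=10, seed=12)
        res = pf.fit(m, x, cohort, cfg)
        labels = cohort.labels
        for lab in ("AD", "MCI", "CN"):
            frac = res.train_mask[labels == lab].mean()
            assert 0.7 <= frac <= 0.9

    def test_supervised_variant_keeps_discriminability(self, small_cohort):
        """Adding the hinge term must not destroy held-out separability."""
        m, x, cohort, _ = small_cohort
        mask = pf.stratified_split(cohort.labels, 0.8, np.random.default_rng(3))
        res_u = pf.fit(m, x, cohort, pf.FitConfig(
            rank=3, lambda_sup=0.0, max_iters=400, seed=5), train_mask=mask)
        res_s = pf.fit(m, x, cohort, pf.FitConfig(
            rank=3, lambda_sup=1.0, max_iters=400, seed=5), train_mask=mask)
        coh = cohort.aligned_to(m.subject_ids)
        auc_u = pf.evaluate_fit(m.values, x.values, res_u, coh)["auc_AD_vs_CN"]
        auc_s = pf.evaluate_fit(m.values, x.values, res_s, coh)["auc_AD_vs_CN"]
        assert auc_s >= auc_u - 0.1


def test_pair_masks_signs():
    labels = np.array(["AD", "CN", "MCI", "AD"])
    in_pair, pm = pair_masks(labels, ("AD", "CN"))
    assert in_pair.tolist() == [True, True, False, True]
    assert pm.tolist() == [1, -1, 1]


def test_variant_configs():
    base = pf.FitConfig(rank=5, omega=0.2, lambda_sup=2.0)
    assert base.for_variant("cnmf").omega == 0.0
    assert base.for_variant("cnmf").lambda_sup == 0.0
    assert base.for_variant("cnmf-svm").lambda_sup == 2.0
    assert base.for_variant("cnmf-l1").omega == 0.2
    cfg = base.for_variant("cnmf-l1-svm")
    assert cfg.omega == 0.2 and cfg.lambda_sup == 2.0
    with pytest.raises(ValueError):
        base.for_variant("pca")
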