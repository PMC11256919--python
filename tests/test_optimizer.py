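import numpy as np
import pytest

from graphtucker.graphs import build_graph_set
from graphtucker.optimizer import (
    FitConfig,
    TuckerModel,
    core_gradient_parts,
    factor_gradient_parts,
    fit,
    impute,
    mu_update_core,
    mu_update_factor,
    normalize,
    objective,
)

from conftest import dense_product_laplacian, random_model


class TestObjective:
    def test_perfect_fit_unregularized(self, rng):
        model = random_model(rng, (3, 4, 2), (2, 2, 2))
        t = model.reconstruct()
        gs = build_graph_set(t.shape)
        f1, f2, total = objective(t, np.ones_like(t), model, gs, 0.0)
        assert f1 == pytest.approx(0.0, abs=1e-12)
        assert total == pytest.approx(0.0, abs=1e-12)

    def test_empty_mask_zeroes_data_term(self, rng, tiny_problem):
        t, _, model, gs = tiny_problem
        f1, _, _ = objective(t, np.zeros_like(t), model, gs, 1.0)
        assert f1 == 0.0

    def test_matches_dense_oracle(self, tiny_problem):
        t, m, model, gs = tiny_problem
        lam = 0.7
        f1, f2, total = objective(t, m, model, gs, lam)
        that = model.reconstruct()
        f1_o = 0.5 * np.sum((m * (t - that)) ** 2)
        v = that.reshape(-1)
        f2_o = 0.5 * v @ dense_product_laplacian(gs) @ v
        assert f1 == pytest.approx(f1_o, rel=1e-10)
        assert f2 == pytest.approx(f2_o, rel=1e-10)
        assert total == pytest.approx(f1_o + lam * f2_o, rel=1e-10)

    def test_shape_mismatch(self, rng, tiny_problem):
        t, m, model, gs = tiny_problem
        with pytest.raises(ValueError):
            objective(t[:2], m, model, gs, 0.1)


class TestGradientSplit:
    def test_parts_are_nonnegative(self, tiny_problem):
        t, m, model, gs = tiny_problem
        for mode in range(3):
            for part in factor_gradient_parts(t, m, model, gs, mode):
                assert part.min() >= 0
        for part in core_gradient_parts(t, m, model, gs):
            assert part.min() >= 0

    @pytest.mark.parametrize("lam", [0.0, 0.5])
    def test_matches_finite_differences(self, tiny_problem, lam):
        t, m, model, gs = tiny_problem
        h = 1e-6

        def fd(block_name):
            block = model.blocks()[block_name]
            g = np.zeros_like(block)
            for idx in np.ndindex(*block.shape):
                up, dn = model.copy(), model.copy()
                up.blocks()[block_name][idx] += h
                dn.blocks()[block_name][idx] -= h
                g[idx] = (
                    objective(t, m, up, gs, lam)[2] - objective(t, m, dn, gs, lam)[2]
                ) / (2 * h)
            return g

        for mode, name in enumerate(["ay", "ax", "ag"]):
            dp, dn_, rp, rn = factor_gradient_parts(t, m, model, gs, mode)
            analytic = (dp - dn_) + lam * (rp - rn)
            g = fd(name)
            assert np.abs(analytic - g).max() <= 1e-5 * max(np.abs(g).max(), 1.0)
        dp, dn_, rp, rn = core_gradient_parts(t, m, model, gs)
        analytic = (dp - dn_) + lam * (rp - rn)
        g = fd("core")
        assert np.abs(analytic - g).max() <= 1e-5 * max(np.abs(g).max(), 1.0)


class TestMultiplicativeUpdates:
    def test_zero_entries_stay_zero(self, tiny_problem):
        t, m, model, gs = tiny_problem
        model.ay[0, 0] = 0.0
        model.core[1, 1, 1] = 0.0
        assert mu_update_factor(t, m, model, gs, 0, 0.5)[0, 0] == 0.0
        assert mu_update_core(t, m, model, gs, 0.5)[1, 1, 1] == 0.0

    def test_stationary_at_perfect_unregularized_fit(self, rng):
        model = random_model(rng, (3, 4, 2), (2, 2, 2))
        t = model.reconstruct()
        m = np.ones_like(t)
        gs = build_graph_set(t.shape)
        for mode in range(3):
            new = mu_update_factor(t, m, model, gs, mode, 0.0)
            np.testing.assert_allclose(new, model.factors()[mode], rtol=1e-8)
        np.testing.assert_allclose(
            mu_update_core(t, m, model, gs, 0.0), model.core, rtol=1e-8
        )

    def test_preserves_nonnegativity(self, tiny_problem):
        t, m, model, gs = tiny_problem
        for mode in range(3):
            assert mu_update_factor(t, m, model, gs, mode, 1.0).min() >= 0
        assert mu_update_core(t, m, model, gs, 1.0).min() >= 0


class TestNormalize:
    def test_reconstruction_invariant(self, rng):
        model = random_model(rng, (4, 5, 3), (2, 3, 2))
        before = model.reconstruct()
        after = normalize(model).reconstruct()
        assert np.abs(before - after).max() < 1e-10

    def test_columns_sum_to_one(self, rng):
        model = normalize(random_model(rng, (4, 5, 3), (2, 3, 2)))
        for a in model.factors():
            np.testing.assert_allclose(a.sum(axis=0), 1.0, atol=1e-9)

    def test_already_normalized_is_fixed_point(self, rng):
        model = normalize(random_model(rng, (4, 5, 3), (2, 3, 2)))
        again = normalize(model)
        np.testing.assert_allclose(again.ay, model.ay, atol=1e-12)
        np.testing.assert_allclose(again.core, model.core, atol=1e-12)

    def test_scale_absorbed_into_core(self):
        # column (2, 2) with core weight 3 -> column (0.5, 0.5), weight 12
        model = TuckerModel(
            core=np.full((1, 1, 1), 3.0),
            ay=np.array([[2.0], [2.0]]),
            ax=np.array([[1.0]]),
            ag=np.array([[1.0]]),
        )
        normed = normalize(model)
        np.testing.assert_allclose(normed.ay, [[0.5], [0.5]])
        assert normed.core[0, 0, 0] == pytest.approx(12.0)
        np.testing.assert_allclose(
            normed.reconstruct(), model.reconstruct(), atol=1e-12
        )

    def test_zero_column_untouched(self):
        model = TuckerModel(
            core=np.ones((2, 1, 1)),
            ay=np.array([[1.0, 0.0], [1.0, 0.0]]),
            ax=np.ones((1, 1)),
            ag=np.ones((1, 1)),
        )
        normed = normalize(model)
        np.testing.assert_array_equal(normed.ay[:, 1], [0.0, 0.0])


class TestFit:
    def test_deterministic_given_seed(self, tiny_problem):
        t, m, _, _ = tiny_problem
        cfg = FitConfig(rank=(2, 2, 2), lambda_=0.1, max_iter=30, tol=1e-12, seed=5)
        r1 = fit(t, m, config=cfg)
        r2 = fit(t, m, config=cfg)
        assert r1.objective_trace == r2.objective_trace
        np.testing.assert_array_equal(r1.model.core, r2.model.core)

    def test_trace_bounded_by_iteration_budget(self, tiny_problem):
        t, m, _, _ = tiny_problem
        cfg = FitConfig(rank=(2, 2, 2), max_iter=40, seed=0)
        res = fit(t, m, config=cfg)
        assert len(res.objective_trace) <= 40
        assert FitConfig().max_iter == 5000

    def test_objective_nonincreasing(self, tiny_problem):
        t, m, _, _ = tiny_problem
        cfg = FitConfig(rank=(2, 2, 2), lambda_=0.5, max_iter=100, tol=1e-12, seed=3)
        res = fit(t, m, config=cfg)
        totals = np.array(res.objective_trace)[:, 2]
        assert np.all(np.diff(totals) <= 1e-8 * np.abs(totals[:-1]) + 1e-12)

    def test_trace_consistency(self, tiny_problem):
        t, m, _, _ = tiny_problem
        cfg = FitConfig(rank=(2, 2, 2), lambda_=0.3, max_iter=20, tol=1e-12, seed=1)
        res = fit(t, m, config=cfg)
        for f1, f2, total in res.objective_trace:
            assert total == pytest.approx(f1 + 0.3 * f2, rel=1e-8)

    def test_unregularized_path_ignores_network(self, rng, tiny_problem):
        t, m, _, _ = tiny_problem
        from conftest import random_gene_graph

        cfg = FitConfig(rank=(2, 2, 2), lambda_=0.0, max_iter=25, tol=1e-12, seed=2)
        with_net = fit(t, m, network=random_gene_graph(rng, t.shape[2], 2), config=cfg)
        without = fit(t, m, network=None, config=cfg)
        np.testing.assert_array_equal(with_net.model.core, without.model.core)
        np.testing.assert_array_equal(with_net.model.ag, without.model.ag)

    def test_masked_entries_have_no_influence(self, rng, tiny_problem):
        t, m, _, _ = tiny_problem
        cfg = FitConfig(rank=(2, 2, 2), lambda_=0.2, max_iter=25, tol=1e-12, seed=4)
        base = fit(t, m, config=cfg)
        perturbed = t.copy()
        perturbed[m == 0] += rng.uniform(1, 10, size=int((m == 0).sum()))
        other = fit(perturbed, m, config=cfg)
        np.testing.assert_array_equal(base.model.core, other.model.core)
        np.testing.assert_array_equal(base.model.ay, other.model.ay)

    def test_rank_exceeding_dimension_rejected(self, tiny_problem):
        t, m, _, _ = tiny_problem
        with pytest.raises(ValueError):
            fit(t, m, config=FitConfig(rank=(2, 2, 10), max_iter=5))

    def test_blocks_stay_nonnegative(self, tiny_problem):
        t, m, _, _ = tiny_problem
        cfg = FitConfig(rank=(2, 2, 2), lambda_=1.0, max_iter=50, tol=1e-12, seed=6)
        res = fit(t, m, config=cfg)
        for block in res.model.blocks().values():
            assert block.min() >= 0

    def test_imputation_is_nonnegative_reconstruction(self, tiny_problem):
        t, m, _, _ = tiny_problem
        res = fit(t, m, config=FitConfig(rank=(2, 2, 2), max_iter=20, seed=0))
        pred = impute(res.model)
        assert pred.shape == t.shape and pred.min() >= 0
        np.testing.assert_array_equal(pred, res.model.reconstruct())


class TestGraphSmoothingEffect:
    def test_reconstruction_smoother_with_stronger_regularization(self, rng):
        """The graph roughness of the fitted reconstruction (the product-
        graph quadratic form the penalty controls) decreases monotonically
        along a lambda grid on a fixed smooth synthetic instance."""
        from graphtucker.graphs import build_graph_set, product_quadratic_form
        from graphtucker.synthetic import SimulationSpec, simulate

        sim = simulate(SimulationSpec(shape=(14, 14, 16), rank=(2, 2, 4), seed=9))
        gs = build_graph_set(sim.tensor.shape, sim.network)
        roughness = []
        for lam in [0.0, 0.1, 1.0, 10.0]:
            cfg = FitConfig(rank=(2, 2, 4), lambda_=lam, max_iter=300, tol=1e-12, seed=1)
            res = fit(sim.tensor, sim.mask, network=sim.network, config=cfg)
            roughness.append(product_quadratic_form(res.model.reconstruct(), gs))
        assert all(b < a for a, b in zip(roughness, roughness[1:]))
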