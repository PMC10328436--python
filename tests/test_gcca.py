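"""Shared-representation learner: closed-form GCCA, gradients, training.

The brute-force oracle below rebuilds the GCCA optimum from the textbook
definition (explicit matrix inverses, dense eigendecomposition, residuals
straight from the objective), independently of the package's solver path.
"""

import numpy as np
import pytest

from gccasub import (
    GccaConfig,
    ViewNetworkConfig,
    embed_samples,
    gcca_loss_and_grads,
    gcca_solve,
    train_dgcca,
)
from gccasub.gcca import ViewNetwork, _input_matrices, load_model, save_model
from gccasub.preprocess import assemble_dataset
from gccasub.simulate import simulate_cohort

from conftest import SMALL_GCCA, SMALL_NET, SMALL_SIM, make_survival, make_view


# ---------------------------------------------------------------------------
# independent oracle
# ---------------------------------------------------------------------------


def brute_force_gcca(outputs, r, rho, weights=None):
    """Dense textbook GCCA: center, P_v = Y^T (YY^T + rho I)^{-1} Y,
    eigendecompose sum(w P), residuals from the objective definition."""
    weights = weights or [1.0] * len(outputs)
    ys = [np.asarray(z) - np.asarray(z).mean(axis=1, keepdims=True) for z in outputs]
    n = ys[0].shape[1]
    m = np.zeros((n, n))
    for w, y in zip(weights, ys):
        c = y @ y.T + rho * np.eye(y.shape[0])
        m += w * (y.T @ np.linalg.inv(c) @ y)
    evals, evecs = np.linalg.eigh(m)
    g = evecs[:, ::-1][:, :r].T
    obj = 0.0
    for w, y in zip(weights, ys):
        u = np.linalg.inv(y @ y.T + rho * np.eye(y.shape[0])) @ y @ g.T
        obj += w * np.linalg.norm(g - u.T @ y) ** 2
    return g, float(obj), evals[::-1][:r]


def principal_angle(a, b):
    """Largest principal angle (radians) between the row spaces of a and b."""
    qa, _ = np.linalg.qr(a.T)
    qb, _ = np.linalg.qr(b.T)
    s = np.linalg.svd(qa.T @ qb, compute_uv=False)
    return float(np.arccos(np.clip(s.min(), -1.0, 1.0)))


class TestGccaSolve:
    def test_matches_brute_force_oracle(self, rng):
        outs = [rng.normal(size=(5, 20)) for _ in range(3)]
        cfg = GccaConfig(embedding_dim=2, view_rank=5, cov_reg=1e-6)
        sol = gcca_solve(outs, cfg=cfg)
        g0, obj0, ev0 = brute_force_gcca(outs, r=2, rho=1e-6)
        assert abs(sol.objective - obj0) <= 1e-8
        assert principal_angle(sol.G, g0) <= 1e-6
        np.testing.assert_allclose(sol.eigenvalues, ev0, atol=1e-8)

    def test_identical_views_degenerate(self, rng):
        x = rng.normal(size=(5, 20))
        cfg = GccaConfig(embedding_dim=2, view_rank=5, cov_reg=1e-10)
        sol = gcca_solve([x, x, x], cfg=cfg)
        assert sol.objective <= 1e-6
        np.testing.assert_allclose(sol.eigenvalues, 3.0, atol=1e-6)

    def test_orthonormal_rows(self, rng):
        outs = [rng.normal(size=(6, 15)) for _ in range(2)]
        sol = gcca_solve(outs, cfg=GccaConfig(embedding_dim=4, view_rank=6))
        np.testing.assert_allclose(sol.G @ sol.G.T, np.eye(4), atol=1e-10)

    def test_eigenvalues_bounded_by_view_count(self, rng):
        outs = [rng.normal(size=(4, 25)) for _ in range(3)]
        sol = gcca_solve(outs, cfg=GccaConfig(embedding_dim=10, view_rank=10))
        assert np.all(sol.eigenvalues >= -1e-10)
        assert np.all(sol.eigenvalues <= 3 + 1e-10)

    def test_objective_permutation_invariant(self, rng):
        outs = [rng.normal(size=(4, 12)) for _ in range(2)]
        cfg = GccaConfig(embedding_dim=2, view_rank=4)
        base = gcca_solve(outs, cfg=cfg).objective
        perm = rng.permutation(12)
        shuffled = gcca_solve([o[:, perm] for o in outs], cfg=cfg).objective
        assert abs(base - shuffled) <= 1e-8

    def test_two_view_matches_classical_cca(self, rng):
        """Leading canonical correlations agree with an SVD-based CCA."""
        x = rng.normal(size=(5, 40))
        y = 0.5 * x + 0.5 * rng.normal(size=(5, 40))
        rho = 1e-9
        sol = gcca_solve([x, y], cfg=GccaConfig(embedding_dim=3, view_rank=5,
                                                cov_reg=rho))
        # oracle: canonical correlations via whitened cross-covariance SVD
        xc = x - x.mean(1, keepdims=True)
        yc = y - y.mean(1, keepdims=True)
        sx = np.linalg.cholesky(np.linalg.inv(xc @ xc.T + rho * np.eye(5)))
        sy = np.linalg.cholesky(np.linalg.inv(yc @ yc.T + rho * np.eye(5)))
        cors = np.linalg.svd(sx.T @ (xc @ yc.T) @ sy, compute_uv=False)[:3]
        # for two views the eigenvalues of M relate to canonical corr: 1 + cor
        np.testing.assert_allclose(sol.eigenvalues, 1 + cors, atol=1e-6)

    def test_fewer_than_two_views_rejected(self, rng):
        with pytest.raises(ValueError, match="2 views"):
            gcca_solve([rng.normal(size=(3, 5))])

    def test_embedding_dim_exceeding_samples_rejected(self, rng):
        with pytest.raises(ValueError, match="exceeds"):
            gcca_solve([rng.normal(size=(3, 4))] * 2,
                       cfg=GccaConfig(embedding_dim=5, view_rank=5))


class TestGccaGradients:
    def test_matches_central_finite_differences(self, rng):
        outs = [rng.normal(size=(4, 12)) for _ in range(2)]
        cfg = GccaConfig(embedding_dim=2, view_rank=4, cov_reg=1e-6)
        _, grads, _ = gcca_loss_and_grads(outs, cfg=cfg)
        eps = 1e-6
        for v in range(2):
            num = np.zeros_like(outs[v])
            for i in range(4):
                for j in range(12):
                    hi = [o.copy() for o in outs]
                    lo = [o.copy() for o in outs]
                    hi[v][i, j] += eps
                    lo[v][i, j] -= eps
                    num[i, j] = (
                        gcca_solve(hi, cfg=cfg).objective
                        - gcca_solve(lo, cfg=cfg).objective
                    ) / (2 * eps)
            scale = max(np.abs(num).max(), 1e-12)
            assert np.abs(num - grads[v]).max() / scale <= 1e-4

    def test_zero_at_degenerate_optimum(self, rng):
        x = rng.normal(size=(4, 10))
        cfg = GccaConfig(embedding_dim=2, view_rank=4, cov_reg=1e-12)
        _, grads, _ = gcca_loss_and_grads([x, x], cfg=cfg)
        for g in grads:
            assert np.abs(g).max() <= 1e-6

    def test_envelope_formula_linear_in_view_weights(self, rng):
        """grads[v] equals 2 w_v (U U^T Y - U G) after centering; doubling a
        view's weight with G, U held fixed doubles its gradient."""
        outs = [rng.normal(size=(3, 8)) for _ in range(2)]
        cfg = GccaConfig(embedding_dim=2, view_rank=3)
        _, grads, sol = gcca_loss_and_grads(outs, cfg=cfg)
        ys = [o - o.mean(1, keepdims=True) for o in outs]
        for v in range(2):
            unit = 2 * (sol.U[v] @ (sol.U[v].T @ ys[v]) - sol.U[v] @ sol.G)
            unit -= unit.mean(1, keepdims=True)
            np.testing.assert_allclose(grads[v], unit, atol=1e-10)
            np.testing.assert_allclose(2.0 * unit, 2 * grads[v], atol=1e-10)


class TestViewNetwork:
    def test_identity_network_is_identity(self, rng):
        cfg = ViewNetworkConfig(hidden_units=3, output_units=3, activation="identity")
        net = ViewNetwork(3, cfg, rng)
        net.W1 = np.eye(3)
        net.W2 = np.eye(3)
        x = rng.normal(size=(3, 5))
        np.testing.assert_array_equal(net.forward(x), x)

    def test_relu_kills_negative_preactivations(self, rng):
        cfg = ViewNetworkConfig(hidden_units=4, output_units=2, activation="relu")
        net = ViewNetwork(3, cfg, rng)
        net.W1 = -np.abs(net.W1)
        net.b1[:] = -1.0
        net.b2[:] = 7.0
        x = np.abs(rng.normal(size=(3, 6)))
        np.testing.assert_allclose(net.forward(x), 7.0)

    @pytest.mark.parametrize("activation", ["tanh", "relu", "identity"])
    def test_backprop_matches_finite_differences(self, activation, rng):
        cfg = ViewNetworkConfig(hidden_units=5, output_units=3,
                                activation=activation, l1=0, l2=0)
        net = ViewNetwork(4, cfg, rng)
        x = rng.normal(size=(4, 3)) + 0.5  # keep relu units away from kinks
        target = rng.normal(size=(3, 3))

        def loss():
            return 0.5 * np.sum((net.forward(x) - target) ** 2)

        cache = {}
        dz = net.forward(x, cache) - target
        grads = net.backward(cache, dz)
        eps = 1e-6
        for name in ("W1", "b1", "W2", "b2"):
            w = getattr(net, name)
            num = np.zeros_like(w)
            it = np.nditer(w, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = w[idx]
                w[idx] = orig + eps
                hi = loss()
                w[idx] = orig - eps
                lo = loss()
                w[idx] = orig
                num[idx] = (hi - lo) / (2 * eps)
            scale = max(np.abs(num).max(), 1e-12)
            assert np.abs(num - grads[name]).max() / scale <= 1e-5, name

    def test_dimension_mismatch_rejected(self, rng):
        net = ViewNetwork(4, ViewNetworkConfig(hidden_units=3, output_units=2), rng)
        with pytest.raises(ValueError, match="input features"):
            net.forward(np.zeros((5, 2)))


class TestTraining:
    def test_deterministic_given_seed(self, small_cohort):
        m1 = train_dgcca(small_cohort.dataset, SMALL_NET, SMALL_GCCA)
        m2 = train_dgcca(small_cohort.dataset, SMALL_NET, SMALL_GCCA)
        assert m1.loss_history == m2.loss_history
        np.testing.assert_array_equal(m1.final_solution.G, m2.final_solution.G)

    def test_loss_history_length_and_finite(self, small_cohort):
        m = train_dgcca(small_cohort.dataset, SMALL_NET, SMALL_GCCA)
        assert len(m.loss_history) == SMALL_GCCA.epochs
        assert np.all(np.isfinite(m.loss_history))

    def test_loss_nonincreasing_at_suitable_rate(self, small_cohort):
        cfg = GccaConfig(embedding_dim=5, view_rank=10, epochs=10,
                         learning_rate=1e-2, seed=3)
        m = train_dgcca(small_cohort.dataset, SMALL_NET, cfg)
        h = np.array(m.loss_history)
        assert np.all(np.diff(h[1:]) <= 0.01 * h[1:-1])

    def test_linear_limit_reaches_closed_form(self):
        cohort = simulate_cohort(SMALL_SIM, n_samples=100,
                                 view_dims=(30, 20, 10), missing_view_rate=0.0)
        ds = cohort.dataset
        cfg = GccaConfig(embedding_dim=5, view_rank=30, cov_reg=1e-6,
                         epochs=20, seed=0)
        net = ViewNetworkConfig(hidden_units=35, output_units=30,
                                activation="identity", l1=0.0, l2=0.0)
        model = train_dgcca(ds, net, cfg)
        closed = gcca_solve(_input_matrices(ds), ds.presence, cfg)
        assert model.final_solution.objective <= 1.05 * closed.objective

    def test_embedding_shape_and_duplication_symmetry(self, rng):
        base = [make_view(rng.normal(size=(6, 15)), name=f"v{i}") for i in range(2)]
        surv = make_survival(15)
        ds = assemble_dataset(base, surv)
        cfg = GccaConfig(embedding_dim=3, view_rank=6, epochs=3, seed=0)
        net = ViewNetworkConfig(hidden_units=8, output_units=6)
        model = train_dgcca(ds, net, cfg)
        emb = embed_samples(model, ds)
        assert emb.shape == (15, 3)
        # duplicating every sample duplicates embedding rows
        dup_views = []
        for v in base:
            vals = np.hstack([v.values, v.values])
            dup = make_view(vals, name=v.name)
            dup_views.append(dup)
        surv2 = make_survival(30)
        ds2 = assemble_dataset(dup_views, surv2)
        emb2 = embed_samples(model, ds2)
        np.testing.assert_allclose(np.abs(emb2[:15]), np.abs(emb2[15:]), atol=1e-6)

    def test_r1_embedding_has_unit_norm(self, small_cohort):
        cfg = GccaConfig(embedding_dim=1, view_rank=10, epochs=2, seed=0)
        model = train_dgcca(small_cohort.dataset, SMALL_NET, cfg)
        emb = embed_samples(model, small_cohort.dataset)
        assert emb.shape[1] == 1
        np.testing.assert_allclose(np.linalg.norm(emb), 1.0, atol=1e-8)

    def test_feature_mismatch_rejected(self, small_cohort, rng):
        model = train_dgcca(small_cohort.dataset, SMALL_NET, SMALL_GCCA)
        wrong = [make_view(rng.normal(size=(5, 4)), name=v.name)
                 for v in small_cohort.dataset.views]
        ds = assemble_dataset(wrong, make_survival(4))
        with pytest.raises(ValueError, match="features"):
            embed_samples(model, ds)

    def test_checkpoint_round_trip(self, small_cohort, tmp_path):
        model = train_dgcca(small_cohort.dataset, SMALL_NET, SMALL_GCCA)
        p = tmp_path / "model.zip"
        save_model(model, p)
        back = load_model(p)
        emb1 = embed_samples(model, small_cohort.dataset)
        emb2 = embed_samples(back, small_cohort.dataset)
        np.testing.assert_array_equal(emb1, emb2)

    def test_missing_view_sample_leaves_other_view_covariance_untouched(self, rng):
        """A sample observed in only one view contributes nothing to the
        other views' centered matrices or covariances."""
        a = make_view(rng.normal(size=(4, 10)), name="a")
        b = make_view(rng.normal(size=(4, 10)), name="b")
        surv = make_survival(11)
        ds_small = assemble_dataset([a, b], make_survival(10))
        # add sample s10 observed only in view a
        a2 = make_view(np.hstack([a.values, rng.normal(size=(4, 1))]), name="a")
        ds_big = assemble_dataset([a2, b], surv)
        from gccasub.gcca import _prepare_views

        ys_small, _ = _prepare_views(
            _input_matrices(ds_small), ds_small.presence, 4
        )
        ys_big, _ = _prepare_views(_input_matrices(ds_big), ds_big.presence, 4)
        np.testing.assert_allclose(ys_big[1][:, :10], ys_small[1], atol=1e-12)
        assert np.all(ys_big[1][:, 10] == 0)
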