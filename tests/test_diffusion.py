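"""Schedule invariants, forward/reverse processes, D3PM posterior, losses."""

import numpy as np
import pytest

from pocketdiff.complexes import AtomTypeVocabulary
from pocketdiff.diffusion import (
    DiffusionState,
    NoiseSchedule,
    d3pm_transition_matrix,
    forward_diffuse_coords,
    forward_diffuse_types,
    reverse_step_coords,
    reverse_step_types,
    sample_com_free_noise,
    training_loss,
)


class TestNoiseSchedule:
    def test_variance_preserving_identity(self, schedule):
        assert np.allclose(schedule.alpha**2 + schedule.sigma**2, 1.0, atol=1e-12)

    def test_monotone_endpoints(self, schedule):
        assert np.all(np.diff(schedule.alpha) < 0)
        assert np.all(np.diff(schedule.sigma) > 0)
        assert schedule.alpha[0] == 1.0 and schedule.sigma[0] == 0.0
        assert schedule.sigma[-1] > 0.99

    def test_beta_range(self, schedule):
        assert np.all((schedule.beta >= 0) & (schedule.beta <= 1))

    def test_step_coefficients_consistent(self, schedule):
        # x_t = a_t x_{t-1} + s_t eps implies alpha_t = a_t alpha_{t-1}
        # and sigma_t^2 = a_t^2 sigma_{t-1}^2 + s_t^2
        for t in (1, 17, 50, 100):
            a, s2 = schedule.step_coeff(t)
            assert np.isclose(a * schedule.alpha[t - 1], schedule.alpha[t])
            assert np.isclose(
                a**2 * schedule.sigma[t - 1] ** 2 + s2, schedule.sigma[t] ** 2
            )


class TestForwardCoords:
    def test_t0_is_identity(self, schedule, rng):
        x0 = rng.normal(size=(8, 3))
        noise = rng.normal(size=(8, 3))
        assert np.allclose(forward_diffuse_coords(x0, 0, noise, schedule), x0)

    def test_zero_noise_scales_signal(self, schedule, rng):
        x0 = rng.normal(size=(5, 3))
        xt = forward_diffuse_coords(x0, 60, np.zeros_like(x0), schedule)
        assert np.allclose(xt, schedule.alpha[60] * x0)

    def test_out_of_range_step(self, schedule):
        with pytest.raises(ValueError):
            forward_diffuse_coords(np.zeros((2, 3)), 101, np.zeros((2, 3)), schedule)

    def test_marginal_variance_closed_form(self, schedule, rng):
        """Monte-Carlo variance of x_t matches alpha^2 Var(x0) + sigma^2."""
        t = 40
        x0 = np.array([1.7])
        draws = forward_diffuse_coords(
            x0, t, rng.standard_normal(100_000), schedule
        )
        expected = schedule.sigma[t] ** 2  # x0 fixed -> Var = sigma^2
        assert abs(draws.var() / expected - 1.0) < 0.02
        assert abs(draws.mean() - schedule.alpha[t] * 1.7) < 0.01


class TestD3PMMatrices:
    def test_beta_zero_identity(self):
        assert np.allclose(d3pm_transition_matrix(0.0, 5), np.eye(5))

    def test_beta_one_uniform(self):
        assert np.allclose(d3pm_transition_matrix(1.0, 4), np.full((4, 4), 0.25))

    def test_rows_stochastic(self, schedule, vocab):
        for t in range(0, 101, 10):
            Q = schedule.transition_matrix(t, vocab.K)
            assert np.allclose(Q.sum(axis=1), 1.0, atol=1e-12)
            assert np.all(Q >= 0)

    def test_invalid_beta(self):
        with pytest.raises(ValueError):
            d3pm_transition_matrix(1.5, 4)

    def test_cumulative_product_converges_to_uniform(self):
        """100 steps at beta=0.05 approach uniform at the closed-form rate.

        The uniform kernel's non-unit eigenvalue is (1-beta), so the residual
        after t steps is exactly (1 - 1/K)(1-beta)^t on the diagonal.
        """
        K = 19
        sch = NoiseSchedule(beta_min=0.05, beta_max=0.05)
        qbar = sch.cumulative_matrix(100, K)
        residual = (1.0 - 1.0 / K) * 0.95**100
        assert np.isclose(np.abs(qbar - 1.0 / K).max(), residual, atol=1e-12)
        assert np.abs(qbar - 1.0 / K).max() < 6e-3
        # against an explicit matrix-power oracle
        oracle = np.linalg.matrix_power(d3pm_transition_matrix(0.05, K), 100)
        assert np.allclose(qbar, oracle, atol=1e-12)


class TestForwardTypes:
    def test_t0_unchanged(self, schedule, vocab, rng):
        types0 = np.array([0, 3, 5, 1])
        lig = np.array([True] * 4)
        out = forward_diffuse_types(types0, 0, rng, schedule, vocab.K, lig)
        assert np.array_equal(out, types0)

    def test_pocket_atoms_never_change(self, schedule, vocab, rng):
        types0 = np.array([10, 11, 2, 4])
        lig = np.array([False, False, True, True])
        for t in (20, 100):
            out = forward_diffuse_types(types0, t, rng, schedule, vocab.K, lig)
            assert np.array_equal(out[:2], types0[:2])

    def test_empirical_marginal_matches_qbar_row(self, schedule, vocab):
        t = 70
        rng = np.random.default_rng(11)
        start = 4
        lig = np.array([True])
        draws = np.array([
            forward_diffuse_types(np.array([start]), t, rng, schedule, vocab.K, lig)[0]
            for _ in range(100_000)
        ])
        emp = np.bincount(draws, minlength=vocab.K) / draws.size
        expected = schedule.cumulative_matrix(t, vocab.K)[start]
        assert np.abs(emp - expected).max() < 0.01


class TestReverseCoords:
    def test_oracle_noise_recovers_x0_exactly(self, schedule, rng):
        """Iterating the posterior with the true noise returns x0."""
        x0 = rng.normal(size=(7, 3)) * 2
        for t_start in (1, 30, 100):
            eps = rng.standard_normal((7, 3))
            x = forward_diffuse_coords(x0, t_start, eps, schedule)
            for t in range(t_start, 0, -1):
                # oracle: the exact noise that links x_t to x0
                eps_t = (x - schedule.alpha[t] * x0) / max(schedule.sigma[t], 1e-300)
                x = reverse_step_coords(
                    x, eps_t, t, np.random.default_rng(0), schedule
                )
                # keep the zero-injected-noise deterministic path
            assert np.abs(x - x0).max() < 1e-6

    def test_final_step_injects_no_noise(self, schedule, rng):
        x1 = rng.normal(size=(4, 3))
        eps = rng.normal(size=(4, 3))
        a = reverse_step_coords(x1, eps, 1, np.random.default_rng(1), schedule)
        b = reverse_step_coords(x1, eps, 1, np.random.default_rng(2), schedule)
        assert np.array_equal(a, b)

    def test_posterior_moments_match_closed_form(self, schedule):
        """Monte-Carlo mean/variance of x_{t-1} vs the Gaussian posterior."""
        t = 50
        x_t = np.array([[2.0, 0.0, -1.0]])
        eps_hat = np.array([[0.3, -0.2, 0.5]])
        rng = np.random.default_rng(5)
        draws = np.array([
            reverse_step_coords(x_t, eps_hat, t, rng, schedule)
            for _ in range(100_000)
        ])[:, 0, :]
        a, s2 = schedule.step_coeff(t)
        sig2, sigp2 = schedule.sigma[t] ** 2, schedule.sigma[t - 1] ** 2
        x0_hat = (x_t - schedule.sigma[t] * eps_hat) / schedule.alpha[t]
        mean = (a * sigp2 / sig2) * x_t + (schedule.alpha[t - 1] * s2 / sig2) * x0_hat
        var = sigp2 * s2 / sig2
        assert np.abs(draws.mean(axis=0) - mean[0]).max() < 0.02 * max(1, np.abs(mean).max())
        # injected noise is zero-CoM projected over the single...
        assert np.allclose(draws.var(axis=0), 0.0, atol=var * 1.2)

    def test_requires_t_at_least_one(self, schedule):
        with pytest.raises(ValueError):
            reverse_step_coords(np.zeros((2, 3)), np.zeros((2, 3)), 0,
                                np.random.default_rng(0), schedule)


def brute_force_type_posterior(schedule, K, t, s_t, p0):
    """Enumerate q(s_{t-1} | s_t, s0) weighted by p0 over all s0."""
    Qt = schedule.transition_matrix(t, K)
    Qbar_t = schedule.cumulative_matrix(t, K)
    Qbar_p = schedule.cumulative_matrix(t - 1, K)
    post = np.zeros(K)
    for j in range(K):
        for s0 in range(K):
            post[j] += p0[s0] * Qt[j, s_t] * Qbar_p[s0, j] / Qbar_t[s0, s_t]
    return post / post.sum()


class TestReverseTypes:
    def test_beta_zero_chain_never_changes(self, rng):
        sch = NoiseSchedule(beta_min=0.0, beta_max=0.0)
        types = np.array([2, 1, 3])
        logits = rng.normal(size=(3, 4))
        lig = np.array([True, True, True])
        for t in (60, 3):
            out = reverse_step_types(types, logits, t, rng, sch, lig)
            assert np.array_equal(out, types)

    def test_one_hot_logits_at_t1_return_same_types(self, schedule, rng):
        types = np.array([3, 0])
        logits = np.full((2, 5), -30.0)
        logits[0, 3] = 30.0
        logits[1, 0] = 30.0
        lig = np.array([True, True])
        out = reverse_step_types(types, logits, 1, rng, schedule, lig)
        assert np.array_equal(out, types)

    def test_posterior_matches_enumeration_K4(self, schedule):
        """Sampled frequencies match the brute-force Bayes posterior."""
        K, t, s_t = 4, 35, 2
        logits = np.array([[0.4, -1.0, 2.0, 0.1]])
        p0 = np.exp(logits[0] - logits[0].max())
        p0 /= p0.sum()
        expected = brute_force_type_posterior(schedule, K, t, s_t, p0)
        rng = np.random.default_rng(3)
        draws = np.array([
            reverse_step_types(np.array([s_t]), logits, t, rng, schedule,
                               np.array([True]))[0]
            for _ in range(40_000)
        ])
        emp = np.bincount(draws, minlength=K) / draws.size
        assert np.abs(emp - expected).max() < 0.01

    def test_pocket_types_untouched(self, schedule, rng):
        types = np.array([7, 2])
        logits = rng.normal(size=(2, 19))
        lig = np.array([False, True])
        out = reverse_step_types(types, logits, 50, rng, schedule, lig)
        assert out[0] == 7


class TestDiffusionState:
    def test_fixed_types_enforced(self):
        lig = np.array([False, True])
        DiffusionState(np.zeros((2, 3)), np.array([5, 1]), 10, lig)
        state = DiffusionState(np.zeros((2, 3)), np.array([5, 1]), 10, lig)
        with pytest.raises(ValueError):
            DiffusionState(np.zeros((2, 3)), np.array([4, 1]), 9, lig,
                           fixed_types=state.fixed_types)


class TestTrainingLoss:
    def test_zero_output_model_gives_chi_square_coords_loss(
        self, fixture_complex, schedule, vocab, tiny_model
    ):
        """Freshly initialised head outputs zero noise; E||eps||^2 ~ 3/atom."""
        cx = fixture_complex.centered()
        rng = np.random.default_rng(0)
        vals = [
            float(training_loss(tiny_model, cx, 50, rng, schedule, vocab)[1].data)
            for _ in range(60)
        ]
        n = cx.n_atoms
        # CoM projection removes 3 dof: E mean ||eps||^2 = 3 (n-1)/n
        assert abs(np.mean(vals) - 3.0 * (n - 1) / n) < 0.25

    def test_perfect_predictions_zero_loss(self, fixture_complex, schedule, vocab):
        """An oracle that outputs the true noise and one-hot true types."""
        cx = fixture_complex.centered()
        types0 = cx.type_indices(vocab)

        class Oracle:
            def forward(self, feats, coords, t, n_steps):
                from pocketdiff.nn import Tensor

                eps = (coords - schedule.alpha[t] * cx.coords) / max(
                    schedule.sigma[t], 1e-300
                )
                logits = np.full((cx.n_atoms, vocab.K), -40.0)
                logits[np.arange(cx.n_atoms), types0] = 40.0
                return Tensor(eps), Tensor(logits)

        rng = np.random.default_rng(1)
        _, lc, lt = training_loss(Oracle(), cx, 30, rng, schedule, vocab)
        assert float(lc.data) < 1e-20
        assert float(lt.data) < 1e-6

    def test_degenerate_mask_warns_and_zeroes(self, schedule, vocab, tiny_model):
        from pocketdiff.complexes import AtomRecord, MolecularComplex

        pocket_only = MolecularComplex([
            AtomRecord(0, "C", "SC_C", [0, 0, 0], 0, "sidechain"),
            AtomRecord(1, "N", "SC_N", [1.4, 0, 0], 0, "sidechain"),
        ])
        rng = np.random.default_rng(0)
        with pytest.warns(UserWarning):
            total, lc, lt = training_loss(
                tiny_model, pocket_only, 10, rng, schedule, vocab,
                diffuse_pocket_coords=False,
            )
        assert float(total.data) == 0.0

    def test_com_free_noise_has_zero_mean(self, rng):
        eps = sample_com_free_noise(rng, 12)
        assert np.abs(eps.mean(axis=0)).max() < 1e-12

    def test_training_config_from_yaml(self, tmp_path):
        from pocketdiff.diffusion import TrainingConfig

        path = tmp_path / "train.yaml"
        path.write_text("n_steps: 123\nlr: 0.01\nlam: 2.0\nseed: 9\n")
        cfg = TrainingConfig.from_yaml(path)
        assert (cfg.n_steps, cfg.lr, cfg.lam, cfg.seed) == (123, 0.01, 2.0, 9)
        bad = tmp_path / "bad.yaml"
        bad.write_text("learning_rate: 0.01\n")
        with pytest.raises(ValueError):
            TrainingConfig.from_yaml(bad)
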