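"""Diffusion schedule, forward/posterior closed forms and the prior."""

import numpy as np
import pytest

from genoface.autodiff import Tensor
from genoface.diffusion import (DiffusionSchedule, PriorNet, PriorNetSpec,
                                PriorTrainConfig, make_schedule,
                                posterior_params, prior_loss, q_sample,
                                sample_prior, train_prior)


class TestSchedule:
    def test_single_step_schedule(self):
        s = DiffusionSchedule(betas=np.array([0.5]))
        assert s.T == 1
        assert np.allclose(s.alpha_bars, [0.5])

    def test_default_linear_schedule_ends_near_zero(self):
        s = make_schedule(1000)  # linear 1e-4 .. 0.02
        assert s.abar(1000) < 1e-4
        assert np.all(np.diff(s.alpha_bars) < 0)

    @pytest.mark.parametrize("kind", ["linear", "cosine"])
    def test_alpha_bars_strictly_decreasing(self, kind):
        s = make_schedule(100, kind)
        assert np.all(np.diff(s.alpha_bars) < 0)
        assert np.all((s.betas > 0) & (s.betas < 1))

    def test_invalid_schedules_rejected(self):
        with pytest.raises(ValueError):
            make_schedule(0)
        with pytest.raises(ValueError):
            DiffusionSchedule(betas=np.array([0.0, 0.5]))


class TestForwardProcess:
    def test_t_zero_returns_input_exactly(self):
        s = make_schedule(10)
        z0 = np.arange(4.0)
        assert np.array_equal(q_sample(z0, 0, s, np.random.default_rng(0)), z0)

    def test_marginal_moments_match_closed_form(self):
        s = make_schedule(50)
        z0 = np.array([1.5, -2.0])
        t = 20
        rng = np.random.default_rng(1)
        draws = np.stack([q_sample(z0, t, s, rng) for _ in range(100_000)])
        ab = s.abar(t)
        want_mean = np.sqrt(ab) * z0
        sd = np.sqrt(1 - ab)
        assert np.all(np.abs(draws.mean(0) - want_mean) < 4 * sd / np.sqrt(len(draws)))
        assert np.all(np.abs(draws.var(0) / (1 - ab) - 1) < 0.05)

    def test_iterated_single_steps_match_one_shot_marginal(self):
        s = make_schedule(8, beta_start=0.05, beta_end=0.3)
        z0 = np.array([2.0])
        t = 8
        rng = np.random.default_rng(2)
        n = 100_000
        z = np.repeat(z0[None], n, axis=0)
        for step in range(1, t + 1):
            b = s.betas[step - 1]
            z = np.sqrt(1 - b) * z + np.sqrt(b) * rng.standard_normal(z.shape)
        ab = s.abar(t)
        assert abs(z.mean() - np.sqrt(ab) * z0[0]) < 4 * np.sqrt((1 - ab) / n)
        assert abs(z.var() / (1 - ab) - 1) < 0.05

    def test_out_of_range_t_rejected(self):
        s = make_schedule(5)
        with pytest.raises(IndexError):
            q_sample(np.zeros(2), 6, s, np.random.default_rng(0))


class TestPosterior:
    def test_noise_free_point_maps_to_previous_marginal_mean(self):
        s = make_schedule(30)
        z0 = np.array([0.7, -1.2])
        for t in (2, 10, 30):
            zt = np.sqrt(s.abar(t)) * z0
            mean, var = posterior_params(z0, zt, t, s)
            assert np.allclose(mean, np.sqrt(s.abar(t - 1)) * z0, atol=1e-12)
            assert var >= 0

    def test_posterior_variance_never_exceeds_beta(self):
        s = make_schedule(100)
        for t in range(2, 101):
            _, var = posterior_params(np.zeros(1), np.zeros(1), t, s)
            assert var <= s.betas[t - 1] + 1e-15

    def test_two_step_exact_linear_gaussian_oracle(self):
        """Brute-force Gaussian conditioning of the 2-step joint must equal
        the implemented posterior at t = 2."""
        b1, b2 = 0.2, 0.4
        s = DiffusionSchedule(betas=np.array([b1, b2]))
        a1, a2 = np.sqrt(1 - b1), np.sqrt(1 - b2)
        z0, z2 = 1.3, -0.8
        # z1 | z0 ~ N(a1 z0, b1); z2 | z1 ~ N(a2 z1, b2)
        prec = 1 / b1 + a2**2 / b2
        var_oracle = 1 / prec
        mean_oracle = var_oracle * (a1 * z0 / b1 + a2 * z2 / b2)
        mean, var = posterior_params(np.array([z0]), np.array([z2]), 2, s)
        assert np.isclose(mean[0], mean_oracle, atol=1e-12)
        assert np.isclose(var, var_oracle, atol=1e-12)

    def test_final_step_is_deterministic_readout(self):
        s = make_schedule(10)
        z0 = np.array([3.0])
        mean, var = posterior_params(z0, np.array([99.0]), 1, s)
        assert np.array_equal(mean, z0) and var == 0.0


class _OracleNet:
    """Stub denoiser returning a fixed value regardless of input."""

    def __init__(self, value, latent):
        self.value = np.asarray(value, dtype=np.float64)
        self.spec = PriorNetSpec(latent=latent)

    def eval(self):
        return self

    def __call__(self, z_t, t, y, covariates=None, cov_mask=None):
        B = z_t.shape[0]
        return Tensor(np.tile(self.value, (B, 1)))


class TestPriorLossAndSampling:
    def test_oracle_net_returning_z0_has_zero_loss(self):
        rng = np.random.default_rng(3)
        z0 = rng.normal(size=(1, 4))
        net = _OracleNet(z0[0], latent=4)
        s = make_schedule(20)
        loss = prior_loss(net, z0, None, s, np.random.default_rng(4))
        assert float(loss.data) == 0.0

    def test_prior_loss_is_seed_deterministic(self):
        rng = np.random.default_rng(5)
        spec = PriorNetSpec(embed_dim=16, depth=1, heads=2, head_dim=8, latent=4)
        net = PriorNet(spec, rng).eval()
        z0 = rng.normal(size=(3, 4))
        y = rng.normal(size=(3, 4))
        s = make_schedule(20)
        a = float(prior_loss(net, z0, y, s, np.random.default_rng(9)).data)
        b = float(prior_loss(net, z0, y, s, np.random.default_rng(9)).data)
        assert a == b

    def test_constant_oracle_chain_converges_to_the_constant(self):
        c = np.array([0.3, -0.7, 1.1])
        net = _OracleNet(c, latent=3)
        s = make_schedule(30)
        out = sample_prior(net, np.zeros((2, 3)), s, np.random.default_rng(6))
        assert np.allclose(out, np.tile(c, (2, 1)))

    def test_sampling_is_seed_deterministic(self):
        rng = np.random.default_rng(7)
        spec = PriorNetSpec(embed_dim=16, depth=1, heads=2, head_dim=8, latent=4)
        net = PriorNet(spec, rng)
        y = rng.normal(size=(2, 4))
        s = make_schedule(15)
        a = sample_prior(net, y, s, np.random.default_rng(11))
        b = sample_prior(net, y, s, np.random.default_rng(11))
        assert np.array_equal(a, b)


class TestPriorTraining:
    def test_short_training_reduces_loss_and_respects_clipping(self):
        rng = np.random.default_rng(8)
        n, latent = 64, 4
        z_s = rng.normal(size=(n, latent))
        z_f = z_s @ rng.normal(size=(latent, latent)) * 0.5  # learnable map
        spec = PriorNetSpec(embed_dim=16, depth=1, heads=2, head_dim=8,
                            dropout=0.0, latent=latent)
        net = PriorNet(spec, rng)
        cfg = PriorTrainConfig(lr=3e-3, weight_decay=1e-3, steps=300,
                               batch_size=32, seed=0, ema_update_every=10)
        s = make_schedule(25)
        net, ema, hist = train_prior(z_f, z_s, net, s, cfg)
        assert np.mean(hist[-30:]) < 0.6 * np.mean(hist[:30])
        assert set(ema.shadow) == set(net.state_dict())
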