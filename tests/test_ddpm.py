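"""DDPM: forward marginals, epsilon loss, reverse step, outlier repair."""

import numpy as np
import pytest

from mrxform.data_io import Volume
from mrxform.ddpm import (
    ddpm_loss,
    ddpm_noise,
    ddpm_sample,
    posterior_variance,
    repair_outliers,
    reverse_step_mean,
)
from mrxform.ensemble_uq import summarize
from mrxform.nn.autodiff import Tensor
from mrxform.schedules import ddpm_linear

rng = np.random.default_rng(0)
SCHED = ddpm_linear(T=20, beta_min=5e-3, beta_max=0.25)


class TestForwardNoising:
    def test_early_step_with_tiny_beta_is_near_identity(self):
        tiny = ddpm_linear(T=10, beta_min=1e-6, beta_max=1e-5)
        y0 = rng.random((4, 4))
        eps = rng.standard_normal((4, 4))
        yt = ddpm_noise(y0, 1, tiny, eps)
        assert np.abs(yt - y0).max() < 0.01

    def test_alpha_bar_running_product_matches_direct_product(self):
        direct = np.array([np.prod(SCHED.alpha[:t]) for t in range(1, SCHED.T + 1)])
        np.testing.assert_allclose(SCHED.alpha_bar, direct, atol=1e-12)

    def test_alpha_bar_strictly_decreasing(self):
        assert np.all(np.diff(SCHED.alpha_bar) < 0)

    def test_out_of_range_step_rejected(self):
        with pytest.raises(ValueError):
            ddpm_noise(np.zeros((2, 2)), 0, SCHED, np.zeros((2, 2)))

    def test_monte_carlo_moments(self):
        y0 = np.full((4,), 0.6)
        t = 15
        ab = SCHED.alpha_bar[t - 1]
        draws = np.stack([
            ddpm_noise(y0, t, SCHED, e)
            for e in np.random.default_rng(5).standard_normal((10_000, 4))
        ])
        np.testing.assert_allclose(draws.mean(axis=0), np.sqrt(ab) * y0, atol=0.02)
        assert abs(draws.var(axis=0).mean() / (1 - ab) - 1) < 0.05


class TestLoss:
    def test_oracle_denoiser_zeroes_epsilon_term(self):
        x = rng.random((4, 1, 3, 3)).astype(np.float32)
        y0 = rng.random((4, 1, 3, 3)).astype(np.float32)
        eps = rng.standard_normal(y0.shape).astype(np.float32)
        t = np.array([2, 8, 14, 20])
        loss, eps_term, _ = ddpm_loss(lambda yt, xx, tt: eps, x, y0, SCHED, rng, t=t, eps=eps)
        assert abs(eps_term.item()) < 1e-10

    def test_zero_denoiser_gives_half_eps_norm_per_sample(self):
        x = rng.random((6, 1, 4, 4)).astype(np.float32)
        y0 = rng.random((6, 1, 4, 4)).astype(np.float32)
        eps = rng.standard_normal(y0.shape).astype(np.float32)
        t = np.array([1, 4, 8, 12, 16, 20])
        _, eps_term, _ = ddpm_loss(lambda yt, xx, tt: np.zeros_like(y0), x, y0, SCHED,
                                   rng, t=t, eps=eps)
        expected = 0.5 * (eps.astype(np.float64) ** 2).sum(axis=(1, 2, 3)).mean()
        np.testing.assert_allclose(eps_term.item(), expected, rtol=1e-4)
        # per pixel the expectation of |eps|^2 is 1
        n_pix = 16
        assert abs(eps_term.item() * 2 / n_pix - 1.0) < 0.5

    def test_zero_hybrid_weight_reduces_to_epsilon_loss(self):
        x = rng.random((3, 1, 3, 3)).astype(np.float32)
        y0 = rng.random((3, 1, 3, 3)).astype(np.float32)
        lv = Tensor(np.zeros(SCHED.T), requires_grad=True)
        loss, eps_term, vlb = ddpm_loss(
            lambda yt, xx, tt: np.zeros_like(y0), x, y0, SCHED,
            np.random.default_rng(3), hybrid_loss_weight=0.0, logvar_interp=lv,
        )
        assert vlb.item() == 0.0
        assert loss.item() == pytest.approx(eps_term.item())

    def test_hybrid_term_trains_logvar_only(self):
        x = rng.random((3, 1, 3, 3)).astype(np.float32)
        y0 = rng.random((3, 1, 3, 3)).astype(np.float32)
        lv = Tensor(np.zeros(SCHED.T), requires_grad=True)
        loss, _, vlb = ddpm_loss(
            lambda yt, xx, tt: np.zeros_like(y0), x, y0, SCHED,
            np.random.default_rng(3), hybrid_loss_weight=0.01, logvar_interp=lv,
        )
        from mrxform.nn import autodiff as ad
        g = ad.grad(vlb, lv)
        assert np.isfinite(g.data).all()
        assert np.abs(g.data).max() > 0


class TestReverse:
    def test_one_step_inversion_recovers_y0_exactly(self):
        """With the true epsilon and no reverse noise, the reverse-step mean
        algebraically inverts the forward noising at T=1."""
        one = ddpm_linear(T=1, beta_min=0.3, beta_max=0.3)
        y0 = rng.random((5, 5))
        eps = rng.standard_normal((5, 5))
        y1 = ddpm_noise(y0, 1, one, eps)
        back = reverse_step_mean(y1, eps, 1, one)
        np.testing.assert_allclose(back, y0, atol=1e-12)

    def test_posterior_variance_below_beta(self):
        pv = posterior_variance(SCHED)
        assert pv[0] == pytest.approx(0.0)
        assert np.all(pv <= SCHED.beta + 1e-15)

    def test_sampling_determinism_and_default_n(self):
        vol = Volume(data=np.random.default_rng(2).random((2, 6, 6)).astype(np.float32),
                     normalized=True)
        eta = lambda y, x, t: np.zeros_like(y)
        e1 = ddpm_sample(eta, vol, schedule=SCHED, n=4, seed=9)
        e2 = ddpm_sample(eta, vol, schedule=SCHED, n=4, seed=9)
        np.testing.assert_array_equal(e1.samples, e2.samples)
        import inspect
        from mrxform import ddpm as ddpm_mod
        from mrxform import cgan as cgan_mod
        assert inspect.signature(ddpm_mod.ddpm_sample).parameters["n"].default == 20
        assert inspect.signature(cgan_mod.sample_cgan).parameters["n"].default == 20


class TestRepair:
    def _ens(self, samples):
        return summarize(np.asarray(samples, np.float64))

    def test_constant_std_field_flags_nothing(self):
        base = rng.random((2, 4, 4))
        samples = np.stack([base + 0.01 * s for s in (-1, 0, 1, 2)])
        out = repair_outliers(self._ens(samples))
        assert out.repaired_pixels.sum() == 0
        np.testing.assert_array_equal(out.mean, self._ens(samples).mean)

    def test_planted_outlier_is_flagged_and_repaired(self):
        samples = np.full((20, 2, 6, 6), 0.5) + 0.01 * rng.standard_normal((20, 2, 6, 6))
        samples[3, 1, 2, 2] = 50.0
        ens = self._ens(samples)
        out = repair_outliers(ens)
        assert out.repaired_pixels[1, 2, 2]
        assert abs(out.mean[1, 2, 2] - 0.5) < 0.05
        # locality: untouched elsewhere
        untouched = ~out.repaired_pixels
        np.testing.assert_array_equal(out.mean[untouched], ens.mean[untouched])

    def test_repair_is_idempotent(self):
        samples = 0.5 + 0.02 * rng.standard_normal((10, 2, 5, 5))
        samples[0, 0, 1, 1] = 30.0
        once = repair_outliers(self._ens(samples))
        twice = repair_outliers(
            summarize(once.samples) if once.repaired_pixels is None else once, mask=None
        )
        np.testing.assert_array_equal(once.mean, twice.mean)
        np.testing.assert_array_equal(once.repaired_pixels, twice.repaired_pixels)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            repair_outliers(self._ens(rng.random((2, 2, 3, 3))))
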