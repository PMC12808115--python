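"""Score network: forward noising, score-matching loss, Langevin sampling."""

import numpy as np
import pytest

from mrxform.data_io import Volume
from mrxform.ncsn import langevin_chain, ncsn_loss, ncsn_noise, ncsn_sample
from mrxform.schedules import LangevinConfig, NoiseSchedule, ncsn_geometric

rng = np.random.default_rng(0)
SCHED = ncsn_geometric(T=20, sigma2_min=1e-3, sigma2_max=0.5)


class TestForwardNoising:
    def test_zero_noise_is_identity(self):
        y0 = rng.random((4, 4))
        for t in (1, 10, 20):
            np.testing.assert_array_equal(ncsn_noise(y0, t, SCHED, np.zeros_like(y0)), y0)

    def test_exact_formula_with_known_draw(self):
        y0 = rng.random((3, 3))
        eps = rng.standard_normal((3, 3))
        t = 7
        expected = y0 + np.sqrt(SCHED.beta[t - 1]) * eps
        np.testing.assert_allclose(ncsn_noise(y0, t, SCHED, eps), expected, rtol=1e-12)

    def test_out_of_range_step_rejected(self):
        y0 = np.zeros((2, 2))
        for t in (0, 21):
            with pytest.raises(ValueError):
                ncsn_noise(y0, t, SCHED, np.zeros_like(y0))

    def test_monte_carlo_moments_match_schedule(self):
        y0 = np.full((4,), 0.3)
        t = 12
        beta = SCHED.beta[t - 1]
        draws = np.stack([
            ncsn_noise(y0, t, SCHED, e) for e in np.random.default_rng(5).standard_normal((10_000, 4))
        ])
        assert abs(draws.var(axis=0).mean() / beta - 1) < 0.05
        np.testing.assert_allclose(draws.mean(axis=0), y0, atol=4 * np.sqrt(beta / 10_000) + 1e-3)


class TestLoss:
    def test_zero_at_analytic_optimum(self):
        """The score -(y_t - y_0)/beta_t is the exact minimizer: loss 0."""
        x = rng.random((5, 1, 4, 4)).astype(np.float32)
        y0 = rng.random((5, 1, 4, 4)).astype(np.float32)
        t = np.array([1, 3, 7, 12, 20])
        eps = rng.standard_normal(y0.shape).astype(np.float32)

        def oracle(yt, xx, tt):
            beta = SCHED.beta[np.asarray(tt) - 1].reshape(-1, 1, 1, 1)
            return -(yt - y0) / beta

        loss = ncsn_loss(oracle, x, y0, SCHED, rng, t=t, eps=eps)
        assert abs(loss.item()) < 1e-8

    def test_zero_score_gives_half_eps_norm(self):
        x = rng.random((4, 1, 3, 3)).astype(np.float32)
        y0 = rng.random((4, 1, 3, 3)).astype(np.float32)
        t = np.array([2, 5, 9, 15])
        eps = rng.standard_normal(y0.shape).astype(np.float32)
        loss = ncsn_loss(lambda yt, xx, tt: np.zeros_like(y0), x, y0, SCHED, rng, t=t, eps=eps)
        expected = 0.5 * (eps.astype(np.float64) ** 2).sum(axis=(1, 2, 3)).mean()
        np.testing.assert_allclose(loss.item(), expected, rtol=1e-4)

    def test_loss_nonnegative(self):
        x = rng.random((3, 1, 4, 4)).astype(np.float32)
        y0 = rng.random((3, 1, 4, 4)).astype(np.float32)
        for s in range(3):
            f = lambda yt, xx, tt: np.random.default_rng(s).standard_normal(yt.shape)
            assert ncsn_loss(f, x, y0, SCHED, np.random.default_rng(s)).item() >= 0

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            ncsn_loss(lambda *a: 0, np.zeros((0, 1, 2, 2)), np.zeros((0, 1, 2, 2)), SCHED, rng)


class TestLangevin:
    def test_step_size_formula(self):
        sched = NoiseSchedule(kind="ncsn_geometric", T=3, beta=np.array([0.01, 0.05, 0.2]))
        gamma = LangevinConfig(lambda_gamma=0.1).gamma(sched)
        assert gamma[0] == pytest.approx(0.1)  # lambda_gamma * beta_1/beta_1
        np.testing.assert_allclose(gamma, 0.1 * sched.beta / 0.01)

    def test_nonpositive_step_scale_rejected(self):
        with pytest.raises(ValueError):
            LangevinConfig(lambda_gamma=0.0).gamma(SCHED)

    def test_point_mass_oracle_convergence(self):
        """With the analytic score of a point mass at y*, annealed Langevin
        lands on y* up to the final-level noise floor."""
        ystar = np.random.default_rng(3).random((1, 1, 4, 4)).astype(np.float32)
        sched = ncsn_geometric(T=50, sigma2_min=1e-4, sigma2_max=1.0)

        def score(y, x, t):
            beta = sched.beta[np.asarray(t) - 1].reshape(-1, 1, 1, 1)
            return -(y - ystar) / beta

        shape = (50, 1, 4, 4)  # 50 independent chains
        chains = langevin_chain(score, None, sched, LangevinConfig(seed=0),
                                np.random.default_rng(7), shape)
        endpoint_mean = chains.mean(axis=0)
        assert np.abs(endpoint_mean - ystar[0]).max() < 0.05

    def test_gaussian_target_stationary_moments(self):
        """Fixed-level Langevin with the analytic Gaussian score: stationary
        mean mu and variance sigma^2 + gamma/2 (AR(1) closed form), checked
        by brute-force long-chain simulation on a 4-pixel image."""
        mu, sig2 = 0.4, 0.02
        gamma = 0.004
        local = np.random.default_rng(11)
        y = np.zeros((500, 4))
        burn, keep = 200, 800
        acc = []
        for it in range(burn + keep):
            y = y + gamma * (-(y - mu) / sig2) + np.sqrt(2 * gamma) * local.standard_normal(y.shape)
            if it >= burn:
                acc.append(y.copy())
        acc = np.concatenate(acc)
        expected_var = sig2 + gamma / 2  # O(gamma) discretization inflation
        assert abs(acc.mean() - mu) < 0.01
        assert abs(acc.var() / expected_var - 1) < 0.05

    def test_sampling_determinism_and_contract(self):
        vol = Volume(data=np.random.default_rng(1).random((2, 8, 8)).astype(np.float32),
                     normalized=True)
        sched = ncsn_geometric(T=10, sigma2_min=1e-3, sigma2_max=0.3)
        score = lambda y, x, t: np.zeros_like(y)
        with pytest.raises(ValueError):
            ncsn_sample(score, vol, schedule=sched, n=0)
        e1 = ncsn_sample(score, vol, schedule=sched, n=3, seed=4)
        e2 = ncsn_sample(score, vol, schedule=sched, n=3, seed=4)
        np.testing.assert_array_equal(e1.samples, e2.samples)
        assert e1.samples.shape == (3, 2, 8, 8)


def test_geometric_schedule_invariants():
    s = ncsn_geometric(T=30, sigma2_min=1e-4, sigma2_max=2.0)
    assert np.all(np.diff(s.beta) > 0)
    assert s.beta[0] == pytest.approx(1e-4)
    assert s.beta[-1] == pytest.approx(2.0)
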