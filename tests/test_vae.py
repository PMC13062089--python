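"""Masked VAE: KL oracle, masked likelihood, reconstruction contracts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ecgrecon.errors import InvalidArgumentError, InvalidStateError
from ecgrecon.vae import (
    GaussianParams, MaskedVAE, VAEConfig, decode, encode, kl_divergence,
    load_vae, reconstruct, reparameterize, save_vae, train_vae, vae_loss,
)
from tests.conftest import make_masked_records

SMALL = VAEConfig(latent_dim=8, hidden_channels=(8, 16), epochs=2,
                  batch_size=4, seed=0, t_len=256)


@pytest.fixture(scope="module")
def small_model():
    data = make_masked_records(8, 70, [0.3])
    model, _ = train_vae(data, SMALL)
    return model


class TestReparameterize:
    def test_zero_eps_returns_mean(self):
        p = GaussianParams(np.array([1.0, -2.0]), np.array([0.5, 3.0]))
        assert np.array_equal(reparameterize(p, np.zeros(2)), p.mean)

    def test_standard_normal_case(self):
        p = GaussianParams(np.zeros(3), np.ones(3))
        eps = np.array([0.3, -1.2, 4.0])
        assert np.array_equal(reparameterize(p, eps), eps)

    def test_elementwise_arithmetic(self):
        p = GaussianParams(np.array([1.0, 2.0]), np.array([0.5, 2.0]))
        assert np.allclose(reparameterize(p, np.array([1.0, -1.0])),
                           [1.5, 0.0])

    def test_length_mismatch(self):
        p = GaussianParams(np.zeros(2), np.ones(2))
        with pytest.raises(InvalidArgumentError):
            reparameterize(p, np.zeros(3))


class TestKLDivergence:
    def test_prior_equals_posterior(self):
        assert kl_divergence(GaussianParams(np.zeros(5), np.ones(5))) == 0.0

    def test_unit_mean_shift(self):
        assert kl_divergence(GaussianParams(np.array([1.0]),
                                            np.array([1.0]))) == 0.5

    def test_matches_monte_carlo(self):
        """Closed form vs a 10^6-sample MC estimate of E_q[ln q - ln p]."""
        mu = np.array([0.3, -0.2])
        sd = np.array([0.8, 1.5])
        closed = kl_divergence(GaussianParams(mu, sd))
        rng = np.random.default_rng(0)
        z = mu + sd * rng.standard_normal((1_000_000, 2))
        log_q = -0.5 * (((z - mu) / sd) ** 2 + np.log(2 * np.pi)
                        + 2 * np.log(sd)).sum(axis=1)
        log_p = -0.5 * (z ** 2 + np.log(2 * np.pi)).sum(axis=1)
        samples = log_q - log_p
        se = samples.std(ddof=1) / 1000.0
        assert abs(closed - samples.mean()) < 3 * se

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(mu=st.lists(st.floats(-3, 3), min_size=1, max_size=4),
           log_sd=st.lists(st.floats(-1.5, 1.5), min_size=1, max_size=4))
    def test_non_negative_with_equality_iff_standard(self, mu, log_sd):
        k = min(len(mu), len(log_sd))
        p = GaussianParams(np.array(mu[:k]), np.exp(np.array(log_sd[:k])))
        kl = kl_divergence(p)
        assert kl >= -1e-12
        if np.allclose(p.mean, 0) and np.allclose(p.std, 1):
            assert kl == pytest.approx(0.0, abs=1e-12)

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(InvalidArgumentError):
            kl_divergence(GaussianParams(np.zeros(1), np.zeros(1)))


class TestVaeLoss:
    def test_exact_mean_unit_variance_full_mask(self):
        """mu = x, sigma = 1, beta = 0: L = (T*L/2) ln(2 pi)."""
        t_len, n_leads = 6, 2
        x = np.random.default_rng(0).random((t_len, n_leads))
        recon = GaussianParams(x.copy(), np.ones_like(x))
        post = GaussianParams(np.zeros(3), np.ones(3))
        loss = vae_loss(x, np.ones_like(x), recon, post, beta=0.0)
        assert loss == pytest.approx(t_len * n_leads / 2 * np.log(2 * np.pi))

    def test_empty_mask_gives_pure_kl(self):
        x = np.zeros((4, 2))
        recon = GaussianParams(np.ones_like(x), np.ones_like(x))
        post = GaussianParams(np.array([1.0]), np.array([1.0]))
        loss = vae_loss(x, np.zeros_like(x), recon, post, beta=1.0)
        assert loss == pytest.approx(kl_divergence(post))

    def test_two_point_hand_oracle(self):
        """x = [0.5, 0.7], mu = [0.5, 0.5], sigma = 1: recon = ln(2pi) + 0.02."""
        x = np.array([[0.5], [0.7]])
        recon = GaussianParams(np.array([[0.5], [0.5]]), np.ones((2, 1)))
        post = GaussianParams(np.zeros(1), np.ones(1))
        loss = vae_loss(x, np.ones_like(x), recon, post, beta=0.0)
        assert loss == pytest.approx(np.log(2 * np.pi) + 0.02)

    def test_invariant_to_values_at_missing_positions(self):
        rng = np.random.default_rng(1)
        x = rng.random((8, 3))
        mask = (rng.random((8, 3)) > 0.5).astype(float)
        recon = GaussianParams(rng.random((8, 3)), np.ones((8, 3)) * 0.7)
        post = GaussianParams(rng.standard_normal(4), np.ones(4))
        base = vae_loss(x, mask, recon, post)
        x2 = x.copy()
        x2[mask == 0] = 99.0
        assert vae_loss(x2, mask, recon, post) == pytest.approx(base)

    def test_beta_monotonicity(self):
        rng = np.random.default_rng(2)
        x = rng.random((8, 3))
        recon = GaussianParams(rng.random((8, 3)), np.ones((8, 3)))
        post = GaussianParams(rng.standard_normal(4) + 0.5, np.ones(4) * 2)
        losses = [vae_loss(x, np.ones_like(x), recon, post, beta=b)
                  for b in (0.0, 0.5, 1.0, 2.0)]
        assert np.all(np.diff(losses) >= 0)

    def test_negative_beta_rejected(self):
        x = np.zeros((2, 1))
        g = GaussianParams(np.zeros((2, 1)), np.ones((2, 1)))
        with pytest.raises(InvalidArgumentError):
            vae_loss(x, np.ones_like(x), g,
                     GaussianParams(np.zeros(1), np.ones(1)), beta=-1.0)


class TestEncodeDecode:
    def test_encoder_deterministic(self, small_model):
        x = np.random.default_rng(3).random((256, 12))
        m = np.ones((256, 12))
        a = encode(x, m, small_model)
        b = encode(x, m, small_model)
        assert np.array_equal(a.mean, b.mean)
        assert np.array_equal(a.std, b.std)

    def test_sigma_positive_on_random_inputs(self, small_model):
        rng = np.random.default_rng(4)
        for _ in range(50):
            x = rng.random((256, 12))
            m = (rng.random((256, 12)) > 0.3).astype(float)
            assert (encode(x * m, m, small_model).std > 0).all()

    def test_all_missing_mask_finite(self, small_model):
        post = encode(np.zeros((256, 12)), np.zeros((256, 12)), small_model)
        assert np.isfinite(post.mean).all()
        assert np.isfinite(post.std).all()

    def test_decode_shape_and_extreme_latents(self, small_model):
        for val in (-10.0, 10.0):
            out = decode(np.full(8, val), small_model)
            assert out.mean.shape == (256, 12)
            assert np.isfinite(out.mean).all()

    def test_decode_wrong_latent_length(self, small_model):
        with pytest.raises(InvalidArgumentError):
            decode(np.zeros(9), small_model)


class TestReconstructTrain:
    def test_full_mask_copies_input(self, small_model):
        x = np.random.default_rng(5).random((256, 12))
        m = np.ones((256, 12))
        assert np.array_equal(reconstruct(x, m, small_model), x)

    def test_mean_policy_deterministic(self, small_model):
        rng = np.random.default_rng(6)
        x = rng.random((256, 12))
        m = (rng.random((256, 12)) > 0.3).astype(float)
        a = reconstruct(x * m, m, small_model, eps_policy="mean")
        b = reconstruct(x * m, m, small_model, eps_policy="mean")
        assert np.array_equal(a, b)

    def test_untrained_model_rejected(self):
        model = MaskedVAE(SMALL)
        with pytest.raises(InvalidStateError):
            reconstruct(np.zeros((256, 12)), np.ones((256, 12)), model)

    def test_empty_training_set_rejected(self):
        with pytest.raises(InvalidArgumentError):
            train_vae([], SMALL)

    def test_seeded_retrain_identical(self):
        data = make_masked_records(4, 80, [0.3])
        _, t1 = train_vae(data, SMALL)
        _, t2 = train_vae(data, SMALL)
        assert t1 == t2

    def test_single_record_overfit_loss_decreases(self):
        data = make_masked_records(1, 90, [0.3])
        cfg = VAEConfig(latent_dim=8, hidden_channels=(8, 16), epochs=10,
                        batch_size=1, seed=1, t_len=256)
        _, trace = train_vae(data, cfg)
        assert trace[-1] < trace[0]

    def test_checkpoint_roundtrip(self, small_model, tmp_path):
        path = str(tmp_path / "vae.npz")
        save_vae(small_model, path)
        back = load_vae(path)
        x = np.random.default_rng(7).random((256, 12))
        m = (np.random.default_rng(8).random((256, 12)) > 0.3).astype(float)
        assert np.array_equal(reconstruct(x * m, m, small_model),
                              reconstruct(x * m, m, back))
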