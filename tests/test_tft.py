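"""TFT components: GRN, variable selection, attention, quantile machinery."""

import numpy as np
import pytest

from ecgrecon.errors import (
    DegenerateAttentionError, InvalidArgumentError, InvalidStateError,
)
from ecgrecon.nn import Tensor
from ecgrecon.tft import (
    ECGImputerTFT, GRN, InterpretableMHA, TFTConfig, cardiac_phase_encoding,
    load_tft, monotone_rearrange, pinball_loss, save_tft, tft_loss,
    tft_reconstruct, train_tft,
)
from tests.conftest import make_masked_records

TINY = TFTConfig(d_model=8, d_attn=4, n_heads=2, grn_hidden=8, epochs=2,
                 batch_size=4, seed=0, t_obs=256, tau_max=128)


def zero_weights(module):
    for p in module.parameters():
        p.data = np.zeros_like(p.data)


class TestConfig:
    def test_median_required(self):
        with pytest.raises(InvalidArgumentError):
            TFTConfig(quantiles=(0.1, 0.9)).validate()

    def test_quantiles_in_open_interval(self):
        with pytest.raises(InvalidArgumentError):
            TFTConfig(quantiles=(0.0, 0.5)).validate()


class TestGRN:
    def test_deterministic(self):
        grn = GRN(6, 8, 8, np.random.default_rng(0))
        x = Tensor(np.random.default_rng(1).standard_normal((3, 6)))
        assert np.array_equal(grn(x).data, grn(x).data)

    def test_zero_weights_reduce_to_layernorm_skip(self):
        """With every weight zero the gate closes: y = LayerNorm(x)."""
        grn = GRN(8, 8, 8, np.random.default_rng(0))
        zero_weights(grn)
        grn.norm.gamma.data = np.ones(8)  # restore LN affine
        x = Tensor(np.random.default_rng(2).standard_normal((4, 8)))
        expected = (x.data - x.data.mean(-1, keepdims=True)) / \
            np.sqrt(x.data.var(-1, keepdims=True) + 1e-5)
        assert np.allclose(grn(x).data, expected, atol=1e-6)

    def test_large_inputs_stay_finite(self):
        grn = GRN(6, 8, 8, np.random.default_rng(3))
        x = Tensor(np.random.default_rng(4).standard_normal((3, 6)) * 100)
        assert np.isfinite(grn(x).data).all()

    def test_context_branch_requires_construction(self):
        grn = GRN(6, 8, 8, np.random.default_rng(5))
        with pytest.raises(InvalidArgumentError):
            grn(Tensor(np.zeros((1, 6))), context=Tensor(np.zeros(8)))


class TestVariableSelect:
    def test_weights_sum_to_one(self):
        model = ECGImputerTFT(TINY)
        rng = np.random.default_rng(6)
        e = Tensor(rng.standard_normal((2, 5, 12, 8)))
        c_s, _ = model.static_contexts()
        _, v = model.variable_select(e, c_s)
        assert np.allclose(v.data.sum(axis=-1), 1.0, atol=1e-6)
        assert (v.data >= 0).all()

    def test_uniform_scores_give_uniform_weights(self):
        """Forcing the pre-softmax scores to a constant yields 1/12 each."""
        model = ECGImputerTFT(TINY)
        zero_weights(model.grn_v)
        model.grn_v.norm.beta.data = np.full(12, 3.0)  # constant logits
        e = Tensor(np.random.default_rng(7).standard_normal((1, 4, 12, 8)))
        c_s, _ = model.static_contexts()
        _, v = model.variable_select(e, c_s)
        assert np.allclose(v.data, 1.0 / 12, atol=1e-9)


class TestInterpretableMHA:
    def test_single_position_attends_fully(self):
        mha = InterpretableMHA(8, 4, 2, np.random.default_rng(0))
        x = Tensor(np.random.default_rng(1).standard_normal((1, 8)))
        out, weights = mha(x, x, x, return_weights=True)
        for w in weights:
            assert np.allclose(w, 1.0)
        expected = np.mean([ (x.data @ wv.w.data) for wv in mha.wv], axis=0)
        assert np.allclose(out.data, expected, atol=1e-9)

    def test_hand_computed_single_head(self):
        """m_H=1, d_attn=1, two positions: weights equal the softmax of the
        hand-computed scaled dot products."""
        mha = InterpretableMHA(1, 1, 1, np.random.default_rng(2))
        mha.wq[0].w.data = np.array([[2.0]])
        mha.wk[0].w.data = np.array([[1.5]])
        mha.wv[0].w.data = np.array([[1.0]])
        x = np.array([[1.0], [2.0]])
        out, weights = mha(Tensor(x), Tensor(x), Tensor(x),
                           return_weights=True)
        q, k = x * 2.0, x * 1.5
        scores = q @ k.T / np.sqrt(1.0)
        expected = np.exp(scores - scores.max(1, keepdims=True))
        expected /= expected.sum(1, keepdims=True)
        assert np.allclose(weights[0], expected)
        assert np.allclose(out.data, expected @ x)

    def test_masked_columns_exactly_zero(self):
        rng = np.random.default_rng(3)
        mha = InterpretableMHA(8, 4, 3, rng)
        for _ in range(100):
            x = Tensor(rng.standard_normal((5, 8)))
            key_mask = rng.random(5) < 0.4
            if key_mask.all():
                continue
            _, weights = mha(x, x, x, key_mask=key_mask, return_weights=True)
            for w in weights:
                assert np.all(w[:, key_mask] == 0.0)
                assert np.allclose(w.sum(axis=-1), 1.0)

    def test_all_masked_raises(self):
        mha = InterpretableMHA(8, 4, 2, np.random.default_rng(4))
        x = Tensor(np.zeros((3, 8)))
        with pytest.raises(DegenerateAttentionError):
            mha(x, x, x, key_mask=np.array([True, True, True]))

    def test_tied_heads_equal_single_head(self):
        """With all heads' projections tied, the mean equals one head."""
        rng = np.random.default_rng(5)
        mha = InterpretableMHA(8, 4, 3, rng)
        for lst in (mha.wq, mha.wk, mha.wv):
            for layer in lst[1:]:
                layer.w.data = lst[0].w.data.copy()
        single = InterpretableMHA(8, 4, 1, rng)
        single.wq[0].w.data = mha.wq[0].w.data.copy()
        single.wk[0].w.data = mha.wk[0].w.data.copy()
        single.wv[0].w.data = mha.wv[0].w.data.copy()
        x = Tensor(rng.standard_normal((6, 8)))
        assert np.allclose(mha(x, x, x).data, single(x, x, x).data)


class TestQuantileMachinery:
    @pytest.mark.parametrize("y,y_hat,q,expected", [
        (1.0, 1.0, 0.5, 0.0),
        (1.0, 0.0, 0.5, 0.5),
        (0.0, 1.0, 0.5, 0.5),
        (1.0, 0.0, 0.9, 0.9),
        (0.0, 1.0, 0.9, 0.1),
    ])
    def test_pinball_values(self, y, y_hat, q, expected):
        assert pinball_loss(y, y_hat, q) == pytest.approx(expected)

    def test_pinball_invalid_quantile(self):
        with pytest.raises(InvalidArgumentError):
            pinball_loss(1.0, 0.0, 1.0)

    @pytest.mark.parametrize("q", [0.1, 0.5, 0.9])
    def test_pinball_minimizer_is_empirical_quantile(self, q):
        """Brute-force grid search over 25-point samples: the minimizer of
        the mean pinball loss is the empirical q-quantile."""
        rng = np.random.default_rng(11)
        y = np.sort(rng.standard_normal(25))
        grid = np.linspace(y.min() - 1, y.max() + 1, 4001)
        mean_loss = np.array([
            np.mean(np.maximum(q * (y - g), (q - 1) * (y - g)))
            for g in grid])
        minimizer = grid[np.argmin(mean_loss)]
        empirical = np.quantile(y, q, method="inverted_cdf")
        assert abs(minimizer - empirical) <= (grid[1] - grid[0]) * 2 + 1e-9

    def test_tft_loss_hand_sum(self):
        """Residuals (0.2, -0.4) at q=0.5, both observed: 0.1 + 0.2 = 0.3."""
        targets = np.array([[0.2], [-0.4]])
        preds = np.zeros((2, 1, 1))
        assert tft_loss(targets, preds, np.ones((2, 1)), (0.5,)) == \
            pytest.approx(0.3)

    def test_tft_loss_zero_when_exact_or_unobserved(self):
        rng = np.random.default_rng(12)
        t = rng.random((4, 3))
        exact = np.repeat(t[..., None], 3, axis=-1)
        assert tft_loss(t, exact, np.ones((4, 3)), (0.1, 0.5, 0.9)) == 0.0
        wild = rng.random((4, 3, 3)) * 100
        assert tft_loss(t, wild, np.zeros((4, 3)), (0.1, 0.5, 0.9)) == 0.0

    def test_tft_loss_indicator_perturbation_invariance(self):
        rng = np.random.default_rng(13)
        t = rng.random((6, 2))
        preds = rng.random((6, 2, 3))
        mask = (rng.random((6, 2)) > 0.5).astype(float)
        base = tft_loss(t, preds, mask, (0.1, 0.5, 0.9))
        t2 = t.copy()
        t2[mask == 0] = -55.0
        assert tft_loss(t2, preds, mask, (0.1, 0.5, 0.9)) == pytest.approx(base)

    def test_monotone_rearrange_orders_quantiles(self):
        rng = np.random.default_rng(14)
        preds = rng.standard_normal((5, 3, 3))
        out = monotone_rearrange(preds)
        assert np.all(np.diff(out, axis=-1) >= 0)
        assert np.array_equal(np.sort(preds, axis=-1), out)

    def test_quantile_heads_zero_weights_give_bias(self):
        model = ECGImputerTFT(TINY)
        model.heads.w.data = np.zeros_like(model.heads.w.data)
        model.heads.b.data = np.arange(model.heads.b.data.size, dtype=float)
        theta = Tensor(np.random.default_rng(15).standard_normal((4, 8)))
        out = model.quantile_heads(theta, theta)
        expected = model.heads.b.data.reshape(12, 3)
        assert np.allclose(out.data, expected[None])


@pytest.fixture(scope="module")
def tiny_trained():
    data = make_masked_records(8, 60, [0.3])
    model, trace = train_tft(data, TINY)
    return model, trace, data


class TestReconstructAndTrain:
    def test_no_missing_copies_input(self, tiny_trained):
        model, _, data = tiny_trained
        rec, _ = data[0]
        full = np.ones_like(rec.signal)
        out, bands = tft_reconstruct(rec, full, model)
        assert np.array_equal(out.signal, rec.signal)
        assert np.array_equal(bands["low"], rec.signal)

    def test_deterministic_reconstruction(self, tiny_trained):
        model, _, data = tiny_trained
        rec, mask = data[1]
        masked = rec.copy_with(signal=rec.signal * mask.mask)
        a, _ = tft_reconstruct(masked, mask, model)
        b, _ = tft_reconstruct(masked, mask, model)
        assert np.array_equal(a.signal, b.signal)

    def test_observed_entries_copied(self, tiny_trained):
        model, _, data = tiny_trained
        rec, mask = data[2]
        masked = rec.copy_with(signal=rec.signal * mask.mask)
        out, bands = tft_reconstruct(masked, mask, model)
        obs = mask.mask.astype(bool)
        assert np.allclose(out.signal[obs], rec.signal[obs])
        assert np.all(bands["low"] <= bands["high"] + 1e-12)

    def test_long_gap_tiled_beyond_tau_max(self, tiny_trained):
        model, _, data = tiny_trained
        rec, _ = data[3]
        mask = np.ones_like(rec.signal)
        mask[40:40 + model.config.tau_max + 60] = 0.0  # longer than tau_max
        masked = rec.copy_with(signal=rec.signal * mask)
        out, _ = tft_reconstruct(masked, mask, model)
        assert np.isfinite(out.signal).all()

    def test_no_observed_context_raises(self, tiny_trained):
        model, _, data = tiny_trained
        rec, _ = data[0]
        with pytest.raises(DegenerateAttentionError):
            tft_reconstruct(rec.copy_with(signal=rec.signal * 0),
                            np.zeros_like(rec.signal), model)

    def test_untrained_model_rejected(self):
        model = ECGImputerTFT(TINY)
        with pytest.raises(InvalidStateError):
            tft_reconstruct(None, np.ones((4, 12)), model)

    def test_seeded_retrain_identical(self):
        data = make_masked_records(4, 65, [0.3])
        _, t1 = train_tft(data, TINY)
        _, t2 = train_tft(data, TINY)
        assert t1 == t2

    def test_single_record_overfit(self):
        data = make_masked_records(1, 66, [0.3])
        cfg = TFTConfig(d_model=8, d_attn=4, n_heads=2, grn_hidden=8,
                        epochs=40, batch_size=1, seed=2)
        _, trace = train_tft(data, cfg)
        assert trace[-1] < trace[0] * 0.5

    def test_checkpoint_roundtrip(self, tiny_trained, tmp_path):
        model, _, data = tiny_trained
        path = str(tmp_path / "tft.npz")
        save_tft(model, path)
        back = load_tft(path)
        rec, mask = data[4]
        masked = rec.copy_with(signal=rec.signal * mask.mask)
        a, _ = tft_reconstruct(masked, mask, model)
        b, _ = tft_reconstruct(masked, mask, back)
        assert np.array_equal(a.signal, b.signal)


class TestPhaseEncoding:
    def test_shape_and_unit_circle(self):
        rec_sig = np.zeros(600)
        enc = cardiac_phase_encoding(rec_sig, 250.0)
        assert enc.shape == (600, 48)  # 24 harmonics x (sin, cos)
        first = enc[:, [0, 24]]
        assert np.allclose((first ** 2).sum(axis=1), 1.0)

    def test_periodic_with_detected_beats(self):
        from ecgrecon.synth import generate_clean_ecg
        rec, ann = generate_clean_ecg(10, 500, 60, seed=0)
        enc = cardiac_phase_encoding(rec.lead("II"), 500.0)
        r = ann.r_peaks.astype(int)
        # the fundamental's phase at successive R peaks is equal (mod 2 pi)
        assert np.allclose(enc[r[1:-1], 0], enc[r[1], 0], atol=0.05)
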