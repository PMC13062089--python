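"""Temporal fusion transformer adapted to 12-lead ECG gap filling.

The network ingests a fixed-length window of the 12-lead signal together
with its observation mask.  Missing positions carry a learnable mask token
instead of a value embedding.  Per-timestep variable selection weighs the 12
leads (softmax over gated-residual-network scores conditioned on a static
lead context); a bidirectional LSTM pair encodes the sequence; interpretable
multi-head attention (head-averaged, with masked positions receiving exactly
zero weight so the model never attends INTO a gap) models long-range
structure; static enrichment and per-(quantile, lead) linear heads emit
quantile forecasts.  A cardiac-cycle-aware positional encoding (phase within
the RR interval from detected R peaks, plain sinusoid when no peaks are
found) replaces the standard position index.  Training minimizes the pinball
(quantile) loss over positions whose ground truth is available; the median
head is the point reconstruction and outer quantiles form the uncertainty
band (monotone-rearranged to remove quantile crossings).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .errors import (
    DegenerateAttentionError, InvalidArgumentError, InvalidStateError,
)
from .features import pan_tompkins
from .nn import Adam, Dense, GLU, LayerNorm, LSTM, Module, Tensor, concatenate
from .types import STANDARD_LEADS, ECGRecord, ObservationMask

__all__ = ["TFTConfig", "GRN", "InterpretableMHA", "ECGImputerTFT",
           "pinball_loss", "tft_loss", "monotone_rearrange",
           "cardiac_phase_encoding", "tft_reconstruct", "train_tft",
           "save_tft", "load_tft"]

# lead category codes: 0 = limb, 1 = augmented, 2 = precordial
LEAD_CATEGORY = {"I": 0, "II": 0, "III": 0, "aVR": 1, "aVL": 1, "aVF": 1,
                 "V1": 2, "V2": 2, "V3": 2, "V4": 2, "V5": 2, "V6": 2}


@dataclass
class TFTConfig:
    d_model: int = 16
    d_attn: int = 4
    n_heads: int = 4
    quantiles: tuple[float, ...] = (0.1, 0.5, 0.9)
    t_obs: int = 256           # window length processed per pass
    tau_max: int = 128         # longest gap chunk reconstructed per pass
    grn_hidden: int = 16
    dropout: float = 0.0
    learning_rate: float = 1e-3
    epochs: int = 12
    batch_size: int = 16
    seed: int = 0
    n_leads: int = 12

    def validate(self) -> None:
        if self.n_heads < 1:
            raise InvalidArgumentError("need at least one attention head")
        if not all(0 < q < 1 for q in self.quantiles):
            raise InvalidArgumentError("quantiles must lie in (0, 1)")
        if 0.5 not in self.quantiles:
            raise InvalidArgumentError("the median (0.5) must be among the quantiles")
        if self.tau_max < 1 or self.tau_max > self.t_obs:
            raise InvalidArgumentError("tau_max must lie in [1, t_obs]")


class GRN(Module):
    """Gated residual network:
    y = LayerNorm(skip(x) + GLU(dense2(ELU(dense1(x) + dense_c(context)))))."""

    def __init__(self, d_in: int, d_hidden: int, d_out: int,
                 rng: np.random.Generator, d_context: int | None = None):
        self.dense1 = Dense(d_in, d_hidden, rng)
        self.dense_c = (Dense(d_context, d_hidden, rng, bias=False)
                        if d_context else None)
        self.dense2 = Dense(d_hidden, d_out, rng)
        self.glu = GLU(d_out, d_out, rng)
        self.skip = Dense(d_in, d_out, rng, bias=False) if d_in != d_out else None
        self.norm = LayerNorm(d_out)

    def __call__(self, x: Tensor, context: Tensor | None = None) -> Tensor:
        h = self.dense1(x)
        if context is not None:
            if self.dense_c is None:
                raise InvalidArgumentError("GRN was built without a context branch")
            h = h + self.dense_c(context)
        h = self.glu(self.dense2(h.elu()))
        x_skip = self.skip(x) if self.skip is not None else x
        return self.norm(x_skip + h)


class InterpretableMHA(Module):
    """Head-averaged multi-head attention with exact-zero masked weights.

    Per head h: softmax(Q W_Q^h (K W_K^h)^T / sqrt(d_attn)) V W_V^h, with
    masked key positions excluded from the softmax entirely; the output is
    the mean over heads (shape ... x T_q x d_attn).
    """

    def __init__(self, d_model: int, d_attn: int, n_heads: int,
                 rng: np.random.Generator):
        self.d_attn = d_attn
        self.wq = [Dense(d_model, d_attn, rng, bias=False) for _ in range(n_heads)]
        self.wk = [Dense(d_model, d_attn, rng, bias=False) for _ in range(n_heads)]
        self.wv = [Dense(d_model, d_attn, rng, bias=False) for _ in range(n_heads)]

    def __call__(self, q_in: Tensor, k_in: Tensor, v_in: Tensor,
                 key_mask: np.ndarray | None = None,
                 return_weights: bool = False):
        """key_mask: boolean (..., T_k); True marks positions attention must
        NOT use.  Raises if every key is masked."""
        if key_mask is not None:
            key_mask = np.asarray(key_mask, dtype=bool)
            if key_mask.all(axis=-1).any():
                raise DegenerateAttentionError(
                    "all key positions masked for some query")
            keep = (~key_mask).astype(np.float64)
        outs, weights = [], []
        scale = self.d_attn ** -0.5
        for wq, wk, wv in zip(self.wq, self.wk, self.wv):
            scores = (wq(q_in) @ wk(k_in).swapaxes(-1, -2)) * scale
            if key_mask is None:
                attn = scores.softmax(axis=-1)
            else:
                shift = np.where(key_mask[..., None, :],
                                 -np.inf, scores.data).max(axis=-1, keepdims=True)
                e = (scores - shift).exp() * keep[..., None, :]
                attn = e / e.sum(axis=-1, keepdims=True)
            outs.append(attn @ wv(v_in))
            weights.append(attn)
        h_tilde = outs[0]
        for o in outs[1:]:
            h_tilde = h_tilde + o
        h_tilde = h_tilde * (1.0 / len(outs))
        if return_weights:
            return h_tilde, [w.data for w in weights]
        return h_tilde


def pinball_loss(y: float, y_hat: float, q: float) -> float:
    """Quantile loss p_q(u) = max(q*u, (q-1)*u) with u = y - y_hat."""
    if not 0 < q < 1:
        raise InvalidArgumentError("quantile must lie in (0, 1)")
    u = y - y_hat
    return float(np.maximum(q * u, (q - 1.0) * u))


def tft_loss(targets: np.ndarray, predictions: np.ndarray,
             mask: np.ndarray, quantiles: tuple[float, ...]) -> float:
    """Sum of pinball losses over (time, lead, quantile), gated by the
    availability indicator ``mask`` (entries with 0 contribute exactly 0)."""
    targets = np.asarray(targets, dtype=np.float64)
    predictions = np.asarray(predictions, dtype=np.float64)
    mask = np.asarray(mask, dtype=np.float64)
    if predictions.shape != targets.shape + (len(quantiles),):
        raise InvalidArgumentError(
            "predictions must have shape targets.shape + (n_quantiles,)")
    if mask.shape != targets.shape:
        raise InvalidArgumentError("mask must match the target shape")
    u = targets[..., None] - predictions
    q = np.asarray(quantiles)
    p = np.maximum(q * u, (q - 1.0) * u)
    return float((p * mask[..., None]).sum())


def _tft_loss_t(targets: Tensor, predictions: Tensor, mask: np.ndarray,
                quantiles: tuple[float, ...]) -> Tensor:
    u = targets.reshape(*targets.shape, 1) - predictions
    q = np.asarray(quantiles)
    from .nn import where
    p = where(u.data >= 0, u * q, u * (q - 1.0))
    return (p * mask[..., None]).sum() * (1.0 / max(1.0, mask.sum() * len(quantiles)))


def monotone_rearrange(predictions: np.ndarray) -> np.ndarray:
    """Sort the quantile axis (last) so bands never cross."""
    return np.sort(np.asarray(predictions), axis=-1)


N_PHASE_HARMONICS = 24


def cardiac_phase_encoding(lead_signal: np.ndarray, fs: float,
                           mask_col: np.ndarray | None = None) -> np.ndarray:
    """(T, 2K) Fourier features [sin k*phi, cos k*phi] of the beat phase.

    K harmonics of the phase within the RR interval let downstream linear
    layers compose sharp periodic morphology (narrow QRS bumps) directly.

    R peaks are detected on the supplied lead after linearly bridging masked
    gaps (``mask_col``: 1 = observed) and reflect-padding signals shorter
    than the detector's 2 s minimum; when fewer than two peaks are found the
    encoding falls back to a plain sinusoid at a nominal 75 bpm period.
    """
    lead_signal = np.asarray(lead_signal, dtype=np.float64)
    t_len = len(lead_signal)
    x = lead_signal.copy()
    if mask_col is not None:
        obs = np.asarray(mask_col) > 0
        if 0 < obs.sum() < t_len:
            t_idx = np.arange(t_len)
            x[~obs] = np.interp(t_idx[~obs], t_idx[obs], x[obs])
    pad = max(0, int(np.ceil(2 * fs)) - t_len + 1)
    try:
        if pad:
            padded = np.concatenate([x, x[::-1][:pad]])
            peaks = pan_tompkins(padded, fs)
            peaks = peaks[peaks < t_len]
        else:
            peaks = pan_tompkins(x, fs)
    except InvalidArgumentError:
        peaks = np.array([], dtype=int)
    idx = np.arange(t_len, dtype=np.float64)
    if len(peaks) >= 2:
        # beats hidden inside a bridged gap leave an anomalously long RR:
        # re-insert them at the median RR so the phase stays periodic
        med = float(np.median(np.diff(peaks)))
        filled = [int(peaks[0])]
        for a, b in zip(peaks, peaks[1:]):
            n_miss = int(round((b - a) / med)) - 1
            if (b - a) > 1.6 * med and n_miss >= 1:
                step = (b - a) / (n_miss + 1)
                filled.extend(int(round(a + step * j)) for j in range(1, n_miss + 1))
            filled.append(int(b))
        peaks = np.array(sorted(set(filled)))
    if len(peaks) < 2:
        phase = 2 * np.pi * idx * (75.0 / 60.0) / fs
        k = np.arange(1, N_PHASE_HARMONICS + 1)
        angles = phase[:, None] * k
        return np.concatenate([np.sin(angles), np.cos(angles)], axis=-1)
    else:
        phase = np.interp(idx, peaks, np.arange(len(peaks), dtype=np.float64),
                          left=np.nan, right=np.nan)
        # extrapolate the edges with the terminal RR intervals
        rr0 = peaks[1] - peaks[0]
        rr1 = peaks[-1] - peaks[-2]
        before = idx < peaks[0]
        after = idx > peaks[-1]
        phase[before] = (idx[before] - peaks[0]) / rr0
        phase[after] = (len(peaks) - 1) + (idx[after] - peaks[-1]) / rr1
        phase = 2 * np.pi * phase
    k = np.arange(1, N_PHASE_HARMONICS + 1)
    angles = phase[:, None] * k
    return np.concatenate([np.sin(angles), np.cos(angles)], axis=-1)


class ECGImputerTFT(Module):
    """The full imputation network; see the module docstring for the flow."""

    def __init__(self, config: TFTConfig):
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        d, dh = config.d_model, config.grn_hidden
        L = config.n_leads

        # per-lead scalar -> d_model value embedding, plus the mask token
        self.emb_w = Tensor(rng.normal(0, 0.1, (L, d)), requires_grad=True)
        self.emb_b = Tensor(np.zeros((L, d)), requires_grad=True)
        self.mask_token = Tensor(rng.normal(0, 0.1, d), requires_grad=True)

        # static lead covariates: category one-hot(3) + lead one-hot(L)
        cov = np.zeros((L, 3 + L))
        for li, name in enumerate(STANDARD_LEADS[:L]):
            cov[li, LEAD_CATEGORY.get(name, 2)] = 1.0
            cov[li, 3 + li] = 1.0
        self._static_cov = cov
        self.static_emb = Dense(3 + L, d, rng)
        self.grn_cs = GRN(d, dh, d, rng)     # variable-selection context
        self.grn_ce = GRN(d, dh, d, rng)     # enrichment context
        self.grn_ch = GRN(d, dh, d, rng)     # horizon context (from attention)

        self.grn_v = GRN(L * d, dh, L, rng, d_context=d)
        self.grn_sel = GRN(d, dh, d, rng)
        self.phase_proj = Dense(2 * N_PHASE_HARMONICS, d, rng)

        self.lstm_fwd = LSTM(d, d, rng)
        self.lstm_bwd = LSTM(d, d, rng)
        self.lstm_proj = Dense(2 * d, d, rng)
        self.gate_lstm = GLU(d, d, rng)
        self.norm_lstm = LayerNorm(d)

        self.attn = InterpretableMHA(d, config.d_attn, config.n_heads, rng)
        self.attn_proj = Dense(config.d_attn, d, rng)
        self.gate_attn = GLU(d, d, rng)
        self.norm_attn = LayerNorm(d)

        self.grn_enrich = GRN(d, dh, d, rng, d_context=d)
        self.heads = Dense(2 * d + 2 * N_PHASE_HARMONICS,
                           L * len(config.quantiles), rng)
        self.trained = False

    # -- pieces exposed for inspection/testing ------------------------------
    def static_contexts(self) -> tuple[Tensor, Tensor]:
        s = self.static_emb(Tensor(self._static_cov))     # (L, d)
        s_mean = s.mean(axis=0)                           # lead-invariant
        return self.grn_cs(s_mean), self.grn_ce(s_mean)

    def variable_select(self, embedded: Tensor, c_s: Tensor
                        ) -> tuple[Tensor, Tensor]:
        """embedded: (..., L, d); returns (selected (..., d), weights (..., L))."""
        L, d = embedded.shape[-2], embedded.shape[-1]
        flat = embedded.reshape(*embedded.shape[:-2], L * d)
        v = self.grn_v(flat, c_s).softmax(axis=-1)        # (..., L)
        transformed = self.grn_sel(embedded)              # (..., L, d)
        sel = (transformed * v.reshape(*v.shape, 1)).sum(axis=-2)
        return sel, v

    def static_enrich(self, h_tilde: Tensor, c_e: Tensor) -> Tensor:
        return self.grn_enrich(h_tilde, c_e)

    def quantile_heads(self, theta: Tensor, c_h: Tensor,
                       phase: np.ndarray | None = None) -> Tensor:
        """(..., d) x (..., d) -> (..., L, |Q|) linear heads per (q, lead).

        The raw cardiac-phase harmonics are re-injected here so the heads can
        compose periodic morphology undiluted by the sequence encoder."""
        L, nq = self.config.n_leads, len(self.config.quantiles)
        if phase is None:
            phase = np.zeros(theta.shape[:-1] + (2 * N_PHASE_HARMONICS,))
        out = self.heads(concatenate([theta, c_h, Tensor(phase)], axis=-1))
        return out.reshape(*out.shape[:-1], L, nq)

    def forward(self, x_obs: np.ndarray, mask: np.ndarray,
                phase: np.ndarray) -> Tensor:
        """x_obs, mask: (N, T, L); phase: (N, T, 2) -> (N, T, L, |Q|)."""
        n, t, L = x_obs.shape
        e = Tensor(x_obs[..., None]) * self.emb_w + self.emb_b   # (N,T,L,d)
        from .nn import where
        e = where(mask[..., None] > 0, e, self.mask_token.reshape(1, 1, 1, -1))
        c_s, c_e = self.static_contexts()
        sel, _ = self.variable_select(e, c_s)                     # (N,T,d)
        sel = sel + self.phase_proj(Tensor(phase))

        fwd = self.lstm_fwd(sel)
        bwd = self.lstm_bwd(sel, reverse=True)
        seq = self.lstm_proj(concatenate([fwd, bwd], axis=-1))
        seq = self.norm_lstm(sel + self.gate_lstm(seq))

        key_mask = (mask.min(axis=-1) == 0)                       # (N, T)
        h = self.attn(seq, seq, seq, key_mask=key_mask)
        h = self.attn_proj(h)
        h_tilde = self.norm_attn(seq + self.gate_attn(h))

        theta = self.static_enrich(h_tilde, c_e)
        c_h = self.grn_ch(h_tilde)
        return self.quantile_heads(theta, c_h, phase)

    __call__ = forward


def _windows_for_record(t_len: int, t_obs: int) -> list[int]:
    if t_len < t_obs:
        raise InvalidArgumentError("record shorter than the model window")
    if t_len == t_obs:
        return [0]
    starts = list(range(0, t_len - t_obs + 1, t_obs))
    if starts[-1] != t_len - t_obs:
        starts.append(t_len - t_obs)
    return starts


def train_tft(data: list[tuple[ECGRecord, ObservationMask]],
              config: TFTConfig | None = None
              ) -> tuple[ECGImputerTFT, list[float]]:
    """Train on (clean normalized record, simulated mask) pairs.

    The simulated mask hides segments from the model; because the records
    are synthetic the ground truth is available everywhere, so the loss
    indicator is 1 at every position.
    """
    config = config or TFTConfig()
    config.validate()
    if not data:
        raise InvalidArgumentError("need at least one training record")
    xs, ms, ps = [], [], []
    for rec, mask in data:
        if not rec.normalized:
            raise InvalidStateError("training records must be normalized")
        x = rec.signal
        m = mask.mask
        x_obs = x * m
        phase = cardiac_phase_encoding(x_obs[:, 1], rec.fs, m[:, 1])  # lead II
        for s in _windows_for_record(rec.n_samples, config.t_obs):
            sl = slice(s, s + config.t_obs)
            xs.append(x[sl])
            ms.append(m[sl])
            ps.append(phase[sl])
    x_all = np.stack(xs)          # (N, T, L) clean targets
    m_all = np.stack(ms)
    p_all = np.stack(ps)
    # drop windows with no observed context at all
    ok = ~(m_all.min(axis=-1) == 0).all(axis=1)
    x_all, m_all, p_all = x_all[ok], m_all[ok], p_all[ok]
    if len(x_all) == 0:
        raise InvalidArgumentError("no window has observed context")

    model = ECGImputerTFT(config)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    rng = np.random.Generator(np.random.MT19937(config.seed + 1))
    n = len(x_all)
    # Ground truth is available everywhere on synthetic data, so the loss
    # indicator is positive at every position; simulated-gap positions are
    # up-weighted because filling them is the model's job, while observed
    # positions only need a pass-through.
    indicator = np.where(m_all > 0, 0.2, 1.0)
    trace: list[float] = []
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            pred = model.forward(x_all[idx] * m_all[idx], m_all[idx], p_all[idx])
            loss = _tft_loss_t(Tensor(x_all[idx]), pred, indicator[idx],
                               config.quantiles)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += loss.item() * len(idx)
        trace.append(epoch_loss / n)
    model.trained = True
    return model, trace


def tft_reconstruct(record: ECGRecord, mask: ObservationMask | np.ndarray,
                    model: ECGImputerTFT
                    ) -> tuple[ECGRecord, dict[str, np.ndarray]]:
    """Fill missing spans with the median quantile; return quantile bands.

    Gaps longer than tau_max are tiled into successive chunks, each
    re-conditioned on the already-imputed context.  Observed samples are
    copied unchanged; the returned bands equal the signal there.
    """
    if not model.trained:
        raise InvalidStateError("model has not been trained")
    m = mask.mask if isinstance(mask, ObservationMask) else np.asarray(mask, float)
    if m.shape != record.signal.shape:
        raise InvalidArgumentError("mask/signal shape mismatch")
    cfg = model.config
    qs = np.asarray(cfg.quantiles)
    i_med = int(np.argmin(np.abs(qs - 0.5)))
    i_lo, i_hi = int(np.argmin(qs)), int(np.argmax(qs))

    working = record.signal * m
    wmask = m.copy()
    low = working.copy()
    high = working.copy()
    t_len = record.n_samples
    if wmask.max() == 0:
        raise DegenerateAttentionError("record has no observed context at all")

    missing_t = np.nonzero(wmask.min(axis=1) == 0)[0]
    if len(missing_t) == 0:
        return record.copy_with(signal=record.signal.copy()), {
            "low": low, "high": high}

    # maximal gap spans on the time axis
    spans = []
    start = missing_t[0]
    prev = missing_t[0]
    for ti in missing_t[1:]:
        if ti != prev + 1:
            spans.append((start, prev + 1))
            start = ti
        prev = ti
    spans.append((start, prev + 1))

    phase = cardiac_phase_encoding(working[:, 1], record.fs, wmask[:, 1])
    for g0, g1 in spans:
        c0 = g0
        while c0 < g1:
            c1 = min(c0 + cfg.tau_max, g1)
            chunk = c1 - c0
            ws = int(np.clip(c0 - (cfg.t_obs - chunk) // 2, 0,
                             t_len - cfg.t_obs))
            sl = slice(ws, ws + cfg.t_obs)
            pred = model.forward((working * wmask)[None, sl],
                                 wmask[None, sl], phase[None, sl]).data[0]
            pred = monotone_rearrange(pred)
            rel = slice(c0 - ws, c1 - ws)
            working[c0:c1] = np.clip(pred[rel, :, i_med], 0.0, 1.0)
            low[c0:c1] = pred[rel, :, i_lo]
            high[c0:c1] = pred[rel, :, i_hi]
            wmask[c0:c1] = 1.0   # re-condition the next chunk on this fill
            c0 = c1
    out = np.where(m > 0, record.signal, working)
    return record.copy_with(signal=out), {"low": low, "high": high}


def save_tft(model: ECGImputerTFT, path: str) -> None:
    cfg = asdict(model.config)
    np.savez(path, __config__=np.frombuffer(
        json.dumps(cfg).encode(), dtype=np.uint8), **model.named_arrays())


def load_tft(path: str) -> ECGImputerTFT:
    data = np.load(path)
    cfg = json.loads(bytes(data["__config__"]).decode())
    cfg["quantiles"] = tuple(cfg["quantiles"])
    model = ECGImputerTFT(TFTConfig(**cfg))
    model.load_arrays({k: data[k] for k in data.files if k != "__config__"})
    model.trained = True
    return model
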