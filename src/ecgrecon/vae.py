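"""Masked variational autoencoder for ECG missing-segment reconstruction.

Generative model: an isotropic Gaussian prior p(z) = N(0, I_K) and a Gaussian
decoder likelihood p(x|z) = N(mu_theta(z), diag(sigma_theta^2)).  The encoder
approximates the posterior q(z|X_obs) = N(mu_phi, diag(sigma_phi^2)) from the
observed signal; the observation mask is concatenated to the input channels
so the network can distinguish genuinely missing samples from isoelectric
zeros.  Training maximizes the ELBO: a Gaussian negative log-likelihood
summed over OBSERVED entries only, plus beta times the closed-form KL
divergence to the prior.  Reconstruction is hybrid: observed samples are
copied through, only masked samples are imputed with the decoder mean.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .errors import InvalidArgumentError, InvalidStateError
from .nn import Adam, Conv1d, ConvTranspose1d, Dense, Module, Tensor, concatenate
from .types import ECGRecord, ObservationMask

__all__ = ["VAEConfig", "GaussianParams", "MaskedVAE", "encode",
           "reparameterize", "decode", "kl_divergence", "vae_loss",
           "reconstruct", "train_vae", "save_vae", "load_vae"]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class VAEConfig:
    latent_dim: int = 32
    hidden_channels: tuple[int, int] = (32, 64)
    beta: float = 1.0
    learning_rate: float = 1e-3
    epochs: int = 40
    batch_size: int = 16
    seed: int = 0
    n_leads: int = 12
    t_len: int = 512          # record length the network is built for
    learn_decoder_sigma: bool = False

    def validate(self) -> None:
        if self.latent_dim < 1:
            raise InvalidArgumentError("latent_dim must be >= 1")
        if self.beta < 0:
            raise InvalidArgumentError("beta must be non-negative")
        if self.t_len % 16:
            raise InvalidArgumentError("t_len must be a multiple of 16")


@dataclass
class GaussianParams:
    """Diagonal Gaussian: mean and strictly positive standard deviation."""

    mean: np.ndarray
    std: np.ndarray

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.std = np.asarray(self.std, dtype=np.float64)
        if self.mean.shape != self.std.shape:
            raise InvalidArgumentError("mean/std shape mismatch")


class MaskedVAE(Module):
    """Convolutional encoder over time (leads + mask as channels), dense
    heads for mu/log sigma^2, mirrored transposed-conv decoder."""

    def __init__(self, config: VAEConfig):
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        c1, c2 = config.hidden_channels
        L, T, K = config.n_leads, config.t_len, config.latent_dim
        self.enc1 = Conv1d(2 * L, c1, 7, rng, stride=4)
        self.enc2 = Conv1d(c1, c2, 7, rng, stride=4)
        self.flat_dim = c2 * (T // 16)
        self.fc_mu = Dense(self.flat_dim, K, rng)
        self.fc_logvar = Dense(self.flat_dim, K, rng)
        self.fc_dec = Dense(K, self.flat_dim, rng)
        self.dec1 = ConvTranspose1d(c2, c1, 7, rng, stride=4, output_padding=3)
        self.dec2 = ConvTranspose1d(c1, L, 7, rng, stride=4, output_padding=3)
        # global log sigma_theta (decoder observation noise); fixed 1 unless learned
        self.log_sigma = Tensor(np.zeros(1),
                                requires_grad=config.learn_decoder_sigma)
        self.trained = False

    # Tensor-path pieces used both by training and the public wrappers ------
    def encode_t(self, x_obs: Tensor, mask: Tensor) -> tuple[Tensor, Tensor]:
        """x_obs/mask: (N, L, T) -> (mu, logvar) each (N, K)."""
        h = concatenate([x_obs, mask], axis=1)
        h = self.enc1(h).elu()
        h = self.enc2(h).elu()
        h = h.reshape(h.shape[0], self.flat_dim)
        return self.fc_mu(h), self.fc_logvar(h)

    def decode_t(self, z: Tensor) -> Tensor:
        """z: (N, K) -> decoder mean (N, L, T)."""
        c2 = self.config.hidden_channels[1]
        h = self.fc_dec(z).elu()
        h = h.reshape(z.shape[0], c2, self.config.t_len // 16)
        h = self.dec1(h).elu()
        return self.dec2(h)

    @property
    def decoder_sigma(self) -> float:
        return float(np.exp(self.log_sigma.data[0]))


def _check_record_shape(x_obs: np.ndarray, mask: np.ndarray, model: MaskedVAE):
    if x_obs.shape != mask.shape:
        raise InvalidArgumentError("signal/mask shape mismatch")
    t, l = x_obs.shape
    if l != model.config.n_leads or t > model.config.t_len:
        raise InvalidArgumentError(
            f"model expects at most {model.config.t_len} x "
            f"{model.config.n_leads} input, got {t} x {l}")


def _pad_tl(x: np.ndarray, mask: np.ndarray, t_len: int):
    """Pad (T, L) signal/mask up to the model window; padding is marked
    missing so it never contributes to the likelihood."""
    t = x.shape[0]
    if t == t_len:
        return x, mask
    pad = t_len - t
    x2 = np.pad(x, ((0, pad), (0, 0)))
    m2 = np.pad(mask, ((0, pad), (0, 0)))
    return x2, m2


def encode(x_obs: np.ndarray, mask: np.ndarray | ObservationMask,
           model: MaskedVAE) -> GaussianParams:
    """Approximate posterior q(z | X_obs); x_obs must be mask * x."""
    if isinstance(mask, ObservationMask):
        mask = mask.mask
    x_obs = np.asarray(x_obs, dtype=np.float64)
    mask = np.asarray(mask, dtype=np.float64)
    _check_record_shape(x_obs, mask, model)
    x_obs, mask = _pad_tl(x_obs, mask, model.config.t_len)
    mu, logvar = model.encode_t(Tensor(x_obs.T[None]), Tensor(mask.T[None]))
    return GaussianParams(mean=mu.data[0], std=np.exp(0.5 * logvar.data[0]))


def reparameterize(params: GaussianParams, eps: np.ndarray) -> np.ndarray:
    """z = mu + sigma * eps with eps ~ N(0, I)."""
    eps = np.asarray(eps, dtype=np.float64)
    if eps.shape != params.mean.shape:
        raise InvalidArgumentError("eps length must match the latent dimension")
    return params.mean + params.std * eps


def decode(z: np.ndarray, model: MaskedVAE) -> GaussianParams:
    """Decoder distribution over the T x L signal."""
    z = np.asarray(z, dtype=np.float64)
    if z.shape != (model.config.latent_dim,):
        raise InvalidArgumentError(
            f"latent vector must have length {model.config.latent_dim}")
    mu = model.decode_t(Tensor(z[None]))
    mean = mu.data[0].T  # (T, L)
    return GaussianParams(mean=mean,
                          std=np.full_like(mean, model.decoder_sigma))


def kl_divergence(params: GaussianParams) -> float:
    """Closed-form KL(q || N(0, I)) = 1/2 sum(mu^2 + sigma^2 - 1 - ln sigma^2)."""
    if np.any(params.std <= 0):
        raise InvalidArgumentError("standard deviations must be positive")
    mu, sd = params.mean, params.std
    return float(0.5 * np.sum(mu ** 2 + sd ** 2 - 1.0 - 2.0 * np.log(sd)))


def vae_loss(x: np.ndarray, mask: np.ndarray | ObservationMask,
             recon_params: GaussianParams, post_params: GaussianParams,
             beta: float = 1.0) -> float:
    """Masked Gaussian NLL over observed entries + beta * KL."""
    if beta < 0:
        raise InvalidArgumentError("beta must be non-negative")
    if isinstance(mask, ObservationMask):
        mask = mask.mask
    x = np.asarray(x, dtype=np.float64)
    mask = np.asarray(mask, dtype=np.float64)
    if x.shape != recon_params.mean.shape or x.shape != mask.shape:
        raise InvalidArgumentError("shape mismatch between x, mask and decoder params")
    mu, sd = recon_params.mean, recon_params.std
    nll = 0.5 * (_LOG_2PI + 2 * np.log(sd)) + (x - mu) ** 2 / (2 * sd ** 2)
    return float((nll * mask).sum() + beta * kl_divergence(post_params))


def reconstruct(x_obs: np.ndarray, mask: np.ndarray | ObservationMask,
                model: MaskedVAE, eps_policy: str = "mean",
                seed: int = 0) -> np.ndarray:
    """Impute masked entries with the decoder mean; copy observed entries.

    eps_policy 'mean' uses z = mu_phi; 'sample' draws one reparameterized z.
    """
    if not model.trained:
        raise InvalidStateError("model has not been trained")
    if eps_policy not in ("mean", "sample"):
        raise InvalidArgumentError("eps_policy must be 'mean' or 'sample'")
    if isinstance(mask, ObservationMask):
        mask = mask.mask
    x_obs = np.asarray(x_obs, dtype=np.float64)
    mask_arr = np.asarray(mask, dtype=np.float64)
    post = encode(x_obs, mask_arr, model)
    if eps_policy == "mean":
        z = post.mean
    else:
        rng = np.random.Generator(np.random.MT19937(seed))
        z = reparameterize(post, rng.standard_normal(post.mean.shape))
    xhat = decode(z, model).mean[: x_obs.shape[0]]
    return np.where(mask_arr > 0, x_obs, np.clip(xhat, 0.0, 1.0))


def train_vae(data: list[tuple[ECGRecord, ObservationMask]],
              config: VAEConfig | None = None) -> tuple[MaskedVAE, list[float]]:
    """Train on masked normalized records; returns (model, per-epoch ELBO loss)."""
    config = config or VAEConfig()
    if not data:
        raise InvalidArgumentError("need at least one training record")
    for rec, _ in data:
        if not rec.normalized:
            raise InvalidStateError("training records must be normalized")
        if rec.n_samples > config.t_len or rec.n_leads != config.n_leads:
            raise InvalidArgumentError(
                f"records must be at most {config.t_len} x {config.n_leads}")
    padded = [_pad_tl(rec.signal, m.mask, config.t_len) for rec, m in data]
    x_all = np.stack([x.T for x, _ in padded])                 # (N, L, T)
    m_all = np.stack([m.T for _, m in padded])
    x_obs_all = x_all * m_all

    model = MaskedVAE(config)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    rng = np.random.Generator(np.random.MT19937(config.seed + 1))
    n = len(data)
    trace: list[float] = []
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb = Tensor(x_all[idx])
            ob = Tensor(x_obs_all[idx])
            mb = Tensor(m_all[idx])
            mu, logvar = model.encode_t(ob, mb)
            eps = rng.standard_normal(mu.shape)
            z = mu + (logvar * 0.5).exp() * eps
            xhat = model.decode_t(z)
            sd2 = (2.0 * model.log_sigma).exp()
            nll = (0.5 * (_LOG_2PI + 2.0 * model.log_sigma)
                   + (xb - xhat) * (xb - xhat) / (2.0 * sd2))
            recon = (nll * mb).sum() * (1.0 / len(idx))
            kl = (0.5 * (mu * mu + logvar.exp() - 1.0 - logvar)).sum() * (1.0 / len(idx))
            loss = recon + config.beta * kl
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += loss.item() * len(idx)
        trace.append(epoch_loss / n)
    model.trained = True
    return model, trace


def save_vae(model: MaskedVAE, path: str) -> None:
    cfg = asdict(model.config)
    arrays = model.named_arrays()
    arrays["__log_sigma__"] = model.log_sigma.data
    np.savez(path, __config__=np.frombuffer(
        json.dumps(cfg).encode(), dtype=np.uint8), **arrays)


def load_vae(path: str) -> MaskedVAE:
    data = np.load(path)
    cfg = json.loads(bytes(data["__config__"]).decode())
    cfg["hidden_channels"] = tuple(cfg["hidden_channels"])
    model = MaskedVAE(VAEConfig(**cfg))
    model.load_arrays({k: data[k] for k in data.files
                       if k not in ("__config__", "__log_sigma__")})
    model.log_sigma.data = np.asarray(data["__log_sigma__"], dtype=np.float64)
    model.trained = True
    return model
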