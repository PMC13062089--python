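"""Shared fixtures: synthetic cohorts and session-scoped trained models.

Model training is expensive, so everything trained is session-scoped and
shared between the unit tests and the acceptance tests.  Problem sizes
(record length, cohort size, epochs) are the package's documented desk-scale
study conditions; see docs/methods.md.
"""

from __future__ import annotations

import numpy as np
import pytest

from ecgrecon.synth import generate_clean_ecg, add_noise, simulate_missing
from ecgrecon.types import NoiseSpec
from ecgrecon.wfdb_io import normalize

# desk-scale study conditions for the reconstruction experiments
RECON_FS = 200.0
RECON_DUR = 1.28            # -> 256 samples, one model window
RECON_SEG_LEN = 48
N_TRAIN = 300
N_HELD_OUT = 50

PIPE_FS = 200.0
PIPE_DUR = 2.56             # -> 512 samples, >= 2 s for QRS detection
PIPE_N_PATIENTS = 100


def make_masked_records(n, seed0, ratios, fs=RECON_FS, dur=RECON_DUR,
                        seg_len=RECON_SEG_LEN):
    """Normalized clean records paired with simulated segment masks."""
    data = []
    rng = np.random.default_rng(seed0)
    for i in range(n):
        hr = rng.uniform(55, 95)
        rec, _ = generate_clean_ecg(dur, fs, hr, seed=seed0 + i)
        rec = normalize(rec)
        ratio = ratios[i % len(ratios)]
        _, mask = simulate_missing(rec, ratio, "segments", seg_len,
                                   seed=seed0 + 1000 + i)
        data.append((rec, mask))
    return data


def linear_interp_fill(x_obs: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per-lead linear interpolation across masked spans (baseline)."""
    out = x_obs.copy()
    t = np.arange(out.shape[0])
    for li in range(out.shape[1]):
        m = mask[:, li] > 0
        if 0 < m.sum() < len(t):
            out[~m, li] = np.interp(t[~m], t[m], x_obs[m, li])
    return out


def make_noise_pairs(n, seed0, spec_fn, fs=250.0, dur=2.048):
    """(noisy, clean) record pairs sharing the clean record's [0,1] frame."""
    pairs = []
    rng = np.random.default_rng(seed0)
    for i in range(n):
        hr = rng.uniform(55, 95)
        rec, _ = generate_clean_ecg(dur, fs, hr, seed=seed0 + i)
        noisy = add_noise(rec, spec_fn(seed0 + 500 + i))
        clean_n = normalize(rec)
        scaled = np.clip((noisy.signal - clean_n.norm_min)
                         / (clean_n.norm_max - clean_n.norm_min), 0.0, 1.0)
        noisy_n = rec.copy_with(signal=scaled, normalized=True,
                                norm_min=clean_n.norm_min,
                                norm_max=clean_n.norm_max)
        pairs.append((noisy_n, clean_n))
    return pairs


@pytest.fixture(scope="session")
def recon_models():
    """VAE and TFT trained on the 300-record imputation fixture."""
    from ecgrecon.vae import VAEConfig, train_vae
    from ecgrecon.tft import TFTConfig, train_tft

    train = make_masked_records(N_TRAIN, 123, [0.1, 0.3, 0.5])
    tft_model, tft_trace = train_tft(train, TFTConfig(epochs=30, seed=7))
    vae_model, vae_trace = train_vae(
        train, VAEConfig(epochs=40, t_len=256, seed=7))
    return {"tft": tft_model, "vae": vae_model,
            "tft_trace": tft_trace, "vae_trace": vae_trace}


@pytest.fixture(scope="session")
def tcdae_mixed():
    """TCDAE trained on mixed-noise pairs, plus a held-out test set."""
    from ecgrecon.denoise import TCDAEConfig, train_tcdae

    def mixed(s):
        return NoiseSpec(baseline_wander_amp=0.08, powerline_amp=0.05,
                         emg_amp=0.03, white_sigma=0.03, seed=s)

    train = make_noise_pairs(96, 0, mixed)
    test = make_noise_pairs(24, 9000, mixed)
    model, trace = train_tcdae(train, TCDAEConfig(epochs=30, batch_size=16,
                                                  seed=0))
    return {"model": model, "trace": trace, "test": test}


@pytest.fixture(scope="session")
def tcdae_powerline():
    """TCDAE trained on pure 50 Hz powerline contamination."""
    from ecgrecon.denoise import TCDAEConfig, train_tcdae

    def powerline(s):
        return NoiseSpec(baseline_wander_amp=0.0, powerline_amp=0.15,
                         emg_amp=0.0, white_sigma=0.0, seed=s)

    train = make_noise_pairs(96, 100, powerline)
    test = make_noise_pairs(12, 8000, powerline)
    model, _ = train_tcdae(train, TCDAEConfig(epochs=30, batch_size=16, seed=0))
    return {"model": model, "test": test}


@pytest.fixture(scope="session")
def comparison_setup():
    """Cohort + split + trained reconstruction arms for end-to-end evaluation."""
    from ecgrecon.types import CohortSpec
    from ecgrecon.synth import generate_cohort
    from ecgrecon.wfdb_io import patient_split
    from ecgrecon.vae import VAEConfig, train_vae, reconstruct as vae_rec
    from ecgrecon.tft import TFTConfig, train_tft, tft_reconstruct

    seed = 7
    cohort_raw = generate_cohort(CohortSpec(
        n_patients=PIPE_N_PATIENTS, duration_s=PIPE_DUR, fs=PIPE_FS, seed=seed))
    cohort = [(normalize(r), a, lbl) for r, a, lbl in cohort_raw]
    split = patient_split([r.patient_id for r, _, _ in cohort], seed=seed)

    train_data = []
    ratios = [0.1, 0.3, 0.5]
    for i, (rec, _, _) in enumerate(cohort):
        if split.assignment[rec.patient_id] != "train":
            continue
        _, mask = simulate_missing(rec, ratios[i % 3], "segments",
                                   RECON_SEG_LEN, seed=seed + 31 * i)
        train_data.append((rec, mask))
    vae_model, _ = train_vae(train_data, VAEConfig(epochs=40, t_len=512,
                                                   seed=seed))
    tft_model, _ = train_tft(train_data, TFTConfig(epochs=15, seed=seed))

    def vae_arm(masked_rec, mask):
        return masked_rec.copy_with(
            signal=vae_rec(masked_rec.signal, mask, vae_model))

    def tft_arm(masked_rec, mask):
        rec, _ = tft_reconstruct(masked_rec, mask, tft_model)
        return rec

    return {"cohort": cohort, "split": split,
            "arms": {"VAE": vae_arm, "TFT": tft_arm}}


@pytest.fixture(scope="session")
def comparison_report(comparison_setup):
    """Full paired evaluation at 10/30/50 % missingness, all 7 classifiers."""
    from ecgrecon.evaluate import run_comparison

    return run_comparison(
        comparison_setup["arms"], comparison_setup["cohort"],
        comparison_setup["split"], missing_ratios=(0.1, 0.3, 0.5),
        segment_len=RECON_SEG_LEN, seed=7)
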