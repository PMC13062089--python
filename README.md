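# ecgrecon

Tools for studying how missing data and noise in 12-lead electrocardiograms
affect downstream rhythm classification — and how much of that damage two
reconstruction models can undo. The package targets researchers in
biomedical signal processing who want a fully seeded, self-contained
test bed: every experiment runs on synthetic cohorts with analytically
known fiducials, so detection, delineation and reconstruction can all be
scored against exact ground truth without access to credentialed clinical
data.

## What's inside

The pipeline has four stages, each usable on its own:

1. **Synthetic cohorts** (`ecgrecon.synth`). Beats are sums of Gaussian
   bumps (P, Q, R, S, T) projected onto the 12 standard leads; rhythm
   classes — normal sinus, sinus bradycardia (< 60 bpm), sinus tachycardia
   (> 100 bpm), atrial fibrillation (log-normal irregular RR, no P wave) —
   are realized through the RR-interval process. Mixed noise (baseline
   wander, powerline, EMG, white) and missing data are injected on top;
   missingness removes exactly `round(ratio * T)` samples, either
   individually or as non-overlapping segments, via a seeded Fisher-Yates
   selection. Records read/write as WFDB-style format-16 header/signal
   pairs (`ecgrecon.wfdb_io`), with leakage-free patient-level 70/10/20
   splits.

2. **Denoising** (`ecgrecon.denoise`). A transformer-convolutional
   denoising autoencoder: three gated convolutions, a self-attention
   bottleneck, transposed-convolution decoder with skip connections,
   trained with a frequency-weighted Huber + cosine-similarity loss.

3. **Missing-segment reconstruction**. Two alternatives:
   a **masked VAE** (`ecgrecon.vae`) with Gaussian likelihood
   p(x|z) = N(mu_theta(z), diag(sigma^2)), posterior
   q(z|X_obs) = N(mu_phi, diag(sigma_phi^2)) and loss
   L = NLL_observed + beta KL(q || N(0, I)); and an ECG-adapted
   **temporal fusion transformer** (`ecgrecon.tft`) with per-lead variable
   selection, gated residual networks, bidirectional LSTM encoding,
   head-averaged attention that never attends into a gap, cardiac-phase
   positional encodings, and pinball-loss quantile heads
   p_q(u) = max(q u, (q-1) u) whose median is the reconstruction and whose
   outer quantiles form an uncertainty band.

4. **Features, classification and statistics** (`ecgrecon.features`,
   `ecgrecon.evaluate`). Pan-Tompkins QRS detection, P/QRS/T boundary
   delineation, the per-record clinical feature vector (RR interval,
   fiducial times, frontal-plane electrical axes from leads I and aVF),
   seven standard classifiers, and the full evaluation battery:
   MAE/MSE/RMSE/NRMSE, bootstrap accuracy +/- SD (1000 resamples), and
   paired McNemar tests (exact binomial below 25 discordant pairs,
   continuity-corrected chi-square above).

The neural models run on a small reverse-mode autodiff engine
(`ecgrecon.nn`) written on numpy, so the whole package trains and runs on
one CPU with no deep-learning framework.

## Worked example

Generate a labeled record, extract its features, hide 30 % of it in 0.5 s
blocks, and impute the gaps with a masked VAE trained on 60 similar
records:

```python
import numpy as np
from ecgrecon import (generate_clean_ecg, simulate_missing, normalize,
                      pan_tompkins, delineate, build_feature_table,
                      reconstruction_metrics)
from ecgrecon.vae import VAEConfig, train_vae, reconstruct

record, truth = generate_clean_ecg(duration_s=10, fs=500, heart_rate=72,
                                   rhythm="sinus_rhythm", seed=1)
peaks = pan_tompkins(record.lead("II"), record.fs)
table = build_feature_table([record], [delineate(record, peaks)])
print("detected beats:", len(peaks), "of", truth.n_beats)
print("mean RR interval: %.3f s" % table["rr_interval"].iloc[0])

rec_n = normalize(record)
masked, mask = simulate_missing(rec_n, ratio=0.3, mode="segments",
                                segment_len=250, seed=2)
train = []
rng = np.random.default_rng(0)
for i in range(60):
    r, _ = generate_clean_ecg(10, 500, rng.uniform(62, 98), seed=100 + i)
    _, m = simulate_missing(normalize(r), 0.3, "segments", 250, seed=200 + i)
    train.append((normalize(r), m))
model, _ = train_vae(train, VAEConfig(epochs=20, t_len=5008, seed=0))
imputed = reconstruct(masked.signal, mask, model)
m = reconstruction_metrics(rec_n.signal, imputed, mask.mask == 0)
print("masked-entry error: MAE %.3f  RMSE %.3f  NRMSE %.3f"
      % (m["mae"], m["rmse"], m["nrmse"]))
```

Output (about 30 s of training on one CPU):

```
detected beats: 12 of 12
mean RR interval: 0.833 s
masked-entry error: MAE 0.088  RMSE 0.153  NRMSE 0.153
```

Every detected beat matches the generator's ground truth, the RR interval
is exact for a 72 bpm record, and the imputed samples sit within ~9 % mean
absolute error of the true normalized waveform — versus ~30 % if the gaps
were simply zero-filled.

There is also a CLI for the common operations, e.g.

```sh
ecgrecon synth --n-patients 20 --duration 10 --fs 500 --seed 1 --out cohort/
ecgrecon split ids.txt --fractions 0.7 0.1 0.2 --seed 0 --out split.json
ecgrecon run --config run.yaml        # full pipeline from one config
```

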