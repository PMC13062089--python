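"""End-to-end orchestration: synth -> split -> denoise -> mask -> reconstruct
-> features -> classify -> evaluate, driven by one configuration mapping.

Every stage draws its seed from the global seed through a fixed per-stage
offset, so toggling one stage never shifts another stage's randomness, and
identical configurations produce byte-identical reports.  Intermediate
artifacts (cohort records, split assignment, model checkpoints, feature
tables, the evaluation report) are written to the run directory together
with a manifest of stage seeds and the configuration hash.
"""

from __future__ import annotations

import hashlib
import json
import os
import time
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError
from .types import CohortSpec, NoiseSpec, RHYTHM_CLASSES

__all__ = ["RunConfig", "validate_config", "run_pipeline", "STAGES"]

STAGES = ("synth", "split", "denoise", "mask", "reconstruct",
          "features", "classify", "evaluate")

# fixed per-stage seed offsets (splittable-counter style)
_STAGE_OFFSET = {name: 1000 * (i + 1) for i, name in enumerate(STAGES)}


@dataclass
class RunConfig:
    out_dir: str = "run"
    seed: int = 0
    n_patients: int = 60
    duration_s: float = 2.56
    fs: float = 200.0
    class_priors: dict = field(default_factory=lambda: {c: 0.25
                                                        for c in RHYTHM_CLASSES})
    noise: dict = field(default_factory=dict)
    missing_ratios: tuple[float, ...] = (0.1, 0.3, 0.5)
    missing_mode: str = "segments"
    segment_len: int = 48
    split_fractions: tuple[float, float, float] = (0.7, 0.1, 0.2)
    tcdae: dict = field(default_factory=dict)
    vae: dict = field(default_factory=dict)
    tft: dict = field(default_factory=dict)
    classifier_kinds: tuple[str, ...] = ()
    n_bootstrap: int = 1000
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(mapping) - known
        if unknown:
            raise InvalidArgumentError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**mapping)
        for key in ("missing_ratios", "split_fractions", "classifier_kinds"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg

    def stage_seed(self, stage: str) -> int:
        return (self.seed + _STAGE_OFFSET[stage]) % (2 ** 31)

    def config_hash(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def validate_config(config: RunConfig) -> list[str]:
    """Return a list of violations; empty means the config is runnable."""
    v: list[str] = []
    if config.n_patients <= 0:
        v.append("n_patients: must be positive")
    if not all(0 <= r < 1 for r in config.missing_ratios):
        v.append("missing_ratios: each ratio must lie in [0, 1)")
    if config.missing_mode not in ("samples", "segments"):
        v.append("missing_mode: must be 'samples' or 'segments'")
    if abs(sum(config.split_fractions) - 1.0) > 1e-9:
        v.append("split_fractions: must sum to 1")
    on = {s for s in STAGES if config.stages.get(s, False)}
    unknown = set(config.stages) - set(STAGES)
    if unknown:
        v.append(f"stages: unknown stage names {sorted(unknown)}")
    deps = {"reconstruct": "mask", "classify": "features",
            "evaluate": "classify", "features": "synth",
            "mask": "synth", "split": "synth", "denoise": "synth"}
    for stage, needs in deps.items():
        if stage in on and needs not in on:
            v.append(f"stages: {stage} requires {needs}")
    from .evaluate import CLASSIFIER_KINDS
    for kind in config.classifier_kinds:
        if kind not in CLASSIFIER_KINDS:
            v.append(f"classifier_kinds: unknown kind {kind!r}")
    return v


def _write_json(path: str, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order; returns a summary dict.

    Raises with the failing stage's name in the message; artifacts of the
    completed stages are left on disk.
    """
    violations = validate_config(config)
    if violations:
        raise InvalidArgumentError("invalid config: " + "; ".join(violations))
    os.makedirs(config.out_dir, exist_ok=True)
    manifest = {"config_hash": config.config_hash(), "stages": {}}
    summary: dict = {}
    state: dict = {}

    def log_stage(name, t0):
        manifest["stages"][name] = {
            "seed": config.stage_seed(name),
            "wall_time_s": round(time.time() - t0, 2),
        }
        _write_json(os.path.join(config.out_dir, "manifest.json"), manifest)

    for stage in STAGES:
        if not config.stages.get(stage, False):
            continue
        t0 = time.time()
        try:
            _run_stage(stage, config, state, summary)
        except Exception as exc:
            raise type(exc)(f"stage {stage!r} failed: {exc}") from exc
        log_stage(stage, t0)
    return summary


def _run_stage(stage: str, config: RunConfig, state: dict, summary: dict):
    from . import synth, wfdb_io
    out = config.out_dir
    seed = config.stage_seed(stage)

    if stage == "synth":
        spec = CohortSpec(n_patients=config.n_patients,
                          class_priors=dict(config.class_priors),
                          duration_s=config.duration_s, fs=config.fs,
                          seed=seed)
        cohort = synth.generate_cohort(spec)
        rec_dir = os.path.join(out, "cohort")
        for rec, _, _ in cohort:
            wfdb_io.write_record(rec, rec_dir)
        state["cohort"] = cohort
        summary["n_records"] = len(cohort)

    elif stage == "split":
        ids = [rec.patient_id for rec, _, _ in state["cohort"]]
        split = wfdb_io.patient_split(ids, config.split_fractions, seed=seed)
        state["split"] = split
        _write_json(os.path.join(out, "split.json"), split.assignment)
        summary["split_counts"] = {p: len(split.ids(p))
                                   for p in ("train", "validation", "test")}

    elif stage == "denoise":
        from .denoise import TCDAEConfig, train_tcdae, tcdae_forward, save_tcdae
        from .types import NoiseSpec
        noise = NoiseSpec(**config.noise) if config.noise else NoiseSpec(seed=seed)
        pairs = []
        for i, (rec, _, _) in enumerate(state["cohort"]):
            if state["split"].assignment[rec.patient_id] != "train":
                continue
            noisy = synth.add_noise(rec, NoiseSpec(
                **{**config.noise, "seed": seed + i}))
            pairs.append((wfdb_io.normalize(noisy), wfdb_io.normalize(rec)))
        cfg = TCDAEConfig(**{**config.tcdae, "seed": seed})
        model, trace = train_tcdae(pairs, cfg)
        save_tcdae(model, os.path.join(out, "tcdae.npz"))
        state["tcdae"] = model
        summary["tcdae_final_loss"] = trace[-1]

    elif stage == "mask":
        normalized = []
        for rec, ann, label in state["cohort"]:
            normalized.append((wfdb_io.normalize(rec), ann, label))
        state["cohort_norm"] = normalized
        masked = {}
        for ratio in config.missing_ratios:
            per_ratio = []
            for i, (rec, _, _) in enumerate(normalized):
                m, mask = synth.simulate_missing(
                    rec, ratio, config.missing_mode, config.segment_len,
                    seed=seed + i + int(round(1000 * ratio)))
                per_ratio.append((m, mask))
            masked[ratio] = per_ratio
        state["masked"] = masked

    elif stage == "reconstruct":
        from .vae import VAEConfig, train_vae, save_vae, reconstruct as vae_rec
        from .tft import TFTConfig, train_tft, save_tft, tft_reconstruct
        train_data = []
        ratios = list(config.missing_ratios) or [0.3]
        for i, (rec, _, _) in enumerate(state["cohort_norm"]):
            if state["split"].assignment[rec.patient_id] != "train":
                continue
            ratio = ratios[i % len(ratios)]
            _, mask = synth.simulate_missing(
                rec, ratio, config.missing_mode, config.segment_len,
                seed=seed + 31 * i)
            train_data.append((rec, mask))
        t_len = int(round(config.duration_s * config.fs))
        vae_cfg = VAEConfig(**{"t_len": t_len, **config.vae, "seed": seed})
        vae_model, _ = train_vae(train_data, vae_cfg)
        save_vae(vae_model, os.path.join(out, "vae.npz"))
        tft_cfg = TFTConfig(**{**config.tft, "seed": seed})
        tft_model, _ = train_tft(train_data, tft_cfg)
        save_tft(tft_model, os.path.join(out, "tft.npz"))

        def vae_arm(masked_rec, mask):
            sig = vae_rec(masked_rec.signal, mask, vae_model)
            return masked_rec.copy_with(signal=sig)

        def tft_arm(masked_rec, mask):
            rec, _ = tft_reconstruct(masked_rec, mask, tft_model)
            return rec

        state["reconstructors"] = {"VAE": vae_arm, "TFT": tft_arm}

    elif stage == "features":
        from .features import pan_tompkins, delineate, build_feature_table
        records, annotations = [], []
        for rec, _, _ in state["cohort"]:
            peaks = pan_tompkins(rec.lead("II"), rec.fs)
            if len(peaks) == 0:
                continue
            records.append(rec)
            annotations.append(delineate(rec, peaks))
        table = build_feature_table(records, annotations)
        table.to_csv(os.path.join(out, "features.csv"), index=False)
        state["features"] = table
        summary["n_feature_rows"] = len(table)

    elif stage == "classify":
        from .evaluate import ClassifierSpec, train_classifier, CLASSIFIER_KINDS
        kinds = config.classifier_kinds or CLASSIFIER_KINDS
        table = state["features"]
        train_ids = set(state["split"].ids("train"))
        train_tab = table[table["patient_id"].isin(train_ids)]
        state["classifiers"] = {
            kind: train_classifier(ClassifierSpec(kind=kind, seed=seed),
                                   train_tab, train_tab["label"])
            for kind in kinds}
        summary["classifiers"] = list(state["classifiers"])

    elif stage == "evaluate":
        from .evaluate import run_comparison, ClassifierSpec
        kinds = config.classifier_kinds or tuple(state["classifiers"])
        report = run_comparison(
            state["reconstructors"], state["cohort_norm"], state["split"],
            missing_ratios=config.missing_ratios,
            classifier_specs=[ClassifierSpec(kind=k, seed=seed) for k in kinds],
            segment_len=config.segment_len, seed=seed,
            n_bootstrap=config.n_bootstrap)
        _write_json(os.path.join(out, "report.json"), report.to_json_dict())
        report.accuracy_table().to_csv(
            os.path.join(out, "accuracy_table.csv"), index=False)
        report.mcnemar_table().to_csv(
            os.path.join(out, "mcnemar_table.csv"), index=False)
        state["report"] = report
        summary["report"] = report.to_json_dict()
    else:  # pragma: no cover
        raise InvalidArgumentError(f"unknown stage {stage}")
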