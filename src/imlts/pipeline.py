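"""End-to-end orchestration: synth -> denoise -> train -> segment -> features
-> classify -> evaluate, driven by one config and one seed.

Every stage writes into its own subdirectory of the run directory and never
mutates its inputs; the run manifest records the config, the seed, package
versions, per-stage outputs and their SHA-256 checksums.  Two runs with the
same config and seed produce identical manifests except for the recorded
wall-clock timestamps.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import (
    measure_nodule,
    size_rule_classify,
    svm_classify,
    train_svm,
    save_svm,
)
from .denoise import DenoiseParams, denoise_volume
from .features import FEATURE_ORDER, GLCMConfig, extract_features
from .imgio import ImageVolume, write_mask
from .metrics import compute_metrics, confusion
from .network import (
    NetworkConfig,
    build_network,
    extract_patches,
    predict_mask,
    save_checkpoint,
    train,
)
from .phantom import PhantomSpec, export_phantom, generate_dataset

__all__ = ["PipelineConfig", "run_pipeline"]

STAGES = ("synth", "denoise", "train", "segment", "features", "classify", "evaluate")
#: Upstream stages each stage requires.
_DEPENDENCIES = {
    "denoise": ("synth",),
    "train": ("synth", "denoise"),
    "segment": ("train",),
    "features": ("segment",),
    "classify": ("features",),
    "evaluate": ("classify",),
}


@dataclass
class PipelineConfig:
    """One config object covering every stage.

    ``stages`` toggles stages on/off (dependencies are checked up front);
    ``seed`` drives every stochastic stage.
    """

    out_dir: str = "runs/run0"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    # synth
    n_phantoms: int = 20
    phantom: PhantomSpec = field(default_factory=lambda: PhantomSpec(noise_sigma=20.0))
    diameter_range_mm: tuple[float, float] = (2.0, 30.0)
    # denoise
    denoise: DenoiseParams = field(default_factory=DenoiseParams)
    # network
    network: NetworkConfig = field(default_factory=NetworkConfig.desk_scale)
    n_patches: int = 128
    # features
    glcm: GLCMConfig = field(default_factory=GLCMConfig)
    # classify
    classifier_backend: str = "rule"  # rule | svm | svm_with_rule_fallback
    svm_kernel_scale: float = 1.0
    svm_C: float = 1.0

    def validate(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stages {unknown}; valid: {STAGES}")
        enabled = set(self.stages)
        for stage in self.stages:
            missing = [d for d in _DEPENDENCIES.get(stage, ()) if d not in enabled]
            if missing:
                raise ValueError(
                    f"stage {stage!r} requires {missing} but they are disabled"
                )
        if self.classifier_backend not in ("rule", "svm", "svm_with_rule_fallback"):
            raise ValueError(f"unknown classifier backend {self.classifier_backend!r}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _record(manifest: dict, stage: str, outputs: list[Path]) -> None:
    manifest["stages"][stage] = {
        "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
    }
    manifest["timestamps"][stage] = time.time()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order; returns the run manifest."""
    config.validate()
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "package": "imlts",
        "version": __version__,
        "seed": config.seed,
        "config": _config_to_json(config),
        "stages": {},
        "timestamps": {},
    }
    enabled = set(config.stages)
    splits = None
    denoised: dict[str, list[ImageVolume]] = {}
    model = None
    predicted_masks = []
    feature_rows = None
    pred_labels = None

    try:
        if "synth" in enabled:
            splits = generate_dataset(
                config.n_phantoms,
                config.phantom,
                seed=config.seed,
                diameter_range_mm=config.diameter_range_mm,
            )
            synth_dir = run_dir / "synth"
            outputs = []
            for split, samples in splits.items():
                for i, s in enumerate(samples):
                    paths = export_phantom(s.spec, synth_dir, stem=f"{split}_{i:03d}")
                    outputs.extend(Path(p) for p in paths.values())
            _record(manifest, "synth", outputs)

        if "denoise" in enabled:
            assert splits is not None
            for split, samples in splits.items():
                denoised[split] = [
                    denoise_volume(s.image, config.denoise) for s in samples
                ]
            stats = {
                split: [float(np.std(v.voxels)) for v in vols]
                for split, vols in denoised.items()
            }
            out = run_dir / "denoise_stats.json"
            out.write_text(json.dumps(stats, indent=2))
            _record(manifest, "denoise", [out])

        if "train" in enabled:
            assert splits is not None
            ps = config.network.input_size
            train_samples = [
                dataclasses.replace(s, image=img)
                for s, img in zip(splits["train"], denoised["train"])
            ]
            val_samples = [
                dataclasses.replace(s, image=img)
                for s, img in zip(splits["val"], denoised["val"])
            ]
            xt, yt = extract_patches(
                train_samples, config.n_patches, ps, seed=config.seed
            )
            xv, yv = extract_patches(
                val_samples, max(config.n_patches // 4, 4), ps, seed=config.seed + 1
            )
            model = build_network(
                dataclasses.replace(config.network, seed=config.seed)
            )
            state = train(model, (xt, yt), (xv, yv), model.config)
            model_dir = run_dir / "model"
            model_dir.mkdir(exist_ok=True)
            ckpt = model_dir / "checkpoint.npz"
            save_checkpoint(model, ckpt)
            log = pd.DataFrame(
                {
                    "epoch": np.arange(1, state.epoch + 1),
                    "train_loss": state.train_losses,
                    "val_loss": state.val_losses,
                    "learning_rate": state.learning_rates,
                }
            )
            log_path = model_dir / "train_log.csv"
            log.to_csv(log_path, index=False, float_format="%.8f")
            _record(manifest, "train", [ckpt, log_path])

        if "segment" in enabled:
            assert model is not None and splits is not None
            mask_dir = run_dir / "masks"
            mask_dir.mkdir(exist_ok=True)
            outputs = []
            test_images = denoised.get("test") or [s.image for s in splits["test"]]
            for i, vol in enumerate(test_images):
                m = predict_mask(model, vol)
                predicted_masks.append(m)
                p = mask_dir / f"test_{i:03d}_mask.png"
                write_mask(m, p)
                outputs.append(p)
            _record(manifest, "segment", outputs)

        if "features" in enabled:
            assert splits is not None
            rows = []
            for i, (sample, mask) in enumerate(zip(splits["test"], predicted_masks)):
                img = denoised["test"][i] if "test" in denoised else sample.image
                use_mask = mask if mask.voxels.any() else sample.mask
                fv = extract_features(img, use_mask, config.glcm)
                row = {"item": f"test_{i:03d}", "mask_source": "predicted" if mask.voxels.any() else "ground_truth"}
                row.update(fv.to_dict())
                rows.append(row)
            feature_rows = pd.DataFrame(rows, columns=["item", "mask_source", *FEATURE_ORDER])
            fpath = run_dir / "features.csv"
            feature_rows.to_csv(fpath, index=False, float_format="%.10g")
            _record(manifest, "features", [fpath])

        if "classify" in enabled:
            assert splits is not None
            backend = config.classifier_backend
            svm_model = None
            if backend in ("svm", "svm_with_rule_fallback"):
                X, y = [], []
                for split in ("train", "val"):
                    for j, s in enumerate(splits[split]):
                        img = denoised[split][j] if split in denoised else s.image
                        fv = extract_features(img, s.mask, config.glcm)
                        X.append(fv.to_array())
                        y.append(s.label)
                if len(set(y)) >= 2:
                    svm_model = train_svm(
                        np.array(X), y, s=config.svm_kernel_scale, C=config.svm_C
                    )
                    save_svm(svm_model, run_dir / "svm_model.pkl")
                elif backend == "svm":
                    raise ValueError(
                        "svm backend requires both classes in the training split"
                    )
            records = []
            pred_labels = []
            for i, (sample, mask) in enumerate(zip(splits["test"], predicted_masks)):
                measurements = measure_nodule(mask if mask.voxels.any() else sample.mask)
                largest = measurements[0] if measurements else None
                if svm_model is not None and feature_rows is not None:
                    feats = feature_rows.iloc[i][list(FEATURE_ORDER)].to_numpy(float)
                    label = svm_classify(svm_model, feats)
                elif largest is not None:
                    label = size_rule_classify(largest)
                else:
                    label = "benign"  # nothing segmented: no >=3 mm nodule
                pred_labels.append(label)
                records.append(
                    {
                        "item": f"test_{i:03d}",
                        "diameter_mm": largest.equivalent_diameter_mm if largest else 0.0,
                        "label": label,
                        "true_label": sample.label,
                        "backend": backend if svm_model is None or backend == "rule" else "svm",
                    }
                )
            lpath = run_dir / "labels.json"
            lpath.write_text(json.dumps(records, indent=2))
            _record(manifest, "classify", [lpath])

        if "evaluate" in enabled:
            assert splits is not None and pred_labels is not None
            truth = [s.label for s in splits["test"]]
            counts = confusion(pred_labels, truth)
            report = compute_metrics(counts)
            payload = {
                "counts": {"tp": counts.tp, "tn": counts.tn, "fp": counts.fp, "fn": counts.fn},
                "rates_percent": report.to_dict(),
            }
            mpath = run_dir / "metrics.json"
            mpath.write_text(json.dumps(payload, indent=2, allow_nan=True))
            _record(manifest, "evaluate", [mpath])
    except Exception as exc:
        failed = next((s for s in STAGES if s in enabled and s not in manifest["stages"]), "?")
        raise RuntimeError(f"pipeline stage {failed!r} failed: {exc}") from exc

    manifest_path = run_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest


def _config_to_json(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    d["phantom"] = config.phantom.to_json()
    return d
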