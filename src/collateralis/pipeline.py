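"""End-to-end orchestration: phantom -> HU/MIP -> skull strip -> denoise ->
enhance -> features -> classify, as one reproducible run.

Stages execute in this fixed order; each persists its artifacts under the
output directory and a manifest records the config hash, seed, per-stage
wall time and output files.  Rerunning with the same config and seed
reproduces the feature CSVs bit-exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classification, denoising, enhancement, features, hu_projection, phantom, skull_removal, volume_io
from .classification import ModelSpec
from .features import FEATURE_GROUPS
from .hu_projection import BrightnessModel
from .phantom import PhantomSpec
from .volume_io import Image2D

__all__ = ["RunConfig", "run_pipeline", "load_config"]

log = logging.getLogger("collateralis")

STAGES = ("phantom", "hu_mip", "skullstrip", "denoise", "enhance", "features", "classify")


@dataclass
class RunConfig:
    """Declarative configuration of one pipeline run; defaults follow the
    method's stated settings (MIP window 20, disc radius 10, block 16,
    shift 1, k=2, degree 3, 100 splits, 10 folds)."""

    seed: int = 0
    dicom_dir: str | None = None  # read a DICOM series instead of generating
    phantom: PhantomSpec = field(default_factory=phantom.easy_spec)
    brightness: BrightnessModel = field(default_factory=BrightnessModel)
    mip_window: int = 20
    mip_stride: int = 2
    filter_name: str = "auto"  # or one of denoising.FILTER_ORDER
    tophat_radii: tuple[int, ...] = (10,)
    stretch: tuple[float, float] = (1.0, 99.0)
    block: int = 16
    shift: int = 1
    glcm_levels: int = 8
    n_train_per_class: int = 50
    n_test: int = 25
    per_mip_per_class: int = 12
    models: tuple[str, ...] = classification.MODEL_KINDS
    feature_groups: tuple[str, ...] = ("glcm", "shape", "moment")
    cv_folds: int = 10
    write_dicom: bool = False

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML document with optional nested sections."""
    import yaml

    doc = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = dict(doc)
    if "phantom" in kwargs and isinstance(kwargs["phantom"], dict):
        ph = {k: tuple(v) if isinstance(v, list) else v for k, v in kwargs["phantom"].items()}
        kwargs["phantom"] = PhantomSpec(**ph)
    if "brightness" in kwargs and isinstance(kwargs["brightness"], dict):
        kwargs["brightness"] = BrightnessModel(**kwargs["brightness"])
    for key in ("tophat_radii", "stretch", "models", "feature_groups"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    return RunConfig(**kwargs)


def _derived_seeds(seed: int) -> dict[str, int]:
    state = np.random.SeedSequence(seed).generate_state(4)
    return {
        "phantom": int(state[0] % 2**31),
        "sampler": int(state[1] % 2**31),
        "model": int(state[2] % 2**31),
    }


def run_pipeline(config: RunConfig, out_dir: str | Path, stop_after: str | None = None) -> dict:
    """Execute the staged pipeline and return the run manifest.

    ``stop_after`` names a stage after which to halt (artifacts of completed
    stages are kept); any stage failure aborts with the stage name.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = _derived_seeds(config.seed)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": [],
    }
    stage_state: dict = {}

    def record(name: str, t0: float, outputs: list[str]) -> None:
        manifest["stages"].append({"name": name, "seconds": round(time.time() - t0, 3), "outputs": outputs})
        log.info("stage %s done in %.2fs (%d outputs)", name, time.time() - t0, len(outputs))

    for stage in STAGES:
        t0 = time.time()
        try:
            outputs = _run_stage(stage, config, seeds, stage_state, out_dir)
        except Exception as exc:
            manifest["failed_stage"] = stage
            manifest["error"] = str(exc)
            (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        if outputs is None:  # stage skipped (e.g. classify without ground truth)
            continue
        record(stage, t0, outputs)
        if stop_after == stage:
            break
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _run_stage(stage: str, config: RunConfig, seeds: dict, st: dict, out_dir: Path):
    if stage == "phantom":
        stage_dir = out_dir / "stage1_phantom"
        if config.dicom_dir:
            st["volume"] = volume_io.read_dicom_series(config.dicom_dir)
            st["truth"] = None
            return [config.dicom_dir]
        spec = dataclasses.replace(config.phantom, seed=seeds["phantom"])
        st["volume"], st["truth"] = phantom.generate_phantom(spec)
        stage_dir.mkdir(parents=True, exist_ok=True)
        outputs = []
        if config.write_dicom:
            paths = volume_io.write_dicom_series(st["volume"], stage_dir / "dicom")
            outputs.append(str(stage_dir / "dicom"))
        np.savez_compressed(stage_dir / "truth_labels.npz", labels=st["truth"].labels)
        (stage_dir / "centerlines.json").write_text(
            json.dumps([{"kind": k, "points_mm": line.tolist()} for k, line in st["truth"].centerlines])
        )
        outputs += [str(stage_dir / "truth_labels.npz"), str(stage_dir / "centerlines.json")]
        return outputs

    if stage == "hu_mip":
        stage_dir = out_dir / "stage2_hu_mip"
        hu_vol = hu_projection.convert_volume_to_hu(st["volume"], config.brightness)
        st["mips"] = hu_projection.sliding_mip(hu_vol, config.mip_window, config.mip_stride)
        if st["truth"] is not None:
            clean_vol = dataclasses.replace(st["volume"], data=st["truth"].clean)
            clean_hu = hu_projection.convert_volume_to_hu(clean_vol, config.brightness)
            st["clean_mips"] = hu_projection.sliding_mip(clean_hu, config.mip_window, config.mip_stride)
        else:
            st["clean_mips"] = None
        objs = {f"mip_{k:03d}": img for k, img in enumerate(st["mips"].images)}
        volume_io.write_outputs(objs, stage_dir, overwrite=True)
        return [str(stage_dir)]

    if stage == "skullstrip":
        stage_dir = out_dir / "stage3_skullstrip"
        st["masked"], st["masks"], st["clean_masked"] = [], [], []
        for k, img in enumerate(st["mips"].images):
            masked, mask = skull_removal.strip_skull(img)
            st["masked"].append(masked)
            st["masks"].append(mask)
            if st["clean_mips"] is not None:
                st["clean_masked"].append(skull_removal.apply_mask(st["clean_mips"].images[k], mask))
        objs = {}
        for k in range(len(st["masked"])):
            objs[f"masked_{k:03d}"] = st["masked"][k]
            objs[f"mask_{k:03d}"] = Image2D(st["masks"][k].mask.astype(float), "normalized")
        volume_io.write_outputs(objs, stage_dir, overwrite=True)
        return [str(stage_dir)]

    if stage == "denoise":
        stage_dir = out_dir / "stage4_denoise"
        references = st["clean_masked"] if st["clean_masked"] else st["masked"]
        mid = len(st["masked"]) // 2
        if config.filter_name == "auto":
            _, report = denoising.denoise_auto(st["masked"][mid], references[mid])
            chosen = report.selected
        else:
            chosen = config.filter_name
            bank = denoising.default_filter_bank()
            if chosen not in bank:
                raise ValueError(f"unknown filter {chosen!r}")
            ref = np.asarray(references[mid].data)
            rng_range = float(np.ptp(ref)) or 1.0
            out_mid = bank[chosen](np.asarray(st["masked"][mid].data))
            report = denoising.select_from_scores(
                {chosen: (denoising.psnr(ref, out_mid, rng_range), denoising.ssim(ref, out_mid, L=rng_range)),
                 "unfiltered": (denoising.psnr(ref, st["masked"][mid].data, rng_range),
                                denoising.ssim(ref, st["masked"][mid].data, L=rng_range))},
                reference="clean phantom MIP" if st["clean_masked"] else "pre-filter MIP",
                dynamic_range=rng_range,
            )
        st["quality_report"] = report
        filt = denoising.default_filter_bank()[chosen]
        st["denoised"] = [
            Image2D(filt(np.asarray(img.data)), value_range=img.value_range,
                    provenance=(img.provenance or "") + f" | {chosen}")
            for img in st["masked"]
        ]
        objs = {f"denoised_{k:03d}": img for k, img in enumerate(st["denoised"])}
        objs["quality_report"] = {
            "reference": report.reference,
            "dynamic_range": report.dynamic_range,
            "selected": report.selected,
            "scores": {name: {"PSNR": p, "SSIM": s} for name, (p, s) in report.scores.items()},
        }
        volume_io.write_outputs(objs, stage_dir, overwrite=True)
        return [str(stage_dir)]

    if stage == "enhance":
        stage_dir = out_dir / "stage5_enhance"
        st["enhanced"] = []
        for img in st["denoised"]:
            th = enhancement.multiscale_tophat(img.data, config.tophat_radii)
            adj = enhancement.contrast_adjust(th, *config.stretch)
            st["enhanced"].append(Image2D(adj, value_range="normalized",
                                          provenance=(img.provenance or "") + " | tophat+stretch"))
        objs = {f"enhanced_{k:03d}": img for k, img in enumerate(st["enhanced"])}
        volume_io.write_outputs(objs, stage_dir, overwrite=True)
        return [str(stage_dir)]

    if stage == "features":
        stage_dir = out_dir / "stage6_features"
        if st["truth"] is None:
            patches = features.extract_patches(st["enhanced"][0], config.block, max(config.shift, 8))
            table = features.build_feature_table(patches, levels=config.glcm_levels)
            volume_io.write_outputs({"features": table}, stage_dir, overwrite=True)
            st["train_table"] = None
            return [str(stage_dir)]
        from scipy.ndimage import maximum_filter

        # accumulate pure-neighbourhood patches ahead of mixed ones, so the
        # training set is drawn from expert-style single-vessel regions first
        pure: dict[int, list] = {0: [], 1: []}
        mixed: dict[int, list] = {0: [], 1: []}
        for k, (lo, hi) in enumerate(st["mips"].windows):
            proj = phantom.project_truth(st["truth"].labels, lo, hi)
            sampled = None
            for n_req in range(config.per_mip_per_class, 0, -1):
                try:
                    sampled = phantom.labelled_patch_sampler(
                        st["enhanced"][k], proj, n_req,
                        block=config.block, seed=seeds["sampler"] + k,
                    )
                    break
                except ValueError:
                    continue
            if sampled is None:
                log.warning("MIP %d supplied no labeled patches", k)
                continue
            near = {
                0: maximum_filter((proj == phantom.LABEL_COLLATERAL).astype(np.uint8), size=config.block) > 0,
                1: maximum_filter((proj == phantom.LABEL_NORMAL).astype(np.uint8), size=config.block) > 0,
            }
            half = config.block // 2
            for p in sampled:
                bucket = mixed if near[p.label][p.row + half, p.col + half] else pure
                bucket[p.label].append(p)
        n_test_pos = (config.n_test + 1) // 2
        n_test_neg = config.n_test - n_test_pos
        split_rng = np.random.default_rng(seeds["sampler"])
        selected: dict[int, list] = {}
        for cls, n_req in ((1, config.n_train_per_class + n_test_pos), (0, config.n_train_per_class + n_test_neg)):
            pool = pure[cls] + mixed[cls]
            if len(pool) < n_req:
                raise ValueError(
                    f"insufficient sampled patches for class {cls}: {len(pool)} < {n_req}"
                )
            # keep the purest n_req, then shuffle so train and holdout are
            # exchangeable draws from the same pool
            keep = pool[:n_req]
            selected[cls] = [keep[i] for i in split_rng.permutation(n_req)]
        train_patches = selected[1][: config.n_train_per_class] + selected[0][: config.n_train_per_class]
        test_patches = selected[1][config.n_train_per_class :] + selected[0][config.n_train_per_class :]
        st["train_table"] = features.build_feature_table(train_patches, levels=config.glcm_levels)
        st["test_table"] = features.build_feature_table(test_patches, levels=config.glcm_levels)
        volume_io.write_outputs(
            {"train_features": st["train_table"], "test_features": st["test_table"]},
            stage_dir, overwrite=True,
        )
        return [str(stage_dir)]

    if stage == "classify":
        if st.get("train_table") is None:
            log.info("no ground truth: classification skipped")
            return None
        stage_dir = out_dir / "stage7_classify"
        results = {}
        for group in config.feature_groups:
            cols = FEATURE_GROUPS[group]
            for kind in config.models:
                spec = ModelSpec(kind=kind, seed=seeds["model"])
                cv = classification.crossvalidate(
                    st["train_table"], spec, k=config.cv_folds, feature_columns=cols
                )
                ho = classification.holdout_evaluate(
                    st["train_table"], st["test_table"], spec, feature_columns=cols
                )
                results[f"{group}_{kind}"] = {
                    "cv": _report_dict(cv),
                    "holdout": _report_dict(ho),
                }
        st["eval_results"] = results
        summary = {
            name: {
                "cv_accuracy": res["cv"]["metrics"]["accuracy"],
                "holdout_accuracy": res["holdout"]["metrics"]["accuracy"],
                "cv_auc": res["cv"]["auc"],
            }
            for name, res in results.items()
        }
        volume_io.write_outputs({"evaluation": results, "summary": summary}, stage_dir, overwrite=True)
        return [str(stage_dir)]

    raise ValueError(f"unknown stage {stage!r}")


def _report_dict(report: classification.EvalReport) -> dict:
    return {
        "confusion": {"TP": report.tp, "TN": report.tn, "FP": report.fp, "FN": report.fn},
        "metrics": report.metrics,
        "auc": report.auc,
        "roc_points": report.roc_points,
        "fold_accuracies": report.fold_accuracies,
        "model": report.model,
    }
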