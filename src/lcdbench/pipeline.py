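"""End-to-end experiment orchestration.

``run_experiment`` drives the whole study from one config and one
seed: generate training and test material, train the CNN observer,
score the test set with the CNN and the template observer, simulate a
reader panel, and write the comparison tables:

* ``condition_table.csv`` -- one row per stratum (total, each dose,
  each reconstruction, each size) with CNN AUC, pooled reader AUC,
  their difference and the z-test p-values (raw, BH-adjusted);
* ``template_table.csv`` -- ten-threshold template-matching AUC per
  object size;
* ``reduction_table.csv`` -- bootstrap comparison of AUC reductions
  (reference dose vs each reduced dose, and FBP vs ADMIRE) between
  the CNN and the pooled readers, on the larger-object subset.

Every stage logs its seed and row counts to ``run_log.json``;
manifests and analysis tables are byte-reproducible for a fixed
config, training within the floating-point determinism of the stack.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as lio
from .cnn_detector import (
    DetectorConfig,
    build_detector,
    grad_cam,
    predict_presence,
    save_checkpoint,
    train_detector,
)
from .errors import InvalidDesignError, LcdBenchError
from .phantom_sim import (
    NoiseModel,
    PatchGeometry,
    generate_test_set,
    generate_training_set,
)
from .reader_sim import make_profiles, simulate_ratings
from .roc_stats import (
    ALPHA_POSTHOC,
    ALPHA_PRIMARY,
    bh_adjust,
    bootstrap_auc_reduction,
    compare_auc,
    empirical_auc,
    mrmc_auc,
)
from .template_observer import roc_ten_thresholds, score_manifest

__all__ = ["ExperimentConfig", "run_experiment", "condition_table", "reduction_table"]


@dataclass
class ExperimentConfig:
    """One config to drive the full pipeline (YAML-serializable)."""

    seed: int = 0
    out_dir: str = "lcdbench-run"
    # phantom material
    n_train: int = 10_000
    train_size_range_mm: tuple[float, float] = (3.0, 20.0)
    train_contrast_range_hu: tuple[float, float] = (5.0, 30.0)
    per_cell_present: int = 20
    per_cell_absent: int = 20
    sizes_mm: tuple[float, ...] = (5.0, 9.0)
    contrast_hu: float = 10.0
    doses: tuple[float, ...] = (200.0, 100.0, 50.0, 26.0)
    recons: tuple[str, ...] = ("FBP", "ADMIRE")
    noise: dict = field(default_factory=dict)
    # detector
    detector: dict = field(default_factory=dict)
    # readers
    n_readers: int = 12
    reader_dprime: float = 1.0
    reader_jitter: float = 0.3
    # analysis
    n_boot: int = 2000
    n_gradcam: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "ExperimentConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InvalidDesignError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**raw)
        if not len(cfg.doses):
            raise InvalidDesignError("doses must be non-empty")
        if not len(cfg.sizes_mm):
            raise InvalidDesignError("sizes_mm must be non-empty")
        if not len(cfg.recons):
            raise InvalidDesignError("recons must be non-empty")
        return cfg

    def noise_model(self) -> NoiseModel:
        return NoiseModel(**self.noise)

    def detector_config(self) -> DetectorConfig:
        params = dict(self.detector)
        params.setdefault("seed", self.seed)
        if "filters_per_level" in params:
            params["filters_per_level"] = tuple(params["filters_per_level"])
        return DetectorConfig(**params)


def _strata(manifest: pd.DataFrame) -> list[tuple[str, str, pd.Series]]:
    """Total / per-dose / per-recon / per-size strata masks."""
    out = [("total", "total", pd.Series(True, index=manifest.index))]
    for mas in sorted(manifest["mas"].unique(), reverse=True):
        out.append(("dose", f"{mas:g} mAs", manifest["mas"] == mas))
    for recon in sorted(manifest["recon"].unique()):
        out.append(("recon", recon, manifest["recon"] == recon))
    for size in sorted(manifest["diameter_mm"].unique()):
        out.append(("size", f"{size:g} mm", manifest["diameter_mm"] == size))
    return out


def condition_table(
    manifest: pd.DataFrame,
    dla_scores: np.ndarray,
    ratings: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-stratum CNN vs pooled-reader AUC comparison."""
    rows = []
    for stype, name, mask in _strata(manifest):
        sub = manifest[mask]
        labels = sub["present"].to_numpy().astype(bool)
        scores = dla_scores[mask.to_numpy()]
        a_dla = empirical_auc(scores[labels], scores[~labels])
        sub_ratings = ratings[ratings["case_id"].isin(sub["case_id"])]
        a_rdr = mrmc_auc(sub_ratings, sub, n_boot=n_boot, seed=seed)
        cmp_ = compare_auc(a_dla, a_rdr)
        rows.append(
            {
                "stratum_type": stype,
                "stratum": name,
                "n_cases": int(mask.sum()),
                "auc_dla": a_dla.auc,
                "auc_dla_ci_lo": a_dla.ci95[0],
                "auc_dla_ci_hi": a_dla.ci95[1],
                "auc_readers": a_rdr.auc,
                "auc_readers_ci_lo": a_rdr.ci95[0],
                "auc_readers_ci_hi": a_rdr.ci95[1],
                "difference": cmp_.estimate,
                "z": cmp_.z,
                "p_raw": cmp_.p_raw,
            }
        )
    table = pd.DataFrame(rows)
    table["p_bh"] = bh_adjust(table["p_raw"].to_numpy())
    table["significant_primary"] = table["p_raw"] < ALPHA_PRIMARY
    return table


def template_table(
    manifest: pd.DataFrame, template_scores: np.ndarray
) -> pd.DataFrame:
    """Ten-threshold template-matching AUC, total and per object size."""
    rows = []
    masks = [("total", pd.Series(True, index=manifest.index))]
    masks += [
        (f"{s:g} mm", manifest["diameter_mm"] == s)
        for s in sorted(manifest["diameter_mm"].unique())
    ]
    for name, mask in masks:
        labels = manifest.loc[mask, "present"].to_numpy().astype(bool)
        roc = roc_ten_thresholds(template_scores[mask.to_numpy()], labels)
        rows.append({"stratum": name, "auc_template": roc.auc, "n_cases": int(mask.sum())})
    return pd.DataFrame(rows)


def _ratings_matrix_for(
    ratings: pd.DataFrame, sub: pd.DataFrame
) -> np.ndarray:
    wide = ratings.pivot(index="reader_id", columns="case_id", values="rating")
    return wide.loc[:, sub["case_id"].to_numpy()].to_numpy(dtype=float)


def reduction_table(
    manifest: pd.DataFrame,
    dla_scores: np.ndarray,
    ratings: pd.DataFrame,
    size_mm: float | None = None,
    n_boot: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Bootstrap comparison of AUC reductions between CNN and readers.

    Dose rows compare the reference (highest) dose against each reduced
    dose; the recon row compares FBP against ADMIRE. Restricted to one
    object size (default: the largest), matching the robustness
    analysis design.
    """
    if size_mm is None:
        size_mm = float(manifest["diameter_mm"].max())
    sub = manifest[manifest["diameter_mm"] == size_mm].reset_index(drop=False)
    doses = sorted(sub["mas"].unique(), reverse=True)
    ref_dose = doses[0]

    def arm(mask: pd.Series):
        cases = sub[mask]
        idx = cases["index"].to_numpy()
        return (
            dla_scores[idx],
            cases["present"].to_numpy().astype(bool),
            _ratings_matrix_for(ratings, cases),
        )

    comparisons = [
        (f"{ref_dose:g}->{d:g} mAs", sub["mas"] == ref_dose, sub["mas"] == d)
        for d in doses[1:]
    ]
    recons = sorted(sub["recon"].unique())
    if len(recons) == 2:
        comparisons.append(
            ("FBP->ADMIRE", sub["recon"] == "FBP", sub["recon"] == "ADMIRE")
        )
    rows = []
    for i, (name, m1, m2) in enumerate(comparisons):
        s1, l1, r1 = arm(m1)
        s2, l2, r2 = arm(m2)
        res = bootstrap_auc_reduction(
            s1, l1, s2, l2, r1, r2, n_boot=n_boot, seed=seed + i
        )
        red_a = (
            empirical_auc(s1[l1], s1[~l1]).auc - empirical_auc(s2[l2], s2[~l2]).auc
        )
        rows.append(
            {
                "comparison": name,
                "size_mm": size_mm,
                "reduction_dla": red_a,
                "reduction_readers": red_a - res.estimate,
                "delta": res.estimate,
                "z": res.z,
                "p_raw": res.p_raw,
                "ci_lo": res.ci95[0],
                "ci_hi": res.ci95[1],
            }
        )
    table = pd.DataFrame(rows)
    table["p_bh"] = bh_adjust(table["p_raw"].to_numpy())
    table["significant_posthoc"] = table["p_raw"] < ALPHA_POSTHOC
    return table


def run_experiment(config: ExperimentConfig) -> dict:
    """Run all stages; returns a dict of artifact paths and key numbers."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"seed": config.seed, "stages": {}}
    model = config.noise_model()
    geometry = PatchGeometry()
    stage = "generate-train"
    try:
        t0 = time.time()
        train_manifest, train_images = generate_training_set(
            n_images=config.n_train,
            size_range_mm=config.train_size_range_mm,
            contrast_range_hu=config.train_contrast_range_hu,
            model=model,
            seed=config.seed,
            geometry=geometry,
        )
        lio.save_manifest(train_manifest, out / "train_manifest.csv")
        lio.save_images_npz(
            train_images, list(train_manifest["case_id"]), out / "train_images.npz"
        )
        log["stages"][stage] = {
            "seconds": round(time.time() - t0, 2),
            "rows": len(train_manifest),
            "present": int(train_manifest["present"].sum()),
        }

        stage = "generate-test"
        t0 = time.time()
        test_manifest, test_images = generate_test_set(
            per_cell_present=config.per_cell_present,
            per_cell_absent=config.per_cell_absent,
            sizes_mm=config.sizes_mm,
            contrast_hu=config.contrast_hu,
            doses=config.doses,
            recons=config.recons,
            model=model,
            seed=config.seed + 1,
            geometry=geometry,
        )
        lio.save_manifest(test_manifest, out / "test_manifest.csv")
        lio.save_images_npz(
            test_images, list(test_manifest["case_id"]), out / "test_images.npz"
        )
        log["stages"][stage] = {
            "seconds": round(time.time() - t0, 2),
            "rows": len(test_manifest),
            "present": int(test_manifest["present"].sum()),
        }

        stage = "train-cnn"
        t0 = time.time()
        det_config = config.detector_config()
        detector = build_detector(det_config)
        trained = train_detector(detector, train_manifest, train_images, det_config)
        save_checkpoint(trained, out / "detector.npz")
        log["stages"][stage] = {
            "seconds": round(time.time() - t0, 2),
            "history": trained.history,
        }

        stage = "score-cnn"
        t0 = time.time()
        dla_scores = predict_presence(trained, test_images)
        lio.save_scores(list(test_manifest["case_id"]), dla_scores, out / "scores_dla.csv")
        log["stages"][stage] = {"seconds": round(time.time() - t0, 2)}

        stage = "score-template"
        t0 = time.time()
        tm_scores = score_manifest(
            test_manifest, test_images, contrast_hu=config.contrast_hu
        )
        lio.save_scores(
            list(test_manifest["case_id"]), tm_scores, out / "scores_template.csv"
        )
        log["stages"][stage] = {"seconds": round(time.time() - t0, 2)}

        stage = "simulate-readers"
        t0 = time.time()
        profiles = make_profiles(
            n_readers=config.n_readers,
            dprime=config.reader_dprime,
            jitter=config.reader_jitter,
            seed=config.seed + 2,
        )
        ratings = simulate_ratings(profiles, test_manifest, seed=config.seed + 3)
        lio.save_ratings(ratings, out / "ratings.csv")
        log["stages"][stage] = {
            "seconds": round(time.time() - t0, 2),
            "rows": len(ratings),
        }

        stage = "analyze"
        t0 = time.time()
        cond = condition_table(
            test_manifest, dla_scores, ratings, n_boot=min(config.n_boot, 1000),
            seed=config.seed + 4,
        )
        cond.to_csv(out / "condition_table.csv", index=False)
        tmpl = template_table(test_manifest, tm_scores)
        tmpl.to_csv(out / "template_table.csv", index=False)
        red = reduction_table(
            test_manifest, dla_scores, ratings, n_boot=config.n_boot,
            seed=config.seed + 5,
        )
        red.to_csv(out / "reduction_table.csv", index=False)
        log["stages"][stage] = {"seconds": round(time.time() - t0, 2)}

        if config.n_gradcam > 0:
            stage = "gradcam-gallery"
            _gradcam_gallery(trained, test_manifest, test_images, out, config.n_gradcam)
    except LcdBenchError as err:
        (out / "run_log.json").write_text(json.dumps(log, indent=2))
        raise type(err)(f"stage {stage!r} failed: {err}") from err
    (out / "run_log.json").write_text(json.dumps(log, indent=2))
    return {
        "out_dir": str(out),
        "condition_table": cond,
        "template_table": tmpl,
        "reduction_table": red,
        "log": log,
    }


def _gradcam_gallery(trained, manifest, images, out: Path, n: int) -> None:
    from PIL import Image

    gallery = out / "gradcam"
    gallery.mkdir(exist_ok=True)
    present = manifest[manifest["present"]].head(n)
    for row in present.itertuples():
        cam = grad_cam(trained, images[row.Index])
        rng = cam.max() - cam.min()
        arr = ((cam - cam.min()) / (rng if rng > 0 else 1.0) * 255).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(gallery / f"{row.case_id}.png")
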