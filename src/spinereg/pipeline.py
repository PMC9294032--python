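"""End-to-end coarse-to-fine registration pipeline.

Chains the stages: (cached) DRR database build -> in-plane similarity
search -> source-to-detector intervertebral-distance sweep -> CMA-ES
refinement -> evaluation report.  In phantom mode the CT, its centroid
landmarks and the "intraoperative" radiograph are generated internally at
a hidden pose drawn from the seed, so the run is a pure function of
(config, seed): rerunning with the same config writes byte-identical
result files.

Per-stage poses, errors and timings are logged to the ``spinereg`` logger;
timings are informational only (they depend on the host).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import coarse as coarse_mod
from . import sdsearch as sd_mod
from .drr import CTVolume, Radiograph, build_drr_database, hu_to_mu
from .evaluate import evaluation_report
from .geometry import CArmPose, LandmarkSet
from .io import (PipelineConfig, read_landmarks, read_radiograph, read_volume,
                 write_landmarks, write_radiograph, write_volume)
from .phantom import (NoiseSpec, SimulationTruth, generate_spine_phantom,
                      simulate_intraoperative_xray)
from .refine import RegistrationResult, refine_pose

log = logging.getLogger("spinereg")

__all__ = ["PipelineOutput", "run_pipeline", "draw_hidden_pose"]


@dataclass
class PipelineOutput:
    result: RegistrationResult
    report: "object"            # pandas DataFrame
    coarse_pose: CArmPose
    sd_pose: CArmPose
    truth: SimulationTruth | None
    config_hash: str


def draw_hidden_pose(seed: int) -> CArmPose:
    """Hidden acquisition pose for phantom mode, drawn from the seed.

    Translations: Tx uniform in [-250, -100] mm (source pulled back, i.e.
    magnification in the clinically typical ~1.3-1.7 band), in-plane Ty/Tz
    uniform in [-30, 30] mm (inside the coarse grid and the detector field
    of view); rotations uniform in [-2, 2] degrees (patient positioning
    differences; the gantry itself is not rotated).
    """
    rng = np.random.default_rng(seed)
    tx = rng.uniform(-250.0, -100.0)
    ty, tz = rng.uniform(-30.0, 30.0, size=2)
    rot = rng.uniform(-2.0, 2.0, size=3)
    return CArmPose(translation=(tx, ty, tz), rotation=tuple(rot))


def _stage(name: str, t0: float) -> float:
    t1 = time.perf_counter()
    log.info("stage %-12s %6.2f s", name, t1 - t0)
    return t1


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None
                 ) -> PipelineOutput:
    """Run the full registration and optionally write result artifacts.

    Outputs (under ``out_dir``): ``result.json`` (final pose, mPDE trace,
    config echo with hash and seed), ``report.csv`` (per-stage errors),
    ``coarse_scores.csv`` and ``sd_curve.csv``.  All artifacts embed the
    config hash; reruns with identical config are byte-identical.
    """
    cfg_hash = config.content_hash()
    intr = config.intrinsics()
    t0 = time.perf_counter()

    truth: SimulationTruth | None = None
    if config.phantom_mode:
        volume, lms3d = generate_spine_phantom(
            n_vertebrae=config.phantom_n_vertebrae,
            spacing_mm=config.phantom_spacing_mm,
            seed=config.seed)
        true_pose = (CArmPose.from_vector(config.true_pose)
                     if config.true_pose is not None
                     else draw_hidden_pose(config.seed))
        xray, lms2d, truth = simulate_intraoperative_xray(
            volume, intr, true_pose, lms3d, config.noise_spec(),
            seed=config.seed, mu_water=config.mu_water)
        t0 = _stage("phantom", t0)
    else:
        volume = read_volume(config.ct_path)
        lms3d = read_landmarks(config.ct_landmarks_path)
        xray, _ = read_radiograph(config.xray_path)
        lms2d = read_landmarks(config.xray_landmarks_path)
        if config.true_pose is not None:
            truth = SimulationTruth(CArmPose.from_vector(config.true_pose),
                                    NoiseSpec(), config.seed)
        t0 = _stage("load", t0)

    # world-frame landmarks: same volume-center-to-isocenter placement as
    # the renderer
    lms3d_world = lms3d.translated(intr.isocenter - volume.center)

    mu = hu_to_mu(volume, mu_water=config.mu_water)
    db = build_drr_database(
        mu, intr, range_mm=config.grid_range_mm, step_mm=config.grid_step_mm,
        coarse_pixel_mm=config.coarse_pixel_mm, cache_dir=config.cache_dir)
    t0 = _stage("build-db", t0)

    coarse_res = coarse_mod.spatial_search(xray, db, config.metric)
    log.info("coarse pose: Ty=%+.1f Tz=%+.1f (%s)",
             coarse_res.best_pose.translation[1],
             coarse_res.best_pose.translation[2], config.metric)
    t0 = _stage("coarse", t0)

    sd_res = sd_mod.source_detector_search(
        lms3d_world, lms2d, intr, coarse_res.best_pose,
        start_offset_mm=config.sd_start_offset_mm,
        step_mm=config.sd_step_mm,
        max_advance_mm=config.sd_max_advance_mm,
        truth_2d=lms2d)
    log.info("S-D search: Tx=%+.1f (magnification %.2f)",
             sd_res.best_tx, sd_res.magnification)
    t0 = _stage("sdsearch", t0)

    result = refine_pose(lms3d_world, lms2d, intr, sd_res.pose,
                         dataclasses.replace(config.cmaes, seed=config.seed))
    log.info("refine: mPDE %.4f mm after %d evaluations",
             result.final_mpde, result.evaluations)
    t0 = _stage("refine", t0)

    report = evaluation_report(result, lms3d_world, lms2d, intr, truth,
                               coarse_pose=coarse_res.best_pose,
                               sd_pose=sd_res.pose)
    out = PipelineOutput(result=result, report=report,
                         coarse_pose=coarse_res.best_pose, sd_pose=sd_res.pose,
                         truth=truth, config_hash=cfg_hash)
    if out_dir is not None:
        _write_outputs(out, config, xray, lms2d, Path(out_dir), coarse_res, sd_res)
    return out


def _write_outputs(out: PipelineOutput, config: PipelineConfig,
                   xray: Radiograph, lms2d: LandmarkSet, out_dir: Path,
                   coarse_res, sd_res) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {
        "config": config.to_dict(),
        "config_hash": out.config_hash,
        "seed": config.seed,
        "result": out.result.to_dict(),
        "coarse_pose": list(out.coarse_pose.as_vector()),
        "sd_pose": list(out.sd_pose.as_vector()),
    }
    if out.truth is not None:
        payload["true_pose"] = list(out.truth.true_pose.as_vector())
    (out_dir / "result.json").write_text(
        json.dumps(payload, indent=1, sort_keys=True, default=list))
    out.report.to_csv(out_dir / "report.csv", index=False)
    coarse_res.to_csv(out_dir / "coarse_scores.csv")
    sd_res.to_csv(out_dir / "sd_curve.csv")
    write_radiograph(xray, out_dir / "xray.png", intensity_max=1.0,
                     sidecar={"config_hash": out.config_hash})
    write_landmarks(lms2d, out_dir / "xray_landmarks.csv")
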