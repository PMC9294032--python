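"""Registration-quality metrics and reporting.

The primary quality measure is the mean projection distance error (mPDE,
detector-plane mm; see :func:`spinereg.refine.fitness_mpde`).  For
simulation studies, where the hidden acquisition pose is known, the mean
target registration error (mTRE) complements it: the mean 3D distance
between each CT landmark as mapped by the ground-truth pose and by the
estimated pose.  A reprojection-based error (RPDE — 3D distance between
back-projected estimated points and gold-standard positions) is a further
member of this taxonomy; it is deliberately not implemented here, since the
pipeline's validation rests on mPDE/mTRE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import CArmIntrinsics, CArmPose, LandmarkSet, rotation_matrix
from .phantom import SimulationTruth
from .refine import RegistrationResult, fitness_mpde

__all__ = ["GroundTruthTransform", "rigid_map_points", "mtre", "evaluation_report"]


@dataclass(frozen=True)
class GroundTruthTransform:
    """True acquisition pose (available for simulated data only) together
    with the isocenter about which poses rotate."""

    pose: CArmPose
    isocenter: tuple[float, float, float] = (0.0, 0.0, 0.0)


def rigid_map_points(pose: CArmPose, points: np.ndarray,
                     isocenter=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Map world points into the camera frame of ``pose``:
    ``p_cam = R.T @ (p - ic - t) + ic``."""
    ic = np.asarray(isocenter, dtype=float)
    t = np.asarray(pose.translation, dtype=float)
    R = rotation_matrix(pose.rotation)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    return (pts - ic - t) @ R + ic


def mtre(points3d: LandmarkSet, t_gt: GroundTruthTransform,
         t_reg: CArmPose) -> float:
    """Mean target registration error (mm).

    Mean 3D Euclidean distance between each landmark mapped by the
    ground-truth rigid transform and by the estimated one.  Zero iff the
    two transforms agree on the landmark set; a pure translation offset
    ``t`` between the poses gives exactly ``||t||``.
    """
    if len(points3d) < 1:
        raise ValueError("mTRE needs at least one point")
    if points3d.dim != 3:
        raise ValueError("mTRE expects 3D landmarks")
    a = rigid_map_points(t_gt.pose, points3d.coords, t_gt.isocenter)
    b = rigid_map_points(t_reg, points3d.coords, t_gt.isocenter)
    return float(np.mean(np.linalg.norm(a - b, axis=1)))


def evaluation_report(result: RegistrationResult,
                      volume_landmarks_world: LandmarkSet,
                      xray_landmarks: LandmarkSet,
                      intrinsics: CArmIntrinsics,
                      truth: SimulationTruth | None = None,
                      coarse_pose: CArmPose | None = None,
                      sd_pose: CArmPose | None = None) -> pd.DataFrame:
    """One-row summary table of a registration run.

    Columns: mPDE at each available stage pose (coarse, source-detector,
    refine initial and final), mTRE against the simulation truth when
    available, and the optimizer bookkeeping.  The simulated-data analogue
    of a per-dataset initial/final error table.
    """
    def stage_mpde(pose: CArmPose | None) -> float | None:
        if pose is None:
            return None
        return fitness_mpde(pose, volume_landmarks_world, xray_landmarks, intrinsics)

    row = {
        "coarse_mpde_mm": stage_mpde(coarse_pose),
        "sd_mpde_mm": stage_mpde(sd_pose),
        "initial_mpde_mm": result.init_mpde if result.init_mpde is not None
        else stage_mpde(result.init_pose),
        "final_mpde_mm": result.final_mpde,
        "evaluations": result.evaluations,
        "converged": result.converged,
        "seed": result.seed,
    }
    for name, pose in (("coarse", coarse_pose), ("sd", sd_pose),
                       ("final", result.final_pose)):
        if pose is not None:
            vec = pose.as_vector()
            for i, p in enumerate(("tx", "ty", "tz", "rx", "ry", "rz")):
                row[f"{name}_{p}"] = vec[i]
    if truth is not None:
        gt = GroundTruthTransform(truth.true_pose, tuple(intrinsics.isocenter))
        row["mtre_mm"] = mtre(volume_landmarks_world, gt, result.final_pose)
        vec = truth.true_pose.as_vector()
        for i, p in enumerate(("tx", "ty", "tz", "rx", "ry", "rz")):
            row[f"true_{p}"] = vec[i]
    return pd.DataFrame([row])
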