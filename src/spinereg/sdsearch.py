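"""Stage 2 coarse registration: source-to-detector (out-of-plane) search.

Intensity similarity is a poor guide along the source-to-detector axis, so
this stage localizes the out-of-plane translation Tx — equivalently the
projection magnification SDD/SOD — from geometry instead: the consecutive
intervertebral centroid distances measured in the radiograph (LX) are
compared with the same distances among the projected CT centroids (LD)
while the C-arm is swept along the viewing axis.  The sweep starts with the
source pulled back to a far point (FP, default 400 mm behind nominal) and
advances toward the volume in fixed steps; the Tx minimizing
``sum_i |LD_i - LX_i|`` is the estimate.

Correspondence is by vertebral label (levels present in both sets, in
anatomical order), replacing the manual level identification a surgeon
would perform.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import (CArmIntrinsics, CArmPose, GeometryError, LandmarkSet,
                       build_projection, level_sort_key, project_array)

__all__ = ["SDSearchResult", "intervertebral_lengths", "source_detector_search"]


@dataclass
class SDSearchResult:
    best_tx: float
    magnification: float          # SDD / SOD of the volume center at best_tx
    curve: pd.DataFrame           # tx, sum_abs_len_diff, magnification[, mpde]
    pose: CArmPose                # base pose with Tx substituted

    def to_csv(self, path) -> None:
        self.curve.to_csv(path, index=False)


def intervertebral_lengths(landmarks2d: LandmarkSet,
                           pixel_mm: float = 1.0) -> np.ndarray:
    """Consecutive centroid-to-centroid Euclidean distances in mm.

    Landmarks are sorted into anatomical (superior-to-inferior) level order
    first; N landmarks yield N-1 distances.  ``pixel_mm`` converts pixel
    coordinates to mm (use 1.0 for coordinates already in mm).
    """
    if len(landmarks2d) < 2:
        raise ValueError("need at least 2 landmarks for intervertebral lengths")
    ordered = landmarks2d.sorted_by_level()
    diffs = np.diff(ordered.coords, axis=0) * pixel_mm
    return np.linalg.norm(diffs, axis=1)


def source_detector_search(volume_landmarks_world: LandmarkSet,
                           xray_landmarks: LandmarkSet,
                           intrinsics: CArmIntrinsics,
                           base_pose: CArmPose,
                           start_offset_mm: float = 400.0,
                           step_mm: float = 10.0,
                           max_advance_mm: float = 200.0,
                           xray_pixel_mm: float | None = None,
                           truth_2d: LandmarkSet | None = None
                           ) -> SDSearchResult:
    """Sweep Tx and match intervertebral distances.

    ``base_pose`` supplies the in-plane translations from the spatial
    search (held fixed); Tx runs from ``-start_offset_mm`` (source at the
    far point) toward the volume up to ``+max_advance_mm`` in ``step_mm``
    increments.  At each step the 3D centroids (world frame) are projected,
    consecutive distances LD are computed on the detector (mm) and compared
    with the radiograph distances LX; the minimizing Tx wins (ties break to
    the lowest Tx).  Steps with degenerate geometry are skipped with a
    warning.  When ``truth_2d`` is given the per-step mPDE is recorded too.
    """
    if xray_pixel_mm is None:
        xray_pixel_mm = float(intrinsics.pixel_size[0])
    common = sorted(set(volume_landmarks_world.labels) & set(xray_landmarks.labels),
                    key=level_sort_key)
    if len(common) < 2:
        raise ValueError(
            f"need >=2 matched labels, got {common} from "
            f"{volume_landmarks_world.labels} vs {xray_landmarks.labels}")
    vol = volume_landmarks_world.subset(common)
    lx = intervertebral_lengths(xray_landmarks.subset(common), xray_pixel_mm)

    tx_values = np.arange(-start_offset_mm, max_advance_mm + step_mm / 2, step_mm)
    px = float(intrinsics.pixel_size[0])
    ty, tz = base_pose.translation[1], base_pose.translation[2]
    rows = []
    for tx in tx_values:
        pose = CArmPose(translation=(float(tx), ty, tz), rotation=base_pose.rotation)
        matrix = build_projection(intrinsics, pose)
        uv, depth = project_array(matrix, vol.coords)
        if np.any(depth <= 0) or np.any(depth >= intrinsics.sdd):
            warnings.warn(f"degenerate geometry at Tx={tx:+.0f} mm, step skipped")
            continue
        proj = LandmarkSet(list(vol.labels), uv)
        ld = intervertebral_lengths(proj, px)
        row = {"tx": float(tx),
               "sum_abs_len_diff": float(np.abs(ld - lx).sum()),
               "magnification": intrinsics.sdd / (intrinsics.sdd / 2.0 - tx)}
        if truth_2d is not None:
            from .refine import fitness_mpde
            row["mpde"] = fitness_mpde(pose, vol, truth_2d, intrinsics)
        rows.append(row)
    if not rows:
        raise GeometryError("all sweep steps were geometrically degenerate")
    curve = pd.DataFrame(rows)
    best = curve.sort_values(["sum_abs_len_diff", "tx"],
                             kind="mergesort").iloc[0]
    best_tx = float(best["tx"])
    pose = CArmPose(translation=(best_tx, ty, tz), rotation=base_pose.rotation)
    return SDSearchResult(best_tx=best_tx,
                          magnification=float(best["magnification"]),
                          curve=curve, pose=pose)
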