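"""Stage 1 coarse registration: exhaustive in-plane similarity search.

The intraoperative radiograph (resampled to the database's coarse
resolution) is scored against every entry of the preoperative DRR database;
the argmax over the (Ty, Tz) translation grid is the coarse 2-DOF estimate.
Both images are min-max normalized to a common range before scoring, since
DRR and radiograph intensities are not on a shared scale.

Ties (possible with quantized images) break deterministically to the
lexicographically smallest pose: lowest Ty, then lowest Tz.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .drr import DRRDatabase, Radiograph, resample_image
from .geometry import CArmIntrinsics, CArmPose, LandmarkSet
from .similarity import METRICS, ZeroVarianceError, compute_metric

__all__ = ["CoarseResult", "spatial_search", "rank_metrics"]


@dataclass
class CoarseResult:
    """Outcome of the in-plane exhaustive search."""

    best_pose: CArmPose
    scores: pd.DataFrame  # columns: ty, tz, score
    metric: str

    @property
    def best_score(self) -> float:
        return float(self.scores["score"].max())

    def to_csv(self, path) -> None:
        self.scores.to_csv(path, index=False)


def _prepare_xray(xray: Radiograph, db: DRRDatabase) -> np.ndarray:
    img = resample_image(xray, db.pixel_mm) if not math.isclose(
        xray.pixel_spacing[0], db.pixel_mm) else xray
    return np.asarray(img.pixels, dtype=np.float64)


def spatial_search(xray: Radiograph, db: DRRDatabase, metric: str = "psnr"
                   ) -> CoarseResult:
    """Score the radiograph against every database DRR; return the argmax.

    The radiograph is resampled to the database resolution if needed; both
    images are normalized identically before each metric evaluation.
    Entries where the metric is undefined (e.g. zero-variance NCC) score
    ``-inf``.  Returns the full score surface for plotting/auditing; the
    best pose is a grid member and its score is the table maximum.
    """
    if len(db) == 0:
        raise ValueError("empty DRR database")
    metric = metric.lower()
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    target = _prepare_xray(xray, db)
    rows = []
    for i in range(len(db)):
        entry = db.image_float(i)
        if entry.shape != target.shape:
            raise ValueError(
                f"radiograph shape {target.shape} does not match database "
                f"entries {entry.shape} at {db.pixel_mm} mm")
        try:
            score = float(compute_metric(metric, entry, target, normalize=True))
        except ZeroVarianceError:
            score = -math.inf
        ty, tz = db.poses[i].translation[1], db.poses[i].translation[2]
        rows.append((ty, tz, score))
    table = pd.DataFrame(rows, columns=["ty", "tz", "score"])
    best = table.sort_values(["score", "ty", "tz"],
                             ascending=[False, True, True],
                             kind="mergesort").iloc[0]
    pose = CArmPose(translation=(0.0, float(best["ty"]), float(best["tz"])))
    return CoarseResult(best_pose=pose, scores=table, metric=metric)


def rank_metrics(xray: Radiograph, db: DRRDatabase,
                 truth_2d: LandmarkSet, volume_landmarks_world: LandmarkSet,
                 intrinsics: CArmIntrinsics) -> pd.DataFrame:
    """Compare all five metrics by the landmark error of their argmax pose.

    For each metric, runs :func:`spatial_search`, projects the 3D centroids
    at the winning pose and computes the mean projection distance error
    (mm) against the ground-truth 2D centroids.  Returns a 5-row table
    sorted by mPDE (best metric first).

    ``volume_landmarks_world`` must already be in world coordinates (volume
    placement applied).
    """
    from .refine import fitness_mpde  # local import avoids a cycle

    rows = []
    for metric in METRICS:
        res = spatial_search(xray, db, metric)
        mpde = fitness_mpde(res.best_pose, volume_landmarks_world, truth_2d,
                            intrinsics)
        ty, tz = res.best_pose.translation[1], res.best_pose.translation[2]
        rows.append({"metric": metric, "ty": ty, "tz": tz,
                     "score": res.best_score, "mpde_mm": mpde})
    return (pd.DataFrame(rows)
            .sort_values("mpde_mm", kind="mergesort")
            .reset_index(drop=True))
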