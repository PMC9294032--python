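"""Synthetic spine phantom: CT volumes with labeled vertebral centroids and
simulated intraoperative radiographs at hidden poses.

The phantom emulates a cropped thoracolumbar preoperative CT: a column of
vertebra-like bodies (high-HU ellipsoids with a posterior-process blob)
evenly spaced along the superior-inferior axis, embedded in a soft-tissue
cylinder over an air background.  Each body's exact analytic center is
stored as its labeled centroid landmark, so every later pipeline stage can
be tested against known ground truth without clinical data.

Anatomical realism is limited to what the registration method needs: the
bodies give the similarity metrics distinct structure along the SI axis, a
mild mediolateral curvature plus per-vertebra jitter breaks exact
collinearity of the centroids (as a real spine does), and an additive
Gaussian noise + gamma contrast perturbation stands in for the
intraoperative contrast/kVp variability of a real fluoroscope.  No scatter,
beam hardening or distortion is modeled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .drr import CTVolume, Radiograph, hu_to_mu, raycast_drr
from .geometry import (CArmIntrinsics, CArmPose, LandmarkSet, build_projection,
                       project_points)

__all__ = [
    "NoiseSpec",
    "SimulationTruth",
    "generate_spine_phantom",
    "simulate_intraoperative_xray",
    "default_intrinsics",
    "HU_BONE",
    "HU_PROCESS",
    "HU_SOFT",
    "HU_AIR",
]

# plausible CT palette (free parameters; the method only needs bone >> soft)
HU_BONE = 700.0      # vertebral body core
HU_PROCESS = 300.0   # posterior process blob
HU_SOFT = 40.0       # soft-tissue background
HU_AIR = -1000.0


@dataclass(frozen=True)
class NoiseSpec:
    """Radiograph perturbation: additive Gaussian sigma (on the [0, I0]
    intensity scale) and a gamma contrast exponent (1 = unchanged)."""

    sigma: float = 0.0
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma < 0 or self.gamma <= 0:
            raise ValueError(f"invalid noise spec sigma={self.sigma} gamma={self.gamma}")


@dataclass(frozen=True)
class SimulationTruth:
    """Hidden acquisition parameters of a simulated radiograph."""

    true_pose: CArmPose
    noise_spec: NoiseSpec
    seed: int


def default_intrinsics() -> CArmIntrinsics:
    """Default C-arm geometry used with the phantom: SDD 1000 mm, 1 mm
    detector pixels, 384 mm square detector (keeps every phantom level in
    view across the coarse search grid)."""
    return CArmIntrinsics(sdd=1000.0, pixel_size=(1.0, 1.0), detector_size=(384, 384))


_LEVEL_NAMES = [f"T{i}" for i in range(1, 13)] + [f"L{i}" for i in range(1, 6)]


def _level_labels(n: int) -> list[str]:
    """Thoracolumbar labels ending at L4 (e.g. n=5 -> T12..L4), mirroring a
    crop around the thoracic-to-lumbar transition."""
    if n > len(_LEVEL_NAMES):
        raise ValueError(f"at most {len(_LEVEL_NAMES)} vertebrae supported, got {n}")
    end = _LEVEL_NAMES.index("L4") + 1
    return _LEVEL_NAMES[end - n:end]


def generate_spine_phantom(n_vertebrae: int = 5,
                           spacing_mm: float = 30.0,
                           body_radius_mm: float = 14.0,
                           volume_shape: tuple[int, int, int] = (64, 64, 112),
                           voxel_mm: float = 2.0,
                           seed: int = 0,
                           curve_amplitude_mm: float = 5.0,
                           jitter_mm: float = 1.5) -> tuple[CTVolume, LandmarkSet]:
    """Generate a spine-like CT volume and its exact centroid landmarks.

    Vertebral bodies are ellipsoids (semi-axes ``0.8 r, r, 0.6 r`` along
    AP/ML/SI for ``r = body_radius_mm``) of ``HU_BONE`` with a posterior
    ``HU_PROCESS`` blob, centered every ``spacing_mm`` along the SI (z)
    axis.  A gentle sinusoidal mediolateral curve of amplitude
    ``curve_amplitude_mm`` plus per-vertebra uniform jitter (``+-jitter_mm``,
    seeded) keeps the centroids realistically non-collinear.  The volume is
    centered on its own origin; landmark coordinates are in the same frame.

    Raises ``ValueError`` if consecutive bodies would overlap or any body
    would leave the soft-tissue region / volume.
    """
    if n_vertebrae < 1:
        raise ValueError("n_vertebrae must be >= 1")
    rng = np.random.default_rng(seed)
    shape = tuple(int(s) for s in volume_shape)
    sp = float(voxel_mm)
    extent = np.asarray(shape) * sp
    origin = -(np.asarray(shape) - 1) * sp / 2.0  # volume centered at 0

    r = float(body_radius_mm)
    semi = np.array([0.8 * r, r, 0.6 * r])  # (x=AP, y=ML, z=SI)
    proc_r = 0.35 * r
    proc_dx = semi[0] + 0.6 * proc_r

    z0 = -spacing_mm * (n_vertebrae - 1) / 2.0
    centers = []
    for k in range(n_vertebrae):
        frac = k / max(n_vertebrae - 1, 1)
        cy = curve_amplitude_mm * math.sin(math.pi * frac)
        jitter = rng.uniform(-jitter_mm, jitter_mm, size=3)
        centers.append(np.array([0.0, cy, z0 + k * spacing_mm]) + jitter)
    centers = np.asarray(centers)

    # geometry guards: no overlap along SI, everything inside the volume
    if n_vertebrae > 1:
        gaps = np.diff(centers[:, 2])
        if np.any(gaps < 2 * semi[2]):
            raise ValueError(
                f"vertebral bodies overlap: min SI gap {gaps.min():.1f} mm "
                f"< body height {2 * semi[2]:.1f} mm")
    lo = centers - (semi + np.array([proc_dx + proc_r - semi[0], 0, 0]))
    hi = centers + semi
    half = extent / 2.0
    if np.any(lo < -half) or np.any(hi > half):
        raise ValueError("vertebral bodies exit the volume; enlarge volume_shape")

    # voxel center coordinates
    xs = origin[0] + sp * np.arange(shape[0])
    ys = origin[1] + sp * np.arange(shape[1])
    zs = origin[2] + sp * np.arange(shape[2])
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")

    hu = np.full(shape, HU_AIR, dtype=np.float64)
    # soft-tissue elliptic cylinder along SI
    soft_ax = min(half[0] - sp, 50.0)
    soft_ay = min(half[1] - sp, 58.0)
    soft = (X / soft_ax) ** 2 + (Y / soft_ay) ** 2 <= 1.0
    hu[soft] = HU_SOFT

    for c in centers:
        body = (((X - c[0]) / semi[0]) ** 2 + ((Y - c[1]) / semi[1]) ** 2
                + ((Z - c[2]) / semi[2]) ** 2) <= 1.0
        hu[body] = HU_BONE
        pc = c + np.array([proc_dx, 0.0, 0.0])
        proc = ((X - pc[0]) ** 2 + (Y - pc[1]) ** 2 + (Z - pc[2]) ** 2) <= proc_r ** 2
        hu[proc & ~body] = HU_PROCESS

    volume = CTVolume(hu, (sp, sp, sp), tuple(origin))
    volume.validate_hu()
    landmarks = LandmarkSet(_level_labels(n_vertebrae), centers)
    return volume, landmarks


def simulate_intraoperative_xray(volume: CTVolume,
                                 intrinsics: CArmIntrinsics,
                                 true_pose: CArmPose,
                                 landmarks: LandmarkSet,
                                 noise_spec: NoiseSpec = NoiseSpec(),
                                 seed: int = 0,
                                 mu_water: float = 0.02,
                                 out_pixel_mm: float | None = None,
                                 backend: str = "auto",
                                 ) -> tuple[Radiograph, LandmarkSet, SimulationTruth]:
    """Render the phantom's "intraoperative X-ray" at a hidden pose.

    The image is the DRR at ``true_pose`` with additive Gaussian noise and a
    gamma contrast change applied (identity for the default noise spec); the
    returned 2D landmarks are the *exact* projections of the 3D centroids at
    the true pose, shifted with the same volume-to-isocenter placement the
    renderer uses.  Same seed, same image — the noise field is drawn from
    ``seed`` alone.
    """
    mu = hu_to_mu(volume, mu_water=mu_water)
    drr = raycast_drr(mu, intrinsics, true_pose, out_pixel_mm, backend=backend)
    img = drr.pixels
    if noise_spec.sigma > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_spec.sigma, size=img.shape)
    if noise_spec.gamma != 1.0:
        img = np.clip(img, 0.0, None) ** noise_spec.gamma
    img = np.clip(img, 0.0, None)

    # landmark frame == volume frame; renderer shifts volume center to isocenter
    world_lms = landmarks.translated(intrinsics.isocenter - volume.center)
    proj = project_points(build_projection(intrinsics, true_pose), world_lms)
    xray = Radiograph(img, drr.pixel_spacing, provenance="simulated-xray")
    return xray, proj, SimulationTruth(true_pose, noise_spec, seed)
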