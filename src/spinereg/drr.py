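"""Digitally reconstructed radiograph (DRR) engine.

Renders synthetic radiographs from a CT volume by Beer-Lambert line
integration along source-to-pixel rays,

    I = I0 * exp(-sum_i mu_i * l_i),

where ``l_i`` are the *exact* intersection lengths of the ray with each
voxel, obtained by incremental Siddon traversal (not fixed-step sampling).
Hounsfield units are mapped to linear attenuation via the water-relative
scaling ``mu = (1000 + HU) / 1000 * mu_water``, clamped below at zero.

The module also builds the preoperative DRR database: one coarse-resolution
DRR per in-plane C-arm translation on a regular (Ty, Tz) grid, cached on
disk as 16-bit PNGs so the expensive rendering happens once.  Database
images are quantized to 16 bits *in memory as well*, so the in-memory and
reloaded databases are bit-identical.

Array conventions: CT voxels are indexed ``[ix, iy, iz]`` along the world
(x=AP, y=ML, z=SI) axes; radiograph pixels are indexed ``[v, u]`` (row =
detector v = SI, column = detector u = ML).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import CArmIntrinsics, CArmPose, GeometryError, camera_frame

__all__ = [
    "CTVolume",
    "Radiograph",
    "DRRDatabase",
    "hu_to_mu",
    "raycast_drr",
    "ray_path_integrals",
    "resample_image",
    "resample_volume",
    "build_drr_database",
    "load_drr_database",
    "save_drr_database",
]

HU_MIN, HU_MAX = -1024.0, 3071.0
QUANT = 65535  # 16-bit quantization of DRR intensities in [0, I0]


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass
class CTVolume:
    """3D voxel grid with spacing and origin.

    ``voxels[ix, iy, iz]`` holds HU values (or attenuation coefficients
    after :func:`hu_to_mu`); ``origin`` is the world position (mm) of the
    *center* of voxel ``(0, 0, 0)`` in the volume's own coordinate frame.
    The renderer places the volume center at the C-arm isocenter.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3D, got shape {self.voxels.shape}")
        if not all(s > 0 and math.isfinite(s) for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def center(self) -> np.ndarray:
        """World position of the volume center (mm, own frame)."""
        sp = np.asarray(self.spacing)
        return np.asarray(self.origin) + (np.asarray(self.shape) - 1) * sp / 2.0

    @property
    def extent_mm(self) -> np.ndarray:
        return np.asarray(self.shape) * np.asarray(self.spacing)

    def validate_hu(self) -> None:
        v = self.voxels
        if not np.all(np.isfinite(v)):
            raise ValueError("volume contains non-finite HU values")
        if v.size and (v.min() < HU_MIN or v.max() > HU_MAX):
            raise ValueError(
                f"HU values outside [{HU_MIN}, {HU_MAX}]: range [{v.min()}, {v.max()}]")


@dataclass
class Radiograph:
    """2D intensity image with physical pixel spacing.

    ``provenance`` records how the image was produced: ``"drr"``,
    ``"simulated-xray"`` or ``"file"``.
    """

    pixels: np.ndarray
    pixel_spacing: tuple[float, float]  # (mm along v/rows, mm along u/cols)
    provenance: str = "drr"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"radiograph must be 2D, got shape {self.pixels.shape}")
        if not all(s > 0 for s in self.pixel_spacing):
            raise ValueError(f"pixel spacing must be positive, got {self.pixel_spacing}")
        if not np.all(np.isfinite(self.pixels)) or (
                self.pixels.size and self.pixels.min() < 0):
            raise ValueError("radiograph intensities must be finite and non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


# --------------------------------------------------------------------------
# HU -> attenuation
# --------------------------------------------------------------------------

def hu_to_mu(volume: CTVolume, mu_water: float = 0.02) -> CTVolume:
    """Map HU values to linear attenuation coefficients (1/mm).

    ``mu = (1000 + HU)/1000 * mu_water`` with negative results clamped to 0
    (air at -1000 HU maps exactly to zero attenuation; water at 0 HU maps to
    ``mu_water``).
    """
    if not (mu_water > 0 and math.isfinite(mu_water)):
        raise ValueError(f"mu_water must be positive, got {mu_water}")
    hu = volume.voxels
    if not np.all(np.isfinite(hu)):
        raise ValueError("volume contains non-finite HU values")
    mu = np.maximum((1000.0 + hu.astype(np.float64)) / 1000.0 * mu_water, 0.0)
    return CTVolume(mu, volume.spacing, volume.origin)


# --------------------------------------------------------------------------
# Siddon ray traversal
# --------------------------------------------------------------------------
#
# Primary path: an incremental Siddon kernel compiled with numba (exact
# per-voxel intersection lengths, O(steps) per ray, no temporaries).
# Reference path: a vectorized numpy implementation collecting all plane
# crossings; slower but independent, used as fallback and cross-check.

def _siddon_rays_py(mu, bmin, h, src, pix, out):  # pragma: no cover - numba source
    nx, ny, nz = mu.shape
    bmax0 = bmin[0] + nx * h[0]
    bmax1 = bmin[1] + ny * h[1]
    bmax2 = bmin[2] + nz * h[2]
    nrays = pix.shape[0]
    for r in range(nrays):
        dx = pix[r, 0] - src[0]
        dy = pix[r, 1] - src[1]
        dz = pix[r, 2] - src[2]
        raylen = math.sqrt(dx * dx + dy * dy + dz * dz)
        # slab entry/exit in ray parameter t in [0, 1]
        tmin = 0.0
        tmax = 1.0
        miss = False
        for k in range(3):
            if k == 0:
                d, a, lo, hi = dx, src[0], bmin[0], bmax0
            elif k == 1:
                d, a, lo, hi = dy, src[1], bmin[1], bmax1
            else:
                d, a, lo, hi = dz, src[2], bmin[2], bmax2
            if d == 0.0:
                if a < lo or a > hi:
                    miss = True
                    break
            else:
                t1 = (lo - a) / d
                t2 = (hi - a) / d
                if t1 > t2:
                    t1, t2 = t2, t1
                if t1 > tmin:
                    tmin = t1
                if t2 < tmax:
                    tmax = t2
        if miss or tmax <= tmin:
            out[r] = 0.0
            continue
        # entry voxel (midpoint of first tiny step avoids boundary ties)
        eps = 1e-12
        tm = tmin + eps * (tmax - tmin)
        ix = int((src[0] + tm * dx - bmin[0]) / h[0])
        iy = int((src[1] + tm * dy - bmin[1]) / h[1])
        iz = int((src[2] + tm * dz - bmin[2]) / h[2])
        if ix < 0:
            ix = 0
        elif ix > nx - 1:
            ix = nx - 1
        if iy < 0:
            iy = 0
        elif iy > ny - 1:
            iy = ny - 1
        if iz < 0:
            iz = 0
        elif iz > nz - 1:
            iz = nz - 1
        big = 1e30
        if dx > 0.0:
            stepx, tdx = 1, h[0] / dx
            tnx = (bmin[0] + (ix + 1) * h[0] - src[0]) / dx
        elif dx < 0.0:
            stepx, tdx = -1, -h[0] / dx
            tnx = (bmin[0] + ix * h[0] - src[0]) / dx
        else:
            stepx, tdx, tnx = 0, big, big
        if dy > 0.0:
            stepy, tdy = 1, h[1] / dy
            tny = (bmin[1] + (iy + 1) * h[1] - src[1]) / dy
        elif dy < 0.0:
            stepy, tdy = -1, -h[1] / dy
            tny = (bmin[1] + iy * h[1] - src[1]) / dy
        else:
            stepy, tdy, tny = 0, big, big
        if dz > 0.0:
            stepz, tdz = 1, h[2] / dz
            tnz = (bmin[2] + (iz + 1) * h[2] - src[2]) / dz
        elif dz < 0.0:
            stepz, tdz = -1, -h[2] / dz
            tnz = (bmin[2] + iz * h[2] - src[2]) / dz
        else:
            stepz, tdz, tnz = 0, big, big
        t = tmin
        path = 0.0
        while t < tmax:
            if tnx <= tny and tnx <= tnz:
                tn = tnx
            elif tny <= tnz:
                tn = tny
            else:
                tn = tnz
            if tn > tmax:
                tn = tmax
            seg = tn - t
            if seg > 0.0:
                path += mu[ix, iy, iz] * seg
            t = tn
            advanced = False
            if tnx <= t:
                ix += stepx
                tnx += tdx
                advanced = True
                if ix < 0 or ix >= nx:
                    break
            if tny <= t:
                iy += stepy
                tny += tdy
                advanced = True
                if iy < 0 or iy >= ny:
                    break
            if tnz <= t:
                iz += stepz
                tnz += tdz
                advanced = True
                if iz < 0 or iz >= nz:
                    break
            if not advanced:
                break
        out[r] = path * raylen


try:  # numba JIT of the same kernel; fall back to numpy path if unavailable
    import numba as _numba

    _siddon_rays = _numba.njit(_siddon_rays_py, cache=True, fastmath=False)
    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _siddon_rays = None
    HAVE_NUMBA = False


def _integrate_rays_numpy(mu: np.ndarray, bmin: np.ndarray, h: np.ndarray,
                          src: np.ndarray, pix: np.ndarray) -> np.ndarray:
    """Reference Siddon integrator: collect every axis-plane crossing,
    sort, and accumulate exact per-voxel segment lengths.  Vectorized over
    rays; memory O(nrays * (nx+ny+nz))."""
    mu = np.asarray(mu, dtype=np.float64)
    shape = np.asarray(mu.shape)
    bmax = bmin + shape * h
    d = pix - src[None, :]  # (N, 3)
    raylen = np.linalg.norm(d, axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = (bmin[None, :] - src[None, :]) / d
        t2 = (bmax[None, :] - src[None, :]) / d
    parallel = d == 0.0
    inside = (src[None, :] >= bmin[None, :]) & (src[None, :] <= bmax[None, :])
    tlo = np.where(parallel, np.where(inside, -np.inf, np.inf), np.minimum(t1, t2))
    thi = np.where(parallel, np.where(inside, np.inf, -np.inf), np.maximum(t1, t2))
    tmin = np.clip(tlo.max(axis=1), 0.0, None)
    tmax = np.clip(thi.min(axis=1), None, 1.0)
    hit = tmax > tmin
    tmin = np.where(hit, tmin, 0.0)
    tmax = np.where(hit, tmax, 0.0)

    cols = [tmin[:, None], tmax[:, None]]
    for k in range(3):
        planes = bmin[k] + h[k] * np.arange(shape[k] + 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            tp = (planes[None, :] - src[k]) / d[:, k:k + 1]
        tp = np.where(np.isfinite(tp), tp, np.inf)
        cols.append(tp)
    ts = np.concatenate(cols, axis=1)
    ts = np.clip(ts, tmin[:, None], tmax[:, None])
    ts.sort(axis=1)
    seg = np.diff(ts, axis=1)
    mid = 0.5 * (ts[:, :-1] + ts[:, 1:])
    pts = src[None, None, :] + mid[:, :, None] * d[:, None, :]
    idx = np.floor((pts - bmin[None, None, :]) / h[None, None, :]).astype(np.int64)
    np.clip(idx, 0, shape[None, None, :] - 1, out=idx)
    vals = mu[idx[..., 0], idx[..., 1], idx[..., 2]]
    return (vals * seg).sum(axis=1) * raylen


def ray_path_integrals(mu_volume: CTVolume, src: np.ndarray, pix: np.ndarray,
                       *, backend: str = "auto") -> np.ndarray:
    """Line integrals ``sum_i mu_i * l_i`` for rays from ``src`` (3,) to the
    rows of ``pix`` (N, 3), all in the volume's own frame (mm).

    ``backend`` is ``"auto"`` (numba when available), ``"numba"`` or
    ``"numpy"`` (the independent reference path).
    """
    mu = np.ascontiguousarray(mu_volume.voxels, dtype=np.float64)
    h = np.asarray(mu_volume.spacing, dtype=np.float64)
    bmin = np.asarray(mu_volume.origin, dtype=np.float64) - h / 2.0
    src = np.asarray(src, dtype=np.float64).reshape(3)
    pix = np.ascontiguousarray(np.asarray(pix, dtype=np.float64).reshape(-1, 3))
    if backend == "auto":
        backend = "numba" if HAVE_NUMBA else "numpy"
    if backend == "numba":
        if not HAVE_NUMBA:
            raise RuntimeError("numba backend requested but numba is unavailable")
        out = np.empty(len(pix), dtype=np.float64)
        _siddon_rays(mu, bmin, h, src, pix, out)
        return out
    if backend == "numpy":
        out = np.empty(len(pix), dtype=np.float64)
        chunk = 8192  # bound the O(nrays * nplanes) temporaries
        for lo in range(0, len(pix), chunk):
            out[lo:lo + chunk] = _integrate_rays_numpy(mu, bmin, h, src, pix[lo:lo + chunk])
        return out
    raise ValueError(f"unknown backend {backend!r}")


# --------------------------------------------------------------------------
# DRR rendering
# --------------------------------------------------------------------------

def _detector_grid_mm(intrinsics: CArmIntrinsics, out_pixel_mm: float
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Centers (mm, relative to the COP) of the output pixel grid covering
    the native detector field of view at spacing ``out_pixel_mm``."""
    u0, v0 = intrinsics.cop  # type: ignore[misc]
    px, py = intrinsics.pixel_size
    nu, nv = intrinsics.detector_size
    y_lo, y_hi = (-0.5 - u0) * px, (nu - 0.5 - u0) * px
    z_lo, z_hi = (-0.5 - v0) * py, (nv - 0.5 - v0) * py
    n_u = max(1, int(round((y_hi - y_lo) / out_pixel_mm)))
    n_v = max(1, int(round((z_hi - z_lo) / out_pixel_mm)))
    y = y_lo + (np.arange(n_u) + 0.5) * out_pixel_mm
    z = z_lo + (np.arange(n_v) + 0.5) * out_pixel_mm
    return y, z


def _volume_world_origin(volume: CTVolume, intrinsics: CArmIntrinsics) -> np.ndarray:
    """Origin of the volume once its center is placed on the isocenter."""
    return intrinsics.isocenter + (np.asarray(volume.origin) - volume.center)


def raycast_drr(mu_volume: CTVolume, intrinsics: CArmIntrinsics, pose: CArmPose,
                out_pixel_mm: float | None = None, i0: float = 1.0,
                *, backend: str = "auto") -> Radiograph:
    """Render a DRR of the attenuation volume at the given C-arm pose.

    One ray is cast from the (moved) source through each output pixel center
    at spacing ``out_pixel_mm`` (default: the native detector pixel size);
    pixel intensity is ``I0 * exp(-sum mu_i l_i)`` with exact Siddon
    intersection lengths.  Rays missing the volume return ``I0``.  The
    volume center is placed at the isocenter (nominal calibration), its own
    origin offset preserved.
    """
    if out_pixel_mm is None:
        out_pixel_mm = float(intrinsics.pixel_size[0])
    if out_pixel_mm <= 0:
        raise ValueError(f"out_pixel_mm must be positive, got {out_pixel_mm}")
    src_w, R = camera_frame(intrinsics, pose)
    world_origin = _volume_world_origin(mu_volume, intrinsics)
    h = np.asarray(mu_volume.spacing, dtype=float)
    bmin = world_origin - h / 2.0
    bmax = bmin + np.asarray(mu_volume.shape) * h
    if np.all(src_w >= bmin) and np.all(src_w <= bmax):
        raise GeometryError("degenerate geometry: X-ray source inside the volume")
    # volume must sit between source and detector along the viewing axis
    corners = np.array([[bmin[i] if b & (1 << i) else bmax[i] for i in range(3)]
                        for b in range(8)])
    depth = (corners - src_w) @ R[:, 0]
    if depth.min() <= 0 or depth.max() >= intrinsics.sdd:
        raise GeometryError(
            "volume is not strictly between source and detector at this pose")

    y, z = _detector_grid_mm(intrinsics, out_pixel_mm)
    ic = intrinsics.isocenter
    t = np.asarray(pose.translation, dtype=float)
    # pixel world positions: R @ (p_cam - ic) + ic + t
    yy, zz = np.meshgrid(y, z)  # (n_v, n_u)
    pix_cam = np.stack([np.full(yy.size, intrinsics.sdd), yy.ravel(), zz.ravel()], axis=1)
    pix_w = (pix_cam - ic) @ R.T + ic + t
    placed = CTVolume(mu_volume.voxels, mu_volume.spacing, tuple(world_origin))
    path = ray_path_integrals(placed, src_w, pix_w, backend=backend)
    img = i0 * np.exp(-path).reshape(yy.shape)
    return Radiograph(img, (out_pixel_mm, out_pixel_mm), provenance="drr")


# --------------------------------------------------------------------------
# resampling
# --------------------------------------------------------------------------

def resample_image(image: Radiograph, target_pixel_mm: float) -> Radiograph:
    """Resample to ``target_pixel_mm``, preserving the field of view.

    Downsampling by an integer factor is an exact block mean (conserves mean
    intensity); other ratios use linear interpolation on the pixel-center
    grid.
    """
    if target_pixel_mm <= 0:
        raise ValueError(f"target spacing must be positive, got {target_pixel_mm}")
    sv, su = image.pixel_spacing
    if math.isclose(sv, target_pixel_mm) and math.isclose(su, target_pixel_mm):
        return Radiograph(image.pixels.copy(), (target_pixel_mm, target_pixel_mm),
                          image.provenance)
    arr = _resample_nd(image.pixels.astype(np.float64), (sv, su),
                       (target_pixel_mm, target_pixel_mm))
    return Radiograph(arr, (target_pixel_mm, target_pixel_mm), image.provenance)


def resample_volume(volume: CTVolume, target_mm: float) -> CTVolume:
    """Resample a volume to isotropic ``target_mm`` voxels (block mean for
    integer downsampling factors, linear otherwise).  Origin is adjusted so
    the volume center is preserved."""
    if target_mm <= 0:
        raise ValueError(f"target spacing must be positive, got {target_mm}")
    sp = np.asarray(volume.spacing, dtype=float)
    if np.allclose(sp, target_mm):
        return CTVolume(volume.voxels.copy(), (target_mm,) * 3, volume.origin)
    arr = _resample_nd(volume.voxels.astype(np.float64), tuple(sp), (target_mm,) * 3)
    center = volume.center
    new_origin = center - (np.asarray(arr.shape) - 1) * target_mm / 2.0
    return CTVolume(arr, (target_mm,) * 3, tuple(new_origin))


def _resample_nd(arr: np.ndarray, spacing: tuple, target: tuple) -> np.ndarray:
    factors = [t / s for s, t in zip(spacing, target)]
    int_down = all(
        f >= 1 and math.isclose(f, round(f)) and n % round(f) == 0
        for f, n in zip(factors, arr.shape))
    if int_down:
        for ax, f in enumerate(factors):
            f = round(f)
            if f == 1:
                continue
            shape = list(arr.shape)
            shape[ax] //= f
            shape.insert(ax + 1, f)
            arr = arr.reshape(shape).mean(axis=ax + 1)
        return arr
    from scipy import ndimage
    zoom = [s / t for s, t in zip(spacing, target)]
    return ndimage.zoom(arr, zoom, order=1, mode="nearest", grid_mode=True)


# --------------------------------------------------------------------------
# DRR database (preoperative coarse-search cache)
# --------------------------------------------------------------------------

@dataclass
class DRRDatabase:
    """Grid of coarse DRRs over in-plane C-arm translations.

    ``images[i]`` is the uint16-quantized DRR at ``poses[i]`` (intensities
    ``round(I/I0 * 65535)``); quantization happens at build time so a
    database reloaded from disk is bit-identical to the freshly built one.
    """

    poses: list[CArmPose]
    images: list[np.ndarray]          # uint16, shape (n_v, n_u)
    grid_spec: dict
    pixel_mm: float
    i0: float = 1.0
    content_hash: str = ""

    def __len__(self) -> int:
        return len(self.poses)

    def image_float(self, i: int) -> np.ndarray:
        return self.images[i].astype(np.float64) * (self.i0 / QUANT)

    def radiograph(self, i: int) -> Radiograph:
        return Radiograph(self.image_float(i), (self.pixel_mm, self.pixel_mm), "drr")


def quantize_intensity(img: np.ndarray, i0: float = 1.0) -> np.ndarray:
    """Deterministic 16-bit quantization of intensities in [0, i0]."""
    return np.clip(np.rint(img / i0 * QUANT), 0, QUANT).astype(np.uint16)


def _db_hash(mu_volume: CTVolume, intrinsics: CArmIntrinsics, grid_spec: dict,
             pixel_mm: float, i0: float) -> str:
    hsh = hashlib.sha256()
    hsh.update(np.ascontiguousarray(mu_volume.voxels, dtype=np.float64).tobytes())
    meta = {
        "spacing": list(mu_volume.spacing), "origin": list(mu_volume.origin),
        "sdd": intrinsics.sdd, "pixel_size": list(intrinsics.pixel_size),
        "detector_size": list(intrinsics.detector_size), "cop": list(intrinsics.cop),
        "grid": grid_spec, "pixel_mm": pixel_mm, "i0": i0,
    }
    hsh.update(json.dumps(meta, sort_keys=True).encode())
    return hsh.hexdigest()


def build_drr_database(mu_volume: CTVolume, intrinsics: CArmIntrinsics,
                       range_mm: float = 50.0, step_mm: float = 2.0,
                       coarse_pixel_mm: float = 4.0,
                       axes: tuple[str, str] = ("ty", "tz"),
                       resample_volume_mm: float | None = None,
                       cache_dir: str | Path | None = None,
                       overwrite: bool = False,
                       i0: float = 1.0, backend: str = "auto") -> DRRDatabase:
    """Render the preoperative coarse-search database.

    One DRR per pose on the regular in-plane translation grid
    ``{-range_mm, ..., +range_mm}`` (step ``step_mm``) along the ML (Ty) and
    SI (Tz) axes, i.e. ``(2*range/step + 1)**2`` entries; the stated +/-50 mm
    at 2 mm yields the 51 x 51 = 2601-image database used for coarse
    localization.  The CT is first resampled to ``resample_volume_mm``
    (default: ``coarse_pixel_mm``, matching the coarse detector resolution)
    so the preoperative build stays cheap.

    If ``cache_dir`` is given, a previously built database with the same
    content hash is reloaded instead of re-rendered; a cache directory built
    from *different* inputs raises unless ``overwrite=True``.
    """
    if range_mm < 0 or step_mm <= 0:
        raise ValueError("range_mm must be >= 0 and step_mm > 0")
    n_half = range_mm / step_mm
    if not math.isclose(n_half, round(n_half)):
        raise ValueError(f"range {range_mm} must be divisible by step {step_mm}")
    if tuple(axes) != ("ty", "tz"):
        raise ValueError("only the in-plane ('ty', 'tz') grid is supported")
    offsets = np.arange(-round(n_half), round(n_half) + 1) * step_mm
    grid_spec = {"axes": list(axes), "range_mm": float(range_mm),
                 "step_mm": float(step_mm), "offsets": [float(o) for o in offsets],
                 "resample_volume_mm": resample_volume_mm}
    if resample_volume_mm is None:
        resample_volume_mm = coarse_pixel_mm
        grid_spec["resample_volume_mm"] = float(resample_volume_mm)
    vol = resample_volume(mu_volume, resample_volume_mm) \
        if resample_volume_mm else mu_volume
    digest = _db_hash(mu_volume, intrinsics, grid_spec, coarse_pixel_mm, i0)

    if cache_dir is not None:
        cache_dir = Path(cache_dir)
        index = cache_dir / "index.json"
        if index.exists():
            meta = json.loads(index.read_text())
            if meta.get("content_hash") == digest:
                return load_drr_database(cache_dir)
            if not overwrite:
                raise FileExistsError(
                    f"{cache_dir} holds a database built from different inputs; "
                    "pass overwrite=True to rebuild")

    poses: list[CArmPose] = []
    images: list[np.ndarray] = []
    for ty in offsets:
        for tz in offsets:
            pose = CArmPose(translation=(0.0, float(ty), float(tz)))
            drr = raycast_drr(vol, intrinsics, pose, coarse_pixel_mm, i0,
                              backend=backend)
            poses.append(pose)
            images.append(quantize_intensity(drr.pixels, i0))
    db = DRRDatabase(poses, images, grid_spec, coarse_pixel_mm, i0, digest)
    if cache_dir is not None:
        save_drr_database(db, cache_dir)
    return db


def _entry_name(pose: CArmPose) -> str:
    ty, tz = pose.translation[1], pose.translation[2]
    return f"drr_ty{ty:+08.2f}_tz{tz:+08.2f}.png"


def save_drr_database(db: DRRDatabase, directory: str | Path) -> Path:
    """Write ``index.json`` plus one 16-bit PNG per pose."""
    import imageio.v3 as iio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for pose, img in zip(db.poses, db.images):
        name = _entry_name(pose)
        iio.imwrite(directory / name, img, extension=".png")
        entries.append({"file": name, "ty": pose.translation[1],
                        "tz": pose.translation[2]})
    meta = {"grid_spec": db.grid_spec, "pixel_mm": db.pixel_mm, "i0": db.i0,
            "content_hash": db.content_hash, "entries": entries}
    (directory / "index.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    return directory


def load_drr_database(directory: str | Path) -> DRRDatabase:
    import imageio.v3 as iio

    directory = Path(directory)
    index = directory / "index.json"
    if not index.exists():
        raise FileNotFoundError(f"no DRR database index at {index}")
    meta = json.loads(index.read_text())
    poses, images = [], []
    for e in meta["entries"]:
        poses.append(CArmPose(translation=(0.0, float(e["ty"]), float(e["tz"]))))
        images.append(np.asarray(iio.imread(directory / e["file"]), dtype=np.uint16))
    return DRRDatabase(poses, images, meta["grid_spec"], float(meta["pixel_mm"]),
                       float(meta["i0"]), meta["content_hash"])
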