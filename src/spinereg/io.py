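"""File I/O and pipeline configuration.

Formats: CT volumes as NIfTI (``.nii``/``.nii.gz``) or MetaImage
(``.mha``/``.mhd``) via SimpleITK; radiographs as 16-bit PNG/TIFF with a
JSON sidecar carrying pixel spacing and provenance; landmarks as CSV with
header ``label,x_mm,y_mm,z_mm`` (3D) or ``label,u_px,v_px`` (2D); pipeline
configuration as YAML.

The in-memory voxel array is indexed ``[ix, iy, iz]`` along the package's
world (AP, ML, SI) axes; SimpleITK stores arrays ``[z, y, x]``, so volumes
are transposed on read/write while spacing and origin are preserved
exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .drr import CTVolume, Radiograph
from .geometry import CArmIntrinsics, LandmarkSet
from .phantom import NoiseSpec
from .refine import CMAESConfig

__all__ = [
    "FormatError",
    "ConfigError",
    "read_volume",
    "write_volume",
    "read_landmarks",
    "write_landmarks",
    "read_radiograph",
    "write_radiograph",
    "PipelineConfig",
    "load_config",
]

VOLUME_SUFFIXES = (".nii", ".nii.gz", ".mha", ".mhd")
RADIOGRAPH_SCALE = 65535


class FormatError(ValueError):
    """Unreadable or malformed input file."""


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


# --------------------------------------------------------------------------
# volumes
# --------------------------------------------------------------------------

def _check_volume_suffix(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(s) for s in VOLUME_SUFFIXES):
        raise FormatError(
            f"unsupported volume format for {path} (expected one of "
            f"{', '.join(VOLUME_SUFFIXES)})")


def read_volume(path: str | Path) -> CTVolume:
    """Read a NIfTI or MetaImage volume into the (x, y, z) convention."""
    import SimpleITK as sitk

    path = Path(path)
    _check_volume_suffix(path)
    if not path.exists():
        raise FormatError(f"volume file not found: {path}")
    try:
        img = sitk.ReadImage(str(path))
    except Exception as exc:
        raise FormatError(f"could not read volume {path}: {exc}") from exc
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    if arr.ndim != 3:
        raise FormatError(f"{path} is not a 3D volume (shape {arr.shape})")
    voxels = np.ascontiguousarray(arr.transpose(2, 1, 0)).astype(np.float64)
    return CTVolume(voxels, tuple(img.GetSpacing()), tuple(img.GetOrigin()))


def write_volume(volume: CTVolume, path: str | Path) -> Path:
    import SimpleITK as sitk

    path = Path(path)
    _check_volume_suffix(path)
    img = sitk.GetImageFromArray(
        np.ascontiguousarray(volume.voxels.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in volume.spacing))
    img.SetOrigin(tuple(float(o) for o in volume.origin))
    path.parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(img, str(path))
    return path


# --------------------------------------------------------------------------
# landmarks
# --------------------------------------------------------------------------

_HEADERS_3D = ["label", "x_mm", "y_mm", "z_mm"]
_HEADERS_2D = ["label", "u_px", "v_px"]


def read_landmarks(path: str | Path) -> LandmarkSet:
    """Read a landmark CSV; dimensionality is inferred from the header."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"landmark file not found: {path}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"could not parse landmark CSV {path}: {exc}") from exc
    cols = [c.strip() for c in df.columns]
    if cols == _HEADERS_3D:
        coord_cols = _HEADERS_3D[1:]
    elif cols == _HEADERS_2D:
        coord_cols = _HEADERS_2D[1:]
    else:
        raise FormatError(
            f"{path}: header must be {','.join(_HEADERS_3D)} or "
            f"{','.join(_HEADERS_2D)}, got {','.join(cols)}")
    labels = [str(l) for l in df["label"]]
    try:
        coords = df[coord_cols].to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric coordinates: {exc}") from exc
    if not np.all(np.isfinite(coords)):
        raise FormatError(f"{path}: non-numeric or non-finite coordinates")
    try:
        return LandmarkSet(labels, coords)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_landmarks(landmarks: LandmarkSet, path: str | Path) -> Path:
    path = Path(path)
    header = _HEADERS_3D if landmarks.dim == 3 else _HEADERS_2D
    df = pd.DataFrame(landmarks.coords, columns=header[1:])
    df.insert(0, "label", landmarks.labels)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


# --------------------------------------------------------------------------
# radiographs
# --------------------------------------------------------------------------

def write_radiograph(radiograph: Radiograph, path: str | Path,
                     intensity_max: float | None = None,
                     sidecar: dict | None = None) -> Path:
    """Write a 16-bit PNG/TIFF plus a ``.json`` sidecar.

    Intensities are linearly mapped to the 16-bit range by
    ``intensity_max`` (default: the image maximum, or 1.0 for an all-zero
    image); the sidecar records the scale, pixel spacing and provenance so
    the float image round-trips.
    """
    import imageio.v3 as iio

    path = Path(path)
    if path.suffix.lower() not in (".png", ".tif", ".tiff"):
        raise FormatError(f"unsupported radiograph format: {path.suffix}")
    if intensity_max is None:
        intensity_max = float(radiograph.pixels.max()) or 1.0
    arr = np.clip(np.rint(radiograph.pixels / intensity_max * RADIOGRAPH_SCALE),
                  0, RADIOGRAPH_SCALE).astype(np.uint16)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, arr)
    meta = {
        "pixel_spacing_mm": list(radiograph.pixel_spacing),
        "provenance": radiograph.provenance,
        "intensity_max": intensity_max,
    }
    if sidecar:
        meta.update(sidecar)
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(meta, indent=1, sort_keys=True))
    return path


def read_radiograph(path: str | Path) -> tuple[Radiograph, dict]:
    """Read a radiograph and its sidecar; returns (image, sidecar dict)."""
    import imageio.v3 as iio

    path = Path(path)
    if not path.exists():
        raise FormatError(f"radiograph file not found: {path}")
    try:
        arr = np.asarray(iio.imread(path), dtype=np.float64)
    except Exception as exc:
        raise FormatError(f"could not read radiograph {path}: {exc}") from exc
    if arr.ndim == 3:  # collapse an RGB(A) image to one channel
        arr = arr[..., 0]
    sidecar_path = path.with_suffix(path.suffix + ".json")
    meta: dict = {}
    spacing = (1.0, 1.0)
    scale = 1.0 / RADIOGRAPH_SCALE
    provenance = "file"
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        spacing = tuple(meta.get("pixel_spacing_mm", spacing))  # type: ignore[assignment]
        scale = float(meta.get("intensity_max", 1.0)) / RADIOGRAPH_SCALE
        provenance = meta.get("provenance", provenance)
    return Radiograph(arr * scale, spacing, provenance), meta


# --------------------------------------------------------------------------
# pipeline configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineConfig:
    """Validated end-to-end pipeline configuration.

    ``phantom`` mode generates the CT, landmarks and radiograph internally
    at a hidden pose drawn from ``seed``; file mode reads them from the
    given paths.  The config hash is echoed into every output for
    provenance.
    """

    # geometry
    sdd_mm: float = 1000.0
    pixel_size_mm: tuple[float, float] = (1.0, 1.0)
    detector_px: tuple[int, int] = (384, 384)
    cop_px: tuple[float, float] | None = None
    # coarse database / search
    grid_range_mm: float = 50.0
    grid_step_mm: float = 2.0
    coarse_pixel_mm: float = 4.0
    metric: str = "psnr"
    # source-to-detector sweep
    sd_start_offset_mm: float = 400.0
    sd_step_mm: float = 10.0
    sd_max_advance_mm: float = 200.0
    # refinement
    cmaes: CMAESConfig = field(default_factory=CMAESConfig)
    # physics / preprocessing
    mu_water: float = 0.02
    # phantom mode
    phantom_mode: bool = True
    phantom_n_vertebrae: int = 5
    phantom_spacing_mm: float = 30.0
    noise_sigma: float = 0.0
    noise_gamma: float = 1.0
    # inputs (file mode)
    ct_path: str | None = None
    ct_landmarks_path: str | None = None
    xray_path: str | None = None
    xray_landmarks_path: str | None = None
    true_pose: tuple[float, ...] | None = None  # optional simulation truth
    # plumbing
    seed: int = 0
    cache_dir: str | None = None

    def __post_init__(self) -> None:
        if self.sdd_mm <= 0:
            raise ConfigError(f"sdd_mm must be positive, got {self.sdd_mm}")
        if any(p <= 0 for p in self.pixel_size_mm):
            raise ConfigError(f"pixel_size_mm must be positive, got {self.pixel_size_mm}")
        if self.metric.lower() not in ("mi", "gi", "psnr", "ssim", "ncc"):
            raise ConfigError(f"unknown metric {self.metric!r}")
        if self.coarse_pixel_mm <= 0 or self.grid_step_mm <= 0:
            raise ConfigError("coarse_pixel_mm and grid_step_mm must be positive")
        if not self.phantom_mode:
            missing = [n for n in ("ct_path", "ct_landmarks_path", "xray_path",
                                   "xray_landmarks_path") if getattr(self, n) is None]
            if missing:
                raise ConfigError(f"file mode requires {missing}")

    def intrinsics(self) -> CArmIntrinsics:
        return CArmIntrinsics(self.sdd_mm, tuple(self.pixel_size_mm),
                              tuple(self.detector_px),
                              None if self.cop_px is None else tuple(self.cop_px))

    def noise_spec(self) -> NoiseSpec:
        return NoiseSpec(self.noise_sigma, self.noise_gamma)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cmaes"] = dataclasses.asdict(self.cmaes)
        return d

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=list).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "cmaes" in data and isinstance(data["cmaes"], dict):
            try:
                data["cmaes"] = CMAESConfig(**{
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in data["cmaes"].items()})
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"invalid cmaes block: {exc}") from exc
        for key in ("pixel_size_mm", "detector_px", "cop_px", "true_pose"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration."""
    import yaml

    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    data = yaml.safe_load(path.read_text())
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path} must hold a YAML mapping")
    return PipelineConfig.from_dict(data)
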