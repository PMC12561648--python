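"""CT volume I/O, Hounsfield windowing, slice preprocessing and augmentation.

A :class:`CTVolume` is an ordered stack of axial slices in Hounsfield units
(HU), indexed 0-based along the scan direction.  Preprocessing follows the
convention of 2D vision backbones: crop a fixed fraction from every edge,
bilinearly resample to the encoder input size, then map HU into ``[0, 1]``
with a level/width intensity window.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
import pydicom
from skimage.transform import AffineTransform, resize, warp

from .errors import ConfigError, FormatError, ParameterError, SeriesError, ShapeError

__all__ = [
    "CTVolume",
    "WindowSpec",
    "PreprocessSpec",
    "load_volume",
    "write_volume",
    "apply_window",
    "preprocess_slice",
    "augment",
    "AUGMENTATION_NAMES",
]


@dataclasses.dataclass(frozen=True)
class WindowSpec:
    """Linear intensity window mapping HU to [0, 1].

    Defaults are a conventional soft-tissue window (level 40 HU, width
    400 HU), i.e. the displayed range is [-160, 240] HU.
    """

    level: float = 40.0
    width: float = 400.0

    def __post_init__(self) -> None:
        if not self.width > 0:
            raise ParameterError(f"window width must be > 0, got {self.width}")


@dataclasses.dataclass(frozen=True)
class PreprocessSpec:
    """Crop/resize/window recipe applied to every slice before encoding.

    ``crop_frac`` is the fraction of each edge removed before resampling;
    the default 32/512 reproduces the usual 512 -> 448 -> 224 pipeline for
    vision-transformer inputs.
    """

    crop_frac: float = 32 / 512
    out_size: tuple[int, int] = (224, 224)
    window: WindowSpec = dataclasses.field(default_factory=WindowSpec)

    def __post_init__(self) -> None:
        if not (0 <= self.crop_frac < 0.5):
            raise ParameterError(f"crop_frac must be in [0, 0.5), got {self.crop_frac}")
        if min(self.out_size) < 1:
            raise ParameterError(f"out_size must be positive, got {self.out_size}")


@dataclasses.dataclass
class CTVolume:
    """Ordered stack of axial HU slices.

    ``slices`` has shape ``(n_slices, rows, cols)``; the slice axis is
    0-based and ascends along a fixed scan direction.  ``spacing`` is
    ``(dz, dy, dx)`` in millimetres when known.
    """

    slices: np.ndarray
    study_id: str = ""
    spacing: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        self.slices = np.asarray(self.slices, dtype=np.float32)
        if self.slices.ndim != 3 or self.slices.shape[0] < 1:
            raise ShapeError(
                f"volume must be (n_slices, rows, cols) with n_slices >= 1, "
                f"got shape {self.slices.shape}"
            )

    @property
    def n_slices(self) -> int:
        return self.slices.shape[0]

    @property
    def pixel_dims(self) -> tuple[int, int]:
        return self.slices.shape[1], self.slices.shape[2]

    def __len__(self) -> int:
        return self.n_slices


def load_volume(path: str | Path, format: str | None = None) -> CTVolume:
    """Read a CT volume from a NIfTI file or a DICOM series directory.

    ``format`` is ``"nifti"``, ``"dicom_dir"`` or ``None`` (inferred: a
    directory is treated as a DICOM series, anything else as NIfTI).
    Slices are returned in ascending axial position with intensities in HU.
    """
    path = Path(path)
    if format is None:
        format = "dicom_dir" if path.is_dir() else "nifti"
    if format == "nifti":
        return _load_nifti(path)
    if format == "dicom_dir":
        return _load_dicom_dir(path)
    raise FormatError(f"unknown volume format {format!r}")


def _load_nifti(path: Path) -> CTVolume:
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"could not read NIfTI file {path}: {exc}") from exc
    data = np.asarray(img.get_fdata(dtype=np.float32))
    if data.ndim != 3:
        raise ShapeError(f"expected a 3D NIfTI volume, got shape {data.shape}")
    # stored (rows, cols, slices); slice axis is last by this package's writer
    slices = np.moveaxis(data, -1, 0)
    zooms = img.header.get_zooms()[:3]
    spacing = (float(zooms[2]), float(zooms[0]), float(zooms[1]))
    return CTVolume(slices=slices, study_id=path.name.split(".")[0], spacing=spacing)


def _load_dicom_dir(path: Path) -> CTVolume:
    files = sorted(p for p in path.iterdir() if p.is_file())
    datasets = []
    for f in files:
        try:
            datasets.append(pydicom.dcmread(str(f)))
        except Exception:
            continue  # non-DICOM clutter (e.g. DICOMDIR, hidden files)
    if not datasets:
        raise SeriesError(f"no readable DICOM files in {path}")
    uids = {getattr(ds, "SeriesInstanceUID", None) for ds in datasets}
    if len(uids) != 1:
        raise SeriesError(f"{path} mixes {len(uids)} DICOM series")

    def z_position(ds: pydicom.Dataset) -> float:
        ipp = getattr(ds, "ImagePositionPatient", None)
        if ipp is not None:
            return float(ipp[2])
        return float(getattr(ds, "InstanceNumber", 0))

    datasets.sort(key=z_position)
    shapes = {ds.pixel_array.shape for ds in datasets}
    if len(shapes) != 1:
        raise ShapeError(f"non-uniform slice shapes in {path}: {shapes}")
    slices = []
    for ds in datasets:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(ds.pixel_array.astype(np.float32) * slope + intercept)
    spacing = None
    ps = getattr(datasets[0], "PixelSpacing", None)
    if ps is not None and len(datasets) > 1:
        dz = abs(z_position(datasets[1]) - z_position(datasets[0]))
        spacing = (dz, float(ps[0]), float(ps[1]))
    study_id = str(getattr(datasets[0], "StudyInstanceUID", path.name))
    return CTVolume(slices=np.stack(slices), study_id=study_id, spacing=spacing)


def write_volume(volume: CTVolume, path: str | Path) -> Path:
    """Write a volume as NIfTI (slice axis last), for fixtures and export."""
    path = Path(path)
    data = np.moveaxis(volume.slices.astype(np.float32), 0, -1)
    affine = np.eye(4)
    if volume.spacing is not None:
        dz, dy, dx = volume.spacing
        affine = np.diag([dy, dx, dz, 1.0])
    img = nib.Nifti1Image(data, affine)
    if volume.spacing is not None:
        img.header.set_zooms((volume.spacing[1], volume.spacing[2], volume.spacing[0]))
    nib.save(img, str(path))
    return path


def apply_window(hu: np.ndarray | float, window: WindowSpec) -> np.ndarray:
    """Map HU values into [0, 1]: ``clip((hu - (level - width/2)) / width, 0, 1)``."""
    if not window.width > 0:
        raise ParameterError(f"window width must be > 0, got {window.width}")
    lo = window.level - window.width / 2
    return np.clip((np.asarray(hu, dtype=np.float32) - lo) / window.width, 0.0, 1.0)


def preprocess_slice(slice_hu: np.ndarray, spec: PreprocessSpec) -> np.ndarray:
    """Crop -> bilinear resample -> window one HU slice to ``spec.out_size``.

    ``floor(crop_frac * dim)`` pixels are removed from each edge (32 per edge
    on a 512-pixel dimension at the default fraction), then the remainder is
    resampled to ``out_size`` with bilinear interpolation and windowed.
    """
    arr = np.asarray(slice_hu, dtype=np.float32)
    if arr.ndim != 2:
        raise ShapeError(f"expected a 2D slice, got shape {arr.shape}")
    crops = [int(np.floor(spec.crop_frac * d)) for d in arr.shape]
    if any(d - 2 * c < 1 for d, c in zip(arr.shape, crops)):
        raise ShapeError(
            f"slice of shape {arr.shape} too small for crop_frac={spec.crop_frac}"
        )
    cr, cc = crops
    cropped = arr[cr : arr.shape[0] - cr, cc : arr.shape[1] - cc]
    if cropped.shape != tuple(spec.out_size):
        cropped = resize(
            cropped,
            spec.out_size,
            order=1,
            mode="edge",
            anti_aliasing=False,
            preserve_range=True,
        ).astype(np.float32)
    return apply_window(cropped, spec.window)


AUGMENTATION_NAMES = (
    "hflip",
    "vflip",
    "translate",
    "scale",
    "rotate",
    "elastic",
    "cutout",
)

_DEFAULT_AUGMENT: dict[str, dict] = {
    "hflip": {},
    "vflip": {},
    "translate": {"max_frac": 0.1},
    "scale": {"min": 0.9, "max": 1.1},
    "rotate": {"max_deg": 10.0},
    "elastic": {"alpha": 2.0, "sigma": 8.0},
    "cutout": {"n": 1, "size_frac": 0.15},
}


def default_augment_config() -> dict[str, dict]:
    """All supported train-time augmentations with conventional magnitudes."""
    return {k: dict(v) for k, v in _DEFAULT_AUGMENT.items()}


def augment(slice01: np.ndarray, config: Mapping[str, Mapping], seed: int) -> np.ndarray:
    """Apply seeded training augmentations to a windowed ``[0, 1]`` slice.

    ``config`` maps augmentation names (a subset of
    :data:`AUGMENTATION_NAMES`) to parameter dicts; an empty config is the
    identity.  The same ``(slice, config, seed)`` always produces the same
    output.  Augmentation is for training only and must never be applied in
    the selection or evaluation paths.
    """
    unknown = set(config) - set(AUGMENTATION_NAMES)
    if unknown:
        raise ConfigError(f"unknown augmentation(s): {sorted(unknown)}")
    out = np.asarray(slice01, dtype=np.float32).copy()
    if out.ndim != 2:
        raise ShapeError(f"expected a 2D slice, got shape {out.shape}")
    rng = np.random.default_rng(seed)
    h, w = out.shape

    if "hflip" in config and rng.random() < config["hflip"].get("p", 0.5):
        out = out[:, ::-1]
    if "vflip" in config and rng.random() < config["vflip"].get("p", 0.5):
        out = out[::-1, :]

    # single affine warp for translate/scale/rotate keeps interpolation loss low
    needs_affine = any(k in config for k in ("translate", "scale", "rotate"))
    if needs_affine:
        ty = tx = 0.0
        s = 1.0
        theta = 0.0
        if "translate" in config:
            m = config["translate"].get("max_frac", 0.1)
            ty, tx = rng.uniform(-m * h, m * h), rng.uniform(-m * w, m * w)
        if "scale" in config:
            s = rng.uniform(config["scale"].get("min", 0.9), config["scale"].get("max", 1.1))
        if "rotate" in config:
            m = config["rotate"].get("max_deg", 10.0)
            theta = np.deg2rad(rng.uniform(-m, m))
        center = np.array([w / 2, h / 2])
        tf = (
            AffineTransform(translation=-center)
            + AffineTransform(scale=s, rotation=theta)
            + AffineTransform(translation=center + [tx, ty])
        )
        out = warp(out, tf.inverse, order=1, mode="constant", cval=0.0, preserve_range=True)

    if "elastic" in config:
        alpha = config["elastic"].get("alpha", 2.0)
        sigma = config["elastic"].get("sigma", 8.0)
        from scipy.ndimage import gaussian_filter, map_coordinates

        dy = gaussian_filter(rng.standard_normal((h, w)), sigma) * alpha
        dx = gaussian_filter(rng.standard_normal((h, w)), sigma) * alpha
        yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        out = map_coordinates(out, [yy + dy, xx + dx], order=1, mode="constant", cval=0.0)

    if "cutout" in config:
        n = int(config["cutout"].get("n", 1))
        frac = config["cutout"].get("size_frac", 0.15)
        bh, bw = max(1, int(frac * h)), max(1, int(frac * w))
        for _ in range(n):
            r = rng.integers(0, max(1, h - bh + 1))
            c = rng.integers(0, max(1, w - bw + 1))
            out[r : r + bh, c : c + bw] = 0.0

    return np.clip(np.ascontiguousarray(out, dtype=np.float32), 0.0, 1.0)
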