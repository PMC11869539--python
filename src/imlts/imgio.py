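"""Image and mask I/O with a single internal convention.

Everything downstream operates on :class:`ImageVolume` / :class:`SegmentationMask`:
a float (or binary) voxel array in ``(z, y, x)`` axis order (``(y, x)`` for 2-D)
with per-axis spacing in millimetres.  Readers for DICOM, PNG and NIfTI-1 permute
into this convention; writers round-trip losslessly for the supported dialects.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ImageVolume",
    "SegmentationMask",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
]


@dataclass
class ImageVolume:
    """A 2-D or 3-D grayscale image with physical voxel spacing.

    Parameters
    ----------
    voxels : ndarray
        Float array, axis order ``(z, y, x)`` (3-D) or ``(y, x)`` (2-D).
    spacing_mm : tuple of float
        Millimetres per voxel along each axis, same order as ``voxels``.
    source_id : str
        Free-text provenance (file path, phantom spec hash, ...).
    """

    voxels: np.ndarray
    spacing_mm: tuple[float, ...]
    source_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim not in (2, 3):
            raise ValueError(f"ImageVolume must be 2-D or 3-D, got {self.voxels.ndim}-D")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != self.voxels.ndim:
            raise ValueError(
                f"spacing_mm has {len(self.spacing_mm)} entries for a "
                f"{self.voxels.ndim}-D image"
            )
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing_mm must be positive, got {self.spacing_mm}")

    @property
    def ndim(self) -> int:
        return self.voxels.ndim

    @property
    def shape(self) -> tuple[int, ...]:
        return self.voxels.shape


@dataclass
class SegmentationMask:
    """Binary mask aligned voxel-for-voxel with an :class:`ImageVolume`."""

    voxels: np.ndarray
    spacing_mm: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        arr = np.asarray(self.voxels)
        uniques = np.unique(arr)
        bad = [v for v in uniques.tolist() if v not in (0, 1)]
        if bad:
            raise ValueError(f"mask values must be in {{0,1}}; found {bad}")
        self.voxels = arr.astype(np.uint8)
        if self.voxels.ndim not in (2, 3):
            raise ValueError(f"mask must be 2-D or 3-D, got {self.voxels.ndim}-D")
        if not self.spacing_mm:
            self.spacing_mm = (1.0,) * self.voxels.ndim
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != self.voxels.ndim:
            raise ValueError("spacing_mm length must match mask dimensionality")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing_mm must be positive, got {self.spacing_mm}")

    @property
    def ndim(self) -> int:
        return self.voxels.ndim

    @property
    def shape(self) -> tuple[int, ...]:
        return self.voxels.shape

    def check_paired(self, image: ImageVolume) -> None:
        """Raise if this mask is not aligned with *image*."""
        if self.shape != image.shape:
            raise ValueError(f"mask shape {self.shape} != image shape {image.shape}")
        if self.spacing_mm != image.spacing_mm:
            raise ValueError(
                f"mask spacing {self.spacing_mm} != image spacing {image.spacing_mm}"
            )


def _guess_format(path: Path, hint: str | None) -> str:
    if hint:
        return hint.lower()
    suffixes = [s.lower() for s in path.suffixes]
    if suffixes[-1:] == [".png"]:
        return "png"
    if suffixes[-2:] == [".nii", ".gz"] or suffixes[-1:] == [".nii"]:
        return "nifti"
    if suffixes[-1:] in ([".dcm"], [".dicom"]) or path.is_dir():
        return "dicom"
    raise ValueError(f"cannot infer image format for {path}; pass a format hint")


def _read_dicom(path: Path) -> ImageVolume:
    import pydicom

    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.is_file())
        datasets = [pydicom.dcmread(str(p)) for p in files]
        if not datasets:
            raise ValueError(f"no DICOM files found in {path}")
        # series assembly by InstanceNumber ascending (deterministic)
        datasets.sort(key=lambda d: int(getattr(d, "InstanceNumber", 0)))
        slices = [d.pixel_array.astype(np.float64) for d in datasets]
        ds = datasets[0]
        voxels = np.stack(slices, axis=0)  # (z, y, x)
    else:
        ds = pydicom.dcmread(str(path))
        voxels = ds.pixel_array.astype(np.float64)

    spacing = getattr(ds, "PixelSpacing", None)
    if spacing is None:
        raise ValueError(f"DICOM {path} has no PixelSpacing; refusing a silent default")
    row_mm, col_mm = float(spacing[0]), float(spacing[1])
    if voxels.ndim == 3:
        thickness = getattr(ds, "SliceThickness", None)
        if thickness is None:
            raise ValueError(f"DICOM series {path} has no SliceThickness")
        spacing_mm: tuple[float, ...] = (float(thickness), row_mm, col_mm)
    else:
        spacing_mm = (row_mm, col_mm)

    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    voxels = voxels * slope + intercept
    return ImageVolume(voxels, spacing_mm, source_id=str(path))


def _read_nifti(path: Path) -> ImageVolume:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float64)
    zooms = img.header.get_zooms()[: data.ndim]
    if data.ndim == 3:
        # NIfTI stores (x, y, z); internal convention is (z, y, x)
        data = np.transpose(data, (2, 1, 0))
        spacing_mm: tuple[float, ...] = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    elif data.ndim == 2:
        data = np.transpose(data, (1, 0))
        spacing_mm = (float(zooms[1]), float(zooms[0]))
    else:
        raise ValueError(f"NIfTI {path} is {data.ndim}-D; only 2-D/3-D supported")
    return ImageVolume(data, spacing_mm, source_id=str(path))


def read_image(path: str | os.PathLike, format: str | None = None) -> ImageVolume:
    """Read a grayscale image into the internal ``(z, y, x)`` convention.

    Spacing comes from DICOM ``PixelSpacing``/``SliceThickness`` or the NIfTI
    header; PNG has no physical spacing, so 1.0 mm is assumed with a warning.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"image path does not exist: {p}")
    fmt = _guess_format(p, format)
    if fmt == "dicom":
        return _read_dicom(p)
    if fmt == "nifti":
        return _read_nifti(p)
    if fmt == "png":
        arr = np.asarray(iio.imread(p)).astype(np.float64)
        if arr.ndim == 3:  # drop color channels if present
            arr = arr[..., 0]
        logger.warning("PNG %s carries no spacing; assuming 1.0 mm per pixel", p)
        return ImageVolume(arr, (1.0, 1.0), source_id=str(p))
    raise ValueError(f"unsupported format {fmt!r}")


def write_image(volume: ImageVolume, path: str | os.PathLike) -> None:
    """Write an image as 16-bit PNG (2-D) or NIfTI-1 float (2-D/3-D).

    PNG export requires values already within [0, 65535]; scaling is the
    caller's responsibility (the phantom exporter records its scale in a JSON
    sidecar so PNG round trips are exact).
    """
    p = Path(path)
    if p.suffix.lower() == ".png":
        if volume.ndim != 2:
            raise ValueError("PNG export supports 2-D images only")
        v = volume.voxels
        if v.min() < 0 or v.max() > 65535:
            raise ValueError("PNG export requires values in [0, 65535]; rescale first")
        iio.imwrite(p, np.round(v).astype(np.uint16))
    elif p.name.lower().endswith((".nii", ".nii.gz")):
        data = volume.voxels
        zooms = volume.spacing_mm
        if data.ndim == 3:
            data = np.transpose(data, (2, 1, 0))
            zooms = (volume.spacing_mm[2], volume.spacing_mm[1], volume.spacing_mm[0])
        else:
            data = np.transpose(data, (1, 0))
            zooms = (volume.spacing_mm[1], volume.spacing_mm[0])
        img = nib.Nifti1Image(data.astype(np.float32), affine=np.diag(list(zooms) + [1.0] * (4 - data.ndim)))
        img.header.set_zooms(zooms)
        nib.save(img, str(p))
    else:
        raise ValueError(f"unsupported image extension for {p}")


def write_mask(mask: SegmentationMask, path: str | os.PathLike) -> None:
    """Write a binary mask: PNG 8-bit {0,255} (2-D) or NIfTI uint8 {0,1}."""
    p = Path(path)
    if p.suffix.lower() == ".png":
        if mask.ndim != 2:
            raise ValueError("PNG mask export supports 2-D masks only")
        iio.imwrite(p, (mask.voxels * 255).astype(np.uint8))
    elif p.name.lower().endswith((".nii", ".nii.gz")):
        data = mask.voxels
        zooms = mask.spacing_mm
        if data.ndim == 3:
            data = np.transpose(data, (2, 1, 0))
            zooms = (mask.spacing_mm[2], mask.spacing_mm[1], mask.spacing_mm[0])
        else:
            data = np.transpose(data, (1, 0))
            zooms = (mask.spacing_mm[1], mask.spacing_mm[0])
        img = nib.Nifti1Image(data.astype(np.uint8), affine=np.diag(list(zooms) + [1.0] * (4 - data.ndim)))
        img.header.set_zooms(zooms)
        nib.save(img, str(p))
    else:
        raise ValueError(f"unsupported mask extension for {p}")


def read_mask(path: str | os.PathLike, spacing_mm: tuple[float, ...] | None = None) -> SegmentationMask:
    """Read a binary mask written by :func:`write_mask`.

    PNG masks must use the {0, 255} dialect; any other pixel value is an error
    (a resampled or lossy mask is a corrupt ground truth, not a warning).
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"mask path does not exist: {p}")
    if p.suffix.lower() == ".png":
        arr = np.asarray(iio.imread(p))
        if arr.ndim == 3:
            arr = arr[..., 0]
        uniques = np.unique(arr)
        bad = [int(v) for v in uniques.tolist() if v not in (0, 255)]
        if bad:
            raise ValueError(f"PNG mask {p} has non-binary values {bad}; expected {{0,255}}")
        voxels = (arr == 255).astype(np.uint8)
        return SegmentationMask(voxels, spacing_mm or (1.0, 1.0))
    if p.name.lower().endswith((".nii", ".nii.gz")):
        vol = _read_nifti(p)
        uniques = np.unique(vol.voxels)
        bad = [float(v) for v in uniques.tolist() if v not in (0.0, 1.0)]
        if bad:
            raise ValueError(f"NIfTI mask {p} has non-binary values {bad}; expected {{0,1}}")
        return SegmentationMask(vol.voxels.astype(np.uint8), spacing_mm or vol.spacing_mm)
    raise ValueError(f"unsupported mask extension for {p}")
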