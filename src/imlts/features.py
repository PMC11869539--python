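"""Radiomic features of a nodule ROI: GLCM texture, shape, and histogram stats.

Fifteen features are computed per nodule:

* four gray-level co-occurrence (GLCM) features — contrast, correlation,
  homogeneity, entropy — from a normalized co-occurrence matrix restricted to
  in-mask voxel pairs;
* five shape features — area (mm^2), aspect rate, roundness, perimeter (mm),
  circularity — from the (largest axial slice of the) binary mask;
* six first-order histogram features — uniformity, mean, standard variance,
  kurtosis, skewness, smoothness — from the quantized intensity histogram of
  the ROI.

Kurtosis and skewness are kept as *raw* central moments of the quantized
histogram (no sigma-normalization); the conventional normalized variants are
available via ``histogram_features(..., normalized_moments=True)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

from .imgio import ImageVolume, SegmentationMask

__all__ = [
    "GLCMConfig",
    "FeatureVector",
    "FEATURE_ORDER",
    "quantize",
    "compute_glcm",
    "glcm_contrast",
    "glcm_correlation",
    "glcm_homogeneity",
    "glcm_entropy",
    "shape_features",
    "histogram_features",
    "extract_features",
]

#: Fixed export order of the 15 features (CSV column order).
FEATURE_ORDER = (
    "correlation",
    "contrast",
    "homogeneity",
    "entropy",
    "area_mm2",
    "aspect_rate",
    "roundness",
    "perimeter_mm",
    "circularity",
    "uniformity",
    "mean",
    "standard_variance",
    "kurtosis",
    "skewness",
    "smoothness",
)

#: The four standard 2-D distance-1 offsets (0, 45, 90, 135 degrees) in
#: (row, col) steps.
DEFAULT_OFFSETS_2D = ((0, 1), (-1, 1), (-1, 0), (-1, -1))


@dataclass
class GLCMConfig:
    """Gray-level co-occurrence configuration.

    levels : number of gray levels after uniform min-max quantization.
    offsets : displacement vectors; defaults to the four standard 2-D
        directions at distance 1.
    symmetric : count each pair in both directions.
    """

    levels: int = 8
    offsets: tuple[tuple[int, ...], ...] = DEFAULT_OFFSETS_2D
    symmetric: bool = True

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        for off in self.offsets:
            if all(o == 0 for o in off):
                raise ValueError("offsets must be nonzero")


@dataclass
class FeatureVector:
    """The 15 radiomic features of one nodule ROI.

    All fields are dimensionless except ``area_mm2`` and ``perimeter_mm``.
    """

    correlation: float
    contrast: float
    homogeneity: float
    entropy: float
    area_mm2: float
    aspect_rate: float
    roundness: float
    perimeter_mm: float
    circularity: float
    uniformity: float
    mean: float
    standard_variance: float
    kurtosis: float
    skewness: float
    smoothness: float

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in FEATURE_ORDER], dtype=np.float64)

    def to_dict(self) -> dict[str, float]:
        return {k: float(getattr(self, k)) for k in FEATURE_ORDER}


def quantize(values: np.ndarray, levels: int) -> np.ndarray:
    """Uniform min-max binning into integer levels 0..levels-1."""
    values = np.asarray(values, dtype=np.float64)
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.zeros(values.shape, dtype=np.intp)
    q = np.floor((values - lo) / (hi - lo) * levels).astype(np.intp)
    return np.minimum(q, levels - 1)


def compute_glcm(
    image: np.ndarray,
    mask: np.ndarray | None = None,
    config: GLCMConfig | None = None,
) -> np.ndarray:
    """Normalized gray-level co-occurrence matrix of the in-mask region.

    Pairs are counted only when *both* voxels of a pair lie inside the mask;
    counts are accumulated over all configured offsets (mirrored as well when
    ``symmetric``), then normalized to sum to 1.
    """
    config = config or GLCMConfig()
    image = np.asarray(image, dtype=np.float64)
    if mask is None:
        mask = np.ones(image.shape, dtype=bool)
    mask = np.asarray(mask).astype(bool)
    if mask.shape != image.shape:
        raise ValueError("mask shape must match image shape")
    if not mask.any():
        raise ValueError("empty mask: no voxels to pair")

    levels = config.levels
    # quantize over the ROI's own intensity range
    q = np.zeros(image.shape, dtype=np.intp)
    q[mask] = quantize(image[mask], levels)

    n = image.ndim
    glcm = np.zeros((levels, levels), dtype=np.float64)
    offsets = list(config.offsets)
    if config.symmetric:
        offsets = offsets + [tuple(-o for o in off) for off in offsets]
    for off in offsets:
        if len(off) != n:
            raise ValueError(f"offset {off} does not match image dimensionality {n}")
        src = tuple(
            slice(max(0, -o), image.shape[ax] - max(0, o)) for ax, o in enumerate(off)
        )
        dst = tuple(
            slice(max(0, o), image.shape[ax] - max(0, -o)) for ax, o in enumerate(off)
        )
        valid = mask[src] & mask[dst]
        if not valid.any():
            continue
        a = q[src][valid]
        b = q[dst][valid]
        np.add.at(glcm, (a, b), 1.0)

    total = glcm.sum()
    if total == 0:
        raise ValueError("no valid in-mask voxel pairs for any offset")
    return glcm / total


def _marginal_stats(glcm: np.ndarray):
    levels = glcm.shape[0]
    idx = np.arange(levels, dtype=np.float64)
    px = glcm.sum(axis=1)
    py = glcm.sum(axis=0)
    mu_x = float(px @ idx)
    mu_y = float(py @ idx)
    var_x = float(px @ (idx - mu_x) ** 2)
    var_y = float(py @ (idx - mu_y) ** 2)
    return idx, mu_x, mu_y, var_x, var_y


def glcm_contrast(glcm: np.ndarray) -> float:
    """Sum of P(x,y) * (x-y)^2: local intensity variation."""
    idx = np.arange(glcm.shape[0], dtype=np.float64)
    diff2 = (idx[:, None] - idx[None, :]) ** 2
    return float(np.sum(glcm * diff2))


def glcm_correlation(glcm: np.ndarray) -> float:
    """Sum of P(x,y) * (x-mu_x)(y-mu_y) / (sigma_x sigma_y), in [-1, 1]."""
    idx, mu_x, mu_y, var_x, var_y = _marginal_stats(glcm)
    if var_x <= 0 or var_y <= 0:
        raise ValueError("degenerate GLCM: a marginal has zero variance")
    outer = (idx[:, None] - mu_x) * (idx[None, :] - mu_y)
    return float(np.sum(glcm * outer) / np.sqrt(var_x * var_y))


def glcm_homogeneity(glcm: np.ndarray) -> float:
    """Sum of P(x,y) / (1 + |x-y|): proximity of mass to the diagonal."""
    idx = np.arange(glcm.shape[0], dtype=np.float64)
    w = 1.0 / (1.0 + np.abs(idx[:, None] - idx[None, :]))
    return float(np.sum(glcm * w))


def glcm_entropy(glcm: np.ndarray) -> float:
    """Shannon entropy -sum P log P (natural log, 0 log 0 := 0)."""
    p = glcm[glcm > 0]
    return float(-np.sum(p * np.log(p)))


def _largest_axial_slice(mask: SegmentationMask) -> tuple[np.ndarray, tuple[float, float]]:
    """2-D working slice: for 3-D masks, the axial (z) slice of largest area."""
    if mask.ndim == 2:
        return mask.voxels.astype(bool), (mask.spacing_mm[0], mask.spacing_mm[1])
    areas = mask.voxels.reshape(mask.shape[0], -1).sum(axis=1)
    z = int(np.argmax(areas))
    return mask.voxels[z].astype(bool), (mask.spacing_mm[1], mask.spacing_mm[2])


def _boundary_perimeter(component: np.ndarray, spacing: tuple[float, float]) -> float:
    """Length of the ordered outer boundary polygon of a binary component.

    The boundary is traced as the 0.5-level contour of the component; the
    perimeter is the closed polygon length with coordinates scaled to mm.
    """
    padded = np.pad(component.astype(np.float64), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        return 0.0
    # outer boundary = longest contour; the raw marching-squares polygon
    # overestimates digitized boundary length (staircase bias), so simplify
    # it to within one pixel before measuring
    contour = max(contours, key=lambda c: len(c))
    contour = measure.approximate_polygon(contour, tolerance=1.0)
    pts = (contour - 1.0) * np.asarray(spacing)[None, :]
    if not np.allclose(pts[0], pts[-1]):
        pts = np.vstack([pts, pts[:1]])
    seg = np.diff(pts, axis=0)
    return float(np.sum(np.sqrt(np.sum(seg**2, axis=1))))


def shape_features(
    mask: SegmentationMask,
) -> tuple[float, float, float, float, float]:
    """(area_mm2, aspect_rate, roundness, perimeter_mm, circularity).

    Computed on the largest axial slice (3-D) or the mask itself (2-D), for
    the largest 8-connected component:

    * area = pixel count x pixel area;
    * aspect rate = major/minor axis length of the moment-matched ellipse;
    * perimeter = ordered outer-boundary polygon length;
    * roundness = 4 pi area / perimeter^2 (isoperimetric ratio);
    * circularity = 4 pi area / perimeter^2 with the same boundary-length
      estimator (the two coincide by construction and are both reported).
    """
    if not mask.voxels.any():
        raise ValueError("empty mask has no shape features")
    sl, spacing = _largest_axial_slice(mask)
    labels = measure.label(sl, connectivity=2)
    props = measure.regionprops(labels, spacing=spacing)
    largest = max(props, key=lambda r: r.area)
    component = labels == largest.label

    pixel_area = spacing[0] * spacing[1]
    area = float(component.sum()) * pixel_area
    minor = largest.axis_minor_length
    major = largest.axis_major_length
    if minor <= 0:
        # degenerate (line-like) component: fall back to a 1-pixel width
        minor = min(spacing)
    aspect_rate = float(major / minor) if major > 0 else 1.0
    aspect_rate = max(aspect_rate, 1.0)
    perimeter = _boundary_perimeter(component, spacing)
    if perimeter > 0:
        roundness = float(4.0 * np.pi * area / perimeter**2)
        circularity = float(4.0 * np.pi * area / perimeter**2)
    else:
        roundness = circularity = 0.0
    return area, aspect_rate, roundness, perimeter, circularity


def histogram_features(
    image: np.ndarray,
    mask: np.ndarray | None = None,
    levels: int = 256,
    normalized_moments: bool = False,
) -> tuple[float, float, float, float, float, float]:
    """(uniformity, mean, standard_variance, kurtosis, skewness, smoothness).

    The ROI's intensities are quantized into ``levels`` uniform bins over
    their min-max range; ``P_i`` is the bin-center intensity and ``HS(P_i)``
    the normalized histogram.  Moments are taken about the histogram mean on
    the original intensity scale; smoothness ``1 - 1/(1+sigma^2)`` uses the
    standard deviation on the [0, 1] rescaled intensity axis so it is
    contrast-range invariant.
    """
    image = np.asarray(image, dtype=np.float64)
    if mask is None:
        mask = np.ones(image.shape, dtype=bool)
    vals = image[np.asarray(mask).astype(bool)]
    if vals.size < 2:
        raise ValueError("histogram features need >= 2 in-mask voxels")

    lo, hi = float(vals.min()), float(vals.max())
    if hi == lo:
        # delta histogram: all mass on one level
        return 1.0, lo, 0.0, 0.0, 0.0, 0.0

    q = quantize(vals, levels)
    hist = np.bincount(q, minlength=levels).astype(np.float64)
    hs = hist / hist.sum()
    width = (hi - lo) / levels
    centers = lo + (np.arange(levels) + 0.5) * width

    uniformity = float(np.sum(hs**2))
    mean = float(np.sum(centers * hs))
    variance = float(np.sum((centers - mean) ** 2 * hs))
    kurt = float(np.sum((centers - mean) ** 4 * hs))
    skew = float(np.sum((centers - mean) ** 3 * hs))
    if normalized_moments and variance > 0:
        kurt /= variance**2
        skew /= variance**1.5

    centers01 = (centers - lo) / (hi - lo)
    mean01 = float(np.sum(centers01 * hs))
    var01 = float(np.sum((centers01 - mean01) ** 2 * hs))
    smoothness = 1.0 - 1.0 / (1.0 + var01)
    return uniformity, mean, variance, kurt, skew, smoothness


def extract_features(
    image: ImageVolume,
    mask: SegmentationMask,
    config: GLCMConfig | None = None,
    histogram_levels: int = 256,
) -> FeatureVector:
    """All 15 features of one nodule ROI.

    For 3-D inputs the GLCM and histogram are computed on the largest axial
    slice of the mask, consistent with the shape features.
    """
    mask.check_paired(image)
    config = config or GLCMConfig()

    if image.ndim == 3:
        areas = mask.voxels.reshape(mask.shape[0], -1).sum(axis=1)
        z = int(np.argmax(areas))
        img2d = image.voxels[z]
        msk2d = mask.voxels[z].astype(bool)
    else:
        img2d = image.voxels
        msk2d = mask.voxels.astype(bool)

    glcm = compute_glcm(img2d, msk2d, config)
    try:
        corr = glcm_correlation(glcm)
    except ValueError:
        corr = 0.0  # constant ROI: no co-variation to measure
    contrast = glcm_contrast(glcm)
    homogeneity = glcm_homogeneity(glcm)
    entropy = glcm_entropy(glcm)

    area, aspect, roundness, perimeter, circ = shape_features(mask)
    uni, mean, var, kurt, skew, smooth = histogram_features(
        img2d, msk2d, levels=histogram_levels
    )
    return FeatureVector(
        correlation=corr,
        contrast=contrast,
        homogeneity=homogeneity,
        entropy=entropy,
        area_mm2=area,
        aspect_rate=aspect,
        roundness=roundness,
        perimeter_mm=perimeter,
        circularity=circ,
        uniformity=uni,
        mean=mean,
        standard_variance=var,
        kurtosis=kurt,
        skewness=skew,
        smoothness=smooth,
    )
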