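"""Synthetic CT phantom generator.

Emulates, at desk scale, the kind of chest-CT inputs the pipeline targets:
a bright body background, a darker elliptical lung field, and one or more
bright ellipsoidal nodules of known physical diameter, plus additive Gaussian
noise.  Every phantom carries an exact ground-truth mask (rasterized before
noise is added) and a benign/malignant label from the 3 mm diameter rule, so
all downstream stages are testable without any external CT collection.

Intensities are float and HU-like: air outside the lung is bright soft tissue
(~50), the aerated lung field is dark (~-800), and nodules sit near soft
tissue density (~40).  Quantization only ever happens in the features module.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .imgio import ImageVolume, SegmentationMask, write_image, write_mask

__all__ = [
    "Nodule",
    "PhantomSpec",
    "generate_phantom",
    "generate_dataset",
    "export_phantom",
    "MALIGNANT_DIAMETER_MM",
]

#: Diameter cutoff of the size rule: nodules >= 3 mm are labelled malignant.
MALIGNANT_DIAMETER_MM = 3.0


@dataclass(frozen=True)
class Nodule:
    """One ellipsoidal nodule.

    ``center_vox`` is in voxel coordinates (axis order matching the image);
    ``diameter_mm`` is the physical diameter along the *minor* axis direction
    scaled so the equivalent sphere/circle has that diameter; ``axis_ratio``
    elongates the first axis relative to the rest (1.0 = sphere/circle).
    """

    center_vox: tuple[float, ...]
    diameter_mm: float
    intensity: float = 40.0
    axis_ratio: float = 1.0

    def semi_axes_mm(self, ndim: int) -> tuple[float, ...]:
        """Semi-axis lengths in mm preserving the equivalent diameter."""
        r = self.diameter_mm / 2.0
        k = self.axis_ratio
        if ndim == 2:
            # area pi*a*b == pi*r^2 with a/b = k
            b = r / np.sqrt(k)
            return (k * b, b)
        b = r / k ** (1.0 / 3.0)
        return (k * b, b, b)


@dataclass(frozen=True)
class LungField:
    """Darker elliptical region standing in for the aerated lung."""

    center_vox: tuple[float, ...]
    semi_axes_vox: tuple[float, ...]
    intensity: float = -800.0


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one phantom; identical specs (incl. seed) yield
    bit-identical output."""

    image_shape: tuple[int, ...] = (128, 128)
    spacing_mm: tuple[float, ...] = (0.5, 0.5)
    background_level: float = 50.0
    lung_field: LungField | None = None
    nodules: tuple[Nodule, ...] = ()
    noise_sigma: float = 0.0
    seed: int = 0

    def resolved_lung_field(self) -> LungField:
        if self.lung_field is not None:
            return self.lung_field
        center = tuple((s - 1) / 2.0 for s in self.image_shape)
        axes = tuple(0.42 * s for s in self.image_shape)
        return LungField(center, axes)

    def validate(self) -> None:
        ndim = len(self.image_shape)
        if ndim not in (2, 3):
            raise ValueError("phantoms are 2-D or 3-D")
        if len(self.spacing_mm) != ndim:
            raise ValueError("spacing_mm must match image_shape dimensionality")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        lung = self.resolved_lung_field()
        for i, nod in enumerate(self.nodules):
            if nod.diameter_mm / min(self.spacing_mm) < 2:
                raise ValueError(
                    f"nodule {i}: diameter {nod.diameter_mm} mm spans <2 voxels "
                    f"at spacing {self.spacing_mm}"
                )
            semi_vox = tuple(
                a / s for a, s in zip(nod.semi_axes_mm(ndim), self.spacing_mm)
            )
            for ax in range(ndim):
                lo = nod.center_vox[ax] - semi_vox[ax]
                hi = nod.center_vox[ax] + semi_vox[ax]
                if lo < 0 or hi > self.image_shape[ax] - 1:
                    raise ValueError(
                        f"nodule {i} (center {nod.center_vox}, "
                        f"{nod.diameter_mm} mm) extends outside image bounds on axis {ax}"
                    )
            # fully inside lung field: every corner of the nodule's bounding
            # box must fall inside the lung ellipse/ellipsoid (sufficient,
            # since the box contains the nodule)
            for signs in itertools.product((-1.0, 1.0), repeat=ndim):
                q = sum(
                    ((c + sgn * e - lc) / la) ** 2
                    for c, sgn, e, lc, la in zip(
                        nod.center_vox, signs, semi_vox,
                        lung.center_vox, lung.semi_axes_vox,
                    )
                )
                if q > 1.0:
                    raise ValueError(
                        f"nodule {i} (center {nod.center_vox}, {nod.diameter_mm} mm) "
                        f"is not fully inside the lung field"
                    )

    def to_json(self) -> dict:
        return _spec_to_json(self)


def _spec_to_json(spec: PhantomSpec) -> dict:
    d = dataclasses.asdict(spec)
    if spec.lung_field is None:
        d["lung_field"] = dataclasses.asdict(spec.resolved_lung_field())
    return d


def _ellipsoid_mask(
    shape: tuple[int, ...],
    center_vox: tuple[float, ...],
    semi_axes_vox: tuple[float, ...],
) -> np.ndarray:
    """Voxels whose CENTER lies inside the ellipsoid (the rasterization rule)."""
    grids = np.meshgrid(*[np.arange(s, dtype=np.float64) for s in shape], indexing="ij")
    q = np.zeros(shape, dtype=np.float64)
    for g, c, a in zip(grids, center_vox, semi_axes_vox):
        q += ((g - c) / a) ** 2
    return q <= 1.0


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[ImageVolume, SegmentationMask, list[str]]:
    """Rasterize one phantom.

    Returns the noisy image, the noise-free ground-truth mask (union of nodule
    ellipsoids) and one ``benign``/``malignant`` label per nodule following the
    3 mm rule applied to the *specified* diameter.
    """
    spec.validate()
    ndim = len(spec.image_shape)
    img = np.full(spec.image_shape, spec.background_level, dtype=np.float64)

    lung = spec.resolved_lung_field()
    lung_mask = _ellipsoid_mask(spec.image_shape, lung.center_vox, lung.semi_axes_vox)
    img[lung_mask] = lung.intensity

    mask = np.zeros(spec.image_shape, dtype=np.uint8)
    labels: list[str] = []
    for nod in spec.nodules:
        semi_vox = tuple(a / s for a, s in zip(nod.semi_axes_mm(ndim), spec.spacing_mm))
        m = _ellipsoid_mask(spec.image_shape, nod.center_vox, semi_vox)
        img[m] = nod.intensity
        mask |= m.astype(np.uint8)
        labels.append(
            "malignant" if nod.diameter_mm >= MALIGNANT_DIAMETER_MM else "benign"
        )

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sigma, size=spec.image_shape)

    sid = "phantom-" + hashlib.sha256(
        json.dumps(_spec_to_json(spec), sort_keys=True).encode()
    ).hexdigest()[:12]
    return (
        ImageVolume(img, spec.spacing_mm, source_id=sid),
        SegmentationMask(mask, spec.spacing_mm),
        labels,
    )


@dataclass
class PhantomSample:
    """One dataset item: image + ground-truth mask + label + true diameter."""

    image: ImageVolume
    mask: SegmentationMask
    label: str
    diameter_mm: float
    spec: PhantomSpec = field(repr=False, default=None)  # type: ignore[assignment]


def _place_nodule(
    rng: np.random.Generator,
    template: PhantomSpec,
    diameter_mm: float,
) -> Nodule:
    """Place a nodule uniformly inside the lung field with a safety margin."""
    ndim = len(template.image_shape)
    lung = template.resolved_lung_field()
    semi_mm = Nodule((0,) * ndim, diameter_mm).semi_axes_mm(ndim)
    semi_vox = tuple(a / s for a, s in zip(semi_mm, template.spacing_mm))
    for _ in range(1000):
        u = rng.uniform(-1.0, 1.0, size=ndim)
        if np.sum(u**2) > 1.0:
            continue
        center = tuple(
            lc + ui * max(la - ev - 1.0, 0.0)
            for lc, ui, la, ev in zip(lung.center_vox, u, lung.semi_axes_vox, semi_vox)
        )
        cand = Nodule(center, diameter_mm, axis_ratio=1.0)
        probe = dataclasses.replace(template, nodules=(cand,))
        try:
            probe.validate()
        except ValueError:
            continue
        return cand
    raise ValueError(
        f"could not place a {diameter_mm} mm nodule inside the lung field of "
        f"shape {template.image_shape} at spacing {template.spacing_mm}"
    )


def generate_dataset(
    n: int,
    spec_template: PhantomSpec | None = None,
    seed: int = 0,
    diameter_range_mm: tuple[float, float] = (2.0, 30.0),
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
) -> dict[str, list[PhantomSample]]:
    """Sample *n* single-nodule phantoms and split into train/val/test.

    Diameters are drawn uniformly from ``diameter_range_mm`` (default 2-30 mm:
    the 3-30 mm clinically annotated range plus sub-3 mm benign cases).  Splits
    are disjoint and fully determined by ``seed``.
    """
    if n < 3:
        raise ValueError(f"need n >= 3 to form three splits, got n={n}")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"split fractions must sum to 1, got {fractions}")
    if spec_template is None:
        spec_template = PhantomSpec(noise_sigma=20.0)
    lo, hi = diameter_range_mm
    min_d = 2.0 * min(spec_template.spacing_mm)
    if lo < min_d:
        raise ValueError(
            f"diameter range low {lo} mm violates the 2-voxel minimum "
            f"({min_d} mm at spacing {spec_template.spacing_mm})"
        )

    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    n_test = n - n_train - n_val
    if min(n_train, n_val, n_test) < 1:
        raise ValueError(
            f"n={n} too small for fractions {fractions}: "
            f"computed split sizes {(n_train, n_val, n_test)}"
        )

    rng = np.random.default_rng(seed)
    samples: list[PhantomSample] = []
    for i in range(n):
        d = float(rng.uniform(lo, hi))
        nod = _place_nodule(rng, spec_template, d)
        item_seed = int(rng.integers(0, 2**31 - 1))
        spec = dataclasses.replace(spec_template, nodules=(nod,), seed=item_seed)
        img, mask, labels = generate_phantom(spec)
        samples.append(PhantomSample(img, mask, labels[0], d, spec))

    order = rng.permutation(n)
    idx_train = order[:n_train]
    idx_val = order[n_train : n_train + n_val]
    idx_test = order[n_train + n_val :]
    return {
        "train": [samples[i] for i in idx_train],
        "val": [samples[i] for i in idx_val],
        "test": [samples[i] for i in idx_test],
    }


def export_phantom(
    spec: PhantomSpec, out_dir: str | Path, stem: str = "phantom"
) -> dict[str, str]:
    """Write image, mask, and a JSON sidecar with spec, labels and diameters.

    2-D phantoms export as 16-bit PNG (intensities affinely mapped to the
    uint16 range; the sidecar records slope/intercept so values round-trip),
    3-D phantoms as NIfTI.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    img, mask, labels = generate_phantom(spec)

    if img.ndim == 2:
        lo, hi = float(img.voxels.min()), float(img.voxels.max())
        scale = 65535.0 / (hi - lo) if hi > lo else 1.0
        stored = np.round((img.voxels - lo) * scale)
        img_path = out / f"{stem}.png"
        write_image(ImageVolume(stored, img.spacing_mm, img.source_id), img_path)
        mask_path = out / f"{stem}_mask.png"
        encode = {"slope": 1.0 / scale, "intercept": lo}
    else:
        img_path = out / f"{stem}.nii.gz"
        write_image(img, img_path)
        mask_path = out / f"{stem}_mask.nii.gz"
        encode = {"slope": 1.0, "intercept": 0.0}
    write_mask(mask, mask_path)

    sidecar = {
        "spec": _spec_to_json(spec),
        "labels": labels,
        "diameters_mm": [nod.diameter_mm for nod in spec.nodules],
        "intensity_encoding": encode,
        "image": img_path.name,
        "mask": mask_path.name,
    }
    sidecar_path = out / f"{stem}.json"
    sidecar_path.write_text(json.dumps(sidecar, indent=2))
    return {"image": str(img_path), "mask": str(mask_path), "sidecar": str(sidecar_path)}
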