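"""Benign/malignant calling: nodule measurement, the 3 mm size rule, RBF-SVM.

Two classification backends are provided and selectable by name:

* ``rule`` — the clinical size convention: a nodule whose equivalent circular
  diameter (on its largest axial slice) is >= 3 mm is called malignant,
  anything smaller benign (the 3.0 mm boundary itself is malignant);
* ``svm`` — a maximum-margin binary classifier on the 15 radiomic features
  with the radial-basis kernel ``R(a, b) = exp(-||a - b||^2 / s^2)``
  (note the ``s^2`` denominator; ``standard_form=True`` switches to the
  common ``2 s^2``);
* ``svm_with_rule_fallback`` — the SVM when a trained model is supplied,
  else the rule.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass

import numpy as np
from skimage import measure
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .imgio import SegmentationMask
from .phantom import MALIGNANT_DIAMETER_MM

__all__ = [
    "NoduleMeasurement",
    "SVMModel",
    "measure_nodule",
    "size_rule_classify",
    "rbf_kernel",
    "train_svm",
    "svm_classify",
    "save_svm",
    "load_svm",
]

BENIGN, MALIGNANT = "benign", "malignant"


@dataclass(frozen=True)
class NoduleMeasurement:
    """Size of one connected mask component on its largest axial slice."""

    equivalent_diameter_mm: float
    area_mm2: float
    component_id: int

    def __post_init__(self) -> None:
        if self.area_mm2 < 0:
            raise ValueError("area must be >= 0")
        expected = 2.0 * np.sqrt(self.area_mm2 / np.pi)
        if abs(self.equivalent_diameter_mm - expected) > 1e-9:
            raise ValueError(
                "equivalent diameter must equal 2*sqrt(area/pi); "
                f"got {self.equivalent_diameter_mm} for area {self.area_mm2}"
            )


def measure_nodule(mask: SegmentationMask) -> list[NoduleMeasurement]:
    """Measure every connected component of a mask, ordered by area descending.

    For 3-D masks each component is measured on its own largest axial slice,
    consistent with the axial-slice area convention of the shape features.
    An empty mask yields an empty list.
    """
    if not mask.voxels.any():
        return []
    connectivity = mask.ndim  # 8-connectivity in 2-D, 26 in 3-D
    labels = measure.label(mask.voxels, connectivity=connectivity)
    if mask.ndim == 2:
        pixel_area = mask.spacing_mm[0] * mask.spacing_mm[1]
    else:
        pixel_area = mask.spacing_mm[1] * mask.spacing_mm[2]

    out: list[NoduleMeasurement] = []
    for comp_id in range(1, labels.max() + 1):
        comp = labels == comp_id
        if mask.ndim == 3:
            counts = comp.reshape(comp.shape[0], -1).sum(axis=1)
            npix = int(counts.max())
        else:
            npix = int(comp.sum())
        area = npix * pixel_area
        diameter = 2.0 * float(np.sqrt(area / np.pi))
        out.append(NoduleMeasurement(diameter, area, comp_id))
    out.sort(key=lambda m: m.area_mm2, reverse=True)
    return out


def size_rule_classify(measurement: NoduleMeasurement) -> str:
    """Malignant iff equivalent diameter >= 3.0 mm (inclusive)."""
    if measurement.equivalent_diameter_mm < 0:
        raise ValueError("diameter must be >= 0")
    return (
        MALIGNANT
        if measurement.equivalent_diameter_mm >= MALIGNANT_DIAMETER_MM
        else BENIGN
    )


def rbf_kernel(a: np.ndarray, b: np.ndarray, s: float, standard_form: bool = False) -> float:
    """Radial basis similarity exp(-||a-b||^2 / s^2).

    ``standard_form=True`` uses the 2 s^2 denominator instead.
    """
    if s <= 0:
        raise ValueError("kernel scale s must be positive")
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"feature vectors differ in shape: {a.shape} vs {b.shape}")
    denom = 2.0 * s**2 if standard_form else s**2
    return float(np.exp(-np.sum((a - b) ** 2) / denom))


@dataclass
class SVMModel:
    """Trained RBF-SVM with its standardization, wrapped for save/load."""

    pipeline: Pipeline
    kernel_scale: float
    n_features: int
    classes: tuple[str, str] = (BENIGN, MALIGNANT)

    def decision_function(self, features: np.ndarray) -> np.ndarray:
        features = np.atleast_2d(np.asarray(features, dtype=np.float64))
        if features.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} features, got {features.shape[1]}"
            )
        return self.pipeline.decision_function(features)


def train_svm(
    features: np.ndarray,
    labels,
    s: float = 1.0,
    C: float = 1.0,
    standard_form: bool = False,
) -> SVMModel:
    """Fit a maximum-margin RBF classifier on standardized features.

    The kernel matches :func:`rbf_kernel` exactly: gamma = 1/s^2 (or
    1/(2 s^2) in standard form).  Both classes must be present.
    """
    if s <= 0:
        raise ValueError("kernel scale s must be positive")
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray([1 if lab == MALIGNANT else 0 for lab in labels])
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both benign and malignant cases")
    gamma = 1.0 / (2.0 * s**2) if standard_form else 1.0 / s**2
    pipe = Pipeline(
        [
            ("scale", StandardScaler()),
            ("svc", SVC(kernel="rbf", gamma=gamma, C=C)),
        ]
    )
    pipe.fit(X, y)
    return SVMModel(pipe, kernel_scale=s, n_features=X.shape[1])


def svm_classify(model: SVMModel, features: np.ndarray) -> str | list[str]:
    """Sign of the decision function mapped to benign/malignant."""
    single = np.asarray(features).ndim == 1
    d = model.decision_function(features)
    labels = [MALIGNANT if v > 0 else BENIGN for v in d]
    return labels[0] if single else labels


def save_svm(model: SVMModel, path) -> None:
    with open(path, "wb") as fh:
        pickle.dump({"format": "imlts-svm-v1", "model": model}, fh)


def load_svm(path) -> SVMModel:
    with open(path, "rb") as fh:
        blob = pickle.load(fh)
    if not isinstance(blob, dict) or blob.get("format") != "imlts-svm-v1":
        raise ValueError(f"unrecognized SVM model file {path}")
    return blob["model"]
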