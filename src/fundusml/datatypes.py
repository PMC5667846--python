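"""Core data containers shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The ten retinal categories, ordered by clinical importance.  Category
#: sweeps start from {normal, BDR} and append the remaining classes in
#: this order.
CLASS_ORDER: tuple[str, ...] = (
    "normal",
    "BDR",
    "PDR",
    "dry AMD",
    "wet AMD",
    "RVO",
    "RAO",
    "hypertensive retinopathy",
    "Coat's disease",
    "retinitis",
)

#: Per-category image counts of the curated STARE subset the study design
#: is modelled on (normal retina plus nine disease categories).
STARE_CLASS_COUNTS: dict[str, int] = {
    "normal": 25,
    "BDR": 63,
    "PDR": 17,
    "dry AMD": 25,
    "wet AMD": 48,
    "RVO": 38,
    "RAO": 12,
    "hypertensive retinopathy": 19,
    "Coat's disease": 12,
    "retinitis": 20,
}


@dataclass(frozen=True)
class ClassSpec:
    """One synthetic disease category.

    Parameters
    ----------
    class_id
        Consecutive integer identifier starting at 0.
    name
        Human-readable class label (unique within a dataset).
    lesion_motif
        Tag of the parametric lesion primitive carrying class identity
        (see :mod:`fundusml.synthetic` for the motif vocabulary).
    motif_intensity
        Non-negative separability control; 0 renders the class
        indistinguishable from a normal retina in distribution.
    """

    class_id: int
    name: str
    lesion_motif: str
    motif_intensity: float = 1.0

    def __post_init__(self) -> None:
        if self.motif_intensity < 0:
            raise ValueError("motif_intensity must be >= 0")


@dataclass
class LabeledImageSet:
    """RGB images with integer class labels and class names.

    Images are H×W×3 float arrays with channel values in [0, 1];
    conversion to 8-bit happens only at PNG write time.
    """

    images: list[np.ndarray]
    labels: np.ndarray
    class_names: list[str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.images) != len(self.labels):
            raise ValueError("images and labels must have equal length")
        if len(self.labels) and self.labels.max() >= len(self.class_names):
            raise ValueError("label index exceeds class_names")
        if len(self.labels) and self.labels.min() < 0:
            raise ValueError("negative label")

    def __len__(self) -> int:
        return len(self.images)

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=len(self.class_names))


@dataclass
class FeatureMatrix:
    """n-samples × d-features real matrix with optional aligned labels."""

    values: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (n_samples, n_features)")
        if not np.isfinite(self.values).all():
            raise ValueError("feature matrix contains non-finite values")
        if not self.sample_ids:
            self.sample_ids = [f"s{i}" for i in range(self.values.shape[0])]
        if len(self.sample_ids) != self.values.shape[0]:
            raise ValueError("sample_ids not aligned with rows")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if len(self.labels) != self.values.shape[0]:
                raise ValueError("labels not aligned with rows")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def feature_dim(self) -> int:
        return self.values.shape[1]
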