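"""Image descriptor stage: a pluggable extractor contract plus a
deterministic built-in descriptor.

The pipeline downstream of feature extraction is agnostic to where the
4096 numbers per image come from.  In transfer-learning studies they are
intermediate-layer activations of a pre-trained CNN; here the built-in
descriptor produces the same 4096-wide contract from classical image
statistics so the pipeline runs without any pre-trained weights:

* per-channel intensity histograms (3 × 64 bins = 192),
* multi-scale grid mean/variance statistics over 1×1, 2×2, 4×4 and 8×8
  partitions (85 cells × 3 channels × 2 stats = 510),
* orientation-binned gradient-magnitude pooling on 8×8 and 16×16 grids
  (9 bins each, 2880 values),

zero-padded from 3582 to exactly 4096.  Every block is independently
recomputable by brute force, which the test-suite exploits.

A callable registered by name may replace the built-in descriptor
(e.g. a real CNN adapter), subject to the same contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from fundusml.datatypes import FeatureMatrix, LabeledImageSet


class ImageSizeError(ValueError):
    """Image does not match the extractor's expected input size."""


@dataclass
class ExtractorContract:
    """Contract every feature extractor fulfils.

    ``fn`` maps one H×W×3 float image to a 1-D vector of ``output_dim``
    values.  ``input_size`` of ``None`` accepts any image size.
    """

    name: str
    output_dim: int
    fn: Callable[[np.ndarray], np.ndarray]
    deterministic: bool = True
    input_size: tuple[int, int] | None = None

    def __call__(self, image: np.ndarray) -> np.ndarray:
        if self.input_size is not None and image.shape[:2] != tuple(self.input_size):
            raise ImageSizeError(
                f"extractor {self.name!r} expects {self.input_size}, "
                f"got {image.shape[:2]}"
            )
        v = np.asarray(self.fn(image), dtype=float).ravel()
        if v.size != self.output_dim:
            raise ValueError(
                f"extractor {self.name!r} produced {v.size} values, "
                f"expected {self.output_dim}"
            )
        return v


# ---------------------------------------------------------------------------
# built-in descriptor blocks
# ---------------------------------------------------------------------------

N_HIST_BINS = 64
GRID_LEVELS = (1, 2, 4, 8)
N_ORI_BINS = 9
ORI_GRIDS = (8, 16)
DESCRIPTOR_DIM = 4096


def channel_histograms(image: np.ndarray, bins: int = N_HIST_BINS) -> np.ndarray:
    """Per-channel normalised intensity histograms on [0, 1]."""
    out = []
    for c in range(3):
        h, _ = np.histogram(image[..., c], bins=bins, range=(0.0, 1.0))
        out.append(h / max(image[..., c].size, 1))
    return np.concatenate(out)


def grid_stats(image: np.ndarray, levels: tuple[int, ...] = GRID_LEVELS) -> np.ndarray:
    """Mean and variance per grid cell per channel, coarse to fine."""
    h, w = image.shape[:2]
    out = []
    for g in levels:
        ys = np.linspace(0, h, g + 1).astype(int)
        xs = np.linspace(0, w, g + 1).astype(int)
        for i in range(g):
            for j in range(g):
                cell = image[ys[i]:ys[i + 1], xs[j]:xs[j + 1]]
                for c in range(3):
                    out.append(cell[..., c].mean())
                    out.append(cell[..., c].var())
    return np.asarray(out)


def oriented_gradient_pool(
    image: np.ndarray,
    grids: tuple[int, ...] = ORI_GRIDS,
    n_bins: int = N_ORI_BINS,
) -> np.ndarray:
    """Gradient-magnitude-weighted orientation histograms per grid cell.

    Orientations are unsigned (folded to [0, π)) as in classic HOG-style
    descriptors; each cell's histogram is L1-normalised over the cell's
    total gradient mass (flat cells stay all-zero).
    """
    gray = image.mean(axis=2)
    gy, gx = np.gradient(gray)
    mag = np.hypot(gx, gy)
    ori = np.mod(np.arctan2(gy, gx), np.pi)
    bin_idx = np.minimum((ori / np.pi * n_bins).astype(int), n_bins - 1)
    h, w = gray.shape
    out = []
    for g in grids:
        ys = np.linspace(0, h, g + 1).astype(int)
        xs = np.linspace(0, w, g + 1).astype(int)
        for i in range(g):
            for j in range(g):
                m = mag[ys[i]:ys[i + 1], xs[j]:xs[j + 1]].ravel()
                b = bin_idx[ys[i]:ys[i + 1], xs[j]:xs[j + 1]].ravel()
                hist = np.bincount(b, weights=m, minlength=n_bins)
                tot = hist.sum()
                out.append(hist / tot if tot > 0 else hist)
    return np.concatenate(out)


def builtin_descriptor_vector(image: np.ndarray) -> np.ndarray:
    """Concatenate all blocks and zero-pad to :data:`DESCRIPTOR_DIM`."""
    v = np.concatenate([
        channel_histograms(image),
        grid_stats(image),
        oriented_gradient_pool(image),
    ])
    if v.size > DESCRIPTOR_DIM:
        return v[:DESCRIPTOR_DIM]
    out = np.zeros(DESCRIPTOR_DIM)
    out[: v.size] = v
    return out


def BuiltinDescriptor(input_size: tuple[int, int] | None = (224, 224)) -> ExtractorContract:
    """The default deterministic 4096-wide descriptor."""
    return ExtractorContract(
        name="builtin-4096",
        output_dim=DESCRIPTOR_DIM,
        fn=builtin_descriptor_vector,
        deterministic=True,
        input_size=input_size,
    )


# adapter registry: alternative extractors addressable by name
_REGISTRY: dict[str, Callable[[], ExtractorContract]] = {
    "builtin-4096": BuiltinDescriptor,
}


def register_extractor(name: str, factory: Callable[[], ExtractorContract]) -> None:
    _REGISTRY[name] = factory


def get_extractor(name: str) -> ExtractorContract:
    try:
        return _REGISTRY[name]()
    except KeyError:
        raise KeyError(f"no extractor registered under {name!r}") from None


def extract_features(dataset: LabeledImageSet, extractor: ExtractorContract | None = None) -> FeatureMatrix:
    """One descriptor row per image, in dataset order, labels carried over.

    No per-feature standardisation happens here; scaling is the
    classifier stage's responsibility so preprocessing has a single
    point of truth.
    """
    extractor = extractor or BuiltinDescriptor()
    rows = [extractor(img) for img in dataset.images]
    values = np.vstack(rows) if rows else np.zeros((0, extractor.output_dim))
    return FeatureMatrix(values=values, labels=np.asarray(dataset.labels, dtype=int))
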