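"""Oversampling augmentation: translation, rotation, brightness, noise.

Class imbalance is handled by sampling source images with replacement and
applying randomly parameterised transforms until every class holds a
fixed number of images, each resized to the downstream model input size.

Operation order is translation → rotation (about the image centre) →
multiplicative brightness → additive Gaussian noise → resize.  Geometric
operations run before photometric ones so the noise field is never
warped.  Both geometric steps are folded into a single bilinear warp to
avoid double interpolation; out-of-frame pixels are filled with black,
matching the fundus surround.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import SimilarityTransform, warp, resize


class AugmentationParameterError(ValueError):
    """Transform parameter outside the configured interval."""


class EmptyClassError(ValueError):
    """A class has no source image to oversample from."""


@dataclass(frozen=True)
class AugmentationSpec:
    """Sampling intervals and output geometry for oversampling.

    Defaults: translation within ±10% of the image width, rotation within
    ±15°, multiplicative brightness change within ±10%, Gaussian noise
    sigma uniform on [0, 0.04] (on the [0, 1] channel scale), output
    224×224, and 1000 images per class.
    """

    translation_frac_range: tuple[float, float] = (-0.10, 0.10)
    rotation_deg_range: tuple[float, float] = (-15.0, 15.0)
    brightness_frac_range: tuple[float, float] = (-0.10, 0.10)
    noise_sigma_range: tuple[float, float] = (0.0, 0.04)
    output_size: tuple[int, int] = (224, 224)
    target_per_class: int = 1000

    def __post_init__(self) -> None:
        for name in ("translation_frac_range", "rotation_deg_range",
                     "brightness_frac_range", "noise_sigma_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must be an ordered (lo, hi) pair")
        if self.output_size[0] <= 0 or self.output_size[1] <= 0:
            raise ValueError("output_size must be positive")
        if self.target_per_class < 0:
            raise ValueError("target_per_class must be >= 0")


def _check_in(name: str, value: float, interval: tuple[float, float]) -> None:
    lo, hi = interval
    if not (lo <= value <= hi):
        raise AugmentationParameterError(
            f"{name}={value} outside configured interval [{lo}, {hi}]"
        )


def transform_image(
    image: np.ndarray,
    dx_frac: float = 0.0,
    dy_frac: float = 0.0,
    angle_deg: float = 0.0,
    brightness_frac: float = 0.0,
    noise_sigma: float = 0.0,
    seed: int | np.random.Generator = 0,
    spec: AugmentationSpec | None = None,
) -> np.ndarray:
    """Apply one parameterised augmentation transform.

    ``dx_frac``/``dy_frac`` translate by that fraction of the image width
    and height; ``angle_deg`` rotates counter-clockwise (in the usual x/y
    frame) about the image centre; brightness multiplies channel values
    by ``1 + brightness_frac``; Gaussian noise with ``noise_sigma`` is
    added pixel-wise; the result is clipped to [0, 1] and resized to
    ``spec.output_size``.

    With all parameters zero and the image already at the output size the
    transform is an exact identity.
    """
    spec = spec or AugmentationSpec()
    _check_in("dx_frac", dx_frac, spec.translation_frac_range)
    _check_in("dy_frac", dy_frac, spec.translation_frac_range)
    _check_in("angle_deg", angle_deg, spec.rotation_deg_range)
    _check_in("brightness_frac", brightness_frac, spec.brightness_frac_range)
    if noise_sigma < spec.noise_sigma_range[0] or noise_sigma > spec.noise_sigma_range[1]:
        raise AugmentationParameterError(
            f"noise_sigma={noise_sigma} outside {spec.noise_sigma_range}"
        )
    img = np.asarray(image, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3 or img.size == 0:
        raise ValueError("image must be a non-empty H×W×3 array")

    h, w = img.shape[:2]
    if dx_frac != 0.0 or dy_frac != 0.0 or angle_deg != 0.0:
        # forward map: translate, then rotate about the centre.
        # skimage transforms use (x, y) = (col, row) coordinates.
        cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
        t_shift = SimilarityTransform(translation=(dx_frac * w, dy_frac * h))
        t_rot = (
            SimilarityTransform(translation=(-cx, -cy))
            + SimilarityTransform(rotation=np.deg2rad(angle_deg))
            + SimilarityTransform(translation=(cx, cy))
        )
        fwd = t_shift + t_rot  # apply shift first, rotation second
        img = warp(img, fwd.inverse, order=1, mode="constant", cval=0.0,
                   preserve_range=True)
    if brightness_frac != 0.0:
        img = img * (1.0 + brightness_frac)
    if noise_sigma > 0.0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sigma, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    if (h, w) != tuple(spec.output_size):
        img = resize(img, (*spec.output_size, 3), order=1, mode="constant",
                     cval=0.0, anti_aliasing=False, preserve_range=True)
        img = np.clip(img, 0.0, 1.0)
    return img


def augment_oversample(
    dataset,
    spec: AugmentationSpec | None = None,
    seed: int = 0,
):
    """Oversample a labelled image set to ``target_per_class`` per class.

    Source images are drawn with replacement from the class's pool and
    transform parameters are sampled uniformly from the spec intervals.
    Each output image uses its own substream spawned from ``seed``, so
    the result is reproducible and independent of class iteration order.
    """
    from fundusml.datatypes import LabeledImageSet

    spec = spec or AugmentationSpec()
    k = len(dataset.class_names)
    counts = dataset.class_counts()
    if spec.target_per_class > 0:
        empty = [dataset.class_names[i] for i in range(k) if counts[i] == 0]
        if empty:
            raise EmptyClassError(f"classes with zero source images: {empty}")

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(k * spec.target_per_class)
    by_class = [np.flatnonzero(dataset.labels == c) for c in range(k)]
    images: list[np.ndarray] = []
    labels: list[int] = []
    idx = 0
    for c in range(k):
        for _ in range(spec.target_per_class):
            rng = np.random.default_rng(children[idx])
            idx += 1
            src = dataset.images[rng.choice(by_class[c])]
            out = transform_image(
                src,
                dx_frac=rng.uniform(*spec.translation_frac_range),
                dy_frac=rng.uniform(*spec.translation_frac_range),
                angle_deg=rng.uniform(*spec.rotation_deg_range),
                brightness_frac=rng.uniform(*spec.brightness_frac_range),
                noise_sigma=rng.uniform(*spec.noise_sigma_range),
                seed=rng,
                spec=spec,
            )
            images.append(out.astype(np.float32))
            labels.append(c)
    return LabeledImageSet(images=images, labels=np.asarray(labels, dtype=int),
                           class_names=list(dataset.class_names))
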