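"""Label-controlled synthetic fundus-like images and feature matrices.

The image generator paints a circular fundus disc with a radial colour
gradient, an optic-disc blob, branching vessel curves, and one parametric
lesion motif per disease category (dark dot haemorrhages for background
diabetic retinopathy, pale drusen for dry AMD, sectoral flame streaks for
vein occlusion, and so on).  The motifs are cheap 2-D primitives — disks,
line segments and quadratic Bezier curves — whose number and contrast is
scaled by ``motif_intensity``, so class separability is controllable and
an intensity of zero collapses every class onto the normal-retina
distribution.

The feature-level generator is a fast stand-in for the image pipeline:
class-conditional Gaussians in a ``dim``-dimensional descriptor space
whose class-mean pairwise distances scale linearly with ``separation``.

Neither generator aims at photorealism; they exist so every downstream
stage is testable without a curated clinical image collection.
"""

from __future__ import annotations

import numpy as np

from fundusml.datatypes import CLASS_ORDER, ClassSpec, FeatureMatrix, LabeledImageSet

# motif vocabulary: tag -> drawing routine dispatched in _draw_motif
MOTIFS = (
    "none",
    "dark_dots",
    "vessel_fronds",
    "drusen",
    "macular_patch",
    "flame_streaks",
    "pale_sector",
    "tortuous_vessels",
    "peripheral_exudate",
    "pale_patches",
)

#: Default motif assignment for the ten retinal categories.
DEFAULT_MOTIF_BY_CLASS = {
    "normal": "none",
    "BDR": "dark_dots",
    "PDR": "vessel_fronds",
    "dry AMD": "drusen",
    "wet AMD": "macular_patch",
    "RVO": "flame_streaks",
    "RAO": "pale_sector",
    "hypertensive retinopathy": "tortuous_vessels",
    "Coat's disease": "peripheral_exudate",
    "retinitis": "pale_patches",
}


class UnknownMotifError(ValueError):
    """Raised when a ClassSpec carries a motif tag outside the vocabulary."""


def default_class_specs(
    names: tuple[str, ...] | list[str] = CLASS_ORDER,
    motif_intensity: float = 1.0,
) -> list[ClassSpec]:
    """Build ClassSpecs for the given class names with the default motifs."""
    return [
        ClassSpec(
            class_id=i,
            name=n,
            lesion_motif=DEFAULT_MOTIF_BY_CLASS.get(n, "none"),
            motif_intensity=0.0 if DEFAULT_MOTIF_BY_CLASS.get(n, "none") == "none" else motif_intensity,
        )
        for i, n in enumerate(names)
    ]


# ---------------------------------------------------------------------------
# drawing primitives (all operate in-place on an H×W×3 float image)
# ---------------------------------------------------------------------------


def _disk_mask(h: int, w: int, cy: float, cx: float, r: float) -> np.ndarray:
    yy, xx = np.ogrid[:h, :w]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r


def _blend_disk(img, cy, cx, r, color, alpha=1.0) -> None:
    h, w = img.shape[:2]
    m = _disk_mask(h, w, cy, cx, r)
    img[m] = (1 - alpha) * img[m] + alpha * np.asarray(color)


def _stamp_curve(img, pts, radius, color, alpha=1.0) -> None:
    """Stamp small disks along a polyline given as (y, x) points."""
    for cy, cx in pts:
        _blend_disk(img, cy, cx, radius, color, alpha)


def _bezier(p0, p1, p2, n=40) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)[:, None]
    p0, p1, p2 = (np.asarray(p, dtype=float) for p in (p0, p1, p2))
    return (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t**2 * p2


def _base_fundus(h: int, w: int, rng: np.random.Generator) -> tuple[np.ndarray, dict]:
    """Fundus disc + radial gradient + optic disc + vessel tree.

    Returns the image and a geometry dict (disc centre/radius, optic disc
    position) reused by the motif painters.
    """
    img = np.zeros((h, w, 3), dtype=float)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r_f = 0.48 * min(h, w)

    yy, xx = np.mgrid[:h, :w]
    d = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    inside = d <= r_f
    # orange-red background, darker toward the rim
    shade = 1.0 - 0.35 * (d / r_f).clip(0, 1) ** 2
    base = np.array([0.80, 0.42, 0.15]) * (0.9 + 0.1 * rng.uniform())
    img[inside] = base[None, :] * shade[inside, None]

    # optic disc: bright yellowish blob off-centre
    side = rng.choice([-1.0, 1.0])
    od_cy = cy + rng.uniform(-0.08, 0.08) * h
    od_cx = cx + side * rng.uniform(0.22, 0.30) * w
    od_r = 0.07 * min(h, w)
    _blend_disk(img, od_cy, od_cx, od_r, [0.95, 0.85, 0.55], alpha=0.9)

    # vessel arcades: dark red Bezier curves fanning out of the optic disc
    vcol = [0.35, 0.08, 0.06]
    vw = max(0.006 * min(h, w), 0.8)
    for _ in range(6):
        ang = rng.uniform(0, 2 * np.pi)
        end = (
            cy + 0.9 * r_f * np.sin(ang),
            cx + 0.9 * r_f * np.cos(ang) - side * 0.2 * w,
        )
        ctrl = (
            (od_cy + end[0]) / 2 + rng.uniform(-0.15, 0.15) * h,
            (od_cx + end[1]) / 2 + rng.uniform(-0.15, 0.15) * w,
        )
        pts = _bezier((od_cy, od_cx), ctrl, end, n=60)
        _stamp_curve(img, pts, vw, vcol, alpha=0.85)

    geom = {"cy": cy, "cx": cx, "r": r_f, "od": (od_cy, od_cx, od_r)}
    np.clip(img, 0.0, 1.0, out=img)
    return img, geom


def _rand_in_disc(rng, geom, frac_lo=0.0, frac_hi=0.85):
    """Uniform point inside the fundus disc between two radial fractions."""
    rr = geom["r"] * np.sqrt(rng.uniform(frac_lo**2, frac_hi**2))
    ang = rng.uniform(0, 2 * np.pi)
    return geom["cy"] + rr * np.sin(ang), geom["cx"] + rr * np.cos(ang)


def _draw_motif(img, geom, motif: str, intensity: float, rng: np.random.Generator) -> None:
    if motif == "none" or intensity <= 0:
        return
    h, w = img.shape[:2]
    s = min(h, w)
    n_scale = max(1, int(round(intensity * 6)))
    alpha = float(np.clip(0.35 + 0.13 * intensity, 0.0, 0.95))

    if motif == "dark_dots":  # dot/blot haemorrhages (BDR)
        for _ in range(4 + n_scale):
            cy, cx = _rand_in_disc(rng, geom)
            _blend_disk(img, cy, cx, rng.uniform(0.008, 0.02) * s, [0.18, 0.02, 0.02], alpha)
    elif motif == "vessel_fronds":  # neovascular fronds (PDR)
        for _ in range(2 + n_scale // 2):
            cy, cx = _rand_in_disc(rng, geom, 0.1, 0.6)
            for _ in range(5):
                ang = rng.uniform(0, 2 * np.pi)
                end = (cy + 0.12 * s * np.sin(ang), cx + 0.12 * s * np.cos(ang))
                ctrl = (cy + rng.uniform(-0.06, 0.06) * s, cx + rng.uniform(-0.06, 0.06) * s)
                _stamp_curve(img, _bezier((cy, cx), ctrl, end, 25), 0.004 * s, [0.45, 0.05, 0.05], alpha)
    elif motif == "drusen":  # pale round deposits (dry AMD)
        for _ in range(6 + n_scale):
            cy, cx = _rand_in_disc(rng, geom, 0.0, 0.45)
            _blend_disk(img, cy, cx, rng.uniform(0.008, 0.016) * s, [0.95, 0.9, 0.7], alpha)
    elif motif == "macular_patch":  # grey-green subretinal patch (wet AMD)
        cy, cx = _rand_in_disc(rng, geom, 0.0, 0.2)
        _blend_disk(img, cy, cx, (0.10 + 0.02 * intensity) * s, [0.35, 0.40, 0.28], alpha)
        _blend_disk(img, cy, cx, 0.05 * s, [0.45, 0.15, 0.12], min(0.9, alpha + 0.2))
    elif motif == "flame_streaks":  # sectoral flame haemorrhages (RVO)
        ang0 = rng.uniform(0, 2 * np.pi)
        for _ in range(5 + n_scale):
            ang = ang0 + rng.uniform(-0.5, 0.5)
            cy, cx = _rand_in_disc(rng, geom, 0.15, 0.8)
            end = (cy + 0.06 * s * np.sin(ang), cx + 0.06 * s * np.cos(ang))
            _stamp_curve(img, _bezier((cy, cx), ((cy + end[0]) / 2, (cx + end[1]) / 2), end, 20),
                         0.005 * s, [0.40, 0.04, 0.03], alpha)
    elif motif == "pale_sector":  # ischaemic whitening in a sector (RAO)
        ang0 = rng.uniform(0, 2 * np.pi)
        width = 0.5 + 0.08 * intensity
        yy, xx = np.mgrid[: img.shape[0], : img.shape[1]]
        ang = np.arctan2(yy - geom["cy"], xx - geom["cx"])
        dd = np.sqrt((yy - geom["cy"]) ** 2 + (xx - geom["cx"]) ** 2)
        diff = np.angle(np.exp(1j * (ang - ang0)))
        m = (np.abs(diff) < width) & (dd <= geom["r"])
        img[m] = (1 - 0.5 * alpha) * img[m] + 0.5 * alpha * np.array([0.85, 0.80, 0.70])
    elif motif == "tortuous_vessels":  # tortuosity/narrowing (hypertensive)
        od_cy, od_cx, _ = geom["od"]
        for _ in range(3 + n_scale // 2):
            ang = rng.uniform(0, 2 * np.pi)
            cy, cx = od_cy, od_cx
            pts = []
            for step in range(24):
                cy += 0.03 * s * np.sin(ang)
                cx += 0.03 * s * np.cos(ang)
                ang += rng.uniform(-0.9, 0.9)  # strong direction jitter = tortuosity
                pts.append((cy, cx))
            _stamp_curve(img, pts, 0.004 * s, [0.30, 0.05, 0.05], alpha)
    elif motif == "peripheral_exudate":  # bright peripheral exudate (Coat's)
        for _ in range(3 + n_scale // 2):
            cy, cx = _rand_in_disc(rng, geom, 0.6, 0.9)
            _blend_disk(img, cy, cx, rng.uniform(0.02, 0.05) * s, [0.98, 0.95, 0.55], alpha)
    elif motif == "pale_patches":  # scattered chorioretinal scars (retinitis)
        for _ in range(4 + n_scale):
            cy, cx = _rand_in_disc(rng, geom, 0.1, 0.8)
            _blend_disk(img, cy, cx, rng.uniform(0.02, 0.04) * s, [0.85, 0.78, 0.62], alpha * 0.8)
    else:
        raise UnknownMotifError(f"unknown lesion motif: {motif!r}")
    np.clip(img, 0.0, 1.0, out=img)


# ---------------------------------------------------------------------------
# public generators
# ---------------------------------------------------------------------------


def generate_image_dataset(
    specs: list[ClassSpec],
    n_per_class: int,
    image_size: tuple[int, int] = (128, 128),
    seed: int = 0,
) -> LabeledImageSet:
    """Generate ``n_per_class`` fundus-like images for each class spec.

    Every image gets its own random substream derived from ``seed`` via
    ``numpy.random.SeedSequence`` spawning, so output is bit-identical
    across runs and independent of generation order.

    Raises
    ------
    UnknownMotifError
        If a spec carries a motif tag outside :data:`MOTIFS`.
    ValueError
        If ``n_per_class`` is negative, ``image_size`` below 32×32, or
        ``specs`` is empty.
    """
    if not specs:
        raise ValueError("specs must be non-empty")
    if n_per_class < 0:
        raise ValueError("n_per_class must be >= 0")
    h, w = image_size
    if h < 32 or w < 32:
        raise ValueError("image_size must be at least (32, 32)")
    for sp in specs:
        if sp.lesion_motif not in MOTIFS:
            raise UnknownMotifError(f"unknown lesion motif: {sp.lesion_motif!r}")
    names = [sp.name for sp in specs]
    if len(set(names)) != len(names):
        raise ValueError("class names must be unique")

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(specs) * n_per_class)
    images: list[np.ndarray] = []
    labels: list[int] = []
    idx = 0
    for sp in specs:
        for _ in range(n_per_class):
            rng = np.random.default_rng(children[idx])
            idx += 1
            img, geom = _base_fundus(h, w, rng)
            _draw_motif(img, geom, sp.lesion_motif, sp.motif_intensity, rng)
            images.append(img)
            labels.append(sp.class_id)
    return LabeledImageSet(images=images, labels=np.asarray(labels, dtype=int), class_names=names)


def generate_feature_dataset(
    n_classes: int,
    n_per_class: int,
    dim: int = 4096,
    separation: float = 1.0,
    seed: int = 0,
) -> FeatureMatrix:
    """Class-conditional Gaussian features with controllable separability.

    Class means sit at ``separation`` times random unit vectors, so any
    two class means are on average ``separation * sqrt(2)`` apart while
    the within-class noise is unit isotropic Gaussian.  ``separation=0``
    gives identical distributions for all classes.

    Returns a :class:`FeatureMatrix` with labels attached
    (``n_classes * n_per_class`` rows, class-blocked order).
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    if n_per_class < 0:
        raise ValueError("n_per_class must be >= 0")
    if separation < 0:
        raise ValueError("separation must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    dirs = rng.standard_normal((n_classes, dim))
    norms = np.linalg.norm(dirs, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    means = separation * dirs / norms
    n = n_classes * n_per_class
    labels = np.repeat(np.arange(n_classes), n_per_class)
    x = rng.standard_normal((n, dim)) + means[labels]
    return FeatureMatrix(values=x, labels=labels)
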