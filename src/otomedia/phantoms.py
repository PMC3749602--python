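"""Seeded eardrum-phantom generator with exported ground truth.

Renders disc-like tympanic-membrane phantoms on a dark ear-canal background,
reproducing the visual cues the diagnostic vocabulary measures:

* AOM archetype — opaque white / pale-yellow membrane with a Lambertian-shaded
  peripheral bulge (off-centre spherical cap) and a dark central concavity;
* OME archetype — smooth semi-opaque amber membrane, optional bubble
  (air-fluid) rings, little or no bulge;
* NOE archetype — flat translucent-gray membrane with a straight malleus
  ridge along the major axis.

Optionally adds saturated specular highlight blobs and Gaussian pixel noise.
Every phantom carries a :class:`PhantomTruth` (masks, analytic depth field,
cue flags) so each pipeline stage can be tested against known geometry.

The renderer is a forward model for testing, not a photorealistic simulator:
palette anchors quantify the clinical colour words as fixed RGB points and
make no claim about true tympanic colours.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .core import AOM, NOE, OME, CLASS_LABELS

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "render_phantom",
    "archetype_spec",
    "generate_dataset",
    "collect_color_training_pixels",
    "PALETTES",
]

#: RGB anchors (0-255) quantifying the per-class colour vocabulary:
#: AOM white/pale-yellow opaque, OME amber semi-opaque, NOE translucent gray.
PALETTES = {
    AOM: (235.0, 220.0, 180.0),
    OME: (200.0, 150.0, 60.0),
    NOE: (128.0, 128.0, 128.0),
}

#: Dark-brown ear-canal background (unit scale) before vignetting.
CANAL_COLOR = (0.24, 0.16, 0.12)


@dataclass(frozen=True)
class PhantomSpec:
    """Full geometric and photometric description of one phantom."""

    label: str
    size: int = 256
    center: tuple[float, float] | None = None  # (row, col); None = frame centre
    radius: float = 96.0  # membrane semi-major axis, pixels
    axis_ratio: float = 0.85  # minor/major; major axis horizontal
    base_color: tuple[float, float, float] = (128.0, 128.0, 128.0)  # 0-255
    bulge_amplitude: float = 0.0  # [0, 1], scales surface gradient
    bulge_radius_fraction: float = 0.5  # of membrane radius
    bulge_offset: tuple[float, float] = (0.0, 0.0)  # (row, col) px from centre
    concavity_radius: float = 0.0  # px; 0 disables the dark central core
    concavity_contrast: float = 0.5
    malleus: bool = False
    malleus_width: float = 6.0
    malleus_brightness: float = 0.55  # ridge brightness boost (additive, unit)
    bubbles: tuple[tuple[float, float, float], ...] = ()  # (row, col, radius)
    specular_blobs: tuple[tuple[float, float, float], ...] = ()
    noise_sigma: float = 0.0  # unit-interval Gaussian noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.label not in CLASS_LABELS:
            raise ValueError(f"label must be one of {CLASS_LABELS}")
        if not 0.0 <= self.bulge_amplitude <= 1.0:
            raise ValueError("bulge_amplitude must lie in [0, 1]")
        if not 0.0 < self.bulge_radius_fraction <= 1.0:
            raise ValueError("bulge_radius_fraction must lie in (0, 1]")
        cm, cn = self.effective_center()
        margin = self.radius
        if not (0 <= cm - self.axis_ratio * margin and cm + self.axis_ratio * margin < self.size
                and 0 <= cn - margin and cn + margin < self.size):
            raise ValueError("membrane geometry extends outside the frame")

    def effective_center(self) -> tuple[float, float]:
        if self.center is None:
            return (self.size - 1) / 2.0, (self.size - 1) / 2.0
        return self.center

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["center"] = None if self.center is None else list(self.center)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        if d.get("center") is not None:
            d["center"] = tuple(d["center"])
        d["bulge_offset"] = tuple(d["bulge_offset"])
        d["bubbles"] = tuple(tuple(b) for b in d["bubbles"])
        d["specular_blobs"] = tuple(tuple(b) for b in d["specular_blobs"])
        return cls(**d)


@dataclass
class PhantomTruth:
    """Ground truth exported with every rendered phantom."""

    label: str
    membrane_mask: np.ndarray  # boolean (H, W)
    depth: np.ndarray  # analytic surface height, arbitrary units, (H, W)
    stripe_mask: np.ndarray
    bubble_mask: np.ndarray
    highlight_mask: np.ndarray
    cues: dict = field(default_factory=dict)  # qualitative per-cue flags


def _height_field(spec: PhantomSpec, mm: np.ndarray, nn: np.ndarray,
                  membrane: np.ndarray) -> np.ndarray:
    """Analytic surface height: spherical-cap bulge minus central dip."""
    cm, cn = spec.effective_center()
    z = np.zeros_like(mm, dtype=float)
    if spec.bulge_amplitude > 0:
        bm, bn = cm + spec.bulge_offset[0], cn + spec.bulge_offset[1]
        a = spec.bulge_radius_fraction * spec.radius
        r2 = ((mm - bm) ** 2 + (nn - bn) ** 2) / a**2
        cap = np.sqrt(np.clip(1.0 - r2, 0.0, None))
        # height in pixels so the shading gradient has a physical scale
        z += spec.bulge_amplitude * 0.45 * a * cap
    if spec.concavity_radius > 0:
        rc = np.hypot(mm - cm, nn - cn) / spec.concavity_radius
        dip = np.clip(1.0 - rc**2, 0.0, None)
        z -= spec.bulge_amplitude * 0.25 * spec.concavity_radius * dip
    z[~membrane] = 0.0
    return z


def render_phantom(spec: PhantomSpec) -> tuple[np.ndarray, PhantomTruth]:
    """Render one phantom; deterministic for a fixed spec (seed included)."""
    H = W = spec.size
    mm, nn = np.mgrid[0:H, 0:W].astype(float)
    cm, cn = spec.effective_center()
    rng = np.random.default_rng(spec.seed)

    # membrane: ellipse with horizontal major axis
    ell = ((mm - cm) / (spec.axis_ratio * spec.radius)) ** 2 + (
        (nn - cn) / spec.radius
    ) ** 2
    membrane = ell <= 1.0

    # dark vignetted canal background
    r_frame = np.hypot(mm - (H - 1) / 2, nn - (W - 1) / 2)
    vignette = 1.0 - 0.55 * (r_frame / r_frame.max()) ** 2
    image = np.empty((H, W, 3))
    for i, c in enumerate(CANAL_COLOR):
        image[..., i] = c * vignette

    # Lambertian shading of the analytic surface under frontal light
    z = _height_field(spec, mm, nn, membrane)
    gm, gn = np.gradient(z)
    shading = 1.0 / np.sqrt(1.0 + gm**2 + gn**2)

    # darken the central concavity core (attached to the malleus)
    if spec.concavity_radius > 0:
        rc = np.hypot(mm - cm, nn - cn) / spec.concavity_radius
        core = np.clip(1.0 - rc**2, 0.0, None)
        shading = shading * (1.0 - spec.concavity_contrast * core)

    base = np.asarray(spec.base_color, dtype=float) / 255.0
    image[membrane] = base[None, :] * shading[membrane, None]

    # malleus: straight bright ridge along the (horizontal) major axis
    stripe = np.zeros((H, W), dtype=bool)
    if spec.malleus:
        stripe = (
            (np.abs(mm - cm) <= spec.malleus_width / 2.0)
            & (np.abs(nn - cn) <= 0.9 * spec.radius)
            & membrane
        )
        ridge = np.clip(image[stripe] + spec.malleus_brightness * base[None, :], 0, 1)
        image[stripe] = ridge

    # bubbles: darker air-fluid boundary rings (the interior is the truth mask)
    bubble_mask = np.zeros((H, W), dtype=bool)
    for bm, bn, br in spec.bubbles:
        rb = np.hypot(mm - bm, nn - bn)
        ring = (np.abs(rb - br) <= 1.5) & membrane
        disc = (rb <= br) & membrane
        image[ring] *= 0.55
        bubble_mask |= disc

    # specular highlights: saturated white blobs
    highlight = np.zeros((H, W), dtype=bool)
    for hm, hn, hr in spec.specular_blobs:
        blob = np.hypot(mm - hm, nn - hn) <= hr
        highlight |= blob
    image[highlight] = 1.0

    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, image.shape)
    image = np.clip(image, 0.0, 1.0)

    truth = PhantomTruth(
        label=spec.label,
        membrane_mask=membrane,
        depth=z,
        stripe_mask=stripe,
        bubble_mask=bubble_mask,
        highlight_mask=highlight,
        cues={
            "bulging": spec.bulge_amplitude > 0.2,
            "translucent": spec.label == NOE,
            "amber": spec.label == OME,
            "bubbles": len(spec.bubbles) > 0,
            "malleus": spec.malleus,
        },
    )
    return image, truth


# ---------------------------------------------------------------------------
# class archetypes and datasets

#: difficulty -> (palette jitter sd, noise sigma, AOM amplitude range,
#:                OME amplitude range, cue dropout probability)
_DIFFICULTY = {
    "separable": dict(jitter=3.0, noise=2.0 / 255.0, aom_amp=(0.7, 1.0),
                      ome_amp=(0.0, 0.08), dropout=0.0),
    "medium": dict(jitter=8.0, noise=4.0 / 255.0, aom_amp=(0.45, 0.9),
                   ome_amp=(0.0, 0.3), dropout=0.1),
    "hard": dict(jitter=16.0, noise=8.0 / 255.0, aom_amp=(0.25, 0.75),
                 ome_amp=(0.0, 0.55), dropout=0.3),
}


def archetype_spec(label: str, seed: int, difficulty: str = "separable",
                   size: int = 256) -> PhantomSpec:
    """Draw one class-conditional phantom spec at the given difficulty."""
    if difficulty not in _DIFFICULTY:
        raise ValueError(f"difficulty must be one of {sorted(_DIFFICULTY)}")
    lv = _DIFFICULTY[difficulty]
    rng = np.random.default_rng(seed)
    base = np.asarray(PALETTES[label], dtype=float)
    color = tuple(np.clip(base + rng.normal(0, lv["jitter"], 3), 0, 255))
    radius = 0.375 * size * rng.uniform(0.92, 1.0)
    kw: dict = dict(label=label, size=size, radius=radius, base_color=color,
                    noise_sigma=lv["noise"], seed=int(rng.integers(2**31)))
    if label == AOM:
        amp = rng.uniform(*lv["aom_amp"])
        ang = rng.uniform(0, 2 * np.pi)
        off = 0.15 * radius
        kw.update(
            bulge_amplitude=amp,
            bulge_radius_fraction=rng.uniform(0.55, 0.7),
            bulge_offset=(off * np.cos(ang), off * np.sin(ang)),
            concavity_radius=rng.uniform(14, 20),
            concavity_contrast=0.5,
        )
    elif label == OME:
        n_bub = int(rng.integers(1, 4)) if rng.uniform() >= lv["dropout"] else 0
        bubbles = []
        for _ in range(n_bub):
            br = rng.uniform(8, 14)
            ang = rng.uniform(0, 2 * np.pi)
            rr = rng.uniform(0.2, 0.6) * radius
            bubbles.append((size / 2 + rr * 0.8 * np.sin(ang),
                            size / 2 + rr * np.cos(ang), br))
        kw.update(
            bulge_amplitude=rng.uniform(*lv["ome_amp"]),
            bulge_radius_fraction=rng.uniform(0.4, 0.6),
            bubbles=tuple(bubbles),
            malleus=bool(rng.uniform() < lv["dropout"]),
        )
    else:  # NOE
        kw.update(
            bulge_amplitude=0.0,
            malleus=rng.uniform() >= lv["dropout"],
            malleus_width=rng.uniform(5, 8),
        )
    return PhantomSpec(**kw)


def generate_dataset(
    n_per_class: int,
    difficulty: str = "separable",
    seed: int = 0,
    size: int = 256,
) -> tuple[list[tuple[np.ndarray, PhantomTruth]], list[dict]]:
    """Class-balanced phantom set plus a JSON-serialisable spec manifest.

    Deterministic: the same arguments always produce the same images and the
    same manifest.  Classes are interleaved AOM, OME, NOE, AOM, ...
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    items: list[tuple[np.ndarray, PhantomTruth]] = []
    manifest: list[dict] = []
    for i in range(n_per_class):
        for label in CLASS_LABELS:
            spec = archetype_spec(label, int(rng.integers(2**31)), difficulty, size)
            items.append(render_phantom(spec))
            manifest.append(spec.to_dict())
    return items, manifest


def collect_color_training_pixels(
    kind: str,
    difficulty: str = "separable",
    seed: int = 0,
    n_images: int = 20,
    n_pixels: int = 100,
    size: int = 256,
) -> np.ndarray:
    """Sample membrane pixels emulating hand-picked colour training regions.

    ``kind``: ``"translucent"`` samples NOE phantoms, ``"amber"`` samples OME
    phantoms.  Pixels on stripes, bubbles or highlights are excluded, as a
    human picking clean translucent/amber patches would.  Returns an
    ``(n_images * n_pixels, 3)`` array on the 0-255 scale.
    """
    label = {"translucent": NOE, "amber": OME}.get(kind)
    if label is None:
        raise ValueError("kind must be 'translucent' or 'amber'")
    rng = np.random.default_rng(seed)
    samples = []
    for _ in range(n_images):
        spec = archetype_spec(label, int(rng.integers(2**31)), difficulty, size)
        image, truth = render_phantom(spec)
        clean = truth.membrane_mask & ~truth.stripe_mask & ~truth.bubble_mask
        clean &= ~truth.highlight_mask
        coords = np.flatnonzero(clean)
        pick = rng.choice(coords, size=n_pixels, replace=False)
        samples.append(image.reshape(-1, 3)[pick] * 255.0)
    return np.concatenate(samples, axis=0)
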