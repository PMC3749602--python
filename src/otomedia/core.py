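"""Shared containers, image conventions and pipeline configuration.

Conventions used throughout the package:

* images are numpy arrays, ``float64`` on the unit interval, shape ``(H, W, 3)``
  for colour and ``(H, W)`` for grayscale; row index ``m``, column index ``n``,
  0-based;
* colour-distance computations (translucency / amber assignment) run on the
  8-bit 0-255 scale, because their distance thresholds are only meaningful
  there — each function states the scale it expects;
* binary masks are boolean arrays dimension-matched to their parent image.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import yaml
from PIL import Image

__all__ = [
    "AOM",
    "OME",
    "NOE",
    "REJECTED",
    "CLASS_LABELS",
    "FEATURE_NAMES",
    "GRAY_WEIGHTS",
    "DepthMap",
    "FeatureVector",
    "PipelineConfig",
    "SegmentedImage",
    "load_image",
    "save_image",
    "to_gray",
]

#: Diagnostic labels.  ``REJECTED`` is only ever emitted by the image-quality
#: gate, never by the rule-based classifier.
AOM = "AOM"
OME = "OME"
NOE = "NOE"
REJECTED = "REJECTED"
CLASS_LABELS = (AOM, OME, NOE)

#: ITU-R 601 luma weights; the fixed deterministic RGB -> gray conversion.
GRAY_WEIGHTS = np.array([0.299, 0.587, 0.114])

#: Canonical ordering of the eight vocabulary features.
FEATURE_NAMES = (
    "bulging",
    "concavity",
    "light",
    "malleus",
    "translucency",
    "amber",
    "bubbles",
    "variance",
)


def to_gray(image: np.ndarray) -> np.ndarray:
    """Deterministic luminance conversion of a unit-interval RGB image.

    Uses ITU-R 601 weights (0.299, 0.587, 0.114).  Idempotent under channel
    replication: ``to_gray(stack([g, g, g])) == g`` up to float rounding.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim == 2:
        return image
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) RGB image, got shape {image.shape}")
    return image @ GRAY_WEIGHTS


def load_image(path: str | Path) -> np.ndarray:
    """Load an 8-bit PNG/JPEG/TIFF as a unit-interval ``(H, W, 3)`` array.

    Grayscale-on-disk files are replicated to three channels; palette or
    alpha images are converted to RGB.  Raises ``IOError`` (with the path in
    the message) for unreadable or truncated files.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            im = im.convert("RGB")
            arr = np.asarray(im, dtype=np.uint8)
    except Exception as exc:  # Pillow raises a zoo of decode errors
        raise IOError(f"cannot read image {path}: {exc}") from exc
    return arr.astype(float) / 255.0


def save_image(image: np.ndarray, path: str | Path) -> None:
    """Save a unit-interval RGB (or gray) array as an 8-bit image file."""
    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    arr8 = np.rint(arr * 255.0).astype(np.uint8)
    Image.fromarray(arr8).save(Path(path))


@dataclass
class SegmentedImage:
    """A colour image together with its tympanic-membrane mask.

    ``image`` is unit-interval ``(H, W, 3)``; ``mask`` is boolean ``(H, W)``
    with at least one true pixel.  ``meta`` carries provenance (segmentation
    convergence flags, highlight-correction notes, ...).
    """

    image: np.ndarray
    mask: np.ndarray
    source_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise ValueError("SegmentedImage.image must be (H, W, 3)")
        if self.mask.shape != self.image.shape[:2]:
            raise ValueError(
                f"mask shape {self.mask.shape} != image shape {self.image.shape[:2]}"
            )
        if not self.mask.any():
            raise ValueError("SegmentedImage.mask must contain at least one pixel")

    @property
    def mask_area(self) -> int:
        return int(self.mask.sum())

    def gray(self) -> np.ndarray:
        return to_gray(self.image)


@dataclass
class DepthMap:
    """Relative depth recovered from shading, normalised to [0, 1].

    ``degenerate`` is set when the raw depth range over the membrane was below
    tolerance (e.g. a constant image): the map is then all zeros and the
    bulging feature is zero by convention.
    """

    pixels: np.ndarray
    degenerate: bool = False


@dataclass(frozen=True)
class FeatureVector:
    """The eight-term otitis-media vocabulary for one image.

    bulging       fraction of membrane whose shading-recovered depth exceeds
                  the depth threshold (AOM cue)
    concavity     bright-annulus / dark-core intensity ratio of the best
                  central circular neighbourhood (AOM cue)
    light         bright-region ratio across the best half-plane split
                  through the concavity centre (AOM cue, non-uniform lighting)
    malleus       0/1 straight-ridge detection along the membrane major axis
                  (visible malleus argues against AOM)
    translucency  fraction of membrane pixels near a trained translucent-gray
                  colour cluster (NOE cue)
    amber         fraction of membrane pixels near a trained amber cluster
                  (OME cue)
    bubbles       fraction of membrane covered by detected air-fluid
                  boundaries (OME cue)
    variance      population variance of membrane gray intensities
    """

    bulging: float
    concavity: float
    light: float
    malleus: float
    translucency: float
    amber: float
    bubbles: float
    variance: float

    def __post_init__(self) -> None:
        for name in ("bulging", "translucency", "amber", "bubbles"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.malleus not in (0.0, 1.0, 0, 1):
            raise ValueError(f"malleus must be 0 or 1, got {self.malleus}")
        if self.concavity < 0 or self.light < 0 or self.variance < 0:
            raise ValueError("concavity, light and variance must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in FEATURE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "FeatureVector":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (len(FEATURE_NAMES),):
            raise ValueError(f"expected {len(FEATURE_NAMES)} features, got {arr.shape}")
        return cls(**dict(zip(FEATURE_NAMES, arr)))

    def as_dict(self) -> dict:
        return {k: float(getattr(self, k)) for k in FEATURE_NAMES}


@dataclass
class PipelineConfig:
    """Every tunable constant of the pipeline, defaulted to its study value.

    Scale notes: ``specular_threshold``, ``light_threshold`` and
    ``depth_threshold`` live on unit-interval intensities;
    ``translucency_threshold`` / ``amber_threshold`` are Euclidean RGB
    distances on the 0-255 scale; radii and window sides are pixels.
    """

    # --- segmentation (morphological geodesic active contour) ---
    seg_init_radius_fraction: float = 0.25  # of min(H, W)
    seg_max_iterations: int = 200
    seg_convergence_window: int = 10  # iterations per convergence check
    seg_convergence_tol: float = 1e-3  # relative area change across a window
    seg_smoothing: int = 1
    seg_balloon: float = 1.0
    seg_edge_alpha: float = 300.0  # inverse-gradient edge-map steepness
    seg_edge_sigma: float = 3.0

    # --- specular highlights and rejection ---
    specular_threshold: float = 0.90  # gray intensity above which a pixel is a highlight
    reject_fraction: float = 0.15  # largest highlight component / membrane area

    # --- bulging (shading-recovered depth) ---
    depth_threshold: float = 0.6
    sfs_iterations: int = 300
    sfs_smooth_sigma: float = 1.0  # pre-smoothing of the gray image, px
    sfs_albedo_percentile: float = 90.0  # brightness quantile taken as albedo
    sfs_intensity_floor: float = 0.05  # clamp on normalised intensity
    sfs_slope_floor_percentile: float = 25.0  # noise-floor subtracted from slopes
    sfs_boundary_erosion: int = 5  # px shaved off the mask rim before recovery
    sfs_opening_radius: int = 15  # sub-bulge-scale peak suppression, px
    sfs_relief_tol: float = 1.0  # px of height below which the surface is flat

    # --- central concavity ---
    concavity_radius: int = 60  # circular neighbourhood radius R
    concavity_window: int = 151  # central search window side
    concavity_stride: int = 5  # candidate-centre stride within the window
    polar_n_angles: int = 360

    # --- light ---
    light_threshold: float = 0.70  # post-equalisation bright cutoff
    light_n_angles: int = 180

    # --- malleus ---
    meanshift_bandwidth: float = 16.0  # RGB 0-255 scale
    meanshift_max_samples: int = 2000
    canny_sigma: float = 1.4
    canny_low: float = 0.1
    canny_high: float = 0.3
    malleus_band_halfwidth: int = 50  # pixels around the major axis
    malleus_min_length_fraction: float = 0.4  # of the major-axis length
    malleus_angle_tol_deg: float = 15.0

    # --- colour models (translucency / amber) ---
    translucency_threshold: float = 10.0  # T_t, RGB 0-255 distance
    amber_threshold: float = 10.0  # T_a, same convention as T_t
    n_color_clusters: int = 10  # K
    n_pixels_per_image: int = 100  # N_t
    n_training_images: int = 20  # N_tl

    # --- bubbles ---
    bubble_close_radius: int = 2
    bubble_min_area: int = 30

    # --- misc ---
    epsilon: float = 1e-6  # dark-mean division guard
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.reject_fraction < 1.0:
            raise ValueError("reject_fraction must lie in (0, 1)")
        for name in ("specular_threshold", "light_threshold", "depth_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    # -- serialisation ---------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def fingerprint(self) -> str:
        """Short stable hash of the full configuration, for provenance."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]

    def replace(self, **kw) -> "PipelineConfig":
        return dataclasses.replace(self, **kw)


def iter_mask_coords(mask: np.ndarray) -> Iterator[tuple[int, int]]:
    """Yield (row, col) of true pixels; helper for brute-force oracles."""
    for m, n in zip(*np.nonzero(mask)):
        yield int(m), int(n)
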