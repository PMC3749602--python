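"""The eight-term otitis-media vocabulary: engineered image features that
mirror the visual cues otoscopists use.

AOM cues: ``bulging`` (area of high shading-recovered depth), ``concavity``
(bright-annulus / dark-core ratio of the best central circular
neighbourhood), ``light`` (bright/dark half-plane ratio through the
concavity centre).  NOE cues: ``malleus`` (straight-ridge detection along the
major axis), ``translucency`` (fraction of membrane near trained
translucent-gray colour clusters).  OME cues: ``amber`` (same colour
machinery with an amber model), ``bubbles`` (closed air-fluid boundaries),
``variance`` (gray-intensity variance).

Unless stated otherwise, intensities are unit-interval and all means and
variances are taken over membrane-mask pixels only; the colour-cluster
distances run on the 0-255 scale, where their thresholds are meaningful.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import binary_fill_holes, gaussian_filter, grey_opening, map_coordinates
from skimage import exposure
from skimage.feature import canny
from skimage.measure import regionprops
from skimage.morphology import closing, disk, erosion, remove_small_objects
from skimage.transform import hough_line, hough_line_peaks, rotate
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cluster import KMeans, MeanShift

from .core import DepthMap, FeatureVector, PipelineConfig, SegmentedImage, to_gray

__all__ = [
    "ColorClusterModel",
    "ConcavitySearchResult",
    "LightSearchResult",
    "VocabularyExtractor",
    "bubble_presence",
    "bulging_feature",
    "central_concavity",
    "color_fraction",
    "depth_from_shading",
    "extract_features",
    "grayscale_variance",
    "light_feature",
    "malleus_presence",
    "polar_neighborhood",
    "train_color_model",
]


# ---------------------------------------------------------------------------
# bulging

def depth_from_shading(
    gray: np.ndarray,
    mask: np.ndarray | None = None,
    iterations: int = 300,
    config: PipelineConfig | None = None,
) -> DepthMap:
    """Recover relative depth from a single shaded grayscale image.

    Under the coaxial (frontal) illumination of an otoscope the Lambertian
    reflectance ``E = 1 / sqrt(1 + |grad z|^2)`` inverts in closed form to a
    surface-slope field ``|grad z| = sqrt(1 / E^2 - 1)``, which is integrated
    into a height field by an iterative upwind (eikonal) scheme growing
    inward from the membrane rim — depth at a pixel is the minimal slope
    integral from the boundary, updated Jacobi-style until convergence or
    ``iterations`` passes.

    Robustness steps, all configurable: the gray image is pre-smoothed
    (``sfs_smooth_sigma``); albedo is estimated as a high brightness quantile
    over the mask (``sfs_albedo_percentile``) and divided out, so palette
    darkness is not mistaken for slope; a low slope quantile
    (``sfs_slope_floor_percentile``) is subtracted as the sensor-noise floor;
    the mask rim is eroded by ``sfs_boundary_erosion`` pixels so background
    bleed-in does not fake a wall of slope; and a grayscale opening at the
    concavity-core scale (``sfs_opening_radius``) removes narrow peaks —
    the ascent-only integration renders concave pits as spikes, which are
    not bulges.

    The map is min-max normalised to [0, 1] over the (eroded) mask.  It is
    degenerate — flagged, all zeros — when the gray image carries no shading
    information (intensity range < 1e-6) or the recovered relief is below
    ``sfs_relief_tol`` pixels of height: flat at imaging resolution.
    Deterministic for fixed inputs.
    """
    cfg = config or PipelineConfig()
    E = np.asarray(gray, dtype=float)
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if mask is None:
        work = np.ones_like(E, dtype=bool)
        work[0, :] = work[-1, :] = work[:, 0] = work[:, -1] = False
    else:
        work = erosion(np.asarray(mask, bool), disk(cfg.sfs_boundary_erosion))
        if not work.any():
            work = np.asarray(mask, bool)
    if not work.any() or E[work].max() - E[work].min() < 1e-6:
        return DepthMap(pixels=np.zeros_like(E), degenerate=True)

    smoothed = gaussian_filter(E, cfg.sfs_smooth_sigma)
    albedo = max(np.percentile(smoothed[work], cfg.sfs_albedo_percentile),
                 cfg.sfs_intensity_floor)
    shading = np.clip(smoothed / albedo, cfg.sfs_intensity_floor, 1.0)
    slope = np.sqrt(1.0 / shading**2 - 1.0)
    slope = np.maximum(
        slope - np.percentile(slope[work], cfg.sfs_slope_floor_percentile), 0.0
    )

    big = 1e12
    z = np.where(work, big, 0.0)
    for _ in range(iterations):
        zp = np.pad(z, 1, constant_values=0.0)
        a = np.minimum(zp[:-2, 1:-1], zp[2:, 1:-1])
        b = np.minimum(zp[1:-1, :-2], zp[1:-1, 2:])
        # Rouy-Tourin upwind update of |grad z| = slope
        upd = np.where(
            np.abs(a - b) >= slope,
            np.minimum(a, b) + slope,
            (a + b + np.sqrt(np.maximum(2 * slope**2 - (a - b) ** 2, 0.0))) / 2,
        )
        znew = np.minimum(z, upd)
        change = np.abs(znew - z)[work].max()
        z = np.where(work, znew, 0.0)
        if change < 1e-9:
            break

    if cfg.sfs_opening_radius > 0:
        z = grey_opening(z, footprint=disk(cfg.sfs_opening_radius))
    vals = z[work]
    span = float(vals.max() - vals.min())
    if span < cfg.sfs_relief_tol:
        return DepthMap(pixels=np.zeros_like(E), degenerate=True)
    depth = np.clip((z - vals.min()) / span, 0.0, 1.0)
    depth[~work] = 0.0
    return DepthMap(pixels=depth, degenerate=False)


def bulging_feature(
    seg: SegmentedImage,
    depth_threshold: float = 0.6,
    iterations: int = 300,
    config: PipelineConfig | None = None,
) -> float:
    """Fraction of the membrane whose normalised depth strictly exceeds the
    depth threshold; 0 for a degenerate (flat) depth map."""
    depth = depth_from_shading(seg.gray(), seg.mask, iterations, config)
    if depth.degenerate:
        return 0.0
    bulged = (depth.pixels > depth_threshold) & seg.mask
    return float(bulged.sum()) / seg.mask_area


# ---------------------------------------------------------------------------
# central concavity

@dataclass
class ConcavitySearchResult:
    value: float  # the concavity feature (best bright/dark mean ratio)
    center: tuple[int, int]  # (row, col) at which it is attained
    r_prime: int  # best core radius, in [R/4, 3R/4]


def polar_neighborhood(
    gray: np.ndarray,
    center: tuple[float, float],
    radius: int,
    n_angles: int = 360,
) -> np.ndarray:
    """Bilinear polar resampling of a circular neighbourhood.

    Returns an ``(radius, n_angles)`` grid sampled at integer radii
    ``r = 1..radius`` and ``n_angles`` uniform angles over [0, 2*pi), with
    the angle measured from the row axis towards the column axis
    (``m = m_c + r cos(theta)``, ``n = n_c + r sin(theta)``).
    """
    gray = np.asarray(gray, dtype=float)
    H, W = gray.shape
    mc, nc = center
    if not (radius <= mc <= H - 1 - radius and radius <= nc <= W - 1 - radius):
        raise ValueError(
            f"circular neighbourhood of radius {radius} at {center} exceeds "
            f"the {H}x{W} image"
        )
    r = np.arange(1, radius + 1, dtype=float)
    theta = np.linspace(0.0, 2.0 * np.pi, n_angles, endpoint=False)
    M = mc + np.outer(r, np.cos(theta))
    N = nc + np.outer(r, np.sin(theta))
    return map_coordinates(gray, [M, N], order=1, mode="nearest")


def central_concavity(
    seg: SegmentedImage,
    radius: int = 60,
    window: int = 151,
    stride: int = 5,
    n_angles: int = 360,
    eps: float = 1e-6,
) -> ConcavitySearchResult:
    """Search the central window for the strongest dark-core / bright-annulus
    pattern (the concavity left where the membrane stays attached to the
    malleus while its periphery bulges).

    For each candidate centre on a ``stride``-spaced grid inside the central
    ``window x window`` region, and each core radius ``R' in [R/4, 3R/4]``,
    the ratio mean(annulus r > R') / mean(core r <= R') is computed on the
    polar resampling of the circular neighbourhood; the feature is the
    maximum ratio.  Dark-core means below ``eps`` are clamped to ``eps``.
    Candidates whose circular neighbourhood leaves the image are skipped;
    ties keep the first candidate in row-major order, smallest core radius.
    """
    gray = seg.gray()
    H, W = gray.shape
    if window > H or window > W:
        raise ValueError(f"search window {window} exceeds image {H}x{W}")
    half = window // 2
    cm, cn = H // 2, W // 2
    rows = np.arange(cm - half, cm + half + 1, stride)
    cols = np.arange(cn - half, cn + half + 1, stride)
    rows = rows[(rows >= radius) & (rows <= H - 1 - radius)]
    cols = cols[(cols >= radius) & (cols <= W - 1 - radius)]
    if len(rows) == 0 or len(cols) == 0:
        raise ValueError("no candidate centre admits the circular neighbourhood")
    r_lo, r_hi = radius // 4, (3 * radius) // 4

    # batched polar sampling: one interpolation call per candidate row
    r = np.arange(1, radius + 1, dtype=float)
    theta = np.linspace(0.0, 2.0 * np.pi, n_angles, endpoint=False)
    m_off = np.outer(r, np.cos(theta))  # (radius, n_angles)
    n_off = np.outer(r, np.sin(theta))
    rp_grid = np.arange(r_lo, r_hi + 1)

    best = ConcavitySearchResult(value=-np.inf, center=(int(rows[0]), int(cols[0])),
                                 r_prime=r_lo)
    for m in rows:
        M = m + np.broadcast_to(m_off, (len(cols),) + m_off.shape)
        N = cols[:, None, None] + n_off[None]
        polar = map_coordinates(gray, [M.ravel(), N.ravel()], order=1, mode="nearest")
        row_means = polar.reshape(len(cols), radius, n_angles).mean(axis=2)
        csum = np.cumsum(row_means, axis=1)  # (n_cols, radius)
        total = csum[:, -1]
        dark = csum[:, rp_grid - 1] / rp_grid[None, :]
        bright = (total[:, None] - csum[:, rp_grid - 1]) / (radius - rp_grid)[None, :]
        ratio = bright / np.maximum(dark, eps)
        j, k = np.unravel_index(np.argmax(ratio), ratio.shape)
        # row-major candidate order with smallest core radius wins ties
        if ratio[j, k] > best.value:
            best = ConcavitySearchResult(
                value=float(ratio[j, k]),
                center=(int(m), int(cols[j])),
                r_prime=int(rp_grid[k]),
            )
    return best


# ---------------------------------------------------------------------------
# light

@dataclass
class LightSearchResult:
    value: float  # bright/dark ratio at the best split
    theta_max: float  # radians, in [0, pi)


def light_feature(
    seg: SegmentedImage,
    threshold: float = 0.70,
    center: tuple[int, int] | None = None,
    n_angles: int = 180,
    eps: float = 1e-6,
    bright_mask: np.ndarray | None = None,
) -> LightSearchResult:
    """Non-uniformity of illumination: best bright/dark ratio over half-plane
    splits through the concavity centre.

    The gray image is contrast-enhanced by histogram equalisation over the
    membrane pixels and thresholded at ``threshold`` to a brightly-lit mask.
    For each angle on a uniform grid over [0, pi) the membrane is split by
    the line through ``center`` (default: the mask centroid) and the ratio of
    bright-pixel fractions between the two halves is computed; the feature is
    the maximum ratio, with ties broken towards the smallest angle.

    Half-plane convention: a pixel is in the "bright side" B when
    ``(n - n_c) cos(theta) - (m - m_c) sin(theta) >= 0``, which matches
    ``n >= tan(theta) (m - m_c) + n_c`` for ``theta < pi/2`` and stays
    well-defined at the vertical split.  Angles whose split leaves either
    side empty are skipped; an empty brightly-lit mask gives 0 by convention.

    ``bright_mask`` overrides the internal enhancement + threshold with a
    precomputed brightly-lit mask (used by analyses that already have one).
    """
    if bright_mask is None:
        equalized = exposure.equalize_hist(seg.gray(), mask=seg.mask)
        bright_mask = (equalized > threshold) & seg.mask
    else:
        bright_mask = np.asarray(bright_mask, bool) & seg.mask
    if not bright_mask.any():
        return LightSearchResult(value=0.0, theta_max=0.0)
    if center is None:
        mm_all, nn_all = np.nonzero(seg.mask)
        center = (int(round(mm_all.mean())), int(round(nn_all.mean())))
    mc, nc = center
    mm, nn = np.nonzero(seg.mask)
    x = bright_mask[mm, nn].astype(float)
    dm = mm - mc
    dn = nn - nc

    best_val, best_theta = -np.inf, 0.0
    for theta in np.linspace(0.0, np.pi, n_angles, endpoint=False):
        s = dn * np.cos(theta) - dm * np.sin(theta)
        side_b = s >= 0
        nb = int(side_b.sum())
        if nb == 0 or nb == len(s):
            continue
        ratio = x[side_b].mean() / max(x[~side_b].mean(), eps)
        if ratio > best_val:
            best_val, best_theta = ratio, float(theta)
    if not np.isfinite(best_val):
        return LightSearchResult(value=0.0, theta_max=0.0)
    return LightSearchResult(value=float(best_val), theta_max=best_theta)


# ---------------------------------------------------------------------------
# malleus

def malleus_presence(seg: SegmentedImage, config: PipelineConfig | None = None) -> int:
    """Detect a straight malleus ridge near the membrane's major axis.

    Pipeline: moment-based ellipse fit of the mask -> rotate so the major
    axis is horizontal -> mean-shift colour quantisation (fitted on a seeded
    pixel subsample) -> Canny edges -> straight-line Hough transform
    restricted to a +/-``malleus_band_halfwidth`` pixel band around the major
    axis and to near-horizontal orientations.  Returns 1 iff an accumulator
    peak reaches ``malleus_min_length_fraction`` of the major-axis length,
    i.e. enough collinear edge pixels to span a ridge.
    """
    cfg = config or PipelineConfig()
    props = regionprops(seg.mask.astype(np.uint8))
    if not props or props[0].axis_major_length < 2:
        warnings.warn("degenerate mask: ellipse fit failed", RuntimeWarning, stacklevel=2)
        return 0
    rp = props[0]
    major_len = rp.axis_major_length
    # orientation: angle between row axis and major axis; rotate so the
    # major axis lies along the columns
    angle_deg = 90.0 - np.degrees(rp.orientation)
    centroid_rc = rp.centroid
    center_xy = (centroid_rc[1], centroid_rc[0])
    rot_image = rotate(seg.image, angle_deg, center=center_xy, order=1)
    rot_mask = rotate(seg.mask.astype(float), angle_deg, center=center_xy, order=0) > 0.5
    if not rot_mask.any():
        return 0

    quantized = _mean_shift_quantize(
        rot_image, rot_mask, cfg.meanshift_bandwidth, cfg.meanshift_max_samples,
        cfg.seed,
    )
    edge_region = erosion(rot_mask, disk(3))
    edges = canny(
        to_gray(quantized),
        sigma=cfg.canny_sigma,
        low_threshold=cfg.canny_low,
        high_threshold=cfg.canny_high,
        mask=edge_region,
    )
    band = np.zeros_like(edges)
    row0 = int(round(centroid_rc[0]))
    lo = max(row0 - cfg.malleus_band_halfwidth, 0)
    hi = min(row0 + cfg.malleus_band_halfwidth + 1, edges.shape[0])
    band[lo:hi] = True
    edges &= band
    if not edges.any():
        return 0

    tol = np.deg2rad(cfg.malleus_angle_tol_deg)
    theta = np.concatenate(
        [
            np.linspace(-np.pi / 2, -np.pi / 2 + tol, 30),
            np.linspace(np.pi / 2 - tol, np.pi / 2, 30, endpoint=False),
        ]
    )
    accum, angles, dists = hough_line(edges, theta=theta)
    min_count = cfg.malleus_min_length_fraction * major_len
    peaks = hough_line_peaks(accum, angles, dists, threshold=min_count)
    return 1 if len(peaks[0]) > 0 else 0


def _mean_shift_quantize(
    image: np.ndarray,
    mask: np.ndarray,
    bandwidth: float,
    max_samples: int,
    seed: int,
) -> np.ndarray:
    """Mean-shift colour quantisation of the masked region (0-255 metric).

    Modes are found on a seeded subsample for speed; every masked pixel is
    replaced by its nearest mode.
    """
    pixels = image[mask] * 255.0
    rng = np.random.default_rng(seed)
    if len(pixels) > max_samples:
        idx = rng.choice(len(pixels), size=max_samples, replace=False)
        sample = pixels[idx]
    else:
        sample = pixels
    ms = MeanShift(bandwidth=bandwidth, bin_seeding=True)
    ms.fit(sample)
    centers = ms.cluster_centers_
    d2 = ((pixels[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    quantized = image.copy()
    quantized[mask] = centers[np.argmin(d2, axis=1)] / 255.0
    return quantized


# ---------------------------------------------------------------------------
# colour models: translucency and amber

@dataclass
class ColorClusterModel:
    """K cluster centres in RGB (0-255) describing a colour vocabulary term
    (translucent gray for NOE, amber for OME)."""

    centers: np.ndarray  # (K, 3), 0-255 scale
    label: str  # "translucent" or "amber"
    provenance: str = ""

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        if self.centers.ndim != 2 or self.centers.shape[1] != 3:
            raise ValueError("centers must be (K, 3)")
        if len(self.centers) < 1:
            raise ValueError("need at least one cluster centre")
        if self.centers.min() < 0 or self.centers.max() > 255:
            raise ValueError("centers must lie in [0, 255]^3")

    @property
    def n_clusters(self) -> int:
        return len(self.centers)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "centers": self.centers.tolist(),
                    "label": self.label,
                    "provenance": self.provenance,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ColorClusterModel":
        d = json.loads(Path(path).read_text())
        return cls(centers=np.array(d["centers"]), label=d["label"],
                   provenance=d.get("provenance", ""))


def train_color_model(
    pixel_samples: np.ndarray,
    n_clusters: int = 10,
    label: str = "translucent",
    seed: int = 0,
    provenance: str = "",
) -> ColorClusterModel:
    """k-means the training pixels (0-255 RGB) into ``n_clusters`` centres.

    With the study defaults the training set is 20 images x 100 pixels =
    2000 samples clustered into K = 10 centres.  Deterministic for a fixed
    seed.
    """
    samples = np.asarray(pixel_samples, dtype=float)
    if samples.ndim != 2 or samples.shape[1] != 3:
        raise ValueError("pixel_samples must be (N, 3) RGB")
    if len(samples) < n_clusters:
        raise ValueError(
            f"{len(samples)} samples cannot support {n_clusters} clusters; "
            "reduce n_clusters"
        )
    km = KMeans(n_clusters=n_clusters, random_state=seed, n_init=10)
    km.fit(samples)
    return ColorClusterModel(
        centers=np.clip(km.cluster_centers_, 0.0, 255.0),
        label=label,
        provenance=provenance,
    )


def color_fraction(
    seg: SegmentedImage, model: ColorClusterModel, threshold: float
) -> float:
    """Fraction of membrane pixels within ``threshold`` (strict, Euclidean
    RGB distance on the 0-255 scale) of any cluster centre.

    With the translucent model this is the translucency feature; with the
    amber model, the amber feature.
    """
    pixels = seg.image[seg.mask] * 255.0
    d2 = ((pixels[:, None, :] - model.centers[None, :, :]) ** 2).sum(axis=2)
    near = np.sqrt(d2.min(axis=1)) < threshold
    return float(near.sum()) / seg.mask_area


# ---------------------------------------------------------------------------
# bubbles and variance

def bubble_presence(seg: SegmentedImage, config: PipelineConfig | None = None) -> float:
    """Fraction of the membrane covered by closed air-fluid boundaries.

    Canny edges of the red and green channels are united, morphologically
    closed (bridging the parallel boundaries Canny places on either side of
    a real edge), hole-filled to recover the enclosed bubble interiors, and
    cleaned of components below ``bubble_min_area``.  Edge detection runs on
    a slightly eroded mask so the membrane's own outline does not count.
    """
    cfg = config or PipelineConfig()
    edge_region = erosion(seg.mask, disk(3))
    edges = np.zeros_like(seg.mask)
    for ch in (0, 1):  # red, green
        edges |= canny(
            seg.image[..., ch],
            sigma=cfg.canny_sigma,
            low_threshold=cfg.canny_low,
            high_threshold=cfg.canny_high,
            mask=edge_region,
        )
    closed = closing(edges, disk(cfg.bubble_close_radius))
    filled = binary_fill_holes(closed)
    cleaned = remove_small_objects(filled, max_size=cfg.bubble_min_area - 1)
    bubble_mask = cleaned & seg.mask
    return float(bubble_mask.sum()) / seg.mask_area


def grayscale_variance(seg: SegmentedImage) -> float:
    """Population variance of unit-interval gray intensities over the mask."""
    return float(np.var(seg.gray()[seg.mask]))


# ---------------------------------------------------------------------------
# full vector

def extract_features(
    seg: SegmentedImage,
    translucent_model: ColorClusterModel,
    amber_model: ColorClusterModel,
    config: PipelineConfig | None = None,
) -> FeatureVector:
    """Compute the full eight-term vocabulary for one segmented,
    highlight-corrected image.

    The concavity search centre is reused for the light feature.  Per-feature
    failures are re-raised with the feature name attached.
    """
    cfg = config or PipelineConfig()
    values: dict[str, float] = {}

    def _run(name, fn):
        try:
            values[name] = fn()
        except Exception as exc:
            raise RuntimeError(f"feature '{name}' failed: {exc}") from exc

    _run("bulging",
         lambda: bulging_feature(seg, cfg.depth_threshold, cfg.sfs_iterations, cfg))
    _run(
        "concavity",
        lambda: central_concavity(
            seg, cfg.concavity_radius, cfg.concavity_window,
            cfg.concavity_stride, cfg.polar_n_angles, cfg.epsilon,
        ),
    )
    conc: ConcavitySearchResult = values["concavity"]
    values["concavity"] = conc.value
    _run(
        "light",
        lambda: light_feature(
            seg, cfg.light_threshold, conc.center, cfg.light_n_angles, cfg.epsilon
        ).value,
    )
    _run("malleus", lambda: float(malleus_presence(seg, cfg)))
    _run("translucency", lambda: color_fraction(seg, translucent_model,
                                                cfg.translucency_threshold))
    _run("amber", lambda: color_fraction(seg, amber_model, cfg.amber_threshold))
    _run("bubbles", lambda: bubble_presence(seg, cfg))
    _run("variance", lambda: grayscale_variance(seg))
    return FeatureVector(**values)


class VocabularyExtractor(BaseEstimator, TransformerMixin):
    """sklearn-style transformer: segmented images -> (n, 8) feature matrix.

    Parameters
    ----------
    translucent_model, amber_model : ColorClusterModel
        Trained colour vocabularies for the translucency and amber terms.
    config : PipelineConfig, optional
        Every extractor constant; defaults to the study values.
    """

    def __init__(self, translucent_model=None, amber_model=None, config=None):
        self.translucent_model = translucent_model
        self.amber_model = amber_model
        self.config = config

    def fit(self, X=None, y=None):
        if self.translucent_model is None or self.amber_model is None:
            raise ValueError(
                "both colour models are required; train them with "
                "train_color_model"
            )
        return self

    def transform(self, X: list[SegmentedImage]) -> np.ndarray:
        self.fit()
        return np.vstack(
            [
                extract_features(
                    seg, self.translucent_model, self.amber_model, self.config
                ).as_array()
                for seg in X
            ]
        )
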