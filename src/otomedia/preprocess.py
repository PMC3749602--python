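"""Membrane localisation, specular-highlight correction and quality gating.

The tympanic membrane is segmented with a morphological geodesic active
contour grown from a circle at the image centre; saturated specular
reflections of the otoscope light are detected by intensity thresholding
inside the membrane and repaired by a harmonic (Laplace) fill matched to each
component's boundary; images whose largest highlight component covers more
than ``reject_fraction`` of the membrane are rejected so the clinician can
retake them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse
import scipy.sparse.linalg
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import convex_hull_image
from skimage.segmentation import (
    disk_level_set,
    inverse_gaussian_gradient,
    morphological_geodesic_active_contour,
)

from .core import PipelineConfig, SegmentedImage, to_gray

__all__ = [
    "HighlightReport",
    "SegmentationError",
    "segment_membrane",
    "detect_specular",
    "correct_specular",
    "should_reject",
]


class SegmentationError(RuntimeError):
    """Raised when the active contour collapses to (almost) nothing."""


@dataclass
class HighlightReport:
    """Connected-component summary of specular highlights inside the mask.

    ``largest_fraction`` is the area of the largest 8-connected highlight
    component divided by the membrane-mask area; it is the quantity the
    rejection rule thresholds ("continuous white pixels").
    """

    highlight_mask: np.ndarray
    components: list[tuple[int, int, tuple[int, int, int, int]]]  # (id, area, bbox)
    largest_fraction: float


def segment_membrane(
    image: np.ndarray,
    config: PipelineConfig | None = None,
    source_id: str = "",
) -> SegmentedImage:
    """Locate the membrane with a geodesic active contour grown from a
    central circle.

    The contour is initialised as a circle of radius
    ``seg_init_radius_fraction * min(H, W)`` at the image centre and evolved
    on an inverted-gradient edge map with an outward balloon force; evolution
    stops when the mask area changes by less than ``seg_convergence_tol``
    (relative) across a window of iterations, or at ``seg_max_iterations``
    (then the best mask so far is returned and ``meta["converged"]`` is
    False).  Deterministic for fixed parameters.

    Raises :class:`SegmentationError` if the final mask covers less than 1%
    of the image.
    """
    cfg = config or PipelineConfig()
    image = np.asarray(image, dtype=float)
    H, W = image.shape[:2]
    if H < 64 or W < 64:
        raise ValueError(f"image must be at least 64x64, got {H}x{W}")
    gray = to_gray(image)
    edge_map = inverse_gaussian_gradient(
        gray, alpha=cfg.seg_edge_alpha, sigma=cfg.seg_edge_sigma
    )
    radius = cfg.seg_init_radius_fraction * min(H, W)
    level_set = disk_level_set(gray.shape, radius=radius)

    converged = False
    iters_done = 0
    prev_area = int(level_set.sum())
    while iters_done < cfg.seg_max_iterations:
        step = min(cfg.seg_convergence_window, cfg.seg_max_iterations - iters_done)
        level_set = morphological_geodesic_active_contour(
            edge_map,
            num_iter=step,
            init_level_set=level_set,
            smoothing=cfg.seg_smoothing,
            balloon=cfg.seg_balloon,
        )
        iters_done += step
        area = int(level_set.sum())
        if abs(area - prev_area) <= cfg.seg_convergence_tol * max(prev_area, 1):
            converged = True
            break
        prev_area = area

    mask = level_set.astype(bool)
    if mask.any():
        # the membrane is convex in projection; the hull bridges bites the
        # contour takes where it pins on internal edges (e.g. a bulge rim)
        mask = convex_hull_image(mask)
    if mask.sum() < 0.01 * H * W:
        raise SegmentationError(
            f"segmentation collapsed: mask covers {mask.sum()} of {H * W} pixels"
        )
    if not converged:
        warnings.warn(
            "active contour did not converge within "
            f"{cfg.seg_max_iterations} iterations; returning last mask",
            RuntimeWarning,
            stacklevel=2,
        )
    return SegmentedImage(
        image=image,
        mask=mask,
        source_id=source_id,
        meta={"converged": converged, "iterations": iters_done},
    )


def detect_specular(
    seg: SegmentedImage, specular_threshold: float = 0.90
) -> HighlightReport:
    """Threshold gray intensity inside the membrane to find highlights.

    Highlight pixels are membrane pixels with gray intensity strictly above
    ``specular_threshold`` (unit scale); components use 8-connectivity.
    """
    gray = seg.gray()
    highlight = (gray > specular_threshold) & seg.mask
    labelled = cc_label(highlight, connectivity=2)
    components = []
    largest = 0
    for rp in regionprops(labelled):
        components.append((int(rp.label), int(rp.area), tuple(int(v) for v in rp.bbox)))
        largest = max(largest, int(rp.area))
    return HighlightReport(
        highlight_mask=highlight,
        components=components,
        largest_fraction=largest / seg.mask_area,
    )


def should_reject(report: HighlightReport, reject_fraction: float = 0.15) -> bool:
    """True iff the largest continuous highlight covers strictly more than
    ``reject_fraction`` of the membrane (such fills are unreliable)."""
    return report.largest_fraction > reject_fraction


def _harmonic_fill_component(channel: np.ndarray, comp: np.ndarray) -> bool:
    """Replace ``channel[comp]`` by the discrete harmonic interpolant of its
    4-neighbour boundary values, in place.

    Interior pixels satisfy the 5-point Laplace equation; neighbours outside
    the image frame reduce the stencil degree (discrete Neumann at the
    frame).  Returns False (leaving the component untouched) if it has no
    boundary values at all.
    """
    H, W = channel.shape
    coords = np.argwhere(comp)
    index = -np.ones((H, W), dtype=int)
    index[comp] = np.arange(len(coords))

    rows, cols, data = [], [], []
    b = np.zeros(len(coords))
    degree = np.zeros(len(coords))
    any_boundary = False
    for i, (m, n) in enumerate(coords):
        for dm, dn in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            mm, nn = m + dm, n + dn
            if not (0 <= mm < H and 0 <= nn < W):
                continue
            degree[i] += 1
            j = index[mm, nn]
            if j >= 0:
                rows.append(i)
                cols.append(j)
                data.append(-1.0)
            else:
                b[i] += channel[mm, nn]
                any_boundary = True
    if not any_boundary:
        return False
    rows.extend(range(len(coords)))
    cols.extend(range(len(coords)))
    data.extend(np.maximum(degree, 1.0))
    A = scipy.sparse.csr_matrix((data, (rows, cols)), shape=(len(coords),) * 2)
    x = scipy.sparse.linalg.spsolve(A.tocsc(), b)
    channel[comp] = x
    return True


def correct_specular(seg: SegmentedImage, report: HighlightReport) -> SegmentedImage:
    """Repair highlight regions by harmonic interpolation of their boundary.

    Gradient-domain editing with a zero guidance field: inside each highlight
    component every channel is replaced by the membrane (Laplace) interpolant
    of the component's boundary values; pixels outside the highlight mask are
    untouched bit-exact and the result is clamped to [0, 1].  Components with
    no valid boundary pixels are left uncorrected with a warning.

    Callers must gate with :func:`should_reject` first: fills covering a
    large membrane fraction are unreliable by construction.
    """
    corrected = seg.image.copy()
    labelled = cc_label(report.highlight_mask, connectivity=2)
    uncorrected = []
    for comp_id in range(1, labelled.max() + 1):
        comp = labelled == comp_id
        ok = True
        for ch in range(3):
            channel = corrected[..., ch]
            ok = _harmonic_fill_component(channel, comp) and ok
        if not ok:
            uncorrected.append(comp_id)
    if uncorrected:
        warnings.warn(
            f"highlight components {uncorrected} had no boundary values; "
            "left uncorrected",
            RuntimeWarning,
            stacklevel=2,
        )
    np.clip(corrected, 0.0, 1.0, out=corrected)
    # bit-exact outside the highlight mask
    corrected[~report.highlight_mask] = seg.image[~report.highlight_mask]
    meta = dict(seg.meta)
    meta["specular_corrected_components"] = len(report.components) - len(uncorrected)
    return SegmentedImage(
        image=corrected, mask=seg.mask, source_id=seg.source_id, meta=meta
    )
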