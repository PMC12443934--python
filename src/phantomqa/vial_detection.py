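"""Automated vial ROI identification.

Mirrors the acquisition-analysis recipe: threshold the magnitude image so
the vial edges become visible, then find a representative circle for each
vial edge.  The representative circle is the wall-annulus mid-circle.

Pipeline: intensity threshold (Otsu or fixed) -> region mask -> boundary
pixels -> circular Hough accumulation over the admissible radius range ->
least-squares (Kasa) refinement on nearby boundary pixels -> non-maximum
suppression and principal-axis ordering.  Every stage is deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import sobel, threshold_otsu
from skimage.transform import hough_circle, hough_circle_peaks

from .errors import (
    DetectionShortfallError,
    NoContrastError,
    ValidationError,
)
from .mr_simulator import SliceImage

__all__ = ["DetectionParams", "VialROI", "threshold_edges", "detect_vials", "order_vials"]


@dataclass(frozen=True)
class DetectionParams:
    """Free parameters of the detection procedure."""

    threshold_method: str = "otsu"  # otsu | fixed
    fixed_threshold: float = 0.0
    radius_range: tuple = (5.0, 12.0)  # mm, brackets both tube classes
    expected_count: int | None = None
    min_separation: float = 15.0  # mm
    fit_method: str = "hough"  # hough | lsq_boundary
    score_floor: float = 0.5  # minimum angular coverage of a fitted ring

    def __post_init__(self):
        if not self.radius_range[0] < self.radius_range[1]:
            raise ValidationError("radius_range min must be < max")
        if not self.min_separation > 0:
            raise ValidationError("min_separation must be > 0")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValidationError(f"unknown threshold_method {self.threshold_method!r}")
        if self.fit_method not in ("hough", "lsq_boundary"):
            raise ValidationError(f"unknown fit_method {self.fit_method!r}")


@dataclass
class VialROI:
    """One detected circular vial cross-section."""

    center_xy: tuple  # (col, row) fractional pixels
    center_world: tuple  # (u, v) mm
    radius: float  # mm
    fit_score: float
    label: int = 0

    def __post_init__(self):
        self.fit_score = float(min(1.0, max(0.0, self.fit_score)))


def threshold_edges(image: SliceImage, params: DetectionParams | None = None) -> np.ndarray:
    """Binary foreground mask in which vial-wall annuli show as holes.

    Uses Otsu's threshold by default, or ``params.fixed_threshold`` with
    ``threshold_method="fixed"``.  Raises :class:`NoContrastError` for a
    constant image under Otsu.
    """
    params = params or DetectionParams()
    px = image.pixels
    if px.size == 0:
        raise ValidationError("empty image")
    if params.threshold_method == "otsu":
        if float(px.max()) == float(px.min()):
            raise NoContrastError("no contrast: image is constant")
        thr = threshold_otsu(px)
    else:
        thr = params.fixed_threshold
    return px > thr


def _boundary(mask: np.ndarray) -> np.ndarray:
    """Pixels within one pixel of a foreground/background transition.

    Two-sided (covers both sides of each edge), so circle fits straddle the
    true edge symmetrically.  The image border is treated as foreground: an
    all-true mask has an empty boundary and yields zero circle candidates
    downstream.
    """
    st = np.ones((3, 3), bool)
    dilated = ndi.binary_dilation(mask, structure=st, border_value=0)
    eroded = ndi.binary_erosion(mask, structure=st, border_value=1)
    return dilated & ~eroded


def _kasa_fit(cols: np.ndarray, rows: np.ndarray):
    """Algebraic least-squares circle fit. Returns (cx, cy, r, rms)."""
    a = np.column_stack([cols, rows, np.ones_like(cols, dtype=float)])
    b = cols**2 + rows**2
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    cx, cy = sol[0] / 2.0, sol[1] / 2.0
    r2 = sol[2] + cx**2 + cy**2
    if r2 <= 0:
        return cx, cy, 0.0, np.inf
    r = math.sqrt(r2)
    rms = float(np.sqrt(np.mean((np.hypot(cols - cx, rows - cy) - r) ** 2)))
    return cx, cy, r, rms


def _weighted_kasa_fit(cols, rows, weights):
    """Gradient-weighted algebraic circle fit for sub-pixel localization."""
    sw = np.sqrt(weights)
    a = np.column_stack([cols, rows, np.ones_like(cols, dtype=float)]) * sw[:, None]
    b = (cols**2 + rows**2) * sw
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    cx, cy = sol[0] / 2.0, sol[1] / 2.0
    r2 = sol[2] + cx**2 + cy**2
    if r2 <= 0:
        return cx, cy, 0.0, np.inf
    r = math.sqrt(r2)
    resid = np.hypot(cols - cx, rows - cy) - r
    rms = float(np.sqrt(np.average(resid**2, weights=weights)))
    return cx, cy, r, rms


def _refine(grad_cols, grad_rows, grad_w, cx, cy, r, window):
    """Iterative reselection + gradient-weighted fit around a seed circle.

    Weighting by the Sobel gradient magnitude of the (anti-aliased) image
    recovers the sub-pixel edge position that a binarized boundary mask
    quantizes away.
    """
    rms = np.inf
    for _ in range(3):
        d = np.hypot(grad_cols - cx, grad_rows - cy)
        sel = np.abs(d - r) <= window
        if sel.sum() < 6:
            return cx, cy, r, np.inf
        cx, cy, r, rms = _weighted_kasa_fit(grad_cols[sel], grad_rows[sel], grad_w[sel])
    return cx, cy, r, rms


def _coverage(grad_cols, grad_rows, cx, cy, r, tol=1.5, bins=16):
    """Fraction of angular sectors with edge support on the fitted ring.

    A full vial ring scores ~1; stray arcs (noise, container corners) score
    low.  Used as the ROI fit_score and as the candidate acceptance test.
    """
    d = np.hypot(grad_cols - cx, grad_rows - cy)
    sel = np.abs(d - r) <= tol
    if not np.any(sel):
        return 0.0
    ang = np.arctan2(grad_rows[sel] - cy, grad_cols[sel] - cx)
    occupied = np.unique((ang // (2 * np.pi / bins)).astype(int))
    return float(len(occupied)) / bins


def _exclude_container_outline(edges, mask, rmax_px):
    """Drop the exterior outline of the phantom body from the edge mask.

    Vial walls are interior holes of the thresholded foreground; the
    container silhouette (and its corners, which mimic arcs) is the exterior
    boundary of the dominant component.  Only components much larger than
    the admissible circle area are treated as container.
    """
    filled = ndi.binary_fill_holes(mask)
    labels, n = ndi.label(filled)
    if n == 0:
        return edges
    sizes = ndi.sum_labels(filled, labels, index=np.arange(1, n + 1))
    out = edges
    for i, size in enumerate(sizes, start=1):
        if size > 4.0 * math.pi * rmax_px**2:
            outline = _boundary(labels == i)
            outline = ndi.binary_dilation(outline, structure=np.ones((3, 3), bool))
            out = out & ~outline
    return out


def _suppress(candidates, min_sep_px):
    """Greedy non-maximum suppression by fit score."""
    kept = []
    for cand in sorted(candidates, key=lambda c: -c[0]):
        if all(math.hypot(cand[1] - k[1], cand[2] - k[2]) >= min_sep_px for k in kept):
            kept.append(cand)
    return kept


def detect_vials(image: SliceImage, params: DetectionParams | None = None) -> list:
    """Detect vial cross-sections and return ordered :class:`VialROI` list.

    If ``params.expected_count`` is set, the highest-scoring candidates
    respecting ``min_separation`` are kept and a
    :class:`DetectionShortfallError` is raised when fewer are found.
    """
    params = params or DetectionParams()
    mask = threshold_edges(image, params)
    edges = _boundary(mask)

    su, sv = image.spacing_xy
    spacing = 0.5 * (su + sv)
    rmin_px = params.radius_range[0] / spacing
    rmax_px = params.radius_range[1] / spacing
    min_sep_px = params.min_separation / spacing
    edges = _exclude_container_outline(edges, mask, rmax_px)

    candidates = []  # (score, cx, cy, r) in pixels
    if edges.any() and rmax_px >= 1.5:
        # Gradient support for sub-pixel refinement: keep pixels in a band
        # around the binary boundary, weighted by Sobel magnitude.
        grad = sobel(image.pixels)
        band = ndi.binary_dilation(edges, structure=np.ones((3, 3), bool))
        gr, gc = np.nonzero(band & (grad > 0))
        grad_rows = gr.astype(float)
        grad_cols = gc.astype(float)
        grad_w = grad[gr, gc]
        window = max(2.5, 0.25 * (rmax_px - rmin_px))
        seeds = []  # (score, cx, cy, r) coarse candidates
        if params.fit_method == "hough":
            radii = np.arange(max(2, int(math.floor(rmin_px))),
                              int(math.ceil(rmax_px)) + 1)
            accum = hough_circle(edges, radii)
            n_peaks = 3 * (params.expected_count or 8)
            scores, cxs, cys, rads = hough_circle_peaks(
                accum, radii,
                min_xdistance=max(1, int(min_sep_px)),
                min_ydistance=max(1, int(min_sep_px)),
                total_num_peaks=n_peaks,
            )
            for s, cx, cy, r in zip(scores, cxs, cys, rads):
                seeds.append((float(min(1.0, s)), float(cx), float(cy), float(r)))
        else:  # lsq_boundary: seed from each connected boundary component
            labels, n_comp = ndi.label(edges, structure=np.ones((3, 3), int))
            for comp in range(1, n_comp + 1):
                rr, cc = np.nonzero(labels == comp)
                if rr.size < 8:
                    continue
                cx, cy, r, rms = _kasa_fit(cc.astype(float), rr.astype(float))
                if not np.isfinite(rms) or not (rmin_px * 0.5 <= r <= rmax_px * 1.5):
                    continue
                seeds.append((float(math.exp(-rms)), cx, cy, r))

        for _, cx, cy, r in seeds:
            cx, cy, r, rms = _refine(grad_cols, grad_rows, grad_w, cx, cy, r, window)
            if not (rmin_px <= r <= rmax_px) or not np.isfinite(rms):
                continue
            score = _coverage(grad_cols, grad_rows, cx, cy, r)
            if score >= params.score_floor:
                candidates.append((score, cx, cy, r))

    kept = _suppress(candidates, min_sep_px)
    if params.expected_count is not None:
        if len(kept) < params.expected_count:
            raise DetectionShortfallError(len(kept), params.expected_count)
        kept = kept[: params.expected_count]

    # Second refinement pass: partition gradient pixels by the nearest kept
    # ring so closely spaced vials cannot contaminate each other's fit.
    if len(kept) > 1:
        ring_dist = np.stack([
            np.abs(np.hypot(grad_cols - cx, grad_rows - cy) - r)
            for _, cx, cy, r in kept
        ])
        owner = np.argmin(ring_dist, axis=0)
        refined = []
        for i, (s, cx, cy, r) in enumerate(kept):
            mine = owner == i
            cx2, cy2, r2, rms = _refine(grad_cols[mine], grad_rows[mine],
                                        grad_w[mine], cx, cy, r, window)
            if np.isfinite(rms) and rmin_px <= r2 <= rmax_px:
                refined.append((s, cx2, cy2, r2))
            else:
                refined.append((s, cx, cy, r))
        kept = refined

    rois = []
    for score, cx, cy, r in kept:
        world = image.px_to_world((cx, cy))
        rois.append(
            VialROI(
                center_xy=(cx, cy),
                center_world=(float(world[0]), float(world[1])),
                radius=r * spacing,
                fit_score=score,
            )
        )
    return order_vials(rois)


def order_vials(rois: list) -> list:
    """Order ROIs along the principal axis of their centers.

    The principal axis is the dominant eigenvector of the center covariance;
    ROIs are sorted by their projection onto it (sign fixed so the axis
    points toward positive coordinates), with ties broken by the orthogonal
    coordinate and then by radius descending.  Labels are assigned 1..n.
    """
    if not rois:
        return []
    if len(rois) == 1:
        rois[0].label = 1
        return list(rois)
    pts = np.array([r.center_world for r in rois], dtype=float)
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered
    w, vecs = np.linalg.eigh(cov)
    axis = vecs[:, int(np.argmax(w))]
    if axis[int(np.argmax(np.abs(axis)))] < 0:
        axis = -axis
    orth = np.array([-axis[1], axis[0]])
    if orth[int(np.argmax(np.abs(orth)))] < 0:
        orth = -orth
    keys = [
        (float(p @ axis), float(p @ orth), -r.radius)
        for p, r in zip(centered, rois)
    ]
    ordered = [roi for _, roi in sorted(zip(keys, rois), key=lambda t: t[0])]
    for i, roi in enumerate(ordered):
        roi.label = i + 1
    return ordered
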