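"""Image-quality measurands: inter-vial distances, SNR and CNR.

Geometric distortion along one dimension is quantified by the Euclidean
distances between consecutive ordered vial centers and their average; two
scans acquired without moving the phantom are compared via the absolute
difference of their average distances, flagged when within one pixel
spacing.

SNR is the mean of a 5x5 signal region divided by the sample standard
deviation (ddof=1) of the pixels pooled from the 10x10 background-noise
regions; CNR subtracts the pooled noise mean from the signal mean first.
No Rician bias correction is applied to the reported SNR; a corrected
estimate (noise std divided by sqrt(2 - pi/2), the Rayleigh std factor) is
logged alongside for information.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .errors import (
    InsufficientDataError,
    PlacementError,
    UndefinedSNRError,
    ValidationError,
)
from .mr_simulator import SliceImage

__all__ = [
    "RegionSpec",
    "QAReport",
    "ScanComparison",
    "inter_vial_distances",
    "average_distance",
    "compare_scans",
    "compute_snr",
    "compute_cnr",
    "rician_corrected_snr",
    "auto_place_regions",
    "analyze_image",
]

#: std(Rayleigh(sigma)) = sigma * sqrt(2 - pi/2)
_RAYLEIGH_STD_FACTOR = math.sqrt(2.0 - math.pi / 2.0)


@dataclass(frozen=True)
class RegionSpec:
    """Rectangular pixel region used for SNR/CNR statistics."""

    kind: str  # noise | signal
    top_left: tuple  # (row, col)
    size: tuple = None  # (rows, cols); defaults 10x10 noise, 5x5 signal
    placement: str = "manual"  # manual | auto

    def __post_init__(self):
        if self.kind not in ("noise", "signal"):
            raise ValidationError(f"unknown region kind {self.kind!r}")
        if self.size is None:
            object.__setattr__(self, "size", (10, 10) if self.kind == "noise" else (5, 5))
        if any(s < 1 for s in self.size):
            raise ValidationError("region size must be at least 1x1")

    def pixels(self, image: SliceImage) -> np.ndarray:
        r0, c0 = self.top_left
        h, w = self.size
        ny, nx = image.shape
        if r0 < 0 or c0 < 0 or r0 + h > ny or c0 + w > nx:
            raise ValidationError(
                f"{self.kind} region {self.top_left}+{self.size} exceeds image {image.shape}"
            )
        return image.pixels[r0:r0 + h, c0:c0 + w]

    def to_dict(self):
        return {"kind": self.kind, "top_left": list(self.top_left),
                "size": list(self.size), "placement": self.placement}

    @classmethod
    def from_dict(cls, d):
        return cls(kind=d["kind"], top_left=tuple(d["top_left"]),
                   size=tuple(d["size"]), placement=d.get("placement", "manual"))


@dataclass
class QAReport:
    """Distances, SNR/CNR and provenance for one analyzed image."""

    distances: list
    average_distance: float
    snr: float
    cnr: float
    regions: list
    pixel_spacing: float
    snr_rician_corrected: float | None = None
    noise_region_stats: list = field(default_factory=list)
    within_pixel: bool | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.distances and any(d < 0 for d in self.distances):
            raise ValidationError("distances must be non-negative")
        if self.snr < 0:
            raise ValidationError("snr must be >= 0")
        mean = sum(self.distances) / len(self.distances) if self.distances else None
        if mean is not None and abs(mean - self.average_distance) > 1e-9:
            raise ValidationError("average_distance must equal the mean of distances")

    def to_dict(self):
        return {
            "schema": "phantomqa-report/1",
            "distances_mm": list(self.distances),
            "average_distance_mm": self.average_distance,
            "snr": self.snr,
            "cnr": self.cnr,
            "snr_rician_corrected": self.snr_rician_corrected,
            "regions": [r.to_dict() for r in self.regions],
            "noise_region_stats": self.noise_region_stats,
            "pixel_spacing_mm": self.pixel_spacing,
            "within_pixel": self.within_pixel,
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d):
        if d.get("schema") != "phantomqa-report/1":
            raise ValidationError(f"unknown report schema {d.get('schema')!r}")
        return cls(
            distances=list(d["distances_mm"]),
            average_distance=d["average_distance_mm"],
            snr=d["snr"],
            cnr=d["cnr"],
            snr_rician_corrected=d.get("snr_rician_corrected"),
            regions=[RegionSpec.from_dict(r) for r in d.get("regions", [])],
            noise_region_stats=d.get("noise_region_stats", []),
            pixel_spacing=d["pixel_spacing_mm"],
            within_pixel=d.get("within_pixel"),
            provenance=d.get("provenance", {}),
        )


@dataclass(frozen=True)
class ScanComparison:
    """Result of comparing two scans' average inter-vial distances."""

    difference: float  # mm
    relative_percent: float
    within_pixel: bool


def inter_vial_distances(rois, spacing: float | None = None) -> list:
    """Euclidean distances (mm) between consecutive ordered ROI centers.

    ``spacing`` is only needed when ROIs lack world coordinates, in which
    case pixel centers are scaled by it.
    """
    if len(rois) < 2:
        raise InsufficientDataError("need at least 2 ROIs for inter-vial distances")
    centers = []
    for r in rois:
        if getattr(r, "center_world", None) is not None:
            centers.append(np.asarray(r.center_world, dtype=float))
        elif spacing is not None:
            centers.append(np.asarray(r.center_xy, dtype=float) * spacing)
        else:
            raise ValidationError("ROI has no world center and no spacing was given")
    return [float(np.linalg.norm(b - a)) for a, b in zip(centers, centers[1:])]


def average_distance(distances) -> float:
    """Arithmetic mean of the inter-vial distances."""
    distances = list(distances)
    if not distances:
        raise InsufficientDataError("no distances to average")
    return float(sum(distances) / len(distances))


def compare_scans(report_a: QAReport, report_b: QAReport) -> ScanComparison:
    """Compare average inter-vial distances of two same-placement scans.

    Returns the absolute difference (mm), the relative difference as a
    percentage of the two averages' mean, and whether the difference is
    within the smaller of the two pixel spacings.
    """
    da, db = report_a.average_distance, report_b.average_distance
    diff = abs(da - db)
    mean = 0.5 * (da + db)
    rel = 100.0 * diff / mean if mean > 0 else 0.0
    within = diff <= min(report_a.pixel_spacing, report_b.pixel_spacing)
    return ScanComparison(difference=diff, relative_percent=rel, within_pixel=within)


def _pooled_noise(image, noise_regions):
    if not noise_regions:
        raise ValidationError("need at least one noise region")
    chunks = [spec.pixels(image).ravel() for spec in noise_regions]
    pooled = np.concatenate(chunks)
    if pooled.size < 2:
        raise ValidationError("noise regions too small")
    return pooled


def compute_snr(image: SliceImage, signal: RegionSpec, noise: list) -> float:
    """Mean of the signal region over the pooled noise standard deviation."""
    if signal.kind != "signal":
        raise ValidationError("signal argument must be a signal region")
    pooled = _pooled_noise(image, noise)
    std = float(np.std(pooled, ddof=1))
    if std == 0.0:
        raise UndefinedSNRError("noise standard deviation is zero; SNR undefined")
    return float(np.mean(signal.pixels(image))) / std


def compute_cnr(image: SliceImage, signal: RegionSpec, noise: list) -> float:
    """(signal mean - pooled noise mean) over the pooled noise std."""
    if signal.kind != "signal":
        raise ValidationError("signal argument must be a signal region")
    pooled = _pooled_noise(image, noise)
    std = float(np.std(pooled, ddof=1))
    if std == 0.0:
        raise UndefinedSNRError("noise standard deviation is zero; CNR undefined")
    return (float(np.mean(signal.pixels(image))) - float(np.mean(pooled))) / std


def rician_corrected_snr(image: SliceImage, signal: RegionSpec, noise: list) -> float:
    """SNR with the background std rescaled from Rayleigh to Gaussian sigma."""
    return compute_snr(image, signal, noise) * _RAYLEIGH_STD_FACTOR


def _foreground(image: SliceImage) -> np.ndarray:
    px = image.pixels
    if float(px.max()) == float(px.min()):
        return np.ones(px.shape, bool)
    from skimage.filters import threshold_otsu  # noqa: PLC0415

    return ndi.binary_fill_holes(px > threshold_otsu(px))


def auto_place_regions(image: SliceImage, rois: list, mode: str = "t2w"):
    """Reconstruct the published region-placement recipe.

    ``t1w``: 5x5 signal region centered on the ROI with the highest interior
    mean (the oil vial under default materials).  ``t2w``: 5x5 region in the
    background water fill near the phantom-interior centroid, excluding all
    ROI disks dilated by 2 pixels.  Noise: two 10x10 regions in opposite
    image corners inset by a 3 pixel margin, slid along the border until
    disjoint from the foreground.

    Returns ``(signal_region, [noise_region, noise_region])``.
    """
    if mode not in ("t1w", "t2w"):
        raise ValidationError(f"unknown mode {mode!r}")
    ny, nx = image.shape
    fg = _foreground(image)

    if mode == "t1w":
        if not rois:
            raise ValidationError("t1w placement needs at least one ROI")
        best, best_mean = None, -np.inf
        yy, xx = np.mgrid[0:ny, 0:nx]
        for roi in rois:
            cx, cy = roi.center_xy
            r_px = 0.6 * roi.radius / (0.5 * sum(image.spacing_xy))
            disk = (xx - cx) ** 2 + (yy - cy) ** 2 <= r_px**2
            if disk.sum() == 0:
                continue
            m = float(image.pixels[disk].mean())
            if m > best_mean:
                best, best_mean = roi, m
        row = int(round(best.center_xy[1])) - 2
        col = int(round(best.center_xy[0])) - 2
        signal = RegionSpec("signal", (row, col), (5, 5), placement="auto")
    else:
        allowed = fg.copy()
        yy, xx = np.mgrid[0:ny, 0:nx]
        spacing = 0.5 * sum(image.spacing_xy)
        for roi in rois:
            cx, cy = roi.center_xy
            r_px = roi.radius / spacing + 2.0
            allowed &= (xx - cx) ** 2 + (yy - cy) ** 2 > r_px**2
        # Keep room for the full 5x5 box.
        allowed = ndi.binary_erosion(allowed, structure=np.ones((7, 7), bool))
        if not allowed.any():
            raise PlacementError("no interior pixel available for the signal region")
        com = ndi.center_of_mass(fg)
        d2 = (yy - com[0]) ** 2 + (xx - com[1]) ** 2
        d2[~allowed] = np.inf
        row, col = np.unravel_index(int(np.argmin(d2)), d2.shape)
        signal = RegionSpec("signal", (int(row) - 2, int(col) - 2), (5, 5), placement="auto")
    signal.pixels(image)  # bounds check

    noise = _place_noise_regions(image, fg)
    return signal, noise


def _place_noise_regions(image: SliceImage, fg: np.ndarray):
    ny, nx = image.shape
    margin, size = 3, 10
    blocked = ndi.binary_dilation(fg, structure=np.ones((3, 3), bool), iterations=2)

    def free(r0, c0):
        if r0 < 0 or c0 < 0 or r0 + size > ny or c0 + size > nx:
            return False
        return not blocked[r0:r0 + size, c0:c0 + size].any()

    corners = [
        (margin, margin), (ny - margin - size, nx - margin - size),
        (margin, nx - margin - size), (ny - margin - size, margin),
    ]
    placed = []
    for i, (r0, c0) in enumerate(corners):
        # Slide along the border (horizontally) until disjoint from foreground.
        step = 2
        found = None
        for shift in range(0, nx, step):
            for sgn in (1, -1):
                c = c0 + sgn * shift
                if free(r0, c):
                    found = (r0, c)
                    break
            if found:
                break
        if found:
            placed.append(RegionSpec("noise", found, (size, size), placement="auto"))
        if len(placed) == 2:
            break
    if len(placed) < 2:
        raise PlacementError(
            "could not place two noise regions disjoint from the foreground; "
            "supply manual regions"
        )
    return placed


def analyze_image(
    image: SliceImage,
    rois: list,
    mode: str = "t2w",
    regions=None,
) -> QAReport:
    """Compose distances + SNR/CNR into a :class:`QAReport`."""
    distances = inter_vial_distances(rois)
    avg = average_distance(distances)
    if regions is None:
        signal, noise = auto_place_regions(image, rois, mode=mode)
    else:
        signal = next(r for r in regions if r.kind == "signal")
        noise = [r for r in regions if r.kind == "noise"]
    snr = compute_snr(image, signal, noise)
    cnr = compute_cnr(image, signal, noise)
    per_region = [
        {
            "top_left": list(spec.top_left),
            "mean": float(np.mean(spec.pixels(image))),
            "std": float(np.std(spec.pixels(image), ddof=1)),
        }
        for spec in noise
    ]
    return QAReport(
        distances=distances,
        average_distance=avg,
        snr=snr,
        cnr=cnr,
        snr_rician_corrected=snr * _RAYLEIGH_STD_FACTOR,
        regions=[signal, *noise],
        noise_region_stats=per_region,
        pixel_spacing=float(min(image.spacing_xy)),
        provenance={
            "image_hash": image.content_hash(),
            "mode": mode,
            "n_rois": len(rois),
            "roi_centers_px": [list(r.center_xy) for r in rois],
        },
    )
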