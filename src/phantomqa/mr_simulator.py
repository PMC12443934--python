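"""Synthetic 2D magnitude-slice renderer for the digital phantom.

Renders noise-free and noisy coronal/axial/sagittal slices under the two
acquisition presets used on the 64 mT scanner: a T1-weighted inversion-
recovery spin-echo (TR 1.5 s, TI 0.3 s, TE 0.006 s, 24 averages, 1.6 mm
in-plane) and a T2-weighted (fast) spin-echo modeled with an effective echo
time (TR 2 s, TE 0.231/0.203 s, 80 averages, 1.5 mm in-plane).

Signal model (standard closed forms; echo-train, B1 and slice-profile
effects are deliberately ignored):

* IR-SE:  ``pd * |1 - 2 exp(-TI/T1) + exp(-TR/T1)| * exp(-TE/T2)``
* SE:     ``pd * (1 - exp(-TR/T1)) * exp(-TE/T2)``

Intensities are arbitrary units scaled so that a fully recovered ``pd = 1``
signal equals :data:`SIGNAL_SCALE`.  Signal averaging enters only through the
effective noise scale ``sigma / sqrt(averages)``.

Image/pixel conventions: ``pixels[row, col]`` with columns along the
in-plane u axis and rows along v; 0-based indices, pixel-center convention;
``world = origin_world + index * spacing``.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .digital_phantom import (
    MaterialSample,
    PhantomGeometry,
    geometry_to_config,
    ground_truth_centers,
)
from .errors import ConfigurationError, UsageError, ValidationError

__all__ = [
    "SequenceParams",
    "NoiseModel",
    "DistortionField",
    "SliceImage",
    "RenderedVial",
    "SEQUENCE_PRESETS",
    "SIGNAL_SCALE",
    "grid_shape",
    "ir_se_signal",
    "se_signal",
    "render_slice",
    "add_noise",
]

#: Intensity of a fully recovered, non-decayed pd=1 signal (arbitrary units).
SIGNAL_SCALE = 1000.0


@dataclass(frozen=True)
class SequenceParams:
    """Acquisition parameters for one scan."""

    family: str  # "ir_se" or "se"
    tr: float
    te: float
    ti: float = 0.0
    averages: int = 1
    fov_xy: tuple = (180.0, 180.0)
    resolution_xy: tuple = (1.5, 1.5)
    slice_thickness: float = 5.0
    plane: str = "coronal"

    def __post_init__(self):
        if self.family not in ("ir_se", "se"):
            raise ValidationError(f"unknown sequence family {self.family!r}")
        if not self.tr > self.te >= 0:
            raise ValidationError("need tr > te >= 0")
        if self.family == "ir_se" and not 0 < self.ti < self.tr:
            raise ValidationError("ir_se needs 0 < ti < tr")
        if self.averages < 1:
            raise ValidationError("averages must be >= 1")
        if any(f <= 0 for f in self.fov_xy) or any(r <= 0 for r in self.resolution_xy):
            raise ValidationError("fov and resolution must be positive")


#: The scanner's two sequence presets per imaged plane.  Coronal FOV is
#: 18 cm x 18 cm (left/right x superior/inferior); axial FOV is 18 cm x 22 cm
#: (left/right x anterior/posterior).
SEQUENCE_PRESETS = {
    "t1w_coronal": SequenceParams(
        family="ir_se", tr=1.5, te=0.006, ti=0.3, averages=24,
        fov_xy=(180.0, 180.0), resolution_xy=(1.6, 1.6), plane="coronal",
    ),
    "t2w_coronal": SequenceParams(
        family="se", tr=2.0, te=0.231, averages=80,
        fov_xy=(180.0, 180.0), resolution_xy=(1.5, 1.5), plane="coronal",
    ),
    "t1w_axial": SequenceParams(
        family="ir_se", tr=1.5, te=0.006, ti=0.3, averages=24,
        fov_xy=(180.0, 220.0), resolution_xy=(1.6, 1.6), plane="axial",
    ),
    "t2w_axial": SequenceParams(
        family="se", tr=2.0, te=0.203, averages=80,
        fov_xy=(180.0, 220.0), resolution_xy=(1.5, 1.5), plane="axial",
    ),
}


def grid_shape(seq: SequenceParams) -> tuple:
    """Pixel grid shape ``(rows, cols)`` = round(fov / resolution) per axis."""
    nx = int(math.floor(seq.fov_xy[0] / seq.resolution_xy[0] + 0.5))
    ny = int(math.floor(seq.fov_xy[1] / seq.resolution_xy[1] + 0.5))
    return (ny, nx)


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise description for magnitude images."""

    kind: str = "none"  # none | gaussian | rician
    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("none", "gaussian", "rician"):
            raise ValidationError(f"unknown noise kind {self.kind!r}")
        if self.sigma < 0:
            raise ValidationError("noise sigma must be >= 0")


@dataclass(frozen=True)
class DistortionField:
    """Invertible in-plane geometric distortion applied in world (mm) space.

    ``affine``: ``w = A u + b`` with a 2x2 matrix and mm offset.
    ``radial``: ``w = u * (1 + k |u|^2)`` with ``k`` per mm^2.
    """

    kind: str = "identity"
    matrix: tuple = ((1.0, 0.0), (0.0, 1.0))
    offset: tuple = (0.0, 0.0)
    radial_coeff: float = 0.0

    def __post_init__(self):
        if self.kind not in ("identity", "affine", "radial"):
            raise ValidationError(f"unknown distortion kind {self.kind!r}")

    @classmethod
    def scale(cls, s: float) -> "DistortionField":
        """Uniform scaling of world coordinates by *s*."""
        return cls(kind="affine", matrix=((float(s), 0.0), (0.0, float(s))))

    def check_invertible(self, max_radius_mm: float) -> None:
        if self.kind == "affine":
            a = np.asarray(self.matrix, dtype=float)
            if abs(np.linalg.det(a)) < 1e-9:
                raise ConfigurationError("affine distortion matrix is singular")
        elif self.kind == "radial":
            # rho -> rho (1 + k rho^2) must be strictly increasing on the footprint
            if 1.0 + 3.0 * self.radial_coeff * max_radius_mm**2 <= 0:
                raise ConfigurationError(
                    "radial distortion is not invertible over the image footprint"
                )

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Forward map, object space -> distorted image space. (N, 2) mm."""
        p = np.asarray(points, dtype=float)
        if self.kind == "identity":
            return p.copy()
        if self.kind == "affine":
            a = np.asarray(self.matrix, dtype=float)
            return p @ a.T + np.asarray(self.offset, dtype=float)
        r2 = np.sum(p * p, axis=-1, keepdims=True)
        return p * (1.0 + self.radial_coeff * r2)

    def invert(self, points: np.ndarray) -> np.ndarray:
        """Inverse map, image space -> object space."""
        w = np.asarray(points, dtype=float)
        if self.kind == "identity":
            return w.copy()
        if self.kind == "affine":
            a = np.asarray(self.matrix, dtype=float)
            return (w - np.asarray(self.offset, dtype=float)) @ np.linalg.inv(a).T
        # Newton on rho (1 + k rho^2) = rho_w for each point's radius.
        k = self.radial_coeff
        rho_w = np.sqrt(np.sum(w * w, axis=-1))
        rho = rho_w.copy()
        for _ in range(50):
            f = rho * (1.0 + k * rho**2) - rho_w
            df = 1.0 + 3.0 * k * rho**2
            rho = rho - f / df
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(rho_w > 0, rho / np.where(rho_w > 0, rho_w, 1.0), 1.0)
        return w * ratio[..., None]


@dataclass
class SliceImage:
    """A 2D magnitude image with its world-coordinate mapping."""

    pixels: np.ndarray
    spacing_xy: tuple  # (mm/px along u=cols, mm/px along v=rows)
    origin_world: tuple  # (u, v) mm of the center of pixel [0, 0]
    plane: str = "coronal"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValidationError("SliceImage pixels must be 2D")
        if np.any(self.pixels < 0):
            raise ValidationError("SliceImage intensities must be non-negative")
        if any(s <= 0 for s in self.spacing_xy):
            raise ValidationError("pixel spacing must be positive")
        self.spacing_xy = tuple(float(s) for s in self.spacing_xy)
        self.origin_world = tuple(float(o) for o in self.origin_world)

    @property
    def shape(self):
        return self.pixels.shape

    def px_to_world(self, px: np.ndarray) -> np.ndarray:
        """(col, row) fractional pixel -> (u, v) mm."""
        p = np.asarray(px, dtype=float)
        return np.asarray(self.origin_world) + p * np.asarray(self.spacing_xy)

    def world_to_px(self, world: np.ndarray) -> np.ndarray:
        """(u, v) mm -> (col, row) fractional pixel."""
        w = np.asarray(world, dtype=float)
        return (w - np.asarray(self.origin_world)) / np.asarray(self.spacing_xy)

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(self.pixels.tobytes())
        h.update(json.dumps([self.spacing_xy, self.origin_world, self.plane]).encode())
        return h.hexdigest()


@dataclass(frozen=True)
class RenderedVial:
    """Sidecar ground truth for one rendered vial cross-section."""

    center_mm: tuple  # (u, v) world mm, after distortion
    center_px: tuple  # (col, row) fractional pixels
    radius_mm: float  # mid-wall circle radius
    radius_px: float
    material: str
    signal: float  # noise-free interior intensity


def _signal(material: MaterialSample, seq: SequenceParams) -> float:
    if seq.family == "ir_se":
        rec = abs(1.0 - 2.0 * math.exp(-seq.ti / material.t1) + math.exp(-seq.tr / material.t1))
    else:
        rec = 1.0 - math.exp(-seq.tr / material.t1)
    return material.pd * rec * math.exp(-seq.te / material.t2)


def ir_se_signal(material: MaterialSample, seq: SequenceParams) -> float:
    """Inversion-recovery spin-echo magnitude signal, dimensionless >= 0.

    ``pd * |1 - 2 exp(-ti/t1) + exp(-tr/t1)| * exp(-te/t2)``
    """
    if seq.family != "ir_se":
        raise UsageError(f"ir_se_signal called with family {seq.family!r}")
    return _signal(material, seq)


def se_signal(material: MaterialSample, seq: SequenceParams) -> float:
    """Spin-echo magnitude signal with effective-TE mono-exponential decay.

    ``pd * (1 - exp(-tr/t1)) * exp(-te/t2)``
    """
    if seq.family != "se":
        raise UsageError(f"se_signal called with family {seq.family!r}")
    return _signal(material, seq)


def add_noise(image: SliceImage, noise: NoiseModel) -> SliceImage:
    """Apply the noise model; deterministic for a fixed seed.

    ``gaussian`` adds zero-mean noise and truncates at zero; ``rician``
    forms ``sqrt((pixel + n1)^2 + n2^2)`` with independent ``N(0, sigma^2)``
    draws, the magnitude-image noise law (Rayleigh where the signal is zero).
    """
    if noise.sigma < 0:
        raise ValidationError("noise sigma must be >= 0")
    meta = dict(image.meta)
    meta["noise"] = {"kind": noise.kind, "sigma": noise.sigma, "seed": noise.seed}
    if noise.kind == "none" or noise.sigma == 0.0:
        return SliceImage(image.pixels.copy(), image.spacing_xy, image.origin_world,
                          image.plane, meta)
    rng = np.random.default_rng(noise.seed)
    if noise.kind == "gaussian":
        out = image.pixels + rng.normal(0.0, noise.sigma, image.pixels.shape)
        out = np.clip(out, 0.0, None)
    else:
        n1 = rng.normal(0.0, noise.sigma, image.pixels.shape)
        n2 = rng.normal(0.0, noise.sigma, image.pixels.shape)
        out = np.hypot(image.pixels + n1, n2)
    return SliceImage(out, image.spacing_xy, image.origin_world, image.plane, meta)


def render_slice(
    geometry: PhantomGeometry,
    seq: SequenceParams,
    distortion: DistortionField | None = None,
    noise: NoiseModel | None = None,
    slice_offset: float = 0.0,
    supersample: int = 4,
):
    """Render one magnitude slice plus its sidecar ground truth.

    Pixels take the signal of the material found at their (inverse-distorted)
    world coordinate: vial interiors at the vial material's signal, tube-wall
    annuli and everything without mobile protons (plastic shell, air) at
    zero, and the background water fill at the water signal.  Edges are
    anti-aliased by ``supersample x supersample`` subpixel averaging; noise
    is applied last with effective scale ``sigma / sqrt(averages)``.

    Returns
    -------
    (SliceImage, list of RenderedVial)
        Ground-truth centers are mapped through the same distortion into
        fractional pixel coordinates.
    """
    distortion = distortion or DistortionField()
    noise = noise or NoiseModel()
    ny, nx = grid_shape(seq)
    su, sv = seq.resolution_xy
    u0 = -(nx - 1) / 2.0 * su
    v0 = -(ny - 1) / 2.0 * sv

    footprint = math.hypot(max(abs(u0), abs(u0 + (nx - 1) * su)),
                           max(abs(v0), abs(v0 + (ny - 1) * sv)))
    distortion.check_invertible(footprint)

    k = max(1, int(supersample))
    sub = (np.arange(k) + 0.5) / k - 0.5
    cols = (np.arange(nx)[:, None] + sub[None, :]).ravel() * su + u0  # (nx*k,)
    rows = (np.arange(ny)[:, None] + sub[None, :]).ravel() * sv + v0  # (ny*k,)
    uu, vv = np.meshgrid(cols, rows)  # (ny*k, nx*k)
    pts = np.stack([uu.ravel(), vv.ravel()], axis=-1)
    obj = distortion.invert(pts)  # undistorted in-plane world coords

    # Background: classify against the (tilted) water cylinder.
    from .digital_phantom import rotation_matrix, _PLANE_AXES  # noqa: PLC0415

    iu, iv, inorm = _PLANE_AXES[seq.plane]
    p3 = np.zeros((obj.shape[0], 3))
    p3[:, iu] = obj[:, 0]
    p3[:, iv] = obj[:, 1]
    p3[:, inorm] = slice_offset
    rot = rotation_matrix(geometry.tilt)
    ph = (p3 - np.asarray(geometry.offset_xyz)) @ rot  # R^T via right-multiply
    r_xy = np.hypot(ph[:, 0], ph[:, 1])
    inside = (r_xy <= geometry.inner_diameter / 2.0) & (
        np.abs(ph[:, 2]) <= geometry.body_length / 2.0
    )
    water = _signal(geometry.background, seq) * SIGNAL_SCALE
    values = np.where(inside, water, 0.0)

    # Vials: annulus + interior disks at the projected ground-truth circles.
    circles = ground_truth_centers(geometry, seq.plane, slice_offset)
    sidecar = []
    for gt in circles:
        c = np.asarray(gt.center)
        d2 = np.sum((obj - c) ** 2, axis=-1)
        sig = _signal(gt.material, seq) * SIGNAL_SCALE
        values = np.where(d2 <= gt.outer_radius**2, 0.0, values)
        values = np.where(d2 <= gt.inner_radius**2, sig, values)
        c_img = distortion.apply(c[None, :])[0]
        col = (c_img[0] - u0) / su
        row = (c_img[1] - v0) / sv
        # Pixel-scale of the distortion at the center (isotropic approx).
        eps = 1e-3
        j = (distortion.apply((c + [eps, 0.0])[None, :])[0] - c_img) / eps
        local_scale = float(np.linalg.norm(j))
        sidecar.append(
            RenderedVial(
                center_mm=(float(c_img[0]), float(c_img[1])),
                center_px=(float(col), float(row)),
                radius_mm=gt.radius * local_scale,
                radius_px=gt.radius * local_scale / (0.5 * (su + sv)),
                material=gt.material.name,
                signal=sig,
            )
        )

    pixels = values.reshape(ny, k, nx, k).mean(axis=(1, 3))

    geo_hash = hashlib.sha256(geometry_to_config(geometry).encode()).hexdigest()[:16]
    meta = {
        "sequence": asdict(seq),
        "distortion": asdict(distortion),
        "slice_offset": slice_offset,
        "supersample": k,
        "geometry_hash": geo_hash,
        "signal_scale": SIGNAL_SCALE,
    }
    img = SliceImage(pixels, (su, sv), (u0, v0), seq.plane, meta)
    if noise.kind != "none" and noise.sigma > 0:
        eff = NoiseModel(noise.kind, noise.sigma / math.sqrt(seq.averages), noise.seed)
        img = add_noise(img, eff)
        img.meta["noise"]["sigma_requested"] = noise.sigma
        img.meta["noise"]["averages"] = seq.averages
    return img, sidecar
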