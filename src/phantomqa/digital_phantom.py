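"""Parametric digital model of the fillable cylinder phantom.

The phantom is a water-filled cylinder (180 mm outer / 148 mm inner diameter)
closed by either a flat top (160 mm total length) or a domed top (214 mm).
An insertable plate holds sample tubes: the "cor_sag" plate is a rectangular
plate aligned with the cylinder axis whose tube cross-sections appear in
coronal/sagittal images, while the "axial" plate is a circular plate coaxial
with the cylinder whose tube cross-sections appear in axial images.

Coordinate conventions
----------------------
The phantom frame has its origin at the midpoint of the cylinder axis with
``z`` along the cylinder axis.  The scanner frame shares the origin unless an
``offset_xyz`` is given; ``tilt`` is an intrinsic z-y-x rotation (degrees) of
the phantom frame relative to the scanner frame.  Slice planes are axis
aligned in the scanner frame:

========  =============  ============  ===========
plane     in-plane u     in-plane v    normal
========  =============  ============  ===========
axial     x              y             z
coronal   x              z             y
sagittal  y              z             x
========  =============  ============  ===========

Ground-truth circle centers are the *orthogonal projections* of the (tilted)
vial mid-points onto the slice plane, so an out-of-plane tilt of the vial row
foreshortens along-row spacing by exactly ``cos(theta)``.  All lengths are in
millimeters, all times in seconds.
"""

from __future__ import annotations

import configparser
import io
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import CapacityError, GeometryError, ValidationError

__all__ = [
    "MaterialSample",
    "VialSlot",
    "PhantomGeometry",
    "GroundTruthCircle",
    "DEFAULT_MATERIALS",
    "TUBE_DIMENSIONS",
    "PLATE_CAPACITY",
    "TOTAL_LENGTH",
    "build_default_phantom",
    "ground_truth_centers",
    "rotation_matrix",
    "geometry_to_config",
    "geometry_from_config",
]

#: (outer radius, inner radius, length) in mm per tube size class.  Tube
#: dimensions are not design dimensions of the phantom itself; these are
#: typical conical-tube values and are fully configurable per slot.
TUBE_DIMENSIONS = {
    "tube_15ml": (8.5, 7.0, 100.0),
    "tube_5ml": (6.1, 5.0, 60.0),
}

#: Plate capacity per tube size class.
PLATE_CAPACITY = {
    "cor_sag": {"tube_15ml": 15, "tube_5ml": 9},
    "axial": {"tube_15ml": 18, "tube_5ml": 6},
    "none": {"tube_15ml": 0, "tube_5ml": 0},
}

#: Overall phantom length by top style, mm.
TOTAL_LENGTH = {"flat": 160.0, "domed": 214.0}

_PLANE_AXES = {"axial": (0, 1, 2), "coronal": (0, 2, 1), "sagittal": (1, 2, 0)}


@dataclass(frozen=True)
class MaterialSample:
    """One measurand material with its relaxation properties.

    Parameters
    ----------
    name : str
        Short label, e.g. ``"water"`` or ``"cu1"``.
    t1, t2 : float
        Longitudinal / transverse relaxation times in seconds.
    pd : float
        Relative proton density in [0, 1].
    description : str
        Free text, e.g. the supplement-capsule count of a copper solution.
    """

    name: str
    t1: float
    t2: float
    pd: float
    description: str = ""

    def __post_init__(self):
        if not self.t1 > 0:
            raise ValidationError(f"material {self.name!r}: t1 must be > 0")
        if not self.t2 > 0:
            raise ValidationError(f"material {self.name!r}: t2 must be > 0")
        if self.t2 > self.t1:
            raise ValidationError(f"material {self.name!r}: t2 must not exceed t1")
        if not 0.0 <= self.pd <= 1.0:
            raise ValidationError(f"material {self.name!r}: pd must be in [0, 1]")


#: Default material catalog.  Relaxation values at 64 mT are placeholders
#: chosen to give the expected qualitative contrast (reference relaxometry of
#: the supplement solutions has not been performed); copper-solution values
#: decrease monotonically with capsule count.  NON-AUTHORITATIVE.
DEFAULT_MATERIALS = {
    "water": MaterialSample("water", t1=2.5, t2=2.0, pd=1.0, description="deionized water fill"),
    "oil": MaterialSample("oil", t1=0.15, t2=0.08, pd=0.9, description="olive oil (fat mimic)"),
    "cu1": MaterialSample("cu1", t1=0.8, t2=0.35, pd=1.0, description="1 capsule: 15 mg Zn + 2 mg Cu"),
    "cu2": MaterialSample("cu2", t1=0.5, t2=0.2, pd=1.0, description="2 capsules: 30 mg Zn + 4 mg Cu"),
    "cu3": MaterialSample("cu3", t1=0.3, t2=0.12, pd=1.0, description="3 capsules: 45 mg Zn + 6 mg Cu"),
}


@dataclass(frozen=True)
class VialSlot:
    """A cylindrical sample tube press-fit into a plate hole."""

    center_xyz: tuple
    outer_radius: float
    inner_radius: float
    axis: tuple
    length: float
    material: MaterialSample
    size_class: str = "tube_15ml"

    def __post_init__(self):
        if not 0 < self.inner_radius < self.outer_radius:
            raise ValidationError("vial: need 0 < inner_radius < outer_radius")
        if not self.length > 0:
            raise ValidationError("vial: length must be > 0")
        a = np.asarray(self.axis, dtype=float)
        if abs(np.linalg.norm(a) - 1.0) > 1e-9:
            raise ValidationError("vial: axis must be a unit vector")
        if self.size_class not in TUBE_DIMENSIONS:
            raise ValidationError(f"vial: unknown size_class {self.size_class!r}")

    @property
    def mid_wall_radius(self) -> float:
        """Radius of the wall-annulus mid-circle, the detector's target."""
        return 0.5 * (self.inner_radius + self.outer_radius)


@dataclass(frozen=True)
class PhantomGeometry:
    """Full physical description of one assembled phantom."""

    outer_diameter: float = 180.0
    inner_diameter: float = 148.0
    # Interior fill-column length; not a printed design dimension.  Chosen so
    # a coronal 18 cm FOV keeps air in the image corners for noise regions.
    body_length: float = 130.0
    top_style: str = "flat"
    total_length: float | None = None
    plate_style: str = "cor_sag"
    vials: tuple = ()
    background: MaterialSample = DEFAULT_MATERIALS["water"]
    tilt: tuple = (0.0, 0.0, 0.0)
    offset_xyz: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if self.top_style not in TOTAL_LENGTH:
            raise ValidationError(f"unknown top_style {self.top_style!r}")
        if self.plate_style not in PLATE_CAPACITY:
            raise ValidationError(f"unknown plate_style {self.plate_style!r}")
        if not self.inner_diameter < self.outer_diameter:
            raise ValidationError("inner_diameter must be smaller than outer_diameter")
        if self.total_length is None:
            object.__setattr__(self, "total_length", TOTAL_LENGTH[self.top_style])
        object.__setattr__(self, "vials", tuple(self.vials))
        object.__setattr__(self, "tilt", tuple(float(t) for t in self.tilt))
        object.__setattr__(self, "offset_xyz", tuple(float(t) for t in self.offset_xyz))
        self._validate_capacity()
        self._validate_containment()
        self._validate_overlap()

    def _validate_capacity(self):
        if len(self.vials) > 24:
            raise CapacityError("phantom holds at most 24 samples")
        caps = PLATE_CAPACITY[self.plate_style]
        counts = {}
        for v in self.vials:
            counts[v.size_class] = counts.get(v.size_class, 0) + 1
        for size_class, n in counts.items():
            if n > caps.get(size_class, 0):
                raise CapacityError(
                    f"{self.plate_style} plate holds at most "
                    f"{caps.get(size_class, 0)} {size_class} tubes, got {n}"
                )

    def _validate_containment(self):
        # Conservative: both axis end points, pushed out by the tube radius,
        # must stay inside the inner cylinder (radially and axially).
        r_cyl = self.inner_diameter / 2.0
        half_z = self.body_length / 2.0
        for v in self.vials:
            c = np.asarray(v.center_xyz, dtype=float)
            a = np.asarray(v.axis, dtype=float)
            for s in (-0.5, 0.5):
                p = c + s * v.length * a
                if math.hypot(p[0], p[1]) + v.outer_radius >= r_cyl:
                    raise GeometryError(
                        f"vial {v.material.name!r} at {tuple(c)} extends outside "
                        "the inner cylinder"
                    )
                if abs(p[2]) + v.outer_radius > half_z + 1e-9:
                    raise GeometryError(
                        f"vial {v.material.name!r} at {tuple(c)} extends beyond "
                        "the cylinder length"
                    )

    def _validate_overlap(self):
        # Parallel-axis tubes only (the only configuration the builder emits).
        for i, vi in enumerate(self.vials):
            ai = np.asarray(vi.axis, dtype=float)
            ci = np.asarray(vi.center_xyz, dtype=float)
            for vj in self.vials[i + 1:]:
                aj = np.asarray(vj.axis, dtype=float)
                if abs(abs(float(ai @ aj)) - 1.0) > 1e-9:
                    continue
                d = np.asarray(vj.center_xyz, dtype=float) - ci
                perp = d - (d @ ai) * ai
                if np.linalg.norm(perp) < vi.outer_radius + vj.outer_radius - 1e-9:
                    raise GeometryError(
                        f"vials {vi.material.name!r} and {vj.material.name!r} overlap"
                    )


@dataclass(frozen=True)
class GroundTruthCircle:
    """Circle traced by one vial cross-section in a slice plane (mm units)."""

    center: tuple  # (u, v) in-plane mm
    radius: float  # mean circle radius of the (possibly elliptical) section
    material: MaterialSample
    inner_radius: float = 0.0  # in-plane inner-wall radius
    outer_radius: float = 0.0  # in-plane outer-wall radius


def rotation_matrix(tilt_deg) -> np.ndarray:
    """Intrinsic z-y-x rotation matrix for tilt angles in degrees."""
    az, ay, ax = (math.radians(float(t)) for t in tilt_deg)
    cz, sz = math.cos(az), math.sin(az)
    cy, sy = math.cos(ay), math.sin(ay)
    cx, sx = math.cos(ax), math.sin(ax)
    rz = np.array([[cz, -sz, 0.0], [sz, cz, 0.0], [0.0, 0.0, 1.0]])
    ry = np.array([[cy, 0.0, sy], [0.0, 1.0, 0.0], [-sy, 0.0, cy]])
    rx = np.array([[1.0, 0.0, 0.0], [0.0, cx, -sx], [0.0, sx, cx]])
    return rz @ ry @ rx


def _plate_axis(plate_style: str) -> np.ndarray:
    # cor_sag plate: tubes perpendicular to the plate, along phantom y.
    # axial plate: tubes along the cylinder axis z.
    return np.array([0.0, 1.0, 0.0]) if plate_style == "cor_sag" else np.array([0.0, 0.0, 1.0])


def build_default_phantom(
    top_style: str = "flat",
    plate_style: str = "cor_sag",
    sample_layout=("oil", "cu1", "cu2", "cu3", "water"),
    spacing: float = 24.0,
    materials: dict | None = None,
    size_classes=None,
    tilt=(0.0, 0.0, 0.0),
    offset_xyz=(0.0, 0.0, 0.0),
) -> PhantomGeometry:
    """Build a phantom with vials on a regular grid.

    Layouts up to six tubes are placed as a single row (the one-dimensional
    distortion row); larger layouts are filled row-major onto a regular grid
    of rows. Vial list order is the along-row order used for "consecutive"
    inter-vial distances.

    Parameters
    ----------
    sample_layout : sequence of str
        Ordered material labels, resolved in ``materials`` (default catalog:
        water, oil, cu1, cu2, cu3).
    spacing : float
        Center-to-center grid spacing in mm; must exceed one tube diameter.
    size_classes : sequence of str, optional
        Per-slot tube class; defaults to ``tube_15ml`` everywhere.

    Raises
    ------
    CapacityError
        If the layout exceeds the plate capacity.
    GeometryError
        If tubes would overlap or stick out of the fill volume.
    """
    catalog = dict(DEFAULT_MATERIALS)
    if materials:
        catalog.update(materials)
    labels = list(sample_layout)
    if size_classes is None:
        size_classes = ["tube_15ml"] * len(labels)
    size_classes = list(size_classes)
    if len(size_classes) != len(labels):
        raise ValidationError("size_classes must match sample_layout length")

    caps = PLATE_CAPACITY[plate_style] if plate_style in PLATE_CAPACITY else None
    if caps is None:
        raise ValidationError(f"unknown plate_style {plate_style!r}")
    for size_class in TUBE_DIMENSIONS:
        n = size_classes.count(size_class)
        if n > caps[size_class]:
            raise CapacityError(
                f"{plate_style} plate holds at most {caps[size_class]} "
                f"{size_class} tubes, got {n}"
            )

    max_outer = max(TUBE_DIMENSIONS[s][0] for s in size_classes) if labels else 0.0
    if labels and not spacing > 2 * max_outer:
        raise ValidationError(
            f"spacing {spacing} mm must exceed one tube diameter ({2 * max_outer} mm)"
        )

    axis = _plate_axis(plate_style)
    n = len(labels)
    per_row = n if n <= 6 else 5
    n_rows = (n + per_row - 1) // per_row if n else 0

    vials = []
    for k, (label, size_class) in enumerate(zip(labels, size_classes)):
        if label not in catalog:
            raise ValidationError(f"unknown material label {label!r}")
        outer, inner, length = TUBE_DIMENSIONS[size_class]
        row, col = divmod(k, per_row)
        n_in_row = min(per_row, n - row * per_row)
        along = (col - (n_in_row - 1) / 2.0) * spacing
        across = (row - (n_rows - 1) / 2.0) * spacing
        if plate_style == "axial":
            center = (along, across, 0.0)  # grid in the x-y plane
        else:
            center = (across, 0.0, along)  # rows run along the cylinder axis
        vials.append(
            VialSlot(
                center_xyz=center,
                outer_radius=outer,
                inner_radius=inner,
                axis=tuple(axis),
                length=length,
                material=catalog[label],
                size_class=size_class,
            )
        )

    return PhantomGeometry(
        top_style=top_style,
        plate_style=plate_style,
        vials=tuple(vials),
        background=catalog["water"],
        tilt=tilt,
        offset_xyz=offset_xyz,
    )


def ground_truth_centers(
    geometry: PhantomGeometry, plane: str, slice_offset: float = 0.0
) -> list:
    """Project vial cross-sections into an axis-aligned slice plane.

    Each vial that intersects the plane contributes one
    :class:`GroundTruthCircle` whose center is the orthogonal projection of
    the vial mid-point (after tilt and offset) onto the plane and whose
    radius is the mean radius of the elliptical section, i.e.
    ``r * (1 + 1/|cos(phi)|) / 2`` for a tube axis at angle ``phi`` to the
    plane normal.  Output order follows ``geometry.vials``; vials not
    intersected are omitted.  A plane outside the phantom yields an empty
    list (not an error).
    """
    if plane not in _PLANE_AXES:
        raise ValidationError(f"unknown plane {plane!r}")
    iu, iv, inorm = _PLANE_AXES[plane]
    rot = rotation_matrix(geometry.tilt)
    offset = np.asarray(geometry.offset_xyz, dtype=float)

    out = []
    for vial in geometry.vials:
        c = rot @ np.asarray(vial.center_xyz, dtype=float) + offset
        a = rot @ np.asarray(vial.axis, dtype=float)
        cos_phi = abs(float(a[inorm]))
        # Extent of the tube solid along the plane normal.
        reach = cos_phi * vial.length / 2.0
        reach += vial.outer_radius * math.sqrt(max(0.0, 1.0 - cos_phi**2))
        if abs(float(c[inorm]) - slice_offset) > reach:
            continue
        if cos_phi < 1e-6:
            continue  # tube lies in the plane: no circular section
        stretch = 0.5 * (1.0 + 1.0 / cos_phi)
        out.append(
            GroundTruthCircle(
                center=(float(c[iu]), float(c[iv])),
                radius=vial.mid_wall_radius * stretch,
                material=vial.material,
                inner_radius=vial.inner_radius * stretch,
                outer_radius=vial.outer_radius * stretch,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Serialization: sectioned key/value config, units in key names (mm / s).
# ---------------------------------------------------------------------------

def geometry_to_config(geometry: PhantomGeometry, path=None) -> str:
    """Serialize a geometry to the sectioned key/value config format.

    If *path* is given, the document is also written there. Returns the
    config text.
    """
    cp = configparser.ConfigParser()
    cp["body"] = {
        "outer_diameter_mm": repr(geometry.outer_diameter),
        "inner_diameter_mm": repr(geometry.inner_diameter),
        "body_length_mm": repr(geometry.body_length),
    }
    cp["top"] = {
        "style": geometry.top_style,
        "total_length_mm": repr(geometry.total_length),
    }
    cp["plate"] = {"style": geometry.plate_style}
    cp["placement"] = {
        "tilt_deg": " ".join(repr(t) for t in geometry.tilt),
        "offset_mm": " ".join(repr(t) for t in geometry.offset_xyz),
    }
    mats = {geometry.background.name: geometry.background}
    for v in geometry.vials:
        mats[v.material.name] = v.material
    for name, m in mats.items():
        cp[f"material:{name}"] = {
            "t1_s": repr(m.t1),
            "t2_s": repr(m.t2),
            "pd": repr(m.pd),
            "description": m.description,
        }
    cp["vials"] = {"count": str(len(geometry.vials)), "background": geometry.background.name}
    for i, v in enumerate(geometry.vials):
        cp[f"vial:{i}"] = {
            "center_mm": " ".join(repr(float(c)) for c in v.center_xyz),
            "axis": " ".join(repr(float(a)) for a in v.axis),
            "outer_radius_mm": repr(v.outer_radius),
            "inner_radius_mm": repr(v.inner_radius),
            "length_mm": repr(v.length),
            "material": v.material.name,
            "size_class": v.size_class,
        }
    buf = io.StringIO()
    cp.write(buf)
    text = buf.getvalue()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def geometry_from_config(source) -> PhantomGeometry:
    """Read a geometry back from config text or a file path."""
    cp = configparser.ConfigParser()
    text = None
    if hasattr(source, "read"):
        text = source.read()
    elif isinstance(source, str) and "\n" in source:
        text = source
    if text is not None:
        cp.read_string(text)
    else:
        read = cp.read(source)
        if not read:
            raise ValidationError(f"geometry config not found: {source}")

    def _vec(s):
        return tuple(float(x) for x in s.split())

    mats = {}
    for sect in cp.sections():
        if sect.startswith("material:"):
            name = sect.split(":", 1)[1]
            mats[name] = MaterialSample(
                name=name,
                t1=cp.getfloat(sect, "t1_s"),
                t2=cp.getfloat(sect, "t2_s"),
                pd=cp.getfloat(sect, "pd"),
                description=cp.get(sect, "description", fallback=""),
            )
    n = cp.getint("vials", "count")
    vials = []
    for i in range(n):
        sect = f"vial:{i}"
        vials.append(
            VialSlot(
                center_xyz=_vec(cp.get(sect, "center_mm")),
                axis=_vec(cp.get(sect, "axis")),
                outer_radius=cp.getfloat(sect, "outer_radius_mm"),
                inner_radius=cp.getfloat(sect, "inner_radius_mm"),
                length=cp.getfloat(sect, "length_mm"),
                material=mats[cp.get(sect, "material")],
                size_class=cp.get(sect, "size_class"),
            )
        )
    return PhantomGeometry(
        outer_diameter=cp.getfloat("body", "outer_diameter_mm"),
        inner_diameter=cp.getfloat("body", "inner_diameter_mm"),
        body_length=cp.getfloat("body", "body_length_mm"),
        top_style=cp.get("top", "style"),
        total_length=cp.getfloat("top", "total_length_mm"),
        plate_style=cp.get("plate", "style"),
        vials=tuple(vials),
        background=mats[cp.get("vials", "background")],
        tilt=_vec(cp.get("placement", "tilt_deg")),
        offset_xyz=_vec(cp.get("placement", "offset_mm")),
    )


def with_tilt(geometry: PhantomGeometry, tilt) -> PhantomGeometry:
    """Return a copy of *geometry* with a different placement tilt."""
    return replace(geometry, tilt=tuple(float(t) for t in tilt))
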