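"""File I/O, fixtures, and report serialization.

NIfTI-1 is the canonical interchange format (float64 data, pixel spacing in
the header, 2D or single-slice 3D).  PNG (16-bit) and TIFF are supported for
grayscale 2D images; they carry no spacing, so a spacing override is
required on read.  Single-frame DICOM is read-only and needs pydicom, which
is optional.  Analysis results are schema-versioned JSON; CSV summaries use
the distance/Average/SNR/CNR column order of the published table.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np

from .digital_phantom import PhantomGeometry, build_default_phantom
from .errors import (
    FormatError,
    InsufficientDataError,
    UnsupportedInputError,
)
from .mr_simulator import (
    SEQUENCE_PRESETS,
    NoiseModel,
    SliceImage,
    render_slice,
)
from .qa_metrics import QAReport

__all__ = [
    "read_image",
    "write_image",
    "write_sidecar",
    "read_sidecar",
    "write_report",
    "read_report",
    "report_to_csv_row",
    "FixtureScan",
    "FixtureSet",
    "make_fixtures",
    "FIXTURE_SIGMA",
]

_NIFTI_EXT = (".nii", ".nii.gz")
_PNG_EXT = (".png",)
_TIFF_EXT = (".tif", ".tiff")
_DICOM_EXT = (".dcm", ".dicom", ".ima")


def read_image(path, spacing=None, plane: str = "unknown") -> SliceImage:
    """Read a 2D magnitude image into a :class:`SliceImage`.

    Pixel spacing is taken from the file header when present (NIfTI, DICOM),
    otherwise the ``spacing`` override (mm or (mm, mm)) is required.
    """
    path = os.fspath(path)
    low = path.lower()
    if spacing is not None and np.isscalar(spacing):
        spacing = (float(spacing), float(spacing))

    if low.endswith(_NIFTI_EXT):
        import nibabel as nib

        img = nib.load(path)
        arr = np.asanyarray(img.dataobj)
        arr = np.squeeze(arr)
        if arr.ndim != 2:
            raise UnsupportedInputError(
                f"{path}: only 2D or single-slice 3D NIfTI is supported"
            )
        zooms = img.header.get_zooms()[:2]
        sp = spacing or (float(zooms[0]), float(zooms[1]))
        # Data stored (u, v); transpose to rows-first.
        pixels = np.asarray(arr, dtype=float).T
    elif low.endswith(_PNG_EXT) or low.endswith(_TIFF_EXT):
        import imageio.v3 as iio

        arr = iio.imread(path)
        if arr.ndim == 3:
            raise UnsupportedInputError(f"{path}: grayscale images only")
        if spacing is None:
            raise FormatError(
                f"{path}: PNG/TIFF carries no pixel spacing; a spacing override is required"
            )
        sp = spacing
        pixels = np.asarray(arr, dtype=float)
    elif low.endswith(_DICOM_EXT):
        try:
            import pydicom
        except ImportError as exc:  # pragma: no cover - env dependent
            raise UnsupportedInputError(
                f"{path}: DICOM reading requires the optional pydicom package"
            ) from exc
        ds = pydicom.dcmread(path)
        if int(getattr(ds, "NumberOfFrames", 1)) > 1:
            raise UnsupportedInputError(
                f"{path}: multi-frame DICOM series are not supported"
            )
        pixels = np.asarray(ds.pixel_array, dtype=float)
        ps = getattr(ds, "PixelSpacing", None)
        if ps is not None:
            sp = (float(ps[1]), float(ps[0]))  # (col, row) spacing
        elif spacing is not None:
            sp = spacing
        else:
            raise FormatError(f"{path}: DICOM has no PixelSpacing and no override given")
    else:
        raise FormatError(f"{path}: unrecognised image format")

    ny, nx = pixels.shape
    origin = (-(nx - 1) / 2.0 * sp[0], -(ny - 1) / 2.0 * sp[1])
    meta = {"source": path}
    side = _sidecar_path(path)
    if os.path.exists(side):
        meta["sidecar"] = side
    return SliceImage(np.clip(pixels, 0.0, None), sp, origin, plane, meta)


def write_image(image: SliceImage, path) -> None:
    """Write a slice as NIfTI (lossless float64), 16-bit PNG, or TIFF."""
    path = os.fspath(path)
    low = path.lower()
    if low.endswith(_NIFTI_EXT):
        import nibabel as nib

        data = image.pixels.T  # store (u, v)
        su, sv = image.spacing_xy
        affine = np.diag([su, sv, 1.0, 1.0])
        affine[0, 3] = image.origin_world[0]
        affine[1, 3] = image.origin_world[1]
        out = nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine)
        out.header.set_zooms((su, sv))
        nib.save(out, path)
    elif low.endswith(_PNG_EXT):
        import imageio.v3 as iio

        peak = float(image.pixels.max())
        scale = 65535.0 / peak if peak > 0 else 1.0
        iio.imwrite(path, np.round(image.pixels * scale).astype(np.uint16))
    elif low.endswith(_TIFF_EXT):
        import tifffile

        tifffile.imwrite(path, np.asarray(image.pixels, dtype=np.float64))
    else:
        raise FormatError(f"{path}: unrecognised output format")


def _sidecar_path(image_path) -> str:
    base = os.fspath(image_path)
    for ext in (".nii.gz", ".nii", ".png", ".tif", ".tiff", ".dcm"):
        if base.lower().endswith(ext):
            base = base[: -len(ext)]
            break
    return base + ".truth.json"


def write_sidecar(image_path, vials, seed=None, extra=None) -> str:
    """Write the ground-truth sidecar next to an image file."""
    doc = {
        "schema": "phantomqa-truth/1",
        "seed": seed,
        "vials": [
            {
                "center_mm": list(v.center_mm),
                "center_px": list(v.center_px),
                "radius_mm": v.radius_mm,
                "radius_px": v.radius_px,
                "material": v.material,
                "signal": v.signal,
            }
            for v in vials
        ],
    }
    if extra:
        doc.update(extra)
    path = _sidecar_path(image_path)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
    return path


def read_sidecar(image_or_sidecar_path) -> dict:
    path = os.fspath(image_or_sidecar_path)
    if not path.endswith(".truth.json"):
        path = _sidecar_path(path)
    with open(path) as fh:
        return json.load(fh)


def write_report(report: QAReport, path, format: str = "json") -> None:
    """Write a QA report as JSON or a one-row CSV summary."""
    if not report.distances:
        raise InsufficientDataError("refusing to write a report with no distances")
    path = os.fspath(path)
    if format == "json":
        with open(path, "w") as fh:
            json.dump(report.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")
    elif format == "csv":
        header, row = report_to_csv_row(report)
        with open(path, "w") as fh:
            fh.write(",".join(header) + "\n")
            fh.write(",".join(row) + "\n")
    else:
        raise FormatError(f"unknown report format {format!r}")


def report_to_csv_row(report: QAReport, label: str = ""):
    """CSV columns in published-table order; distances at 0.1 mm precision."""
    header = ["scan"]
    row = [label]
    for i in range(len(report.distances)):
        header.append(f"dist_{i + 1}_{i + 2}_mm")
        row.append(f"{report.distances[i]:.1f}")
    header += ["average_mm", "snr", "cnr"]
    row += [f"{report.average_distance:.1f}", f"{report.snr:.0f}", f"{report.cnr:.0f}"]
    return header, row


def read_report(path) -> QAReport:
    with open(path) as fh:
        return QAReport.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Fixture generation: a synthetic stand-in for the four-scan experiment.
# ---------------------------------------------------------------------------

#: Pre-averaging noise sigma per weighting, chosen so that T1-weighted SNR is
#: O(10^2) and T2-weighted SNR is O(10^3), the published order-of-magnitude gap.
FIXTURE_SIGMA = {"t1w": 13.8, "t2w": 2.4}

_FIXTURE_LAYOUT = ("oil", "cu1", "cu2", "cu3")
_FIXTURE_SPACING = 24.0
#: Small rigid in-plane move applied to the domed-top placement (coronal
#: in-plane rotation = tilt about y); preserves true inter-vial distances.
_DOMED_TILT = (0.0, 6.0, 0.0)


@dataclass(frozen=True)
class FixtureScan:
    """One simulated scan: noisy + noise-free images and ground truth."""

    name: str
    mode: str  # t1w | t2w
    top_style: str
    image: SliceImage
    noise_free: SliceImage
    vials: tuple
    geometry: PhantomGeometry
    preset: str
    seed: int


@dataclass(frozen=True)
class FixtureSet:
    """The four-scan design: T1w/T2w for flat- and domed-top placements."""

    scans: dict
    seed: int

    def __getitem__(self, name) -> FixtureScan:
        return self.scans[name]

    def pair(self, top_style: str):
        return self.scans[f"t1w_{top_style}"], self.scans[f"t2w_{top_style}"]


def make_fixtures(seed: int = 0, spacing: float = _FIXTURE_SPACING) -> FixtureSet:
    """Deterministically simulate the four-scan experiment.

    Within each top style the phantom placement is identical across the T1w
    and T2w acquisitions (the validity requirement for comparing average
    distances); the domed-top placement differs from the flat-top one by a
    small rigid in-plane rotation.
    """
    scans = {}
    for i, (mode, top) in enumerate(
        [("t1w", "flat"), ("t2w", "flat"), ("t1w", "domed"), ("t2w", "domed")]
    ):
        tilt = (0.0, 0.0, 0.0) if top == "flat" else _DOMED_TILT
        geometry = build_default_phantom(
            top_style=top, sample_layout=_FIXTURE_LAYOUT, spacing=spacing, tilt=tilt
        )
        preset = f"{mode}_coronal"
        seq = SEQUENCE_PRESETS[preset]
        scan_seed = int(seed) * 97 + i
        noise = NoiseModel(kind="rician", sigma=FIXTURE_SIGMA[mode], seed=scan_seed)
        clean, vials = render_slice(geometry, seq)
        noisy, _ = render_slice(geometry, seq, noise=noise)
        scans[f"{mode}_{top}"] = FixtureScan(
            name=f"{mode}_{top}",
            mode=mode,
            top_style=top,
            image=noisy,
            noise_free=clean,
            vials=tuple(vials),
            geometry=geometry,
            preset=preset,
            seed=scan_seed,
        )
    return FixtureSet(scans=scans, seed=int(seed))


def write_fixtures(fixtures: FixtureSet, out_dir) -> list:
    """Write fixture images + sidecars to a directory; returns paths."""
    os.makedirs(out_dir, exist_ok=True)
    paths = []
    for name, scan in fixtures.scans.items():
        img_path = os.path.join(out_dir, f"{name}.nii")
        write_image(scan.image, img_path)
        write_image(scan.noise_free, os.path.join(out_dir, f"{name}_noisefree.nii"))
        write_sidecar(
            img_path,
            scan.vials,
            seed=scan.seed,
            extra={
                "preset": scan.preset,
                "mode": scan.mode,
                "top_style": scan.top_style,
                "sigma": FIXTURE_SIGMA[scan.mode],
                "tilt_deg": list(scan.geometry.tilt),
            },
        )
        paths.append(img_path)
    return paths
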