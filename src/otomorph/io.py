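"""Readers and writers for the formats the pipeline touches.

Labeled volumes: TIFF stacks (no reliable spacing metadata — an explicit
spacing override is required), NIfTI-1 (canonical interchange format for
this package; spacing stored in the affine, interpreted in μm),
MetaImage (.mhd/.raw), and DICOM series (read-only; DICOM spatial
attributes are in mm and are converted to μm on read).  Centerlines:
legacy-VTK polydata polylines and plain CSV.  Rigid transforms: JSON.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import numpy as np

from .centerline import Polyline3D
from .grids import LabeledVolume
from .register import RigidTransform3D

__all__ = [
    "read_volume",
    "write_volume",
    "export_polyline",
    "import_polyline",
    "save_transform",
    "load_transform",
]

_SUPPORTED_WRITE = (".nii", ".nii.gz", ".tif", ".tiff", ".mhd")


def _fmt_of(path: Path, format_hint: str | None) -> str:
    if format_hint:
        return format_hint.lower().lstrip(".")
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith((".tif", ".tiff")):
        return "tiff"
    if name.endswith(".mhd"):
        return "metaimage"
    if path.is_dir() or name.endswith(".dcm"):
        return "dicom"
    raise ValueError(
        f"cannot infer format of {path}; supported: NIfTI (.nii/.nii.gz), "
        "TIFF stack (.tif), MetaImage (.mhd), DICOM series (directory)"
    )


def _check_integer(arr: np.ndarray) -> np.ndarray:
    if np.issubdtype(arr.dtype, np.integer):
        return arr
    if np.issubdtype(arr.dtype, np.floating) and np.all(arr == np.rint(arr)):
        return arr.astype(np.int32)
    raise ValueError(
        "volume contains non-integer voxel values; expected a labeled "
        "segmentation, not a grayscale image"
    )


def read_volume(
    path: str | os.PathLike,
    format_hint: str | None = None,
    spacing_um=None,
    dicom_units: str = "mm",
) -> LabeledVolume:
    """Read a labeled volume.

    ``spacing_um`` is required for TIFF stacks (TIFF carries no reliable
    spacing) and overrides file metadata elsewhere.  DICOM series are read
    from a directory; their mm-based spatial attributes are converted to
    μm unless ``dicom_units="um"``.
    """
    path = Path(path)
    fmt = _fmt_of(path, format_hint)
    if fmt in ("nifti", "nii"):
        return _read_nifti(path, spacing_um)
    if fmt in ("tiff", "tif"):
        return _read_tiff(path, spacing_um)
    if fmt in ("metaimage", "mhd"):
        return _read_metaimage(path, spacing_um)
    if fmt == "dicom":
        return _read_dicom_series(path, dicom_units)
    raise ValueError(f"unsupported volume format {fmt!r}")


def write_volume(vol: LabeledVolume, path: str | os.PathLike, format_hint: str | None = None) -> Path:
    """Write a labeled volume to NIfTI, TIFF, or MetaImage."""
    path = Path(path)
    fmt = _fmt_of(path, format_hint)
    if fmt in ("nifti", "nii"):
        _write_nifti(vol, path)
    elif fmt in ("tiff", "tif"):
        _write_tiff(vol, path)
    elif fmt in ("metaimage", "mhd"):
        _write_metaimage(vol, path)
    else:
        raise ValueError(
            f"unsupported write format {fmt!r}; supported extensions: "
            + ", ".join(_SUPPORTED_WRITE)
        )
    return path


# -- NIfTI ------------------------------------------------------------------


def _read_nifti(path: Path, spacing_um) -> LabeledVolume:
    import nibabel as nib

    img = nib.load(str(path))
    labels = _check_integer(np.asanyarray(img.dataobj))
    affine = img.affine
    spacing = np.abs(np.array([affine[i, i] for i in range(3)], dtype=float))
    origin = np.array(affine[:3, 3], dtype=float)
    if spacing_um is not None:
        spacing = np.broadcast_to(np.asarray(spacing_um, dtype=float), (3,)).copy()
    return LabeledVolume(labels=labels, spacing_um=spacing, origin_um=origin)


def _write_nifti(vol: LabeledVolume, path: Path) -> None:
    import nibabel as nib

    affine = np.diag([*vol.spacing_um, 1.0])
    affine[:3, 3] = vol.origin_um
    img = nib.Nifti1Image(vol.labels.astype(np.int32), affine)
    img.header.set_xyzt_units(xyz="micron")
    nib.save(img, str(path))


# -- TIFF -------------------------------------------------------------------


def _read_tiff(path: Path, spacing_um) -> LabeledVolume:
    import tifffile

    if spacing_um is None:
        raise ValueError(
            "TIFF stacks carry no reliable physical spacing; pass "
            "spacing_um explicitly (e.g. spacing_um=10 or --spacing on the CLI)"
        )
    labels = _check_integer(tifffile.imread(str(path)))
    if labels.ndim == 2:
        labels = labels[None]
    return LabeledVolume(labels=labels, spacing_um=spacing_um)


def _write_tiff(vol: LabeledVolume, path: Path) -> None:
    import tifffile

    tifffile.imwrite(str(path), vol.labels.astype(np.int32))


# -- MetaImage --------------------------------------------------------------
# SimpleITK indexes images (x, y, z); our arrays are (i, j, k) with i the
# slowest axis, so spacing/origin vectors are reversed on the way through.


def _read_metaimage(path: Path, spacing_um) -> LabeledVolume:
    import SimpleITK as sitk

    img = sitk.ReadImage(str(path))
    labels = _check_integer(sitk.GetArrayFromImage(img))
    spacing = np.array(img.GetSpacing()[::-1], dtype=float)
    origin = np.array(img.GetOrigin()[::-1], dtype=float)
    if spacing_um is not None:
        spacing = np.broadcast_to(np.asarray(spacing_um, dtype=float), (3,)).copy()
    return LabeledVolume(labels=labels, spacing_um=spacing, origin_um=origin)


def _write_metaimage(vol: LabeledVolume, path: Path) -> None:
    import SimpleITK as sitk

    img = sitk.GetImageFromArray(vol.labels.astype(np.int32))
    img.SetSpacing(tuple(float(s) for s in vol.spacing_um[::-1]))
    img.SetOrigin(tuple(float(o) for o in vol.origin_um[::-1]))
    sitk.WriteImage(img, str(path))


# -- DICOM (read-only) ------------------------------------------------------


def _read_dicom_series(path: Path, dicom_units: str = "mm") -> LabeledVolume:
    import pydicom

    scale = {"mm": 1000.0, "um": 1.0}.get(dicom_units)
    if scale is None:
        raise ValueError("dicom_units must be 'mm' or 'um'")
    files = sorted(path.glob("*.dcm")) if path.is_dir() else [path]
    if not files:
        raise ValueError(f"no .dcm files in {path}")
    slices = [pydicom.dcmread(str(f)) for f in files]
    slices.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
    arr = np.stack([_check_integer(ds.pixel_array) for ds in slices], axis=0)
    px = [float(v) for v in slices[0].PixelSpacing]
    if len(slices) > 1:
        dz = float(slices[1].ImagePositionPatient[2]) - float(slices[0].ImagePositionPatient[2])
    else:
        dz = float(getattr(slices[0], "SliceThickness", px[0]))
    pos0 = [float(v) for v in slices[0].ImagePositionPatient]
    spacing = np.array([abs(dz), px[0], px[1]]) * scale
    origin = np.array([pos0[2], pos0[1], pos0[0]]) * scale
    return LabeledVolume(labels=arr, spacing_um=spacing, origin_um=origin)


# -- polylines --------------------------------------------------------------


def export_polyline(p: Polyline3D, path: str | os.PathLike, fmt: str | None = None) -> Path:
    """Write a centerline as CSV (x_um,y_um,z_um) or legacy-VTK polydata."""
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "csv":
        header = "x_um,y_um,z_um"
        np.savetxt(path, p.points, delimiter=",", header=header, comments="", fmt="%.6f")
    elif fmt == "vtk":
        n = len(p)
        with open(path, "w") as fh:
            fh.write("# vtk DataFile Version 3.0\ncenterline polyline\nASCII\n")
            fh.write("DATASET POLYDATA\n")
            fh.write(f"POINTS {n} float\n")
            for x, y, z in p.points:
                fh.write(f"{x:.6f} {y:.6f} {z:.6f}\n")
            fh.write(f"LINES 1 {n + 1}\n")
            fh.write(" ".join([str(n), *map(str, range(n))]) + "\n")
    else:
        raise ValueError(f"unsupported polyline format {fmt!r}; use 'csv' or 'vtk'")
    return path


def import_polyline(path: str | os.PathLike, fmt: str | None = None) -> Polyline3D:
    """Read a centerline written by :func:`export_polyline`."""
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "csv":
        pts = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        return Polyline3D(points=pts)
    if fmt == "vtk":
        with open(path) as fh:
            lines = fh.read().splitlines()
        i = next(k for k, l in enumerate(lines) if l.startswith("POINTS"))
        n = int(lines[i].split()[1])
        vals: list[float] = []
        k = i + 1
        while len(vals) < 3 * n:
            vals.extend(float(v) for v in lines[k].split())
            k += 1
        pts = np.array(vals).reshape(n, 3)
        i = next(k for k, l in enumerate(lines) if l.startswith("LINES"))
        order = [int(v) for v in lines[i + 1].split()][1:]
        return Polyline3D(points=pts[order])
    raise ValueError(f"unsupported polyline format {fmt!r}; use 'csv' or 'vtk'")


# -- transforms -------------------------------------------------------------


def save_transform(t: RigidTransform3D, path: str | os.PathLike, pixel_spacing_um: float | None = None) -> Path:
    """Serialize a rigid transform as JSON (quaternion x,y,z,w + translation μm)."""
    path = Path(path)
    payload = {
        "quaternion_xyzw": [float(v) for v in t.quaternion],
        "translation_um": [float(v) for v in t.translation_um],
    }
    if pixel_spacing_um is not None:
        payload["pixel_spacing_um"] = float(pixel_spacing_um)
    path.write_text(json.dumps(payload, indent=2) + "\n")
    return path


def load_transform(path: str | os.PathLike) -> RigidTransform3D:
    payload = json.loads(Path(path).read_text())
    return RigidTransform3D(
        quaternion=np.array(payload["quaternion_xyzw"], dtype=float),
        translation_um=np.array(payload["translation_um"], dtype=float),
    )
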