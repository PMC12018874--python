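"""Domain containers and I/O for per-patient delineation data.

A patient is described by six repeat-MRI delineations of the primary gross
tumor volume (GTVp): one baseline structure and five test structures, each a
stack of planar closed polygons ("contour slices") in the patient LPS frame
(+x = patient left, +y = posterior, +z = cranial; all lengths in mm).  Test
scans carry a rigid transform into the baseline frame, obtained upstream
from bone registration.  The record also stores the axial position of the
anal verge and a polyline approximation of the rectal central axis, which
anchor the tumor-height (CAX) coordinate used by the reference mapping.

The on-disk format is a small JSON dialect with canonical serialization
(sorted keys, floats at 6 decimals) so that write->read->write round trips
are byte-stable.  A convenience reader for DICOM RT Structure Sets is
provided for real structure sets exported from a planning system.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from shapely.geometry import Polygon

__all__ = [
    "ValidationError",
    "ParseError",
    "SerializationError",
    "ContourSlice",
    "StructureSet",
    "RigidTransform",
    "ScanRecord",
    "PatientRecord",
    "read_patient",
    "write_patient",
    "ingest_rtstruct",
    "records_equal",
]

#: Fallback inter-slice spacing (mm) for single-slice structures; matches the
#: isotropic acquisition grid the analysis assumes.
DEFAULT_SLAB_MM = 1.5

_SPACING_TOL_MM = 1e-6
_MAX_ROTATION_DEG = 10.0


class ValidationError(ValueError):
    """A domain invariant is violated; message lists all violations found."""


class ParseError(ValueError):
    """A file does not conform to the patient JSON dialect."""


class SerializationError(ValueError):
    """A record cannot be serialized (e.g. non-finite coordinates)."""


def _shoelace_area(vertices: np.ndarray) -> float:
    """Signed polygon area; positive = counter-clockwise viewed from +z."""
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass(frozen=True, eq=False)
class ContourSlice:
    """One planar closed contour at axial position ``z_mm``.

    Vertices are stored open (last != first) and implicitly closed.  On
    construction the polygon is validated (>=3 vertices, simple, non-zero
    area) and its orientation normalized to counter-clockwise as viewed
    from cranial (+z).
    """

    z_mm: float
    vertices: np.ndarray  # (V, 2) float

    def __post_init__(self) -> None:
        verts = np.asarray(self.vertices, dtype=float)
        if verts.ndim != 2 or verts.shape[1] != 2:
            raise ValidationError("contour vertices must be an (V, 2) array")
        if not np.isfinite(verts).all() or not math.isfinite(self.z_mm):
            raise ValidationError(f"non-finite coordinate in contour at z={self.z_mm}")
        if len(verts) >= 2 and np.allclose(verts[0], verts[-1]):
            verts = verts[:-1]  # tolerate explicitly closed input
        if len(verts) < 3:
            raise ValidationError(f"contour at z={self.z_mm} has <3 vertices")
        poly = Polygon(verts)
        if not poly.is_valid or poly.area <= 0.0:
            raise ValidationError(f"contour at z={self.z_mm} is not a simple polygon")
        if _shoelace_area(verts) < 0.0:
            verts = verts[::-1].copy()
        verts.setflags(write=False)
        object.__setattr__(self, "vertices", verts)
        object.__setattr__(self, "z_mm", float(self.z_mm))

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    @property
    def perimeter_mm(self) -> float:
        closed = np.vstack([self.vertices, self.vertices[:1]])
        return float(np.sum(np.linalg.norm(np.diff(closed, axis=0), axis=1)))


@dataclass(eq=False)
class StructureSet:
    """A named stack of contour slices sorted by ascending z (a delineation)."""

    name: str
    slices: list[ContourSlice]

    def __post_init__(self) -> None:
        if not self.slices:
            raise ValidationError(f"structure '{self.name}' has no slices")
        z = np.array([s.z_mm for s in self.slices], dtype=float)
        if not np.all(np.diff(z) > 0):
            raise ValidationError(f"structure '{self.name}': slice z not strictly increasing")
        if len(z) >= 3:
            gaps = np.diff(z)
            if gaps.max() - gaps.min() > _SPACING_TOL_MM:
                raise ValidationError(
                    f"structure '{self.name}': inter-slice spacing not constant "
                    f"(spread {gaps.max() - gaps.min():.2e} mm)"
                )

    @property
    def z_values(self) -> np.ndarray:
        return np.array([s.z_mm for s in self.slices], dtype=float)

    @property
    def slice_spacing_mm(self) -> float:
        """Inter-slice spacing; falls back to 1.5 mm for single-slice stacks."""
        if len(self.slices) < 2:
            return DEFAULT_SLAB_MM
        return float(self.slices[1].z_mm - self.slices[0].z_mm)

    @property
    def z_range(self) -> tuple[float, float]:
        return self.slices[0].z_mm, self.slices[-1].z_mm

    def translated(self, t: Sequence[float]) -> "StructureSet":
        """Rigidly translated copy (used by the simulator and tests)."""
        tx, ty, tz = (float(v) for v in t)
        return StructureSet(
            self.name,
            [ContourSlice(s.z_mm + tz, s.vertices + np.array([tx, ty])) for s in self.slices],
        )


@dataclass(frozen=True, eq=False)
class RigidTransform:
    """Rigid transform p -> R(p - c) + c + t.

    Euler angles in degrees, applied in order rx -> ry -> rz (extrinsic,
    about the fixed LPS axes) around ``center_mm``.
    """

    rotation_deg: np.ndarray  # (3,)
    translation_mm: np.ndarray  # (3,)
    center_mm: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        for name in ("rotation_deg", "translation_mm", "center_mm"):
            v = np.asarray(getattr(self, name), dtype=float).reshape(3)
            if not np.isfinite(v).all():
                raise ValidationError(f"transform {name} non-finite")
            v.setflags(write=False)
            object.__setattr__(self, name, v)
        if np.abs(self.rotation_deg).max() > _MAX_ROTATION_DEG:
            raise ValidationError(
                f"rotation {self.rotation_deg} exceeds sanity bound of "
                f"{_MAX_ROTATION_DEG} degrees"
            )

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.zeros(3), np.zeros(3), np.zeros(3))

    @property
    def is_identity(self) -> bool:
        return not (self.rotation_deg.any() or self.translation_mm.any())

    @property
    def matrix(self) -> np.ndarray:
        """3x3 rotation matrix (rx then ry then rz about fixed axes)."""
        from scipy.spatial.transform import Rotation

        return Rotation.from_euler("xyz", self.rotation_deg, degrees=True).as_matrix()


@dataclass(eq=False)
class ScanRecord:
    """One MRI time point: its GTVp and the rigid transform to baseline."""

    scan_id: str
    timepoint: int
    role: str  # "baseline" | "test"
    transform_to_baseline: RigidTransform
    gtvp: StructureSet

    def __post_init__(self) -> None:
        if self.role not in ("baseline", "test"):
            raise ValidationError(f"scan '{self.scan_id}': role must be baseline|test")
        if not 1 <= int(self.timepoint) <= 6:
            raise ValidationError(f"scan '{self.scan_id}': timepoint must be 1-6")
        self.timepoint = int(self.timepoint)


@dataclass(eq=False)
class PatientRecord:
    """All per-patient inputs: scans, anal-verge position, rectal centerline."""

    patient_id: str
    anal_verge_z_mm: float
    centerline_mm: np.ndarray  # (K, 3) ordered polyline
    scans: list[ScanRecord]
    incomplete: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        errors: list[str] = []
        cl = np.asarray(self.centerline_mm, dtype=float)
        if cl.ndim != 2 or cl.shape[1] != 3 or len(cl) < 2:
            raise ValidationError(f"patient '{self.patient_id}': centerline must be (K>=2, 3)")
        if not np.isfinite(cl).all():
            errors.append("non-finite centerline coordinate")
        self.centerline_mm = cl

        roles = [s.role for s in self.scans]
        if roles.count("baseline") > 1:
            errors.append("multiple baselines")
        elif roles.count("baseline") == 0:
            errors.append("no baseline scan")
        tps = [s.timepoint for s in self.scans]
        if len(set(tps)) != len(tps):
            errors.append("duplicated timepoints")
        if len(self.scans) < 6:
            self.incomplete = True
            warnings.warn(
                f"patient '{self.patient_id}': only {len(self.scans)} scans present",
                stacklevel=2,
            )
        if self.scans and not errors:
            z_lo = min(s.gtvp.z_range[0] for s in self.scans)
            z_hi = max(s.gtvp.z_range[1] for s in self.scans)
            if cl[:, 2].min() > z_lo or cl[:, 2].max() < z_hi:
                errors.append(
                    f"centerline z-range [{cl[:, 2].min():g}, {cl[:, 2].max():g}] does not "
                    f"cover GTVp z-range [{z_lo:g}, {z_hi:g}]"
                )
        if errors:
            raise ValidationError(f"patient '{self.patient_id}': " + "; ".join(errors))

    @property
    def baseline(self) -> ScanRecord:
        return next(s for s in self.scans if s.role == "baseline")

    @property
    def test_scans(self) -> list[ScanRecord]:
        return [s for s in self.scans if s.role == "test"]


# ---------------------------------------------------------------------------
# canonical JSON serialization


def _canon(obj) -> str:
    """Canonical JSON: sorted keys, floats at 6 decimals, no whitespace."""
    if isinstance(obj, dict):
        items = ", ".join(f"{json.dumps(str(k))}: {_canon(obj[k])}" for k in sorted(obj))
        return "{" + items + "}"
    if isinstance(obj, (list, tuple, np.ndarray)):
        return "[" + ", ".join(_canon(v) for v in obj) + "]"
    if isinstance(obj, (bool, np.bool_)):
        return "true" if obj else "false"
    if isinstance(obj, (int, np.integer)):
        return str(int(obj))
    if isinstance(obj, (float, np.floating)):
        if not math.isfinite(obj):
            raise SerializationError(f"non-finite value {obj!r} cannot be serialized")
        return f"{float(obj):.6f}"
    if isinstance(obj, str):
        return json.dumps(obj)
    raise SerializationError(f"cannot serialize object of type {type(obj).__name__}")


def _transform_to_dict(t: RigidTransform) -> dict:
    return {
        "rotation_deg": t.rotation_deg,
        "translation_mm": t.translation_mm,
        "center_mm": t.center_mm,
    }


def patient_to_dict(record: PatientRecord) -> dict:
    return {
        "patient_id": record.patient_id,
        "anal_verge_z_mm": float(record.anal_verge_z_mm),
        "centerline_mm": record.centerline_mm,
        "scans": [
            {
                "scan_id": s.scan_id,
                "timepoint": s.timepoint,
                "role": s.role,
                "transform_to_baseline": _transform_to_dict(s.transform_to_baseline),
                "structures": {
                    s.gtvp.name: {
                        "slices": [
                            {"z_mm": sl.z_mm, "points_mm": sl.vertices} for sl in s.gtvp.slices
                        ]
                    }
                },
            }
            for s in record.scans
        ],
    }


def write_patient(record: PatientRecord, path: str | Path) -> None:
    """Write a record in canonical form (bit-stable round trips)."""
    text = _canon(patient_to_dict(record)) + "\n"
    Path(path).write_text(text, encoding="utf-8")


def _require(mapping: dict, key: str, context: str):
    try:
        return mapping[key]
    except (KeyError, TypeError) as exc:
        raise ParseError(f"missing or malformed field '{key}' in {context}") from exc


def _parse_structure(name: str, data: dict, context: str) -> StructureSet:
    slices_raw = _require(data, "slices", context)
    slices = []
    for i, sl in enumerate(slices_raw):
        z = _require(sl, "z_mm", f"{context} slice {i}")
        pts = _require(sl, "points_mm", f"{context} slice {i}")
        slices.append(ContourSlice(float(z), np.asarray(pts, dtype=float)))
    return StructureSet(name, slices)


def read_patient(path: str | Path) -> PatientRecord:
    """Read and fully validate a patient file in the JSON dialect."""
    try:
        raw = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: not valid JSON ({exc})") from exc
    pid = _require(raw, "patient_id", "patient record")
    scans = []
    for j, sc in enumerate(_require(raw, "scans", "patient record")):
        ctx = f"scan {j}"
        tr_raw = _require(sc, "transform_to_baseline", ctx)
        transform = RigidTransform(
            np.asarray(_require(tr_raw, "rotation_deg", ctx), dtype=float),
            np.asarray(_require(tr_raw, "translation_mm", ctx), dtype=float),
            np.asarray(_require(tr_raw, "center_mm", ctx), dtype=float),
        )
        structs = _require(sc, "structures", ctx)
        if "GTVp" not in structs:
            raise ParseError(f"missing or malformed field 'GTVp' in {ctx}")
        scans.append(
            ScanRecord(
                scan_id=str(_require(sc, "scan_id", ctx)),
                timepoint=int(_require(sc, "timepoint", ctx)),
                role=str(_require(sc, "role", ctx)),
                transform_to_baseline=transform,
                gtvp=_parse_structure("GTVp", structs["GTVp"], ctx),
            )
        )
    return PatientRecord(
        patient_id=str(pid),
        anal_verge_z_mm=float(_require(raw, "anal_verge_z_mm", "patient record")),
        centerline_mm=np.asarray(_require(raw, "centerline_mm", "patient record"), dtype=float),
        scans=scans,
    )


def records_equal(a: PatientRecord, b: PatientRecord) -> bool:
    """Exact structural equality of two records (coordinates compared exactly)."""
    return _canon(patient_to_dict(a)) == _canon(patient_to_dict(b))


# ---------------------------------------------------------------------------
# DICOM RT-STRUCT ingestion (optional convenience)


def ingest_rtstruct(path: str | Path, roi_name: str) -> StructureSet:
    """Extract one ROI from a DICOM RT Structure Set as a contour stack.

    Contours must be planar (constant z per contour); coordinates are taken
    as-is in the DICOM patient (LPS) frame.  Orientation is normalized on
    construction.
    """
    import pydicom

    ds = pydicom.dcmread(str(path))
    roi_number = None
    for roi in getattr(ds, "StructureSetROISequence", []):
        if str(roi.ROIName) == roi_name:
            roi_number = roi.ROINumber
            break
    if roi_number is None:
        raise LookupError(f"ROI '{roi_name}' not found in {path}")
    slices = []
    for rc in getattr(ds, "ROIContourSequence", []):
        if rc.ReferencedROINumber != roi_number:
            continue
        for contour in getattr(rc, "ContourSequence", []):
            pts = np.asarray(contour.ContourData, dtype=float).reshape(-1, 3)
            z = pts[:, 2]
            if z.max() - z.min() > 1e-6:
                raise ValueError(
                    f"non-planar contour in ROI '{roi_name}' "
                    f"(z spread {z.max() - z.min():.2e} mm)"
                )
            slices.append(ContourSlice(float(z[0]), pts[:, :2]))
    if not slices:
        raise LookupError(f"ROI '{roi_name}' has no contours in {path}")
    slices.sort(key=lambda s: s.z_mm)
    return StructureSet(roi_name, slices)
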