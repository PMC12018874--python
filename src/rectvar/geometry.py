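"""Surface sampling, centers of mass, rigid transforms and containment.

The surface-displacement analysis operates on dense point clouds sampled
from contour stacks rather than on meshes: the BLD measure is defined
point-to-point, and point sampling sidesteps the resampling artifacts that
re-slicing transformed contours would introduce.

Sampling is area-true: each contour ring receives a number of points
proportional to the lateral band area it represents (perimeter times the
local slant height estimated from neighboring slices), so the total count
scales as (surface area)/spacing^2.  The top and bottom slices additionally
receive interior grid points ("caps") so cranio-caudal displacements at the
tumor ends are represented.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import shapely

from .structures import (
    DEFAULT_SLAB_MM,
    ContourSlice,
    RigidTransform,
    StructureSet,
    ValidationError,
)

__all__ = [
    "SurfacePointCloud",
    "Com",
    "sample_surface",
    "center_of_mass",
    "transform_points",
    "point_inside",
    "points_inside",
    "write_ply",
]


@dataclass(eq=False)
class SurfacePointCloud:
    """Dense 3D surface samples of a structure, in the baseline frame."""

    points: np.ndarray  # (N, 3)
    source_scan_id: str = ""
    nominal_spacing_mm: float = 1.0

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValidationError("point cloud must be an (N, 3) array")
        if pts.size == 0:
            raise ValidationError("point cloud is empty")
        if not np.isfinite(pts).all():
            raise ValidationError("point cloud contains non-finite coordinates")
        self.points = pts

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class Com:
    """Volume centroid of a structure (mm)."""

    point: tuple[float, float, float]

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.point, dtype=float)


def _resample_ring(vertices: np.ndarray, n: int) -> np.ndarray:
    """``n`` points at uniform arc length along the closed polygon boundary."""
    closed = np.vstack([vertices, vertices[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    perimeter = cum[-1]
    targets = np.arange(n) * perimeter / n
    idx = np.searchsorted(cum, targets, side="right") - 1
    idx = np.clip(idx, 0, len(seg) - 1)
    frac = (targets - cum[idx]) / np.where(seg[idx] > 0, seg[idx], 1.0)
    return closed[idx] + frac[:, None] * (closed[idx + 1] - closed[idx])


def _cap_grid(contour: ContourSlice, spacing: float) -> np.ndarray:
    """Interior grid points of one contour at ``spacing`` (possibly empty)."""
    poly = contour.polygon
    minx, miny, maxx, maxy = poly.bounds
    xs = np.arange(minx + spacing / 2.0, maxx, spacing)
    ys = np.arange(miny + spacing / 2.0, maxy, spacing)
    if len(xs) == 0 or len(ys) == 0:
        return np.empty((0, 2))
    gx, gy = np.meshgrid(xs, ys)
    keep = shapely.contains_xy(poly, gx.ravel(), gy.ravel())
    return np.column_stack([gx.ravel()[keep], gy.ravel()[keep]])


def sample_surface(
    structure: StructureSet,
    spacing_mm: float = 1.0,
    source_scan_id: str = "",
) -> SurfacePointCloud:
    """Sample the closed surface of a contour stack as a 3D point cloud.

    Each contour ring gets ``perimeter * slant / spacing^2`` points at
    uniform arc length, where the slant height of the band a ring represents
    is estimated from the effective radii (perimeter / 2pi) of neighboring
    slices; single-contour structures use ``slant = spacing``.  Top and
    bottom slices are additionally filled with an interior cap grid.
    """
    if spacing_mm <= 0:
        raise ValueError("spacing_mm must be positive")
    perims = np.array([s.perimeter_mm for s in structure.slices])
    if spacing_mm > perims.min():
        raise ValueError(
            f"undersampled contour: spacing {spacing_mm} mm exceeds smallest "
            f"contour perimeter {perims.min():.3f} mm"
        )
    n_slices = len(structure.slices)
    slab = structure.slice_spacing_mm
    rho = perims / (2.0 * math.pi)  # effective ring radii
    if n_slices == 1:
        slants = np.array([spacing_mm])
    else:
        slants = np.zeros(n_slices)
        half = 0.5 * np.sqrt(slab**2 + np.diff(rho) ** 2)
        slants[:-1] += half
        slants[1:] += half

    chunks = []
    for i, contour in enumerate(structure.slices):
        n = max(3, int(round(perims[i] * slants[i] / spacing_mm**2)))
        ring = _resample_ring(contour.vertices, n)
        chunks.append(np.column_stack([ring, np.full(len(ring), contour.z_mm)]))
        if i in {0, n_slices - 1}:  # set: a single slice gets one cap, not two
            cap = _cap_grid(contour, spacing_mm)
            if len(cap):
                chunks.append(np.column_stack([cap, np.full(len(cap), contour.z_mm)]))
    return SurfacePointCloud(
        np.vstack(chunks), source_scan_id=source_scan_id, nominal_spacing_mm=spacing_mm
    )


def center_of_mass(structure: StructureSet) -> Com:
    """Volume centroid from slice-wise polygon areas and centroids.

    Each slice contributes weight area*slab at its own z; in-plane centroids
    come from the shoelace formulas (via shapely).  Constant slab cancels in
    the weighted mean but is kept for clarity.
    """
    slab = structure.slice_spacing_mm
    areas, cx, cy, cz = [], [], [], []
    for s in structure.slices:
        poly = s.polygon
        areas.append(poly.area)
        c = poly.centroid
        cx.append(c.x)
        cy.append(c.y)
        cz.append(s.z_mm)
    areas = np.asarray(areas)
    w = areas * slab
    if w.sum() <= 0:
        raise ValidationError(f"structure '{structure.name}' has zero volume")
    w = w / w.sum()
    return Com((float(w @ cx), float(w @ cy), float(w @ cz)))


def transform_points(points: np.ndarray, transform: RigidTransform) -> np.ndarray:
    """Apply p -> R(p - c) + c + t to an (N, 3) array (or a single point)."""
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    if transform.is_identity:
        out = pts.copy()
    else:
        c = transform.center_mm
        out = (pts - c) @ transform.matrix.T + c + transform.translation_mm
    return out[0] if single else out


def points_inside(structure: StructureSet, query: np.ndarray) -> np.ndarray:
    """Vectorized strict containment test for an (N, 3) array of points.

    A point is inside iff its z lies within [z_min - slab/2, z_max + slab/2]
    and its (x, y) projection falls strictly inside the contour polygon of
    the nearest slice.  Boundary points classify as outside.
    """
    pts = np.atleast_2d(np.asarray(query, dtype=float))
    z = structure.z_values
    slab = structure.slice_spacing_mm
    inside = (pts[:, 2] >= z[0] - slab / 2.0) & (pts[:, 2] <= z[-1] + slab / 2.0)
    if not inside.any():
        return inside
    # nearest slice per query point
    idx = np.searchsorted(z, pts[:, 2])
    idx = np.clip(idx, 1, len(z) - 1) if len(z) > 1 else np.zeros(len(pts), dtype=int)
    if len(z) > 1:
        left_closer = (pts[:, 2] - z[idx - 1]) <= (z[idx] - pts[:, 2])
        idx = np.where(left_closer, idx - 1, idx)
    for i in np.unique(idx[inside]):
        sel = inside & (idx == i)
        poly = structure.slices[i].polygon
        inside[sel] = shapely.contains_xy(poly, pts[sel, 0], pts[sel, 1])
    return inside


def point_inside(structure: StructureSet, query) -> bool:
    """Scalar version of :func:`points_inside`."""
    return bool(points_inside(structure, np.asarray(query, dtype=float))[0])


def write_ply(cloud: SurfacePointCloud, path: str | Path, scalars: dict | None = None) -> None:
    """ASCII PLY export with optional per-point scalar channels."""
    scalars = scalars or {}
    n = len(cloud)
    for name, values in scalars.items():
        if len(values) != n:
            raise ValueError(f"scalar channel '{name}' has wrong length")
    header = ["ply", "format ascii 1.0", f"element vertex {n}"]
    header += [f"property float {ax}" for ax in "xyz"]
    header += [f"property float {name}" for name in scalars]
    header += ["end_header"]
    cols = [cloud.points] + [np.asarray(v, dtype=float)[:, None] for v in scalars.values()]
    data = np.hstack(cols)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(header) + "\n")
        np.savetxt(fh, data, fmt="%.6f")
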