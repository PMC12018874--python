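"""Shared geometric fixtures: analytic shapes with known properties."""

import numpy as np
import pytest

from rectvar.structures import (
    ContourSlice,
    PatientRecord,
    RigidTransform,
    ScanRecord,
    StructureSet,
)


def circle(radius, n=96, center=(0.0, 0.0)):
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return np.column_stack([center[0] + radius * np.cos(t), center[1] + radius * np.sin(t)])


def square(half, center=(0.0, 0.0)):
    cx, cy = center
    return np.array(
        [[cx - half, cy - half], [cx + half, cy - half], [cx + half, cy + half], [cx - half, cy + half]]
    )


def make_sphere(radius, slab=1.5, n=96, z0=0.0, min_rho=2.0):
    """Sphere discretized as circular contour slices on a regular z grid."""
    zs = np.arange(-radius + slab / 2.0, radius, slab)
    slices = []
    for z in zs:
        rho = np.sqrt(max(radius * radius - z * z, 0.0))
        if rho < min_rho:
            continue
        slices.append(ContourSlice(z + z0, circle(rho, n)))
    return StructureSet("GTVp", slices)


def make_blob(seed=0, n_slices=9, slab=1.5):
    """Irregular star-shaped structure for oracle comparisons."""
    rng = np.random.default_rng(seed)
    amp = rng.uniform(0.05, 0.2, 4)
    phase = rng.uniform(0, 2 * np.pi, 4)
    slices = []
    for i in range(n_slices):
        z = i * slab
        env = np.sin(np.pi * (i + 0.5) / n_slices)
        t = np.linspace(0, 2 * np.pi, 80, endpoint=False)
        r = 8.0 * (0.5 + env) * (1 + sum(a * np.sin((k + 2) * t + p) for k, (a, p) in enumerate(zip(amp, phase))))
        slices.append(ContourSlice(z, np.column_stack([r * np.cos(t), r * np.sin(t)])))
    return StructureSet("GTVp", slices)


@pytest.fixture
def square_stack():
    """2x2 squares centered at (1, 2) on z = 0..4: COM is (1, 2, 2)."""
    return StructureSet(
        "GTVp", [ContourSlice(float(z), square(1.0, (1.0, 2.0))) for z in range(5)]
    )


def make_patient(patient_id="P0", n_scans=6, shift=(0.0, 0.0, 0.0)):
    """Minimal valid patient: identical sphere on every scan (optionally shifted tests)."""
    base = make_sphere(10.0, z0=40.0, n=48)
    scans = []
    for k in range(n_scans):
        struct = base if k == 0 else base.translated(shift)
        scans.append(
            ScanRecord(
                scan_id=f"{patient_id}_S{k + 1}",
                timepoint=k + 1,
                role="baseline" if k == 0 else "test",
                transform_to_baseline=RigidTransform.identity(),
                gtvp=struct,
            )
        )
    cl_z = np.arange(-10.0, 120.0, 1.5)
    centerline = np.column_stack([np.zeros_like(cl_z), np.zeros_like(cl_z), cl_z])
    return PatientRecord(
        patient_id=patient_id, anal_verge_z_mm=0.0, centerline_mm=centerline, scans=scans
    )


def voxel_mask(structure, voxel=0.25, pad=1.0):
    """Independent voxelization oracle built on matplotlib's point-in-path.

    Returns (mask, xs, ys, zs): per-slice rasterization of the contour
    polygons on a regular grid; each slice's mask spans the slab around it.
    """
    from matplotlib.path import Path

    verts_all = np.vstack([s.vertices for s in structure.slices])
    x0, y0 = verts_all.min(axis=0) - pad
    x1, y1 = verts_all.max(axis=0) + pad
    xs = np.arange(x0, x1, voxel)
    ys = np.arange(y0, y1, voxel)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    zs = structure.z_values
    mask = np.zeros((len(xs), len(ys), len(zs)), dtype=bool)
    for i, s in enumerate(structure.slices):
        mask[:, :, i] = Path(s.vertices).contains_points(pts).reshape(len(xs), len(ys))
    return mask, xs, ys, zs
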