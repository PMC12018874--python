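"""Synthetic cohorts with known motion structure for pipeline validation.

Real repeat-MRI delineations of rectal tumors are not publicly shareable,
so validation runs on generated cohorts that reproduce the statistical
structure the analysis assumes:

* a wall-hugging tumor (crescent-shaped axial cross section on a tubular
  rectum of radius ~15 mm, straight centerline along +z, anal verge at
  z = 0), discretized as contour slices on a 1.5 mm grid;
* per-patient systematic offsets s_p ~ N(0, Sigma_true), per-scan random
  offsets r_pk ~ N(0, sigma_true) and a constant group-mean drift gm_true,
  applied as rigid shifts per direction (RL, AP, CC);
* optional local deformations: a lobulated "breathing" mode - radial
  surface displacement d(theta, z) = A sin(m theta + phi) g(z) with a
  Gaussian axial profile g - whose angular mode m >= 2 makes it
  volume-balanced, so the COM stays essentially still while surface crests
  move in and out by the full amplitude.  The lobe phase and axial center
  persist per patient (a deforming region), the amplitude jitters per
  scan - the regime in which COM-based analysis underestimates local
  deformation.

Offsets are quantized to 1e-3 mm (micron-level motion is far below
delineation precision) so canonical 6-decimal serialization can never
perturb the constant-slice-spacing invariant.  Every patient draws from an
independent seeded stream, so growing the cohort never reshuffles earlier
patients.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .structures import (
    ContourSlice,
    PatientRecord,
    RigidTransform,
    ScanRecord,
    StructureSet,
    write_patient,
)

__all__ = [
    "CohortConfig",
    "PatientTruth",
    "GroundTruth",
    "generate_patient",
    "generate_cohort",
    "make_study_like_cohort",
    "study_like_config",
]

_SLICE_GRID_MM = 1.5  # axial discretization grid (isotropic acquisition)


@dataclass
class CohortConfig:
    """All knobs of the generator; the defaults are the study conditions."""

    seed: int
    n_patients: int = 16
    n_test_scans: int = 5
    # true error structure per direction (rl, ap, cc), mm
    Sigma_true_mm: tuple[float, float, float] = (1.3, 1.7, 2.0)
    sigma_true_mm: tuple[float, float, float] = (1.2, 2.1, 2.2)
    gm_true_mm: tuple[float, float, float] = (0.5, -0.3, -0.3)
    # local deformation (0 amplitude disables): sinusoidal lobulation with
    # deform_lobes angular periods and a Gaussian axial profile
    deform_amplitude_mm: float = 0.0
    deform_lobes: int = 3
    deform_axial_sigma_mm: float = 30.0
    # tumor geometry (ranges sampled per patient; one size draw couples them
    # so small tumors are small in every dimension)
    height_range_mm: tuple[float, float] = (36.0, 66.0)  # cranio-caudal extent
    angular_extent_deg: tuple[float, float] = (280.0, 320.0)
    wall_thickness_mm: tuple[float, float] = (12.0, 16.0)
    extramural_bulge_mm: tuple[float, float] = (3.0, 5.5)
    # surface irregularity: relative radial ripple of the outer wall
    # (advanced tumors present wrinkled, lobulated surfaces)
    ripple_amp: tuple[float, float] = (0.14, 0.17)
    ripple_lobes: tuple[int, int] = (13, 16)
    # distal tumor border (clinical location convention): low tumors ladder
    # over this CAX range, mid tumors start above 52 mm
    low_distal_range_mm: tuple[float, float] = (8.0, 50.0)
    mid_distal_range_mm: tuple[float, float] = (55.0, 85.0)
    max_tumor_top_mm: float = 122.0
    low_fraction: float = 13.0 / 16.0  # fraction of tumors located low
    # rectum geometry
    rectum_length_mm: float = 130.0
    rectum_radius_mm: float = 15.0
    # surface sampling
    spacing_mm: float = 1.0
    # validation mode: match the empirical moments of the drawn offsets
    # exactly to (gm, Sigma, sigma) so parameter recovery tests isolate
    # pipeline error from Monte-Carlo error
    moment_match: bool = False

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory (no implicit entropy)")
        for name in ("Sigma_true_mm", "sigma_true_mm"):
            if min(getattr(self, name)) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_test_scans < 2:
            raise ValueError("need >=2 test scans")


@dataclass
class PatientTruth:
    """The draws behind one generated patient."""

    patient_id: str
    systematic_mm: list  # (3,)
    random_mm: list  # (n_test, 3)
    center_cax_mm: float
    height_mm: float
    angular_center_deg: float
    angular_extent_deg: float
    thickness_mm: float
    location: str  # "low" | "mid"
    deformation: dict  # lobe phase / axial center, or {}


@dataclass
class GroundTruth:
    """Cohort manifest: all draws plus the analytic expected errors."""

    config: dict
    patients: list
    expected_errors: dict  # per direction: Sigma, sigma, gm (the true values)


def _quantize(x: np.ndarray) -> np.ndarray:
    return np.round(np.asarray(x, dtype=float), 3)


def _crescent(
    theta_c_deg: float,
    half_w_deg: float,
    thickness: float,
    radius: float,
    bulge: float = 2.0,
    ripple: tuple[float, int, float] = (0.0, 0, 0.0),
    step_deg: float = 1.5,
) -> np.ndarray:
    """Crescent polygon (CCW): outer arc at radius+bulge, inner at radius-thickness.

    Angles follow the reference convention (0 = anterior, + toward patient
    left): (x, y) = r (sin t, -cos t).  ``ripple = (amplitude, lobes,
    phase)`` modulates the outer radius, emulating a lobulated tumor wall.
    """
    n_arc = max(int(round(2.0 * half_w_deg / step_deg)) + 1, 5)
    t = np.deg2rad(np.linspace(theta_c_deg - half_w_deg, theta_c_deg + half_w_deg, n_arc))
    amp, lobes, phase = ripple
    r_out = (radius + bulge) * (1.0 + amp * np.sin(lobes * t + phase))
    r_in = max(radius - thickness, 2.0)
    outer = np.column_stack([r_out * np.sin(t), -r_out * np.cos(t)])
    inner = np.column_stack([r_in * np.sin(t[::-1]), -r_in * np.cos(t[::-1])])
    return np.vstack([outer, inner])


def _outward_normals(vertices: np.ndarray) -> np.ndarray:
    """Per-vertex outward unit normals of a CCW polygon."""
    prev = np.roll(vertices, 1, axis=0)
    nxt = np.roll(vertices, -1, axis=0)
    edges = nxt - prev  # central-difference tangent
    normals = np.column_stack([edges[:, 1], -edges[:, 0]])  # CCW -> outward
    norm = np.linalg.norm(normals, axis=1, keepdims=True)
    return normals / np.where(norm > 0, norm, 1.0)


def _tumor_slices(
    z_lo: float,
    z_hi: float,
    theta_c: float,
    half_w: float,
    thickness: float,
    radius: float,
    bulge: float = 2.0,
    ripple_amp: float = 0.0,
    ripple_lobes: int = 0,
    ripple_phase0: float = 0.0,
) -> list[ContourSlice]:
    """Baseline contour stack: crescent cross sections with tapered ends.

    The ripple phase drifts slowly with z so the lobulation is genuinely
    three-dimensional rather than a prism.
    """
    z_grid = np.arange(
        math.ceil(z_lo / _SLICE_GRID_MM) * _SLICE_GRID_MM, z_hi + 1e-9, _SLICE_GRID_MM
    )
    zc, h = 0.5 * (z_lo + z_hi), z_hi - z_lo
    slices = []
    for z in z_grid:
        u = np.clip(2.0 * (z - zc) / h, -1.0, 1.0)
        env = math.sqrt(max(1.0 - u * u, 0.15))
        verts = _crescent(
            theta_c,
            half_w * env,
            thickness * (0.4 + 0.6 * env),
            radius,
            bulge=bulge,
            ripple=(ripple_amp * env, ripple_lobes, ripple_phase0 + 0.12 * z),
        )
        slices.append(ContourSlice(float(z), verts))
    return slices


def _apply_deformation(
    slices: list[ContourSlice],
    amplitude: float,
    lobes: int,
    phase: float,
    z_center: float,
    axial_sigma: float,
) -> list[ContourSlice]:
    """Lobulated radial deformation: d = A sin(lobes*theta + phase) g(z).

    Displacement is radial about the rectal axis, oriented by the local
    outward polygon normal (wall-side surface bulges away from the axis,
    lumen-facing surface toward it), with a Gaussian axial profile g
    centered at ``z_center``.  For lobes >= 2 the in/out crests balance,
    so tumor volume and COM are nearly unchanged while surface points move
    by up to the full amplitude.  Radial motion keeps the crescent
    star-shaped about the axis, so contours remain simple polygons.
    """
    out = []
    for s in slices:
        verts = s.vertices.copy()
        theta = np.arctan2(verts[:, 0], -verts[:, 1])  # 0 = anterior
        g = math.exp(-((s.z_mm - z_center) ** 2) / (2.0 * axial_sigma**2))
        disp = amplitude * np.sin(lobes * theta + phase) * g
        r = np.linalg.norm(verts, axis=1)
        r_hat = verts / np.where(r > 0, r, 1.0)[:, None]
        outward = np.sign((_outward_normals(verts) * r_hat).sum(axis=1))
        outward[outward == 0] = 1.0
        new_r = np.maximum(r + outward * disp, 1.0)
        out.append(ContourSlice(s.z_mm, r_hat * new_r[:, None]))
    return out


def _patient_streams(seed: int, index: int) -> tuple[np.random.Generator, ...]:
    return tuple(np.random.default_rng([seed, index, k]) for k in range(3))


def _draw_offsets(config: CohortConfig) -> tuple[np.ndarray, np.ndarray]:
    """Systematic (P, 3) and random (P, K, 3) offset draws, quantized to um.

    With ``moment_match`` the empirical cohort moments are matched exactly
    to the requested parameters: systematic draws standardized per
    direction to mean gm_true and SD Sigma_true, random draws centered and
    scaled per patient to SD sigma_true.
    """
    p, k = config.n_patients, config.n_test_scans
    sys = np.zeros((p, 3))
    rnd = np.zeros((p, k, 3))
    for i in range(p):
        _, rng_off, _ = _patient_streams(config.seed, i)
        sys[i] = rng_off.normal(0.0, config.Sigma_true_mm)
        rnd[i] = rng_off.normal(0.0, config.sigma_true_mm, size=(k, 3))
    if config.moment_match:
        sd = sys.std(axis=0, ddof=1)
        sys = (sys - sys.mean(axis=0)) / np.where(sd > 0, sd, 1.0) * np.asarray(
            config.Sigma_true_mm
        )
        rnd = rnd - rnd.mean(axis=1, keepdims=True)
        rsd = rnd.std(axis=1, ddof=1, keepdims=True)
        rnd = rnd / np.where(rsd > 0, rsd, 1.0) * np.asarray(config.sigma_true_mm)
    sys = sys + np.asarray(config.gm_true_mm)
    return _quantize(sys), _quantize(rnd)


def _patient_geometry(config: CohortConfig, index: int, rng: np.random.Generator) -> dict:
    """Per-patient tumor geometry draw.

    Distal tumor borders follow a deterministic ladder over the configured
    CAX range (with small seeded jitter), and tumor height grows with the
    ladder position.  The lowest tumor is the shortest, so its cranial end
    stays below the distal border of the highest low tumor: no reference
    slice is covered by every patient, which spreads cohort occupancy the
    way mixed tumor locations do in practice.  Location labels use the
    clinical convention (distance of the distal border from the anal
    verge): low <= 51 mm, mid above.
    """
    n = config.n_patients
    n_low = int(round(config.low_fraction * n))
    d_lo, d_hi = config.low_distal_range_mm
    if index < n_low:
        frac = index / max(n_low - 1, 1)
        distal = d_lo + frac * (d_hi - d_lo)
        size = frac
    else:
        j = index - n_low
        m_lo, m_hi = config.mid_distal_range_mm
        distal = m_lo + (m_hi - m_lo) * j / max(n - n_low - 1, 1)
        size = rng.uniform(0.4, 1.0)
    distal += rng.uniform(-0.5, 0.5)

    def _lerp(rng_pair):
        lo_v, hi_v = rng_pair
        return lo_v + size * (hi_v - lo_v)

    height = _lerp(config.height_range_mm) + rng.uniform(-1.0, 1.0)
    z_lo = max(distal, 4.0)
    z_hi = min(z_lo + height, config.max_tumor_top_mm)
    if z_hi > config.rectum_length_mm - 6.0 or z_hi - z_lo < 10.0:
        raise ValueError(f"patient {index}: tumor geometry leaves the reference CAX range")
    return {
        "center_cax_mm": 0.5 * (z_lo + z_hi),
        "z_lo": z_lo,
        "z_hi": z_hi,
        "theta_c": rng.uniform(0.0, 360.0),
        "half_w": _lerp(config.angular_extent_deg) / 2.0,
        "thickness": _lerp(config.wall_thickness_mm),
        "bulge": _lerp(config.extramural_bulge_mm),
        "ripple_amp": rng.uniform(*config.ripple_amp),
        "ripple_lobes": int(rng.integers(config.ripple_lobes[0], config.ripple_lobes[1] + 1)),
        "ripple_phase0": rng.uniform(0.0, 2.0 * math.pi),
        "location": "low" if z_lo <= 51.0 else "mid",
    }


def generate_patient(
    config: CohortConfig,
    patient_index: int,
    offsets: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[PatientRecord, PatientTruth]:
    """One patient: baseline + n_test_scans rigidly shifted (and bumped) copies."""
    rng_geom, _, rng_bump = _patient_streams(config.seed, patient_index)
    if offsets is None:
        sys_all, rnd_all = _draw_offsets(config)
    else:
        sys_all, rnd_all = offsets
    s_p = sys_all[patient_index]
    r_pk = rnd_all[patient_index]

    geom = _patient_geometry(config, patient_index, rng_geom)
    base_slices = _tumor_slices(
        geom["z_lo"], geom["z_hi"], geom["theta_c"], geom["half_w"],
        geom["thickness"], config.rectum_radius_mm,
        bulge=geom["bulge"],
        ripple_amp=geom["ripple_amp"],
        ripple_lobes=geom["ripple_lobes"],
        ripple_phase0=geom["ripple_phase0"],
    )
    pid = f"P{patient_index:03d}"

    deformation: dict = {}
    if config.deform_amplitude_mm > 0 and config.deform_lobes > 0:
        deformation = {
            "phase": float(rng_bump.uniform(0.0, 2.0 * math.pi)),
            "z_center": float(rng_bump.uniform(geom["z_lo"] + 5, geom["z_hi"] - 5)),
        }

    scans = [
        ScanRecord(
            scan_id=f"{pid}_S1",
            timepoint=1,
            role="baseline",
            transform_to_baseline=RigidTransform.identity(),
            gtvp=StructureSet("GTVp", list(base_slices)),
        )
    ]
    for k in range(config.n_test_scans):
        slices = base_slices
        if deformation:
            amp = config.deform_amplitude_mm * rng_bump.uniform(0.5, 1.5)
            slices = _apply_deformation(
                slices, amp, config.deform_lobes, deformation["phase"],
                deformation["z_center"], config.deform_axial_sigma_mm,
            )
        shift = s_p + r_pk[k]
        shifted = [
            ContourSlice(s.z_mm + shift[2], s.vertices + shift[:2]) for s in slices
        ]
        scans.append(
            ScanRecord(
                scan_id=f"{pid}_S{k + 2}",
                timepoint=k + 2,
                role="test",
                transform_to_baseline=RigidTransform.identity(),
                gtvp=StructureSet("GTVp", shifted),
            )
        )
    z_pad = 15.0
    cl_z = np.arange(-z_pad, config.rectum_length_mm + z_pad + 15.0 + 1e-9, 1.5)
    centerline = np.column_stack([np.zeros_like(cl_z), np.zeros_like(cl_z), cl_z])
    record = PatientRecord(
        patient_id=pid,
        anal_verge_z_mm=0.0,
        centerline_mm=centerline,
        scans=scans,
    )
    truth = PatientTruth(
        patient_id=pid,
        systematic_mm=(s_p - np.asarray(config.gm_true_mm)).tolist(),
        random_mm=r_pk.tolist(),
        center_cax_mm=geom["center_cax_mm"],
        height_mm=geom["z_hi"] - geom["z_lo"],
        angular_center_deg=geom["theta_c"],
        angular_extent_deg=2 * geom["half_w"],
        thickness_mm=geom["thickness"],
        location=geom["location"],
        deformation=deformation,
    )
    return record, truth


def generate_cohort(
    config: CohortConfig,
    out_dir: str | Path | None = None,
    overwrite: bool = False,
) -> tuple[list[PatientRecord], GroundTruth]:
    """Generate all patients; optionally write patient files plus a manifest."""
    offsets = _draw_offsets(config)
    records, truths = [], []
    for i in range(config.n_patients):
        rec, truth = generate_patient(config, i, offsets=offsets)
        records.append(rec)
        truths.append(truth)
    manifest = GroundTruth(
        config=asdict(config),
        patients=[asdict(t) for t in truths],
        expected_errors={
            "Sigma_mm": list(config.Sigma_true_mm),
            "sigma_mm": list(config.sigma_true_mm),
            "gm_mm": list(config.gm_true_mm),
        },
    )
    if out_dir is not None:
        out = Path(out_dir)
        if out.exists() and any(out.iterdir()) and not overwrite:
            raise FileExistsError(f"output directory {out} is not empty (use overwrite)")
        out.mkdir(parents=True, exist_ok=True)
        for rec in records:
            write_patient(rec, out / f"{rec.patient_id}.json")
        (out / "ground_truth.json").write_text(
            json.dumps(asdict(manifest), indent=1, sort_keys=True), encoding="utf-8"
        )
    return records, manifest


def study_like_config(seed: int, **overrides) -> CohortConfig:
    """The 16-patient, 6-scan preset mirroring the study cohort layout.

    13 of 16 tumors are centered in the low height band and 3 in the mid
    band; tumor sizes are chosen so baseline clouds sampled at the default
    1 mm spacing land in the 7000-28000-point range.
    """
    return CohortConfig(seed=seed, **overrides)


def make_study_like_cohort(
    seed: int, out_dir: str | Path | None = None, overwrite: bool = False
) -> tuple[list[PatientRecord], GroundTruth]:
    return generate_cohort(study_like_config(seed), out_dir=out_dir, overwrite=overwrite)
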