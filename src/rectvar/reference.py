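"""Mapping patient surface statistics onto a common reference rectum.

Tumors sit at different heights and on different walls of the rectum, so
inter-patient statistics require a common spatial frame.  The reference
rectum is a straight tube along +z with circular cross sections of 120
equally spaced surface points per slice; slice positions are central-axis
(CAX) distances from the anal verge in mm.  The angular convention is
0 deg = anterior (-y), increasing counter-clockwise (viewed from cranial)
toward patient left (+x) at 90 deg.

Each patient's baseline surface points get a CAX coordinate (arc length
along the patient's rectal centerline from the anal verge to the nearest
centerline vertex), are re-expressed about the reference axis by
translating their centerline foot onto it, and are then assigned to
reference points by the reverse-nearest step of the BLD mapping.  Per
reference point and patient, the mapped points' per-point means and SDs
are averaged (so large tumors do not dominate the variance), and
inter-patient Sigma / sigma / GM maps are computed wherever at least
``min_patients`` patients contribute.

Segment summaries follow the directional halves (anterior / posterior /
left / right, 180 deg each, 60 points per slice) and three height bands
(low 28-51, mid 52-100, high 102-130 mm CAX).  Cranio-caudal statistics
use only the top and bottom slices of each baseline tumor.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bld import nearest_with_ties
from .geometry import SurfacePointCloud
from .stats import PerPointStats
from .structures import PatientRecord

__all__ = [
    "ReferenceRectum",
    "SectionScheme",
    "PatientContribution",
    "ReferencePointMap",
    "build_reference_rectum",
    "map_patient_to_reference",
    "aggregate_reference",
    "segment_summary",
    "cc_extremes",
    "reference_map_table",
]

#: quantiles reported in segment tables: (row label, q)
_SEGMENT_ROWS = (("median", 50.0), ("iqr", None), ("p95", 95.0))


@dataclass(eq=False)
class ReferenceRectum:
    """Straight tubular reference geometry (see module docstring)."""

    cax_mm: np.ndarray  # (S,) slice positions = CAX distance from anal verge
    radius_mm: float
    theta_deg: np.ndarray  # (n_points,) angular positions, 0 = anterior
    points: np.ndarray  # (S * n_points, 3)
    point_cax_mm: np.ndarray  # (S * n_points,)
    point_theta_deg: np.ndarray  # (S * n_points,)

    @property
    def n_slices(self) -> int:
        return len(self.cax_mm)

    @property
    def n_points_per_slice(self) -> int:
        return len(self.theta_deg)

    @property
    def slice_spacing_mm(self) -> float:
        return float(self.cax_mm[1] - self.cax_mm[0])


def build_reference_rectum(
    length_mm: float = 130.0,
    slice_spacing_mm: float = 1.5,
    radius_mm: float = 15.0,
    n_points: int = 120,
) -> ReferenceRectum:
    """Deterministic reference tube: floor(length/spacing)+1 slices x n_points."""
    if length_mm <= 0 or slice_spacing_mm <= 0 or radius_mm <= 0 or n_points < 3:
        raise ValueError("reference rectum dimensions must be positive")
    n_slices = int(math.floor(length_mm / slice_spacing_mm)) + 1
    cax = np.arange(n_slices) * slice_spacing_mm
    theta = np.arange(n_points) * (360.0 / n_points)
    rad = np.deg2rad(theta)
    # 0 deg anterior (-y), +90 deg patient left (+x)
    ring = radius_mm * np.column_stack([np.sin(rad), -np.cos(rad)])
    pts = np.column_stack(
        [
            np.tile(ring, (n_slices, 1)),
            np.repeat(cax, n_points)[:, None],
        ]
    )
    return ReferenceRectum(
        cax_mm=cax,
        radius_mm=float(radius_mm),
        theta_deg=theta,
        points=pts,
        point_cax_mm=np.repeat(cax, n_points),
        point_theta_deg=np.tile(theta, n_slices),
    )


@dataclass(eq=False)
class SectionScheme:
    """Directional 180-degree halves and CAX height bands (mm)."""

    height_bands: dict = field(
        default_factory=lambda: {"low": (28.0, 51.0), "mid": (52.0, 100.0), "high": (102.0, 130.0)}
    )

    #: directional half -> (center angle deg, signed component used)
    HALVES = {
        "anterior": (0.0, "ap"),
        "left": (90.0, "rl"),
        "posterior": (180.0, "ap"),
        "right": (270.0, "rl"),
    }

    def half_mask(self, theta_deg: np.ndarray, half: str) -> np.ndarray:
        """Membership of angular positions in a 180-degree half-window.

        Window is [center - 90, center + 90) so every point belongs to
        exactly two of the four halves.
        """
        center, _ = self.HALVES[half]
        delta = np.mod(theta_deg - center + 180.0, 360.0) - 180.0
        return (delta >= -90.0) & (delta < 90.0)

    def band_mask(self, cax_mm: np.ndarray, band: str) -> np.ndarray:
        lo, hi = self.height_bands[band]
        return (cax_mm >= lo) & (cax_mm <= hi)


@dataclass(eq=False)
class PatientContribution:
    """One patient's per-reference-point aggregated (mean, SD) per direction."""

    patient_id: str
    ref_index: np.ndarray  # (K,) global reference point indices, unique
    mean_mm: np.ndarray  # (K, 2) columns (rl, ap)
    sd_mm: np.ndarray  # (K, 2)
    n_points: np.ndarray  # (K,) patient surface points mapped to each ref point


def _centerline_cax(patient: PatientRecord) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative arc length of centerline vertices, zeroed at the anal verge."""
    cl = patient.centerline_mm
    seg = np.linalg.norm(np.diff(cl, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    verge_idx = int(np.argmin(np.abs(cl[:, 2] - patient.anal_verge_z_mm)))
    return cl, cum - cum[verge_idx]


def map_patient_to_reference(
    baseline_cloud: SurfacePointCloud,
    stats: PerPointStats,
    patient: PatientRecord,
    ref: ReferenceRectum,
) -> PatientContribution:
    """Assign a patient's baseline points (and stats) to reference points."""
    if len(stats) != len(baseline_cloud):
        raise ValueError("stats and baseline cloud have mismatched point counts")
    cl, cax_at_vertex = _centerline_cax(patient)
    foot_idx, _ = nearest_with_ties(cl, baseline_cloud.points)
    cax = cax_at_vertex[foot_idx]
    # re-express about the reference axis: translate each centerline foot
    # onto the axis at the same CAX coordinate
    feet = cl[foot_idx]
    shifted = baseline_cloud.points - feet
    shifted[:, 2] += cax

    lo, hi = float(cax.min()), float(cax.max())
    pad = ref.slice_spacing_mm / 2.0
    if lo < ref.cax_mm[0] - pad or hi > ref.cax_mm[-1] + pad:
        raise ValueError(
            f"tumor CAX range [{lo:.1f}, {hi:.1f}] mm outside reference range "
            f"[{ref.cax_mm[0]:.1f}, {ref.cax_mm[-1]:.1f}] mm"
        )
    slice_sel = (ref.cax_mm >= lo - pad) & (ref.cax_mm <= hi + pad)
    npts = ref.n_points_per_slice
    point_sel = np.repeat(slice_sel, npts)
    sub_points = ref.points[point_sel]
    sub_global = np.nonzero(point_sel)[0]

    # reverse-nearest step of the BLD mapping: each patient point is assigned
    # to the reference point it is nearest to
    assign, _ = nearest_with_ties(sub_points, shifted)
    global_assign = sub_global[assign]

    uniq, inverse, counts = np.unique(global_assign, return_inverse=True, return_counts=True)
    mean = np.zeros((len(uniq), 2))
    sd = np.zeros((len(uniq), 2))
    for col, dcol in enumerate((0, 1)):  # rl, ap columns of the (N, 3) stats
        np.add.at(mean[:, col], inverse, stats.mean_mm[:, dcol])
        np.add.at(sd[:, col], inverse, stats.sd_mm[:, dcol])
    mean /= counts[:, None]
    sd /= counts[:, None]
    return PatientContribution(
        patient_id=stats.patient_id,
        ref_index=uniq,
        mean_mm=mean,
        sd_mm=sd,
        n_points=counts,
    )


@dataclass(eq=False)
class ReferencePointMap:
    """Inter-patient Sigma / sigma / GM per reference point and direction."""

    ref: ReferenceRectum
    n_patients: np.ndarray  # (R,) contributing patients per point
    valid: np.ndarray  # (R,) bool, n_patients >= min_patients
    gm_mm: np.ndarray  # (R, 2) columns (rl, ap); NaN where undefined
    Sigma_mm: np.ndarray  # (R, 2)
    sigma_mm: np.ndarray  # (R, 2)
    min_patients: int


def aggregate_reference(
    contributions: list[PatientContribution],
    ref: ReferenceRectum,
    min_patients: int = 5,
) -> ReferencePointMap:
    """Inter-patient maps from per-patient contributions.

    Per reference point and direction: GM = mean over contributing patients
    of the contributed means, Sigma = their sample SD, sigma = RMS of the
    contributed SDs.  Points with fewer than ``min_patients`` contributors
    are flagged invalid and excluded from all downstream summaries.
    """
    if not contributions:
        raise ValueError("no patient contributions")
    r = len(ref.points)
    count = np.zeros(r, dtype=int)
    sum_mean = np.zeros((r, 2))
    sum_mean2 = np.zeros((r, 2))
    sum_sd2 = np.zeros((r, 2))
    for c in contributions:
        count[c.ref_index] += 1
        sum_mean[c.ref_index] += c.mean_mm
        sum_mean2[c.ref_index] += c.mean_mm**2
        sum_sd2[c.ref_index] += c.sd_mm**2
    with np.errstate(invalid="ignore", divide="ignore"):
        n = count[:, None].astype(float)
        gm = np.where(n > 0, sum_mean / np.maximum(n, 1), np.nan)
        var = (sum_mean2 - n * gm**2) / np.maximum(n - 1, 1)
        Sigma = np.where(n >= 2, np.sqrt(np.maximum(var, 0.0)), np.nan)
        sigma = np.where(n > 0, np.sqrt(sum_sd2 / np.maximum(n, 1)), np.nan)
    return ReferencePointMap(
        ref=ref,
        n_patients=count,
        valid=count >= min_patients,
        gm_mm=gm,
        Sigma_mm=Sigma,
        sigma_mm=sigma,
        min_patients=min_patients,
    )


def _quantile_rows(values: np.ndarray) -> dict[str, float]:
    out = {}
    for label, q in _SEGMENT_ROWS:
        if q is None:
            out[label] = float(np.percentile(values, 75) - np.percentile(values, 25))
        else:
            out[label] = float(np.percentile(values, q))
    return out


def segment_summary(refmap: ReferencePointMap, scheme: SectionScheme | None = None) -> pd.DataFrame:
    """Median / IQR / p95 of Sigma, sigma and GM per direction x height band.

    Left/right halves summarize the RL maps, anterior/posterior the AP maps,
    over the segment's valid reference points only.  Empty segments produce
    rows of NaNs with a warning.
    """
    scheme = scheme or SectionScheme()
    ref = refmap.ref
    rows = []
    for half, (_, comp) in SectionScheme.HALVES.items():
        col = 0 if comp == "rl" else 1
        hmask = scheme.half_mask(ref.point_theta_deg, half)
        for band in scheme.height_bands:
            mask = refmap.valid & hmask & scheme.band_mask(ref.point_cax_mm, band)
            row = {"direction": half, "band": band, "n_points": int(mask.sum())}
            if not mask.any():
                warnings.warn(f"segment {half}/{band} has no valid reference points")
                for quantity in ("Sigma", "sigma", "gm"):
                    for label, _ in _SEGMENT_ROWS:
                        row[f"{quantity}_{label}_mm"] = np.nan
            else:
                for quantity, values in (
                    ("Sigma", refmap.Sigma_mm[mask, col]),
                    ("sigma", refmap.sigma_mm[mask, col]),
                    ("gm", refmap.gm_mm[mask, col]),
                ):
                    for label, v in _quantile_rows(values).items():
                        row[f"{quantity}_{label}_mm"] = v
            rows.append(row)
    return pd.DataFrame(rows)


def cc_extremes(
    patients: list[tuple[SurfacePointCloud, PerPointStats]],
    z_tol_mm: float = 1e-6,
) -> pd.DataFrame:
    """Cranial/caudal segment rows from top- and bottom-slice CC statistics.

    Top and bottom slices of different patients sit at different heights and
    cannot be aligned pointwise on the reference geometry, so the segment
    quantiles are taken through a per-patient quantile profile: for each
    quantile q, every patient contributes the q-th percentile over its
    top (bottom) slice points of the per-point CC means and SDs, and the
    inter-patient Sigma / sigma / GM are computed at that q.  The reported
    median and p95 rows are the q=50 and q=95 profiles; the IQR row is the
    q=75 minus the q=25 profile.
    """
    if len(patients) < 2:
        raise ValueError("need >=2 patients for cranial/caudal statistics")
    rows = []
    for direction, is_top in (("cranial", True), ("caudal", False)):
        per_q: dict[float, tuple[list[float], list[float]]] = {
            25.0: ([], []), 50.0: ([], []), 75.0: ([], []), 95.0: ([], [])
        }
        n_pts = 0
        for cloud, stats in patients:
            z = cloud.points[:, 2]
            zsel = z >= z.max() - z_tol_mm if is_top else z <= z.min() + z_tol_mm
            n_pts += int(zsel.sum())
            means = stats.mean_mm[zsel, 2]
            sds = stats.sd_mm[zsel, 2]
            for q, (mq, sq) in per_q.items():
                mq.append(float(np.percentile(means, q)))
                sq.append(float(np.percentile(sds, q)))
        def _decompose(q: float) -> tuple[float, float, float]:
            m = np.asarray(per_q[q][0])
            s = np.asarray(per_q[q][1])
            return float(m.std(ddof=1)), float(np.sqrt((s**2).mean())), float(m.mean())
        profiles = {q: _decompose(q) for q in per_q}
        row = {"direction": direction, "band": "none", "n_points": n_pts}
        for i, quantity in enumerate(("Sigma", "sigma", "gm")):
            row[f"{quantity}_median_mm"] = profiles[50.0][i]
            row[f"{quantity}_iqr_mm"] = profiles[75.0][i] - profiles[25.0][i]
            row[f"{quantity}_p95_mm"] = profiles[95.0][i]
        rows.append(row)
    return pd.DataFrame(rows)


def reference_map_table(refmap: ReferencePointMap) -> pd.DataFrame:
    """Per-reference-point CSV-ready table of the inter-patient maps."""
    ref = refmap.ref
    return pd.DataFrame(
        {
            "ref_point_id": np.arange(len(ref.points)),
            "cax_mm": ref.point_cax_mm,
            "theta_deg": ref.point_theta_deg,
            "n_patients": refmap.n_patients,
            "valid": refmap.valid,
            "Sigma_rl": refmap.Sigma_mm[:, 0],
            "sigma_rl": refmap.sigma_mm[:, 0],
            "gm_rl": refmap.gm_mm[:, 0],
            "Sigma_ap": refmap.Sigma_mm[:, 1],
            "sigma_ap": refmap.sigma_mm[:, 1],
            "gm_ap": refmap.gm_mm[:, 1],
        }
    )
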