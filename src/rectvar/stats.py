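"""Per-point, per-patient and population statistics (Van Herk decomposition).

Directions are ordered (RL, AP, CC) throughout, matching the signed x/y/z
displacement components.  Conventions, fixed package-wide:

* percentile: linear interpolation between order statistics
  (h = 1 + (n-1) q/100); median = p50, IQR = p75 - p25;
* SD: sample standard deviation (n-1 denominator) at both the patient and
  the population level;
* population ("Van Herk") decomposition over patients p with per-patient
  per-direction mean m_p and SD s_p:
  GM = mean_p(m_p),  Sigma = SD_p(m_p),  sigma = sqrt(mean_p(s_p^2)).

The surface method summarizes each patient by the 95th percentile over
baseline surface points of the per-point means and of the per-point SDs
across that patient's test scans ("point-mean-p95" mode).  An alternative
reading - per-scan 95th percentile first, then moments across scans - is
available as "scan-p95-moments" for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bld import ComDisplacement, DisplacementField

__all__ = [
    "DIRECTIONS",
    "percentile",
    "iqr",
    "PerPointStats",
    "per_point_stats",
    "PatientSummary",
    "patient_summary_surface",
    "patient_summary_com",
    "PopulationErrors",
    "population_errors",
    "population_table",
]

DIRECTIONS = ("rl", "ap", "cc")

SURFACE_MODES = ("point-mean-p95", "scan-p95-moments")


def percentile(values, q: float) -> float:
    """q-th percentile with linear interpolation between order statistics."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("percentile of empty input")
    return float(np.percentile(arr, q))


def iqr(values) -> float:
    return percentile(values, 75) - percentile(values, 25)


@dataclass(eq=False)
class PerPointStats:
    """Per baseline point, per direction: mean and SD across test scans."""

    mean_mm: np.ndarray  # (N, 3)
    sd_mm: np.ndarray  # (N, 3)
    n_test: int
    patient_id: str = ""

    def __len__(self) -> int:
        return len(self.mean_mm)


def per_point_stats(fields: list[DisplacementField], patient_id: str = "") -> PerPointStats:
    """Pointwise mean and sample SD of signed displacements across scans."""
    if len(fields) < 2:
        raise ValueError("need >=2 displacement fields for per-point statistics")
    sizes = {len(f) for f in fields}
    if len(sizes) != 1:
        raise ValueError(f"fields have mismatched point counts: {sorted(sizes)}")
    for f in fields:
        if f.signed_mm is None:
            raise ValueError("fields must be signed (run sign_components first)")
    stack = np.stack([f.signed_mm for f in fields])  # (K, N, 3)
    return PerPointStats(
        mean_mm=stack.mean(axis=0),
        sd_mm=stack.std(axis=0, ddof=1),
        n_test=len(fields),
        patient_id=patient_id,
    )


@dataclass(eq=False)
class PatientSummary:
    """Per-patient, per-direction scalars feeding the population statistics.

    ``mean_mm``/``sd_mm`` are the Van Herk inputs (COM: mean/SD of the scan
    shifts; surface: 95th percentile over points of per-point means/SDs).
    ``median_mm``/``iqr_mm``/``p95_mm`` summarize the pooled signed
    displacement distribution per direction.
    """

    patient_id: str
    method: str  # "com" | "surface_p95"
    mean_mm: np.ndarray  # (3,)
    sd_mm: np.ndarray  # (3,)
    median_mm: np.ndarray  # (3,)
    iqr_mm: np.ndarray  # (3,)
    p95_mm: np.ndarray  # (3,)


def patient_summary_surface(
    stats: PerPointStats,
    pooled: np.ndarray,
    q: float = 95.0,
    mode: str = "point-mean-p95",
    patient_id: str = "",
) -> PatientSummary:
    """Summarize one patient's surface displacement distribution.

    ``pooled`` is the (K, N, 3) stack (or (M, 3) pool) of all signed
    displacements over the patient's test scans, used for the global
    median/IQR/p95 rows.
    """
    pooled = np.asarray(pooled, dtype=float).reshape(-1, 3)
    if mode == "point-mean-p95":
        mean = np.percentile(stats.mean_mm, q, axis=0)
        sd = np.percentile(stats.sd_mm, q, axis=0)
    elif mode == "scan-p95-moments":
        # per-scan q-th percentile per direction, then moments across scans
        k, n = stats.n_test, len(stats)
        per_scan = np.percentile(pooled.reshape(k, n, 3), q, axis=1)  # (K, 3)
        mean = per_scan.mean(axis=0)
        sd = per_scan.std(axis=0, ddof=1)
    else:
        raise ValueError(f"unknown surface summary mode '{mode}'; choose from {SURFACE_MODES}")
    return PatientSummary(
        patient_id=patient_id or stats.patient_id,
        method="surface_p95",
        mean_mm=np.asarray(mean, dtype=float),
        sd_mm=np.asarray(sd, dtype=float),
        median_mm=np.percentile(pooled, 50, axis=0),
        iqr_mm=np.percentile(pooled, 75, axis=0) - np.percentile(pooled, 25, axis=0),
        p95_mm=np.percentile(pooled, 95, axis=0),
    )


def patient_summary_com(
    shifts: list[ComDisplacement], patient_id: str = ""
) -> PatientSummary:
    """Mean and sample SD of the per-scan COM shifts, per direction."""
    if len(shifts) < 2:
        raise ValueError("need >=2 COM displacements for a patient summary")
    arr = np.stack([s.array for s in shifts])  # (K, 3)
    return PatientSummary(
        patient_id=patient_id,
        method="com",
        mean_mm=arr.mean(axis=0),
        sd_mm=arr.std(axis=0, ddof=1),
        median_mm=np.percentile(arr, 50, axis=0),
        iqr_mm=np.percentile(arr, 75, axis=0) - np.percentile(arr, 25, axis=0),
        p95_mm=np.percentile(arr, 95, axis=0),
    )


@dataclass(eq=False)
class PopulationErrors:
    """Systematic (Sigma), random (sigma) and group-mean errors per direction."""

    method: str
    Sigma_mm: np.ndarray  # (3,)
    sigma_mm: np.ndarray  # (3,)
    gm_mm: np.ndarray  # (3,)
    n_patients: int


def population_errors(summaries: list[PatientSummary]) -> PopulationErrors:
    """Van Herk decomposition over a cohort of patient summaries."""
    if len(summaries) < 2:
        raise ValueError("need >=2 patients for population errors")
    methods = {s.method for s in summaries}
    if len(methods) != 1:
        raise ValueError(f"summaries mix methods: {sorted(methods)}")
    means = np.stack([s.mean_mm for s in summaries])  # (P, 3)
    sds = np.stack([s.sd_mm for s in summaries])
    return PopulationErrors(
        method=methods.pop(),
        Sigma_mm=means.std(axis=0, ddof=1),
        sigma_mm=np.sqrt((sds**2).mean(axis=0)),
        gm_mm=means.mean(axis=0),
        n_patients=len(summaries),
    )


def population_table(errors: list[PopulationErrors]) -> pd.DataFrame:
    """Long-form population-error table: one row per method x direction."""
    rows = []
    for e in errors:
        for d, direction in enumerate(DIRECTIONS):
            rows.append(
                {
                    "method": e.method,
                    "direction": direction,
                    "Sigma_mm": e.Sigma_mm[d],
                    "sigma_mm": e.sigma_mm[d],
                    "gm_mm": e.gm_mm[d],
                    "n_patients": e.n_patients,
                }
            )
    return pd.DataFrame(rows)
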