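"""End-to-end orchestration: per-patient analysis and cohort aggregation.

``analyze_patient`` runs both quantification paths for one patient:

* COM path: volume centroid of each test GTVp, transformed to the baseline
  frame, minus the baseline centroid;
* surface path: BLD displacement field from the baseline surface cloud to
  each (transformed) test cloud, signed, then per-point mean/SD across
  scans and the 95th-percentile patient summary.

``aggregate_cohort`` turns per-patient results into population errors
(both methods), the inter-patient reference-rectum maps and the segment
tables.  All analysis stages are deterministic; randomness lives only in
the simulator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import bld, geometry, reference, stats
from .structures import PatientRecord

__all__ = ["PatientAnalysis", "CohortResults", "analyze_patient", "aggregate_cohort"]

log = logging.getLogger("rectvar")


@dataclass(eq=False)
class PatientAnalysis:
    """Everything aggregation needs from one patient."""

    record: PatientRecord
    baseline_cloud: geometry.SurfacePointCloud
    com_shifts: list[bld.ComDisplacement]
    point_stats: stats.PerPointStats
    com_summary: stats.PatientSummary
    surface_summary: stats.PatientSummary


def analyze_patient(
    record: PatientRecord,
    spacing_mm: float = 1.0,
    surface_mode: str = "point-mean-p95",
    percentile_q: float = 95.0,
) -> PatientAnalysis:
    baseline = record.baseline
    base_struct = baseline.gtvp
    base_cloud = geometry.sample_surface(base_struct, spacing_mm, baseline.scan_id)
    base_com = geometry.center_of_mass(base_struct)

    shifts: list[bld.ComDisplacement] = []
    fields: list[bld.DisplacementField] = []
    for scan in record.test_scans:
        tr = scan.transform_to_baseline
        test_cloud = geometry.sample_surface(scan.gtvp, spacing_mm, scan.scan_id)
        if not tr.is_identity:
            test_cloud = geometry.SurfacePointCloud(
                geometry.transform_points(test_cloud.points, tr),
                source_scan_id=scan.scan_id,
                nominal_spacing_mm=spacing_mm,
            )
        test_com_pt = geometry.transform_points(
            geometry.center_of_mass(scan.gtvp).array, tr
        )
        shifts.append(
            bld.com_displacement(base_com, geometry.Com(tuple(test_com_pt)), scan.scan_id)
        )
        f = bld.bld_map(base_cloud, test_cloud)
        fields.append(bld.sign_components(f, base_struct, base_com))

    point_stats = stats.per_point_stats(fields, patient_id=record.patient_id)
    pooled = np.stack([f.signed_mm for f in fields])
    return PatientAnalysis(
        record=record,
        baseline_cloud=base_cloud,
        com_shifts=shifts,
        point_stats=point_stats,
        com_summary=stats.patient_summary_com(shifts, patient_id=record.patient_id),
        surface_summary=stats.patient_summary_surface(
            point_stats, pooled, q=percentile_q, mode=surface_mode,
            patient_id=record.patient_id,
        ),
    )


@dataclass(eq=False)
class CohortResults:
    """Population-level outputs of a cohort run."""

    com_errors: stats.PopulationErrors
    surface_errors: stats.PopulationErrors
    population_table: pd.DataFrame
    patient_table: pd.DataFrame
    refmap: reference.ReferencePointMap
    reference_table: pd.DataFrame
    segment_table: pd.DataFrame  # directional x height bands plus cranial/caudal


def _patient_table(analyses: list[PatientAnalysis]) -> pd.DataFrame:
    rows = []
    for a in analyses:
        for summary in (a.com_summary, a.surface_summary):
            row = {"patient_id": summary.patient_id, "method": summary.method}
            for d, direction in enumerate(stats.DIRECTIONS):
                for name in ("mean", "sd", "median", "iqr", "p95"):
                    row[f"{name}_{direction}_mm"] = getattr(summary, f"{name}_mm")[d]
            rows.append(row)
    return pd.DataFrame(rows)


def aggregate_cohort(
    analyses: list[PatientAnalysis],
    min_patients: int = 5,
    ref_length_mm: float = 130.0,
    ref_spacing_mm: float = 1.5,
    ref_radius_mm: float = 15.0,
    scheme: reference.SectionScheme | None = None,
) -> CohortResults:
    if len(analyses) < 2:
        raise ValueError("need >=2 analyzed patients to aggregate")
    com_errors = stats.population_errors([a.com_summary for a in analyses])
    surface_errors = stats.population_errors([a.surface_summary for a in analyses])

    ref = reference.build_reference_rectum(ref_length_mm, ref_spacing_mm, ref_radius_mm)
    contributions = [
        reference.map_patient_to_reference(a.baseline_cloud, a.point_stats, a.record, ref)
        for a in analyses
    ]
    refmap = reference.aggregate_reference(contributions, ref, min_patients=min_patients)
    segments = reference.segment_summary(refmap, scheme)
    cc = reference.cc_extremes([(a.baseline_cloud, a.point_stats) for a in analyses])
    return CohortResults(
        com_errors=com_errors,
        surface_errors=surface_errors,
        population_table=stats.population_table([com_errors, surface_errors]),
        patient_table=_patient_table(analyses),
        refmap=refmap,
        reference_table=reference.reference_map_table(refmap),
        segment_table=pd.concat([segments, cc], ignore_index=True),
    )
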