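"""Reference-rectum construction, patient mapping, aggregation, segments."""

import numpy as np
import pandas as pd
import pytest

from rectvar.geometry import SurfacePointCloud, sample_surface
from rectvar.reference import (
    PatientContribution,
    SectionScheme,
    aggregate_reference,
    build_reference_rectum,
    cc_extremes,
    map_patient_to_reference,
    segment_summary,
)
from rectvar.stats import PerPointStats

from conftest import make_patient


@pytest.fixture(scope="module")
def ref():
    return build_reference_rectum(130.0, 1.5, 15.0)


class TestBuildReference:
    def test_slice_and_point_counts(self, ref):
        assert ref.n_slices == 87  # floor(130/1.5) + 1
        assert ref.n_points_per_slice == 120
        assert len(ref.points) == 87 * 120

    def test_angle_conventions(self, ref):
        ring = ref.points[:120]
        assert ring[0, 1] < 0  # k=0 anterior (-y)
        assert ring[30, 0] > 0  # k=30 patient left (+x)
        assert np.allclose(np.linalg.norm(ring[:, :2], axis=1), 15.0)

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ValueError):
            build_reference_rectum(-1.0)


class TestSectionScheme:
    def test_halves_have_sixty_points_each(self, ref):
        scheme = SectionScheme()
        theta = ref.theta_deg
        for half in SectionScheme.HALVES:
            assert scheme.half_mask(theta, half).sum() == 60

    def test_each_point_in_exactly_two_halves(self, ref):
        scheme = SectionScheme()
        counts = sum(
            scheme.half_mask(ref.theta_deg, h).astype(int) for h in SectionScheme.HALVES
        )
        assert np.all(counts == 2)

    def test_height_bands_disjoint(self, ref):
        scheme = SectionScheme()
        total = sum(
            scheme.band_mask(ref.cax_mm, b).astype(int) for b in scheme.height_bands
        )
        assert total.max() <= 1


def stats_for(cloud, mean=1.0, sd=0.5):
    n = len(cloud)
    return PerPointStats(
        mean_mm=np.full((n, 3), mean), sd_mm=np.full((n, 3), sd), n_test=5, patient_id="p"
    )


class TestMapPatient:
    def test_phantom_on_reference_surface_maps_identically(self, ref):
        """Points taken from the reference surface map to themselves (distance 0)."""
        sel = slice(20 * 120, 30 * 120)  # slices 20..29
        cloud = SurfacePointCloud(ref.points[sel].copy(), "ph", 1.0)
        patient = make_patient()
        contrib = map_patient_to_reference(cloud, stats_for(cloud), patient, ref)
        assert np.array_equal(np.sort(contrib.ref_index), np.arange(sel.start, sel.stop))
        assert np.all(contrib.n_points == 1)

    def test_band_landing_by_construction(self, ref):
        """A tumor centered at CAX 60 contributes only inside the mid band."""
        from conftest import make_sphere

        struct = make_sphere(7.0, z0=60.0, n=48)
        cloud = sample_surface(struct, 1.5)
        patient = make_patient()
        contrib = map_patient_to_reference(cloud, stats_for(cloud), patient, ref)
        cax = ref.point_cax_mm[contrib.ref_index]
        assert cax.min() >= 52.0 and cax.max() <= 100.0

    def test_contribution_mass_conserved(self, ref):
        from conftest import make_sphere

        struct = make_sphere(9.0, z0=45.0, n=48)
        cloud = sample_surface(struct, 1.5)
        contrib = map_patient_to_reference(cloud, stats_for(cloud), make_patient(), ref)
        assert contrib.n_points.sum() == len(cloud)

    def test_anterior_tumor_misses_posterior_half(self, ref):
        """A tumor hugging the anterior wall contributes nothing posteriorly."""
        theta = np.deg2rad(np.linspace(-50, 50, 40))
        ring = 15.0 * np.column_stack([np.sin(theta), -np.cos(theta)])
        pts = np.vstack([np.column_stack([ring, np.full(len(ring), z)]) for z in (40.0, 41.5)])
        cloud = SurfacePointCloud(pts, "ant", 1.0)
        contrib = map_patient_to_reference(cloud, stats_for(cloud), make_patient(), ref)
        scheme = SectionScheme()
        posterior = scheme.half_mask(ref.point_theta_deg[contrib.ref_index], "posterior")
        assert posterior.sum() == 0

    def test_out_of_range_tumor_rejected(self, ref):
        from rectvar.structures import PatientRecord

        base = make_patient()
        cl_z = np.arange(-10.0, 260.0, 1.5)
        long_cl = np.column_stack([np.zeros_like(cl_z), np.zeros_like(cl_z), cl_z])
        patient = PatientRecord(base.patient_id, 0.0, long_cl, base.scans)
        pts = np.array([[15.0, 0.0, 200.0], [15.0, 0.0, 201.5]])
        cloud = SurfacePointCloud(pts, "far", 1.0)
        with pytest.raises(ValueError, match="outside reference range"):
            map_patient_to_reference(cloud, stats_for(cloud), patient, ref)


def contribution(pid, ref_index, mean, sd):
    k = len(ref_index)
    return PatientContribution(
        patient_id=pid,
        ref_index=np.asarray(ref_index),
        mean_mm=np.full((k, 2), float(mean)),
        sd_mm=np.full((k, 2), float(sd)),
        n_points=np.ones(k, dtype=int),
    )


class TestAggregate:
    def test_below_threshold_points_invalid(self, ref):
        contribs = [contribution(f"p{i}", [0, 1], 1.0, 0.5) for i in range(4)]
        out = aggregate_reference(contribs, ref, min_patients=5)
        assert not out.valid[0] and not out.valid[1]
        assert out.n_patients[0] == 4

    def test_identical_contributions_closed_form(self, ref):
        contribs = [contribution(f"p{i}", [5], 1.2, 0.8) for i in range(6)]
        out = aggregate_reference(contribs, ref, min_patients=5)
        assert out.valid[5]
        assert out.gm_mm[5] == pytest.approx([1.2, 1.2])
        assert out.Sigma_mm[5] == pytest.approx([0.0, 0.0], abs=1e-12)
        assert out.sigma_mm[5] == pytest.approx([0.8, 0.8])

    def test_occupancy_monotone_under_cohort_growth(self, ref):
        contribs = [contribution(f"p{i}", [3], 1.0, 0.5) for i in range(5)]
        small = aggregate_reference(contribs, ref, min_patients=5)
        grown = aggregate_reference(
            contribs + [contribution("new", [3, 7], 2.0, 0.1)], ref, min_patients=5
        )
        assert np.all(grown.valid[small.valid])

    def test_single_patient_gm_equals_contribution(self, ref):
        out = aggregate_reference([contribution("p", [11], 2.5, 0.4)], ref, min_patients=1)
        assert out.valid[11]
        assert out.gm_mm[11] == pytest.approx([2.5, 2.5])


class TestSegmentSummary:
    def test_constant_map_every_segment_constant(self, ref):
        contribs = [
            contribution(f"p{i}", np.arange(len(ref.points)), 1.0, 0.5) for i in range(6)
        ]
        refmap = aggregate_reference(contribs, ref, min_patients=5)
        table = segment_summary(refmap)
        assert len(table) == 12  # 4 halves x 3 bands
        assert np.allclose(table["Sigma_median_mm"], 0.0)
        assert np.allclose(table["gm_median_mm"], 1.0)
        assert np.allclose(table["gm_p95_mm"], 1.0)
        assert np.allclose(table["gm_iqr_mm"], 0.0)

    def test_gradient_in_cax_orders_bands(self, ref):
        """Sigma rising with height: every direction's high median > low median."""
        rng = np.random.default_rng(0)
        idx = np.arange(len(ref.points))
        contribs = []
        for i in range(8):
            mean = ref.point_cax_mm * 0.02 * rng.normal(1.0, 0.5)  # inter-patient spread grows with cax
            c = PatientContribution(
                f"p{i}", idx, np.column_stack([mean, mean]),
                np.full((len(idx), 2), 0.3), np.ones(len(idx), dtype=int),
            )
            contribs.append(c)
        refmap = aggregate_reference(contribs, ref, min_patients=5)
        table = segment_summary(refmap).set_index(["direction", "band"])
        for half in ("anterior", "posterior", "left", "right"):
            assert (
                table.loc[(half, "high"), "Sigma_median_mm"]
                > table.loc[(half, "low"), "Sigma_median_mm"]
            )

    def test_invalid_points_do_not_contribute(self, ref):
        """Deleting invalid points' values changes no segment statistic."""
        full = np.arange(len(ref.points))
        low_only = full[ref.point_cax_mm <= 60]
        contribs = [contribution(f"p{i}", full if i < 5 else low_only, 1.0, 0.5) for i in range(6)]
        refmap = aggregate_reference(contribs, ref, min_patients=6)
        table = segment_summary(refmap)
        poisoned = aggregate_reference(contribs, ref, min_patients=6)
        poisoned.gm_mm[~poisoned.valid] = 99.0
        assert segment_summary(poisoned).equals(table)


class TestCcExtremes:
    @staticmethod
    def _patients(cc_mean, cc_sd, n_pat=4):
        from conftest import make_sphere

        out = []
        for i in range(n_pat):
            cloud = sample_surface(make_sphere(8.0, z0=40.0, n=48), 1.5)
            n = len(cloud)
            stats = PerPointStats(
                mean_mm=np.column_stack([np.zeros(n), np.zeros(n), np.full(n, cc_mean)]),
                sd_mm=np.full((n, 3), cc_sd),
                n_test=5,
                patient_id=f"p{i}",
            )
            out.append((cloud, stats))
        return out

    def test_no_motion_all_zero(self):
        table = cc_extremes(self._patients(0.0, 0.0))
        for col in ("Sigma_median_mm", "sigma_median_mm", "gm_median_mm"):
            assert np.allclose(table[col], 0.0)

    def test_uniform_cc_value_reported_as_gm(self):
        table = cc_extremes(self._patients(2.0, 0.3)).set_index("direction")
        assert table.loc["cranial", "gm_median_mm"] == pytest.approx(2.0)
        assert table.loc["caudal", "gm_median_mm"] == pytest.approx(2.0)
        assert table.loc["cranial", "sigma_median_mm"] == pytest.approx(0.3)
        assert table.loc["cranial", "Sigma_median_mm"] == pytest.approx(0.0, abs=1e-12)

    def test_top_slice_selection_uses_extreme_points_only(self):
        patients = self._patients(1.0, 0.1, n_pat=2)
        cloud, stats = patients[0]
        z = cloud.points[:, 2]
        stats.mean_mm[z < z.max() - 1e-6, 2] = 99.0  # poison non-top points
        table = cc_extremes(patients).set_index("direction")
        assert table.loc["cranial", "gm_median_mm"] == pytest.approx(1.0)

    def test_rigid_cranial_shift_signs(self):
        """+t shift: cranial face moves outward (+), caudal face inward (-)."""
        from rectvar.bld import bld_map, sign_components
        from rectvar.geometry import center_of_mass
        from rectvar.stats import per_point_stats
        from conftest import make_sphere

        base = make_sphere(10.0, z0=40.0, n=64)
        cloud = sample_surface(base, 1.0)
        com = center_of_mass(base)
        fields = []
        for _ in range(2):
            f = bld_map(cloud, sample_surface(make_sphere(10.0, z0=43.0, n=64), 1.0))
            fields.append(sign_components(f, base, com))
        patients = [(cloud, per_point_stats(fields, "a")), (cloud, per_point_stats(fields, "b"))]
        table = cc_extremes(patients).set_index("direction")
        assert table.loc["cranial", "gm_median_mm"] == pytest.approx(3.0, abs=0.8)
        assert table.loc["caudal", "gm_median_mm"] == pytest.approx(-3.0, abs=0.8)
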