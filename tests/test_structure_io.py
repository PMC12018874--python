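"""Patient JSON dialect: validation, canonical round trips, RT-STRUCT ingestion."""

import numpy as np
import pytest

from rectvar.structures import (
    ContourSlice,
    PatientRecord,
    RigidTransform,
    ScanRecord,
    SerializationError,
    StructureSet,
    ValidationError,
    ingest_rtstruct,
    read_patient,
    records_equal,
    write_patient,
)

from conftest import make_patient, square


class TestValidation:
    def test_contour_needs_three_vertices(self):
        with pytest.raises(ValidationError, match="<3 vertices"):
            ContourSlice(0.0, np.array([[0.0, 0.0], [1.0, 0.0]]))

    def test_bowtie_polygon_rejected(self):
        bowtie = np.array([[0.0, 0.0], [2.0, 2.0], [2.0, 0.0], [0.0, 2.0]])
        with pytest.raises(ValidationError, match="simple polygon"):
            ContourSlice(0.0, bowtie)

    def test_clockwise_input_normalized_to_ccw(self):
        cw = square(1.0)[::-1]
        s = ContourSlice(0.0, cw)
        x, y = s.vertices[:, 0], s.vertices[:, 1]
        area = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
        assert area > 0
        assert {tuple(v) for v in s.vertices} == {tuple(v) for v in cw}

    def test_non_monotone_slice_z_rejected(self):
        slices = [ContourSlice(z, square(1.0)) for z in (0.0, 2.0, 1.0)]
        with pytest.raises(ValidationError, match="strictly increasing"):
            StructureSet("GTVp", slices)

    def test_uneven_slice_spacing_rejected(self):
        slices = [ContourSlice(z, square(1.0)) for z in (0.0, 1.5, 3.5)]
        with pytest.raises(ValidationError, match="spacing"):
            StructureSet("GTVp", slices)

    def test_empty_slices_rejected(self):
        with pytest.raises(ValidationError, match="no slices"):
            StructureSet("GTVp", [])

    def test_excessive_rotation_rejected(self):
        with pytest.raises(ValidationError, match="sanity bound"):
            RigidTransform(np.array([0.0, 12.0, 0.0]), np.zeros(3), np.zeros(3))

    def test_multiple_baselines_rejected(self):
        record = make_patient()
        record.scans[1].role = "baseline"
        with pytest.raises(ValidationError, match="multiple baselines"):
            PatientRecord(
                record.patient_id, record.anal_verge_z_mm, record.centerline_mm, record.scans
            )

    def test_duplicate_timepoints_rejected(self):
        record = make_patient()
        record.scans[2].timepoint = 2
        with pytest.raises(ValidationError, match="duplicated timepoints"):
            PatientRecord(
                record.patient_id, record.anal_verge_z_mm, record.centerline_mm, record.scans
            )

    def test_centerline_must_cover_tumor(self):
        record = make_patient()
        short = record.centerline_mm[record.centerline_mm[:, 2] < 30.0]
        with pytest.raises(ValidationError, match="does not\n?.*cover|cover"):
            PatientRecord(record.patient_id, 0.0, short, record.scans)

    def test_missing_scans_flagged_not_fatal(self):
        with pytest.warns(UserWarning, match="scans present"):
            record = make_patient(n_scans=4)
        assert record.incomplete
        assert len(record.test_scans) == 3


class TestRoundTrip:
    def test_write_read_is_identity(self, tmp_path):
        record = make_patient(shift=(1.25, -0.5, 3.0))
        path = tmp_path / "p.json"
        write_patient(record, path)
        assert records_equal(read_patient(path), record)

    def test_rewrite_is_byte_stable(self, tmp_path):
        record = make_patient()
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        write_patient(record, p1)
        write_patient(read_patient(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_noncanonical_input_canonicalized(self, tmp_path):
        # hand-written file with unsorted keys and ragged float formatting
        path = tmp_path / "hand.json"
        path.write_text(HAND_WRITTEN, encoding="utf-8")
        rec = read_patient(path)
        out1, out2 = tmp_path / "c1.json", tmp_path / "c2.json"
        write_patient(rec, out1)
        write_patient(read_patient(out1), out2)
        assert out1.read_bytes() == out2.read_bytes()
        assert len(rec.scans) == 6

    def test_nan_coordinate_rejected_on_write(self, tmp_path):
        record = make_patient()
        record.anal_verge_z_mm = float("nan")
        with pytest.raises(SerializationError, match="non-finite"):
            write_patient(record, tmp_path / "bad.json")


def _hand_written() -> str:
    """A minimal 6-scan patient file with deliberately unsorted keys."""
    import json

    tri = [[0.0, 0.0], [6.0, 0.0], [3.0, 5.0]]
    scans = []
    for k in range(6):
        scans.append(
            {
                "role": "baseline" if k == 0 else "test",
                "scan_id": f"S{k + 1}",
                "structures": {
                    "GTVp": {
                        "slices": [
                            {"points_mm": tri, "z_mm": 10.0},
                            {"z_mm": 11.5, "points_mm": tri},
                        ]
                    }
                },
                "timepoint": k + 1,
                "transform_to_baseline": {
                    "translation_mm": [0, 0, 0],
                    "rotation_deg": [0, 0, 0],
                    "center_mm": [0, 0, 0],
                },
            }
        )
    return json.dumps(
        {
            "scans": scans,
            "patient_id": "H1",
            "centerline_mm": [[0, 0, float(z)] for z in range(0, 30, 2)],
            "anal_verge_z_mm": 0,
        }
    )


HAND_WRITTEN = _hand_written()


class TestRtStruct:
    @staticmethod
    def _write_rtstruct(path, roi_name="GTVp", clockwise=False):
        import pydicom
        from pydicom.dataset import Dataset, FileMetaDataset
        from pydicom.uid import ImplicitVRLittleEndian, generate_uid

        sq = square(10.0)
        if clockwise:
            sq = sq[::-1]
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.UID("1.2.840.10008.5.1.4.1.1.481.3")
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ImplicitVRLittleEndian
        ds = Dataset()
        ds.file_meta = meta
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.Modality = "RTSTRUCT"
        roi = Dataset()
        roi.ROINumber = 1
        roi.ROIName = roi_name
        ds.StructureSetROISequence = [roi]
        rc = Dataset()
        rc.ReferencedROINumber = 1
        contours = []
        for z in (0.0, 1.5):
            c = Dataset()
            c.ContourGeometricType = "CLOSED_PLANAR"
            c.NumberOfContourPoints = len(sq)
            c.ContourData = [float(v) for xy in sq for v in (*xy, z)]
            contours.append(c)
        rc.ContourSequence = contours
        ds.ROIContourSequence = [rc]
        ds.save_as(str(path), enforce_file_format=True)

    def test_square_roi_round_trip(self, tmp_path):
        path = tmp_path / "rs.dcm"
        self._write_rtstruct(path)
        struct = ingest_rtstruct(path, "GTVp")
        assert len(struct.slices) == 2
        assert {tuple(v) for v in struct.slices[0].vertices} == {tuple(v) for v in square(10.0)}

    def test_missing_roi_is_lookup_error(self, tmp_path):
        path = tmp_path / "rs.dcm"
        self._write_rtstruct(path)
        with pytest.raises(LookupError, match="CTV"):
            ingest_rtstruct(path, "CTV")

    def test_clockwise_contour_normalized(self, tmp_path):
        path = tmp_path / "rs.dcm"
        self._write_rtstruct(path, clockwise=True)
        struct = ingest_rtstruct(path, "GTVp")
        v = struct.slices[0].vertices
        area = 0.5 * np.sum(v[:, 0] * np.roll(v[:, 1], -1) - np.roll(v[:, 0], -1) * v[:, 1])
        assert area > 0
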