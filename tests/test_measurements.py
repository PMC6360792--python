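"""The DRM statistic and the long-format measurement CSV dialect."""

from datetime import date

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sinumetry.errors import (
    DuplicateRecordError,
    InsufficientDataError,
    ParseError,
    ValidationError,
)
from sinumetry.measurements import (
    DiameterRecord,
    ScanMeasurement,
    compute_drm,
    drm_table,
    read_measurements,
)

from conftest import make_complete_scan


class TestReadMeasurements:
    def test_minimal_file_one_diameter_one_reference(self, measurement_csv):
        path = measurement_csv([
            "p1,2010-01-01,maxillary_L,axial,depth,35.0",
            "p1,2010-01-01,reference,axial,lateral_orbital,100.0",
        ])
        cohort = read_measurements(path)
        assert list(cohort) == ["p1"]
        (scan,) = cohort["p1"]
        assert scan.present_diameters == [35.0]
        assert scan.axial_ref_mm == 100.0
        assert scan.coronal_ref_mm is None
        assert not scan.is_complete

    def test_negative_value_rejected(self, measurement_csv):
        path = measurement_csv(["p1,2010-01-01,maxillary_L,axial,depth,-3"])
        with pytest.raises(ValidationError, match="positive"):
            read_measurements(path)

    def test_malformed_date_names_row(self, measurement_csv):
        path = measurement_csv([
            "p1,2010-01-01,maxillary_L,axial,depth,35.0",
            "p1,01/02/2010,maxillary_L,axial,width,30.0",
        ])
        with pytest.raises(ParseError, match="row 3"):
            read_measurements(path)

    def test_duplicate_record_rejected(self, measurement_csv):
        row = "p1,2010-01-01,maxillary_L,axial,depth,35.0"
        with pytest.raises(DuplicateRecordError, match="duplicate"):
            read_measurements(measurement_csv([row, row]))

    def test_complete_scan_inventory(self, measurement_csv):
        """18 sinus diameters + 2 references make a complete scan."""
        rows = []
        for sinus, n in (("maxillary_L", 5), ("maxillary_R", 5),
                         ("sphenoid_L", 4), ("sphenoid_R", 4)):
            for j in range(n):
                plane = "axial" if j % 2 else "coronal"
                rows.append(f"p1,2010-01-01,{sinus},{plane},d{j},30.0")
        rows.append("p1,2010-01-01,reference,axial,lateral_orbital,100.0")
        rows.append("p1,2010-01-01,reference,coronal,skull_width,120.0")
        assert len(rows) == 20
        (scan,) = read_measurements(measurement_csv(rows))["p1"]
        assert scan.is_complete
        assert len(scan.present_diameters) == 18

    def test_empty_cell_is_missing_not_error(self, measurement_csv):
        path = measurement_csv([
            "p1,2010-01-01,maxillary_L,axial,depth,",
            "p1,2010-01-01,maxillary_L,axial,width,30.0",
            "p1,2010-01-01,reference,axial,lateral_orbital,100.0",
        ])
        (scan,) = read_measurements(path)["p1"]
        assert scan.present_diameters == [30.0]
        assert len(scan.diameters) == 2

    def test_scans_sorted_chronologically_within_patient(self, measurement_csv):
        path = measurement_csv([
            "p1,2012-06-01,maxillary_L,axial,depth,28.0",
            "p1,2010-01-01,maxillary_L,axial,depth,30.0",
        ])
        dates = [s.scan_date for s in read_measurements(path)["p1"]]
        assert dates == sorted(dates)


class TestScanValidation:
    def test_frontal_and_ethmoid_rejected(self):
        for sinus in ("frontal_L", "ethmoid_R", "ethmoid_anterior_L"):
            with pytest.raises(ValidationError, match="excluded|unknown"):
                DiameterRecord(sinus, "axial", "depth", 20.0)

    def test_count_ceiling_per_sinus(self):
        diameters = [DiameterRecord("sphenoid_L", "axial", f"d{j}", 20.0)
                     for j in range(5)]  # sphenoid ceiling is 4
        with pytest.raises(ValidationError, match="ceiling"):
            ScanMeasurement("p1", date(2010, 1, 1), diameters)


class TestComputeDrm:
    def test_equal_numerator_denominator(self, complete_scan):
        point = compute_drm(complete_scan)
        assert point.drm == pytest.approx(1.0)
        assert point.n_diameters == 18
        assert point.n_references == 2

    def test_constant_ratio(self):
        scan = make_complete_scan(diameter_mm=30.0, axial_ref_mm=120.0,
                                  coronal_ref_mm=120.0)
        assert compute_drm(scan).drm == pytest.approx(0.25)

    def test_mixed_set_single_reference_hand_computed(self):
        """Pooled mean of a listed diameter set over the lone reference."""
        values = [31.0, 28.5, 24.0, 35.0, 18.0]
        diameters = [DiameterRecord("maxillary_L", "axial", f"d{j}", v)
                     for j, v in enumerate(values)]
        scan = ScanMeasurement("p1", date(2010, 1, 1), diameters,
                               axial_ref_mm=98.0, coronal_ref_mm=None)
        expected = (sum(values) / len(values)) / 98.0  # = 27.3 / 98
        assert compute_drm(scan).drm == pytest.approx(expected)
        assert compute_drm(scan).n_references == 1

    def test_missing_diameters_do_not_block_drm(self):
        diameters = [DiameterRecord("maxillary_L", "axial", "depth", 30.0),
                     DiameterRecord("maxillary_L", "coronal", "height", None)]
        scan = ScanMeasurement("p1", date(2010, 1, 1), diameters,
                               axial_ref_mm=100.0)
        assert compute_drm(scan).drm == pytest.approx(0.30)

    def test_no_diameters_is_insufficient(self):
        scan = ScanMeasurement("p1", date(2010, 1, 1), [], axial_ref_mm=100.0)
        with pytest.raises(InsufficientDataError):
            compute_drm(scan)

    def test_no_references_is_insufficient(self):
        scan = ScanMeasurement(
            "p1", date(2010, 1, 1),
            [DiameterRecord("maxillary_L", "axial", "depth", 30.0)])
        with pytest.raises(InsufficientDataError):
            compute_drm(scan)

    def test_axial_reference_mode(self):
        scan = make_complete_scan(diameter_mm=30.0, axial_ref_mm=100.0,
                                  coronal_ref_mm=140.0)
        assert compute_drm(scan, reference_mode="axial").drm == pytest.approx(0.30)
        assert compute_drm(scan).drm == pytest.approx(0.25)

    def test_per_sinus_pooling_differs_under_imbalance(self):
        diameters = [DiameterRecord("maxillary_L", "axial", "depth", 40.0),
                     DiameterRecord("maxillary_L", "axial", "width", 40.0),
                     DiameterRecord("sphenoid_L", "axial", "depth", 10.0)]
        scan = ScanMeasurement("p1", date(2010, 1, 1), diameters,
                               axial_ref_mm=100.0)
        assert compute_drm(scan, pooling="pooled").drm == pytest.approx(0.30)
        assert compute_drm(scan, pooling="per_sinus").drm == pytest.approx(0.25)


class TestDrmProperties:
    @settings(max_examples=50, derandomize=True)
    @given(k=st.floats(min_value=0.1, max_value=10.0,
                       allow_nan=False, allow_infinity=False))
    def test_scale_invariance(self, k):
        """Rescaling every length by k (patient size) leaves the DRM fixed."""
        base = compute_drm(make_complete_scan(diameter_mm=30.0,
                                              axial_ref_mm=95.0,
                                              coronal_ref_mm=120.0)).drm
        scaled = compute_drm(make_complete_scan(diameter_mm=30.0 * k,
                                                axial_ref_mm=95.0 * k,
                                                coronal_ref_mm=120.0 * k)).drm
        assert scaled == pytest.approx(base, rel=1e-12)

    def test_shrinking_one_diameter_strictly_decreases_drm(self, complete_scan):
        baseline = compute_drm(complete_scan).drm
        shrunk = make_complete_scan()
        record = shrunk.diameters[0]
        shrunk.diameters[0] = DiameterRecord(record.sinus, record.plane,
                                             record.label, record.value_mm - 5.0)
        assert compute_drm(shrunk).drm < baseline

    def test_permutation_invariance(self, complete_scan):
        shuffled = make_complete_scan()
        shuffled.diameters = list(reversed(shuffled.diameters))
        assert compute_drm(shuffled).drm == pytest.approx(
            compute_drm(complete_scan).drm)


def test_drm_table_columns_and_skipping(measurement_csv):
    path = measurement_csv([
        "p1,2010-01-01,maxillary_L,axial,depth,30.0",
        "p1,2010-01-01,reference,axial,lateral_orbital,100.0",
        "p2,2011-01-01,maxillary_L,axial,depth,30.0",  # no reference: skipped
    ])
    table = drm_table(read_measurements(path))
    assert list(table.columns) == ["patient_id", "scan_date", "drm",
                                   "n_diameters_used", "n_references_used"]
    assert list(table["patient_id"]) == ["p1"]
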