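from datetime import date

import pytest

from sinumetry.measurements import (
    DiameterRecord,
    ScanMeasurement,
    DIAMETERS_PER_SINUS,
)


def make_complete_scan(patient_id="p001", scan_date=date(2010, 1, 1),
                       diameter_mm=30.0, axial_ref_mm=30.0,
                       coronal_ref_mm=30.0) -> ScanMeasurement:
    """A complete scan: 18 equal diameters and both references."""
    diameters = []
    for sinus, n in DIAMETERS_PER_SINUS.items():
        for j in range(n):
            plane = "axial" if j % 2 == 0 else "coronal"
            diameters.append(DiameterRecord(sinus, plane, f"d{j}", diameter_mm))
    return ScanMeasurement(patient_id, scan_date, diameters,
                           axial_ref_mm=axial_ref_mm,
                           coronal_ref_mm=coronal_ref_mm)


@pytest.fixture
def complete_scan():
    return make_complete_scan()


@pytest.fixture
def measurement_csv(tmp_path):
    """Factory writing measurement CSV text rows to a temp file."""
    def write(rows, header="patient_id,scan_date,structure,plane,label,value_mm"):
        path = tmp_path / "measurements.csv"
        path.write_text("\n".join([header, *rows]) + "\n")
        return path
    return write
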