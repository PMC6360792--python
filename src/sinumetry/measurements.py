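"""Per-scan sinus diameter measurements and the diameter ratio measurement (DRM).

The DRM is a dimensionless per-scan summary of paranasal sinus size: the
pooled arithmetic mean of the maxillary and sphenoid sinus diameters divided
by the mean of two skull reference diameters.  Normalising by skull landmarks
controls for patient size and for scanner-to-scanner calibration differences,
so serial DRM values of one adult patient are comparable even across scanners.

Frontal and ethmoid sinuses are excluded from the measurement protocol
(frequent aplasia and destruction make them unreliable), so only the four
measured sinuses — left/right maxillary and left/right sphenoid — are legal
here.  A complete scan carries five diameters per maxillary sinus and four
per sphenoid sinus (18 in total) plus an axial and a coronal reference
diameter, but incomplete scans are first-class: a missing diameter lowers the
number of values pooled without invalidating the scan's DRM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import (
    DuplicateRecordError,
    InsufficientDataError,
    ParseError,
    ValidationError,
)

#: The four sinuses entering the DRM.
MEASURED_SINUSES = ("maxillary_L", "maxillary_R", "sphenoid_L", "sphenoid_R")

#: Sinuses explicitly excluded from the diameter protocol.
EXCLUDED_SINUSES = ("frontal_L", "frontal_R", "ethmoid_L", "ethmoid_R",
                    "ethmoid_anterior_L", "ethmoid_anterior_R",
                    "ethmoid_posterior_L", "ethmoid_posterior_R")

PLANES = ("axial", "coronal")

#: Maximum diameters per sinus in a complete scan (5 maxillary, 4 sphenoid).
DIAMETERS_PER_SINUS = {
    "maxillary_L": 5, "maxillary_R": 5, "sphenoid_L": 4, "sphenoid_R": 4,
}

#: Sentinel structure name for reference rows in the CSV dialect.
REFERENCE_STRUCTURE = "reference"

MEASUREMENT_COLUMNS = ("patient_id", "scan_date", "structure", "plane",
                       "label", "value_mm")


def _check_positive(value: float, what: str) -> None:
    if not math.isfinite(value) or value <= 0:
        raise ValidationError(f"{what} must be strictly positive and finite, got {value!r}")


@dataclass(frozen=True)
class DiameterRecord:
    """One measured sinus diameter; ``value_mm`` is None when missing."""

    sinus: str
    plane: str
    label: str
    value_mm: float | None

    def __post_init__(self) -> None:
        if self.sinus in EXCLUDED_SINUSES:
            raise ValidationError(
                f"sinus {self.sinus!r} is excluded from the diameter protocol "
                "(frontal and ethmoid sinuses are not measured)")
        if self.sinus not in MEASURED_SINUSES:
            raise ValidationError(f"unknown sinus {self.sinus!r}")
        if self.plane not in PLANES:
            raise ValidationError(f"unknown plane {self.plane!r}")
        if self.value_mm is not None:
            _check_positive(self.value_mm, f"diameter {self.sinus}/{self.label}")


@dataclass
class ScanMeasurement:
    """All diameters and reference measurements of one CT scan of one patient."""

    patient_id: str
    scan_date: date
    diameters: list[DiameterRecord] = field(default_factory=list)
    axial_ref_mm: float | None = None
    coronal_ref_mm: float | None = None

    def __post_init__(self) -> None:
        if self.axial_ref_mm is not None:
            _check_positive(self.axial_ref_mm, "axial reference")
        if self.coronal_ref_mm is not None:
            _check_positive(self.coronal_ref_mm, "coronal reference")
        counts: dict[str, int] = {}
        for d in self.diameters:
            counts[d.sinus] = counts.get(d.sinus, 0) + 1
        for sinus, n in counts.items():
            if n > DIAMETERS_PER_SINUS[sinus]:
                raise ValidationError(
                    f"{self.patient_id}/{self.scan_date}: {n} diameters for "
                    f"{sinus}, protocol ceiling is {DIAMETERS_PER_SINUS[sinus]}")

    @property
    def present_diameters(self) -> list[float]:
        return [d.value_mm for d in self.diameters if d.value_mm is not None]

    @property
    def present_references(self) -> list[float]:
        return [r for r in (self.axial_ref_mm, self.coronal_ref_mm) if r is not None]

    @property
    def is_complete(self) -> bool:
        """True when all 18 diameters and both references are present."""
        counts: dict[str, int] = {s: 0 for s in MEASURED_SINUSES}
        for d in self.diameters:
            if d.value_mm is not None:
                counts[d.sinus] += 1
        return (all(counts[s] == DIAMETERS_PER_SINUS[s] for s in MEASURED_SINUSES)
                and self.axial_ref_mm is not None
                and self.coronal_ref_mm is not None)


@dataclass(frozen=True)
class DrmPoint:
    """The DRM of one scan, with the data counts that produced it."""

    scan_date: date
    drm: float
    n_diameters: int = 0
    n_references: int = 0

    def __post_init__(self) -> None:
        if not math.isfinite(self.drm) or self.drm <= 0:
            raise ValidationError(f"DRM must be finite and positive, got {self.drm!r}")


def compute_drm(scan: ScanMeasurement, *, reference_mode: str = "both",
                pooling: str = "pooled") -> DrmPoint:
    """Compute the diameter ratio measurement of one scan.

    Parameters
    ----------
    scan:
        The per-scan measurement record.  At least one sinus diameter and one
        reference must be present.
    reference_mode:
        ``"both"`` (default) averages the axial and coronal reference
        diameters; ``"axial"`` divides by the axial reference alone.
    pooling:
        ``"pooled"`` (default) takes a single arithmetic mean over every
        present diameter, which is robust to missing values in one plane;
        ``"per_sinus"`` averages per-sinus means instead.

    Raises
    ------
    InsufficientDataError
        If no sinus diameter, or no reference in the requested mode, is present.
    """
    diam = scan.present_diameters
    if not diam:
        raise InsufficientDataError(
            f"{scan.patient_id}/{scan.scan_date}: no sinus diameters present")

    if reference_mode == "both":
        refs = scan.present_references
    elif reference_mode == "axial":
        refs = [scan.axial_ref_mm] if scan.axial_ref_mm is not None else []
    else:
        raise ValidationError(f"unknown reference_mode {reference_mode!r}")
    if not refs:
        raise InsufficientDataError(
            f"{scan.patient_id}/{scan.scan_date}: no reference measurement present")

    if pooling == "pooled":
        numerator = sum(diam) / len(diam)
    elif pooling == "per_sinus":
        per_sinus: dict[str, list[float]] = {}
        for d in scan.diameters:
            if d.value_mm is not None:
                per_sinus.setdefault(d.sinus, []).append(d.value_mm)
        means = [sum(v) / len(v) for v in per_sinus.values()]
        numerator = sum(means) / len(means)
    else:
        raise ValidationError(f"unknown pooling {pooling!r}")

    denominator = sum(refs) / len(refs)
    return DrmPoint(scan_date=scan.scan_date, drm=numerator / denominator,
                    n_diameters=len(diam), n_references=len(refs))


def _parse_date(raw: str, row: int) -> date:
    try:
        return date.fromisoformat(str(raw).strip())
    except (TypeError, ValueError) as exc:
        raise ParseError(f"row {row}: cannot parse scan_date {raw!r} as an "
                         "ISO-8601 calendar date") from exc


def read_measurements(path, *, strict_duplicates: bool = True
                      ) -> dict[str, list[ScanMeasurement]]:
    """Read a long-format measurement CSV into per-patient scan series.

    The dialect has columns ``patient_id, scan_date, structure, plane, label,
    value_mm``; ``structure`` is a measured sinus or ``"reference"``, and an
    empty ``value_mm`` cell denotes a missing measurement.  Scans are grouped
    per (patient, date) and sorted chronologically within each patient.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ParseError(f"{path}: missing required columns {missing_cols}")
    return measurements_from_frame(df, strict_duplicates=strict_duplicates)


def measurements_from_frame(df: pd.DataFrame, *, strict_duplicates: bool = True
                            ) -> dict[str, list[ScanMeasurement]]:
    """Group a long-format measurement table into ScanMeasurement objects."""
    scans: dict[tuple[str, date], ScanMeasurement] = {}
    seen: set[tuple[str, date, str, str, str]] = set()

    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        pid = str(row.patient_id)
        when = row.scan_date if isinstance(row.scan_date, date) else _parse_date(row.scan_date, i)
        structure = str(row.structure)
        plane = str(row.plane)
        label = str(row.label)
        raw = row.value_mm
        if raw is None or (isinstance(raw, float) and math.isnan(raw)) or str(raw).strip() == "":
            value = None
        else:
            try:
                value = float(raw)
            except ValueError as exc:
                raise ParseError(f"row {i}: cannot parse value_mm {raw!r}") from exc
            if not math.isfinite(value) or value <= 0:
                raise ValidationError(
                    f"row {i}: value_mm must be strictly positive, got {value}")

        key = (pid, when, structure, plane, label)
        if key in seen and strict_duplicates:
            raise DuplicateRecordError(
                f"row {i}: duplicate record for patient {pid}, scan {when}, "
                f"{structure}/{plane}/{label}")
        seen.add(key)

        scan = scans.setdefault((pid, when), ScanMeasurement(pid, when))
        if structure == REFERENCE_STRUCTURE:
            if plane == "axial":
                scan.axial_ref_mm = value
            elif plane == "coronal":
                scan.coronal_ref_mm = value
            else:
                raise ValidationError(f"row {i}: unknown reference plane {plane!r}")
        else:
            scan.diameters.append(DiameterRecord(structure, plane, label, value))

    cohort: dict[str, list[ScanMeasurement]] = {}
    for (pid, _), scan in scans.items():
        scan.__post_init__()  # re-check count ceilings after accumulation
        cohort.setdefault(pid, []).append(scan)
    for pid in cohort:
        cohort[pid].sort(key=lambda s: s.scan_date)
    return cohort


def drm_table(cohort: Mapping[str, Sequence[ScanMeasurement]] | Iterable[ScanMeasurement],
              *, reference_mode: str = "both", pooling: str = "pooled") -> pd.DataFrame:
    """Per-scan DRM table: patient_id, scan_date, drm, counts used.

    Scans on which the DRM is not computable (no diameter or no reference)
    are omitted from the table, never silently imputed.
    """
    if isinstance(cohort, Mapping):
        scans = [s for series in cohort.values() for s in series]
    else:
        scans = list(cohort)
    rows = []
    for scan in scans:
        try:
            p = compute_drm(scan, reference_mode=reference_mode, pooling=pooling)
        except InsufficientDataError:
            continue
        rows.append((scan.patient_id, scan.scan_date, p.drm,
                     p.n_diameters, p.n_references))
    out = pd.DataFrame(rows, columns=["patient_id", "scan_date", "drm",
                                      "n_diameters_used", "n_references_used"])
    return out.sort_values(["patient_id", "scan_date"], ignore_index=True)
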