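"""Osteitis-trajectory grouping from last-CT GOSS and the DRM slope.

Patients are partitioned into three trajectory groups by two rules applied in
order: (1) a last-CT GOSS of zero means no osteitis, whatever the slope —
this also keeps silent-sinus-syndrome-like DRM declines out of the disease
groups; (2) among patients with osteitis (GOSS > 0), those whose ΔDRM lies at
or above the median split are *stable* and those below are *progressive*.
The median is, by default, taken over the whole cohort's ΔDRM distribution
and then applied to the GOSS-positive subset, which generally yields an
uneven stable/progressive split; a switch restricts the reference set to the
GOSS-positive patients, and a fixed external threshold can replace the median
entirely (e.g. to classify a new patient against a historical cohort — a
cohort-relative median is unusable at n = 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ValidationError

LABELS = ("no_osteitis", "stable", "progressive")


@dataclass(frozen=True)
class ClassificationResult:
    """Per-patient labels plus the split value and group counts."""

    labels: pd.DataFrame          # patient_id, last_goss, delta_drm, label
    unclassifiable: pd.DataFrame  # patient_id, reason
    split_value: float
    median_scope: str

    @property
    def counts(self) -> dict[str, int]:
        c = self.labels["label"].value_counts()
        return {lab: int(c.get(lab, 0)) for lab in LABELS}

    def summary(self) -> dict:
        c = self.counts
        return {"n_no_osteitis": c["no_osteitis"], "n_stable": c["stable"],
                "n_progressive": c["progressive"],
                "n_unclassifiable": int(len(self.unclassifiable)),
                "median_delta_drm": float(self.split_value),
                "median_scope": self.median_scope}


def classify_cohort(rows: pd.DataFrame, *, median_scope: str = "cohort",
                    threshold: float | None = None) -> ClassificationResult:
    """Assign each patient a trajectory label from (last_goss, delta_drm).

    Parameters
    ----------
    rows:
        DataFrame with columns ``patient_id``, ``last_goss`` (integer 0-50)
        and ``delta_drm`` (ratio units / year; may be NaN, in which case a
        GOSS-positive patient is reported unclassifiable).
    median_scope:
        ``"cohort"`` (default) computes the median split over every patient
        with a ΔDRM; ``"goss_positive"`` restricts the reference set to
        patients with last-CT GOSS > 0.
    threshold:
        A fixed external split value overriding the median entirely.

    Rules: last_goss == 0 -> ``no_osteitis``; otherwise ΔDRM >= split ->
    ``stable`` (ties go to stable), ΔDRM < split -> ``progressive``.
    """
    if len(rows) == 0:
        raise InsufficientDataError("cannot classify an empty cohort")
    required = {"patient_id", "last_goss", "delta_drm"}
    if not required.issubset(rows.columns):
        raise ValidationError(f"rows must have columns {sorted(required)}")
    df = rows[["patient_id", "last_goss", "delta_drm"]].copy()
    if (df["last_goss"] < 0).any() or (df["last_goss"] > 50).any():
        raise ValidationError("last_goss must lie in 0-50")

    slopes = df["delta_drm"].to_numpy(dtype=float)
    if threshold is not None:
        split = float(threshold)
        scope = "fixed"
    else:
        if median_scope == "cohort":
            ref = slopes[np.isfinite(slopes)]
        elif median_scope == "goss_positive":
            mask = (df["last_goss"] > 0).to_numpy() & np.isfinite(slopes)
            ref = slopes[mask]
        else:
            raise ValidationError(f"unknown median_scope {median_scope!r}")
        if ref.size == 0:
            raise InsufficientDataError("no finite ΔDRM values to take a median over")
        split = float(np.median(ref))
        scope = median_scope

    labels, bad = [], []
    for pid, goss, slope in df.itertuples(index=False):
        if goss == 0:
            labels.append((pid, goss, slope, "no_osteitis"))
        elif not np.isfinite(slope):
            bad.append((pid, "GOSS > 0 but ΔDRM missing"))
        elif slope >= split:
            labels.append((pid, goss, slope, "stable"))
        else:
            labels.append((pid, goss, slope, "progressive"))

    return ClassificationResult(
        labels=pd.DataFrame(labels, columns=["patient_id", "last_goss",
                                             "delta_drm", "label"]),
        unclassifiable=pd.DataFrame(bad, columns=["patient_id", "reason"]),
        split_value=split, median_scope=scope)
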