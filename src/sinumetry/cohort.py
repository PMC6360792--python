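"""Synthetic longitudinal cohorts with known ground truth.

Every downstream stage of the package (DRM, slopes, scoring, classification,
agreement) is exercisable without clinical data through generators that
emulate the archetypal osteitis trajectories seen in granulomatosis with
polyangiitis:

* **control** — no sinus disease, flat DRM, GOSS 0 throughout;
* **no_osteitis** — GPA without osteitis: flat DRM, GOSS 0;
* **stable** — osteitis present (GOSS > 0, constant) but unchanging sinus
  size: slope centred at zero;
* **progressive** — wall thickening shrinks the sinuses: strictly negative
  DRM slope with GOSS rising towards its ceiling;
* **mucocele** — an expansile lesion balloons the sinus so the DRM does not
  fall even though GOSS keeps rising; classified *stable* by the grouping
  rule, the documented edge case of the method.

Each patient's true DRM is linear in time (baseline + slope·t); individual
diameters are disaggregated from a fixed per-sinus profile scaled so their
pooled ratio reproduces the true DRM exactly before noise, then perturbed by
i.i.d. Gaussian measurement noise.  All randomness flows from a single seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .errors import ValidationError
from .measurements import MEASUREMENT_COLUMNS
from .phantoms import Cavity, PhantomSpec, ellipsoid_volume_mm3
from .scoring import SCORED_SINUSES

GROUPS = ("control", "no_osteitis", "stable", "progressive", "mucocele")

#: Relative diameter profiles (pooled over both planes); the absolute scale
#: is set per scan so the pooled mean matches the target DRM.
_MAXILLARY_PROFILE = {
    ("axial", "depth"): 1.25, ("axial", "width"): 1.00,
    ("axial", "middle_width"): 0.80, ("coronal", "height"): 1.15,
    ("coronal", "width"): 0.95,
}
_SPHENOID_PROFILE = {
    ("axial", "depth"): 0.65, ("axial", "width"): 0.55,
    ("coronal", "height"): 0.60, ("coronal", "width"): 0.50,
}
_PROFILES = {
    "maxillary_L": _MAXILLARY_PROFILE, "maxillary_R": _MAXILLARY_PROFILE,
    "sphenoid_L": _SPHENOID_PROFILE, "sphenoid_R": _SPHENOID_PROFILE,
}


@dataclass(frozen=True)
class CohortConfig:
    """Generator settings; the defaults are the package's reference scenario.

    Group sizes put the progressive patients at half the classified cohort so
    that the cohort-median ΔDRM falls between the declining and the flat
    slope clusters, making the generated labels identifiable by the median
    split rule.  Slope scales (ratio units per year) keep the flat groups
    centred at zero and the progressive group strictly negative and well
    separated.
    """

    n_control: int = 15
    n_no_osteitis: int = 30
    n_stable: int = 19
    n_progressive: int = 50
    n_mucocele: int = 1
    scans_range: tuple[int, int] = (3, 9)          # scans per patient
    span_years_range: tuple[float, float] = (3.0, 10.0)
    baseline_drm_mean: float = 0.40
    baseline_drm_sd: float = 0.04
    flat_slope_sd: float = 0.002                   # control/no_osteitis/stable
    progressive_slope_mean: float = -0.022
    progressive_slope_sd: float = 0.004
    progressive_slope_max: float = -0.010          # truncation: strictly negative
    mucocele_slope: float = 0.008                  # non-negative despite rising GOSS
    axial_reference_mm: float = 95.0
    coronal_reference_mm: float = 120.0
    diameter_noise_sd_mm: float = 1.0
    reference_noise_sd_mm: float = 0.5
    missing_plane_prob: float = 0.0                # drop a scan's coronal plane
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_control", "n_no_osteitis", "n_stable",
                     "n_progressive", "n_mucocele"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.scans_range[0] < 2 or self.scans_range[1] < self.scans_range[0]:
            raise ValidationError("scans_range must be an increasing range with >= 2 scans")
        if self.span_years_range[0] <= 0 or self.span_years_range[1] < self.span_years_range[0]:
            raise ValidationError("span_years_range must be positive and increasing")
        if min(self.diameter_noise_sd_mm, self.reference_noise_sd_mm,
               self.flat_slope_sd, self.progressive_slope_sd,
               self.baseline_drm_sd) < 0:
            raise ValidationError("all standard deviations must be >= 0")
        if self.progressive_slope_max >= 0:
            raise ValidationError("progressive slopes must be strictly negative")
        if self.mucocele_slope < 0:
            raise ValidationError("the mucocele archetype has a non-negative slope")
        if not 0 <= self.missing_plane_prob < 1:
            raise ValidationError("missing_plane_prob must lie in [0, 1)")


@dataclass
class SimulatedCohort:
    """Measurement table, GOSS table and ground truth of one simulated cohort."""

    measurements: pd.DataFrame   # the measurement_model CSV dialect
    goss: pd.DataFrame           # patient_id, scan_date, sinus, subscore
    truth: pd.DataFrame          # per-patient ground truth
    config: CohortConfig

    def write(self, outdir) -> None:
        from pathlib import Path
        import json

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.measurements.to_csv(out / "measurements.csv", index=False)
        self.goss.to_csv(out / "goss.csv", index=False)
        self.truth.to_csv(out / "truth.csv", index=False)
        (out / "ground_truth.json").write_text(json.dumps({
            "seed": self.config.seed,
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in asdict(self.config).items()},
            "patients": self.truth.to_dict(orient="records"),
        }, default=str, indent=2))


def _scan_times(rng: np.random.Generator, n_scans: int, span_years: float
                ) -> np.ndarray:
    """First scan at t=0, last at the span, interior dates uniform."""
    interior = np.sort(rng.uniform(0.05, 0.95, size=n_scans - 2)) * span_years \
        if n_scans > 2 else np.empty(0)
    t = np.concatenate([[0.0], interior, [span_years]])
    days = np.round(t * 365.25).astype(int)
    for i in range(1, len(days)):       # enforce strictly increasing dates
        if days[i] <= days[i - 1]:
            days[i] = days[i - 1] + 1
    return days


def _goss_subscores(group: str, frac: float) -> dict[str, int]:
    """Per-sinus GOSS subscores at relative follow-up time ``frac`` in [0,1]."""
    scores = {s: 0 for s in SCORED_SINUSES}
    if group in ("control", "no_osteitis"):
        return scores
    if group == "stable":
        scores["maxillary_L"] = 3
        scores["maxillary_R"] = 2
        scores["sphenoid_L"] = 1
        return scores
    if group == "progressive":
        level = 1 + frac * 4            # rises 1 -> 5 over follow-up
        for s in ("maxillary_L", "maxillary_R"):
            scores[s] = min(5, int(round(level)))
        for s in ("sphenoid_L", "sphenoid_R"):
            scores[s] = min(5, max(1, int(round(level * 0.8))))
        return scores
    if group == "mucocele":
        scores["maxillary_R"] = min(5, 1 + int(round(frac * 4)))
        scores["frontal_R"] = min(5, int(round(frac * 3)))
        scores["ethmoid_anterior_R"] = min(5, int(round(frac * 3)))
        return scores
    raise ValidationError(f"unknown group {group!r}")


def simulate_cohort(config: CohortConfig = CohortConfig()) -> SimulatedCohort:
    """Generate a full longitudinal cohort in the measurement CSV dialect."""
    rng = np.random.default_rng(config.seed)
    ref_mean = (config.axial_reference_mm + config.coronal_reference_mm) / 2.0
    profile_values = [w for prof in _PROFILES.values() for w in prof.values()]
    profile_mean = float(np.mean(profile_values))

    meas_rows: list[tuple] = []
    goss_rows: list[tuple] = []
    truth_rows: list[tuple] = []

    roster = ([("control", i) for i in range(config.n_control)]
              + [("no_osteitis", i) for i in range(config.n_no_osteitis)]
              + [("stable", i) for i in range(config.n_stable)]
              + [("progressive", i) for i in range(config.n_progressive)]
              + [("mucocele", i) for i in range(config.n_mucocele)])

    for serial, (group, _) in enumerate(roster, start=1):
        pid = f"p{serial:03d}"
        baseline = max(0.1, rng.normal(config.baseline_drm_mean,
                                       config.baseline_drm_sd))
        if group in ("control", "no_osteitis", "stable"):
            slope = rng.normal(0.0, config.flat_slope_sd)
        elif group == "progressive":
            slope = config.progressive_slope_max + 1.0
            while slope > config.progressive_slope_max:
                slope = rng.normal(config.progressive_slope_mean,
                                   config.progressive_slope_sd)
        else:  # mucocele
            slope = config.mucocele_slope

        n_scans = int(rng.integers(config.scans_range[0], config.scans_range[1] + 1))
        span = float(rng.uniform(*config.span_years_range))
        days = _scan_times(rng, n_scans, span)
        start = date(2004, 1, 1) + timedelta(days=int(rng.integers(0, 3000)))

        for k, d in enumerate(days):
            when = start + timedelta(days=int(d))
            t = d / 365.25
            drm_true = max(0.05, baseline + slope * t)
            scale = drm_true * ref_mean / profile_mean
            drop_coronal = (config.missing_plane_prob > 0
                            and rng.random() < config.missing_plane_prob)
            for sinus, prof in _PROFILES.items():
                for (plane, label), weight in prof.items():
                    if drop_coronal and plane == "coronal":
                        value = ""
                    else:
                        v = weight * scale + rng.normal(0.0, config.diameter_noise_sd_mm)
                        value = f"{max(v, 0.5):.3f}"
                    meas_rows.append((pid, when.isoformat(), sinus, plane,
                                      label, value))
            ax = config.axial_reference_mm + rng.normal(0.0, config.reference_noise_sd_mm)
            meas_rows.append((pid, when.isoformat(), "reference", "axial",
                              "lateral_orbital", f"{max(ax, 1.0):.3f}"))
            if drop_coronal:
                meas_rows.append((pid, when.isoformat(), "reference", "coronal",
                                  "skull_width", ""))
            else:
                co = config.coronal_reference_mm + rng.normal(
                    0.0, config.reference_noise_sd_mm)
                meas_rows.append((pid, when.isoformat(), "reference", "coronal",
                                  "skull_width", f"{max(co, 1.0):.3f}"))
            frac = t / span if span > 0 else 0.0
            for sinus, sub in _goss_subscores(group, frac).items():
                goss_rows.append((pid, when.isoformat(), sinus, sub))

        expected = {"control": "no_osteitis", "no_osteitis": "no_osteitis",
                    "stable": "stable", "progressive": "progressive",
                    "mucocele": "stable"}[group]
        last_goss = sum(_goss_subscores(group, 1.0).values())
        truth_rows.append((pid, group, expected, baseline, slope,
                           n_scans, span, last_goss))

    measurements = pd.DataFrame(meas_rows, columns=list(MEASUREMENT_COLUMNS))
    goss = pd.DataFrame(goss_rows, columns=["patient_id", "scan_date",
                                            "sinus", "subscore"])
    truth = pd.DataFrame(truth_rows, columns=[
        "patient_id", "group", "expected_label", "true_baseline",
        "true_slope", "n_scans", "span_years", "last_goss_true"])
    return SimulatedCohort(measurements=measurements, goss=goss,
                           truth=truth, config=config)


# ---------------------------------------------------------------------------
# Reader study

def simulate_reader_study(*, n_patients: int = 20, n_readers: int = 2,
                          n_replicates: int = 2, var_patient: float = 0.01,
                          var_reader: float = 0.0005,
                          var_residual: float = 0.0005,
                          grand_mean: float = 0.40, seed: int = 0
                          ) -> tuple[pd.DataFrame, float]:
    """Nested reader-study readings with a closed-form implied ICC.

    Each reading is grand_mean + patient effect + reader-within-patient
    effect + replicate error, all Gaussian.  Returns the tidy table and the
    implied inter-reader ICC var_patient / (var_patient + var_reader +
    var_residual).
    """
    if n_patients < 2:
        raise ValidationError("need at least 2 patients")
    if min(var_patient, var_reader, var_residual) < 0:
        raise ValidationError("variance components must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_patients):
        pe = rng.normal(0.0, math.sqrt(var_patient)) if var_patient > 0 else 0.0
        for r in range(n_readers):
            re_ = rng.normal(0.0, math.sqrt(var_reader)) if var_reader > 0 else 0.0
            for k in range(n_replicates):
                eps = rng.normal(0.0, math.sqrt(var_residual)) if var_residual > 0 else 0.0
                rows.append((f"p{p + 1:03d}", f"reader{r + 1}", k + 1,
                             grand_mean + pe + re_ + eps))
    df = pd.DataFrame(rows, columns=["patient_id", "reader_id", "replicate", "value"])
    total = var_patient + var_reader + var_residual
    implied_icc = var_patient / total if total > 0 else 0.0
    return df, implied_icc


# ---------------------------------------------------------------------------
# Diameter-vs-volume size-comparison study

#: Baseline semi-axis ranges (mm) per sinus type, loosely anatomical.
_AXES_RANGES = {
    "maxillary": ((16.0, 21.0), (12.0, 16.0), (14.0, 19.0)),
    "sphenoid": ((9.0, 12.0), (7.0, 10.0), (8.0, 11.0)),
}
_COMP_SINUSES = ("maxillary_L", "maxillary_R", "sphenoid_L", "sphenoid_R")


@dataclass
class SizeComparison:
    """Shared-geometry diameter and volume series for method comparison."""

    measurements: pd.DataFrame    # measurement CSV dialect
    volumes: pd.DataFrame         # patient_id, scan_date, sinus, volume_mm3, method
    references: pd.DataFrame     # patient_id, scan_date, axial_ref_mm, coronal_ref_mm
    geometry: dict = field(default_factory=dict)  # pid -> {sinus: axes0}, shrink rate


def _comparison_diameters(axes: np.ndarray, sinus: str) -> list[tuple[str, str, float]]:
    """The measured diameter set of one ellipsoidal sinus: the three principal
    diameters, plus two middle widths for the maxillary sinuses."""
    d = 2.0 * axes
    out = [("axial", "depth", d[0]), ("axial", "width", d[1]),
           ("coronal", "height", d[2])]
    if sinus.startswith("maxillary"):
        out += [("axial", "middle_width", 0.75 * d[1]),
                ("coronal", "middle_width", 0.85 * d[2])]
    else:
        out += [("coronal", "width", 0.9 * d[1])]
    return out


def simulate_size_comparison(*, n_patients: int = 40, n_scans: int = 5,
                             span_years: float = 6.0,
                             shrink_rate_range: tuple[float, float] = (0.004, 0.022),
                             diameter_noise_sd_mm: float = 0.6,
                             volume_noise_frac: float = 0.02,
                             reference_noise_sd_mm: float = 0.5,
                             axial_reference_mm: float = 95.0,
                             coronal_reference_mm: float = 120.0,
                             seed: int = 0) -> SizeComparison:
    """Cohort whose diameters and volumes shrink consistently.

    Each patient's four sinuses are ellipsoids whose semi-axes shrink
    proportionally, ``axes(t) = axes0 * (1 - k t)`` (uniform wall thickening
    expressed as a per-year fractional rate k).  The diameter profile of each
    patient is calibrated so the baseline pooled diameter mean equals the
    baseline mean cube-root volume; under proportional shrinkage the two
    ratio measures then share the same true slope, so their Bland-Altman
    difference is pure measurement noise.
    """
    rng = np.random.default_rng(seed)
    meas_rows, vol_rows, ref_rows = [], [], []
    geometry: dict[str, dict] = {}
    for p in range(n_patients):
        pid = f"v{p + 1:03d}"
        axes0 = {}
        for sinus in _COMP_SINUSES:
            kind = "maxillary" if sinus.startswith("maxillary") else "sphenoid"
            axes0[sinus] = np.array([rng.uniform(*r) for r in _AXES_RANGES[kind]])
        k = float(rng.uniform(*shrink_rate_range))
        geometry[pid] = {"axes0": axes0, "shrink_rate": k}

        # calibrate diameters to the cube-root volume scale at baseline
        m_v0 = float(np.mean([ellipsoid_volume_mm3(axes0[s]) ** (1 / 3)
                              for s in _COMP_SINUSES]))
        base_diams = [v for s in _COMP_SINUSES
                      for (_, _, v) in _comparison_diameters(axes0[s], s)]
        scale = m_v0 / float(np.mean(base_diams))

        start = date(2005, 1, 1) + timedelta(days=int(rng.integers(0, 2000)))
        times = np.linspace(0.0, span_years, n_scans)
        for t in times:
            when = (start + timedelta(days=int(round(t * 365.25)))).isoformat()
            factor = max(0.2, 1.0 - k * t)
            for sinus in _COMP_SINUSES:
                axes_t = axes0[sinus] * factor
                for plane, label, v in _comparison_diameters(axes_t, sinus):
                    noisy = scale * v + rng.normal(0.0, diameter_noise_sd_mm)
                    meas_rows.append((pid, when, sinus, plane, label,
                                      f"{max(noisy, 0.5):.3f}"))
                vol = ellipsoid_volume_mm3(axes_t) * (
                    1.0 + rng.normal(0.0, volume_noise_frac))
                vol_rows.append((pid, when, sinus, max(vol, 1.0), "analytic"))
            ax = axial_reference_mm + rng.normal(0.0, reference_noise_sd_mm)
            co = coronal_reference_mm + rng.normal(0.0, reference_noise_sd_mm)
            meas_rows.append((pid, when, "reference", "axial",
                              "lateral_orbital", f"{ax:.3f}"))
            meas_rows.append((pid, when, "reference", "coronal",
                              "skull_width", f"{co:.3f}"))
            ref_rows.append((pid, when, ax, co))

    return SizeComparison(
        measurements=pd.DataFrame(meas_rows, columns=list(MEASUREMENT_COLUMNS)),
        volumes=pd.DataFrame(vol_rows, columns=["patient_id", "scan_date",
                                                "sinus", "volume_mm3", "method"]),
        references=pd.DataFrame(ref_rows, columns=["patient_id", "scan_date",
                                                   "axial_ref_mm", "coronal_ref_mm"]),
        geometry=geometry)


def phantom_spec_for_geometry(axes_by_sinus: dict[str, np.ndarray],
                              *, voxel_size_mm: float = 0.8,
                              noise_sd_hu: float = 0.0, seed: int = 0,
                              filled: tuple[str, ...] = ()) -> PhantomSpec:
    """Lay the four sinus ellipsoids out on a 2x2 grid in one phantom volume."""
    max_r = max(float(np.max(a)) for a in axes_by_sinus.values())
    cell = int(math.ceil(2 * max_r / voxel_size_mm)) + 6
    shape = (2 * cell, 2 * cell, cell)
    cavities = []
    for i, (sinus, axes) in enumerate(sorted(axes_by_sinus.items())):
        cx = cell // 2 + (i % 2) * cell
        cy = cell // 2 + (i // 2) * cell
        cavities.append(Cavity(sinus=sinus, center_voxel=(cx, cy, cell // 2),
                               semi_axes_mm=tuple(float(a) for a in axes),
                               filled=sinus in filled))
    return PhantomSpec(grid_shape=shape, voxel_size_mm=voxel_size_mm,
                       cavities=tuple(cavities), noise_sd_hu=noise_sd_hu,
                       seed=seed)
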