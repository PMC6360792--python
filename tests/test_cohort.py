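"""The synthetic cohort generator and its ground-truth contracts."""

import numpy as np
import pandas as pd
import pytest

from sinumetry.cohort import (
    CohortConfig,
    phantom_spec_for_geometry,
    simulate_cohort,
    simulate_reader_study,
    simulate_size_comparison,
)
from sinumetry.errors import ValidationError
from sinumetry.measurements import drm_table, measurements_from_frame
from sinumetry.phantoms import (
    generate_phantom,
    mask_volume_mm3,
    segment_cavity,
    vrm_table,
)
from sinumetry.scoring import last_goss_table
from sinumetry.trajectory import fit_cohort_slopes, fit_slope

SMALL = CohortConfig(n_control=2, n_no_osteitis=3, n_stable=2,
                     n_progressive=4, n_mucocele=1, seed=11)


class TestSimulateCohort:
    def test_same_seed_is_byte_identical(self):
        a, b = simulate_cohort(SMALL), simulate_cohort(SMALL)
        assert a.measurements.equals(b.measurements)
        assert a.goss.equals(b.goss)
        assert a.truth.equals(b.truth)

    def test_noise_free_flat_patient_has_constant_drm(self):
        cfg = CohortConfig(n_control=0, n_no_osteitis=1, n_stable=0,
                           n_progressive=0, n_mucocele=0,
                           flat_slope_sd=0.0, diameter_noise_sd_mm=0.0,
                           reference_noise_sd_mm=0.0, seed=2)
        sim = simulate_cohort(cfg)
        table = drm_table(measurements_from_frame(sim.measurements))
        assert table["drm"].std() == pytest.approx(0.0, abs=1e-4)

    def test_groups_obey_goss_contracts(self):
        sim = simulate_cohort(SMALL)
        last = last_goss_table(sim.goss).set_index("patient_id")["last_goss"]
        for pid, group in zip(sim.truth["patient_id"], sim.truth["group"]):
            if group in ("control", "no_osteitis"):
                assert last[pid] == 0
            else:
                assert last[pid] > 0

    def test_mucocele_has_rising_goss_and_nonnegative_slope(self):
        sim = simulate_cohort(SMALL)
        muc = sim.truth[sim.truth["group"] == "mucocele"].iloc[0]
        assert muc["true_slope"] >= 0
        totals = (sim.goss[sim.goss["patient_id"] == muc["patient_id"]]
                  .groupby("scan_date")["subscore"].sum().sort_index())
        assert totals.iloc[-1] > totals.iloc[0]

    def test_progressive_slopes_strictly_negative(self):
        sim = simulate_cohort(SMALL)
        prog = sim.truth[sim.truth["group"] == "progressive"]
        assert (prog["true_slope"] < 0).all()

    def test_missingness_exercises_missing_value_contract(self):
        cfg = CohortConfig(n_control=0, n_no_osteitis=4, n_stable=0,
                           n_progressive=0, n_mucocele=0,
                           missing_plane_prob=0.5, seed=3)
        sim = simulate_cohort(cfg)
        assert (sim.measurements["value_mm"] == "").any()
        table = drm_table(measurements_from_frame(sim.measurements))
        # every scan still yields a DRM despite whole missing planes
        n_scans = sim.measurements.groupby(
            ["patient_id", "scan_date"]).ngroups
        assert len(table) == n_scans
        assert (table["n_diameters_used"] < 18).any()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValidationError):
            CohortConfig(span_years_range=(-1.0, 5.0))
        with pytest.raises(ValidationError):
            CohortConfig(progressive_slope_max=0.01)
        with pytest.raises(ValidationError):
            CohortConfig(scans_range=(1, 5))

    def test_write_outputs(self, tmp_path):
        simulate_cohort(SMALL).write(tmp_path / "cohort")
        for name in ("measurements.csv", "goss.csv", "truth.csv",
                     "ground_truth.json"):
            assert (tmp_path / "cohort" / name).exists()
        import json
        meta = json.loads((tmp_path / "cohort" / "ground_truth.json").read_text())
        assert meta["seed"] == SMALL.seed


class TestSlopeRecovery:
    def test_progressive_slope_recovered_within_sampling_error(self):
        """OLS on simulated series recovers the generating slope within
        3 empirical standard errors in at least 95% of replicates."""
        slope_true = -0.02
        hits, n_rep = 0, 500
        for rep in range(n_rep):
            cfg = CohortConfig(n_control=0, n_no_osteitis=0, n_stable=0,
                               n_progressive=1, n_mucocele=0,
                               progressive_slope_mean=slope_true,
                               progressive_slope_sd=0.0,
                               progressive_slope_max=-0.0199,
                               scans_range=(5, 5),
                               span_years_range=(6.0, 6.0),
                               seed=10_000 + rep)
            sim = simulate_cohort(cfg)
            table = drm_table(measurements_from_frame(sim.measurements))
            pts = list(zip(table["scan_date"], table["drm"]))
            fit = fit_slope(pts)
            t = np.array([(d - pts[0][0]).days / 365.25 for d, _ in pts])
            sxx = np.sum((t - t.mean()) ** 2)
            se = fit.residual_sd / np.sqrt(sxx)
            if abs(fit.beta1 - slope_true) <= 3 * se:
                hits += 1
        assert hits / n_rep >= 0.95


class TestReaderStudy:
    def test_zero_reader_and_replicate_noise_is_truth(self):
        df, implied = simulate_reader_study(var_reader=0.0, var_residual=0.0,
                                            seed=1)
        assert implied == 1.0
        spread = df.groupby("patient_id")["value"].std(ddof=0)
        assert np.allclose(spread, 0.0)

    def test_zero_patient_variance_implies_icc_zero(self):
        _, implied = simulate_reader_study(var_patient=0.0, seed=1)
        assert implied == 0.0

    def test_implied_icc_closed_form(self):
        _, implied = simulate_reader_study(var_patient=0.01,
                                           var_reader=0.0005,
                                           var_residual=0.0005, seed=1)
        assert implied == pytest.approx(0.01 / 0.011, rel=1e-12)


class TestSizeComparison:
    def test_deterministic_and_shared_geometry(self):
        a = simulate_size_comparison(n_patients=3, seed=5)
        b = simulate_size_comparison(n_patients=3, seed=5)
        assert a.measurements.equals(b.measurements)
        assert a.volumes.equals(b.volumes)

    def test_diameter_and_volume_slopes_agree_per_patient(self):
        comp = simulate_size_comparison(n_patients=8, seed=6,
                                        diameter_noise_sd_mm=0.0,
                                        volume_noise_frac=0.0,
                                        reference_noise_sd_mm=0.0)
        dtab = drm_table(measurements_from_frame(comp.measurements))
        vtab = vrm_table(comp.volumes, comp.references)
        ds, _ = fit_cohort_slopes(dtab, value_col="drm")
        vs, _ = fit_cohort_slopes(vtab, value_col="vrm")
        merged = ds.merge(vs, on="patient_id", suffixes=("_d", "_v"))
        # noiseless, proportional shrinkage: slopes match closely
        assert np.allclose(merged["beta1_per_year_d"],
                           merged["beta1_per_year_v"], rtol=0.05, atol=2e-4)

    def test_segmented_phantom_volumes_track_analytic_series(self):
        """Threshold segmentation of the phantom-rendered geometry yields
        volume slopes consistent with the diameter-based slopes."""
        comp = simulate_size_comparison(n_patients=1, n_scans=3,
                                        span_years=6.0, seed=7,
                                        diameter_noise_sd_mm=0.0,
                                        volume_noise_frac=0.0,
                                        reference_noise_sd_mm=0.0)
        pid = comp.volumes["patient_id"].iloc[0]
        geom = comp.geometry[pid]
        scan_dates = sorted(comp.volumes["scan_date"].unique())
        seg_rows = []
        for i, when in enumerate(scan_dates):
            t = 6.0 * i / (len(scan_dates) - 1)
            factor = max(0.2, 1.0 - geom["shrink_rate"] * t)
            axes = {s: a * factor for s, a in geom["axes0"].items()}
            spec = phantom_spec_for_geometry(axes, voxel_size_mm=0.8)
            vol = generate_phantom(spec)
            for cav in spec.cavities:
                mask = segment_cavity(vol, tuple(int(c) for c in cav.center_voxel))
                seg_rows.append((pid, when, cav.sinus,
                                 mask_volume_mm3(mask, spec.voxel_size_mm),
                                 "threshold_segmentation"))
        seg = pd.DataFrame(seg_rows, columns=list(comp.volumes.columns))
        vtab = vrm_table(seg, comp.references)
        dtab = drm_table(measurements_from_frame(comp.measurements))
        vslope = fit_cohort_slopes(vtab, value_col="vrm")[0].loc[0, "beta1_per_year"]
        dslope = fit_cohort_slopes(dtab, value_col="drm")[0].loc[0, "beta1_per_year"]
        assert vslope == pytest.approx(dslope, rel=0.10, abs=5e-4)
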