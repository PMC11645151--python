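"""Generators: determinism, truth round trips, null calibration."""

import numpy as np
import pytest

from nephrokit.mri import compute_fsoc, fit_adc, fit_r2star
from nephrokit.petkinetics import PKParameters, fit_roi, simulate_tac
from nephrokit.petkinetics.types import TimeActivityCurve
from nephrokit.renal import aggregate_clearance, rpf_from_pah
from nephrokit.stats import group_compare, ks_2sample, spearman
from nephrokit.synth import (
    gen_aif,
    gen_clearance_study,
    gen_cohort,
    gen_dynamic_phantom,
    gen_mri_signals,
    gen_pseudotime,
)


class TestAIF:
    def test_zero_amplitude_is_zero_curve(self):
        fn, _ = gen_aif(amplitude=0.0)
        assert np.all(fn.parent_activity == 0.0)

    def test_default_curve_is_unimodal_with_interior_peak(self):
        fn, truth = gen_aif()
        v = fn.parent_activity
        i = int(np.argmax(v))
        assert 0 < i < v.size - 1
        # grid-scan oracle: nondecreasing to the peak, nonincreasing after
        assert np.all(np.diff(v[:i + 1]) >= -1e-12)
        assert np.all(np.diff(v[i:]) <= 1e-12)
        assert v[0] == 0.0

    def test_deterministic(self):
        a, _ = gen_aif(seed=5)
        b, _ = gen_aif(seed=5)
        np.testing.assert_array_equal(a.parent_activity, b.parent_activity)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            gen_aif(peak_time=-1.0)


class TestPhantom:
    def test_noise_free_cortex_voxels_equal_model_curve(self, aif):
        image, mask, truth = gen_dynamic_phantom(aif=aif)
        params = truth.parameters["region_params"]["cortex"]
        expected = simulate_tac(PKParameters(**params), aif,
                                image.schedule).activity
        for voxel in image.voxels[mask.region("cortex")]:
            np.testing.assert_allclose(voxel, expected, rtol=1e-12)

    def test_seeded_regeneration_is_bit_identical(self, aif):
        a, _, _ = gen_dynamic_phantom(aif=aif, noise_cv=0.1, seed=3)
        b, _, _ = gen_dynamic_phantom(aif=aif, noise_cv=0.1, seed=3)
        np.testing.assert_array_equal(a.voxels, b.voxels)

    def test_noise_requires_seed(self, aif):
        with pytest.raises(ValueError, match="seed"):
            gen_dynamic_phantom(aif=aif, noise_cv=0.1)

    def test_unknown_region_rejected(self, aif):
        with pytest.raises(ValueError):
            gen_dynamic_phantom(region_params={"liver": PKParameters(0.1, 0.1)},
                                aif=aif)

    def test_roi_fit_recovers_phantom_truth(self, aif):
        image, mask, truth = gen_dynamic_phantom(aif=aif)
        p = truth.parameters["region_params"]["medulla"]
        tac = TimeActivityCurve(
            image.schedule, image.voxels[mask.region("medulla")].mean(axis=0))
        res = fit_roi(tac, aif)
        assert res.K1 == pytest.approx(p["K1"], rel=1e-6)
        assert res.k2 == pytest.approx(p["k2"], rel=1e-6)


class TestMRISignals:
    def test_noise_free_truth_recovery(self):
        pre, post, dwi, truth = gen_mri_signals()
        r_pre = fit_r2star(pre).rate
        r_post = fit_r2star(post).rate
        assert r_pre == pytest.approx(truth.parameters["r2star_pre"], rel=1e-9)
        assert compute_fsoc(r_pre, r_post) == pytest.approx(
            truth.parameters["fsoc"], rel=1e-9)
        assert fit_adc(dwi).rate == pytest.approx(truth.parameters["adc"],
                                                  rel=1e-9)

    def test_seeded_reproducibility(self):
        a = gen_mri_signals(noise_cv=0.02, seed=8)
        b = gen_mri_signals(noise_cv=0.02, seed=8)
        np.testing.assert_array_equal(a[0].signals, b[0].signals)
        np.testing.assert_array_equal(a[2].signals, b[2].signals)


class TestClearanceStudy:
    def test_noise_free_recovers_truth_exactly(self):
        iox, pah, truth = gen_clearance_study(true_gfr=120.0, true_rpf=600.0)
        gfr, _, _ = aggregate_clearance(iox)
        assert gfr == pytest.approx(120.0, rel=1e-12)
        pah_cl, _, _ = aggregate_clearance(pah)
        assert rpf_from_pah(pah_cl, gfr, 0.85) == pytest.approx(600.0,
                                                               rel=1e-12)

    def test_noisy_mean_within_1pct_over_500_seeds(self):
        estimates = []
        for seed in range(500):
            iox, _, _ = gen_clearance_study(true_gfr=120.0, noise_cv=0.05,
                                            seed=seed)
            estimates.append(aggregate_clearance(iox)[0])
        assert np.mean(estimates) == pytest.approx(120.0, rel=0.01)


class TestCohort:
    def test_defaults_carry_printed_group_means(self):
        table, truth = gen_cohort(n_t1d=4000, n_hc=4000, seed=0)
        by = table.groupby("group")
        assert by["m_value"].mean()["T1D"] == pytest.approx(7.8, rel=0.05)
        assert by["m_value"].mean()["HC"] == pytest.approx(14.3, rel=0.05)
        assert by["k2_cortex"].mean()["T1D"] == pytest.approx(0.16, rel=0.02)
        assert by["k2_cortex"].mean()["HC"] == pytest.approx(0.18, rel=0.02)
        assert by["gbm_width"].median()["T1D"] == pytest.approx(521.5, rel=0.05)

    def test_type_I_error_near_alpha_with_zero_effect(self):
        cfg = {
            "m_value": {"t1d": (10.0, 3.0), "hc": (10.0, 3.0)},
            "k2_cortex": {"t1d": (0.17, 0.02), "hc": (0.17, 0.02)},
            "k2_medulla": {"t1d": (0.17, 0.02), "hc": (0.17, 0.02)},
            "gbm_width": {"t1d": (480.0, 0.2), "hc": (480.0, 0.2)},
        }
        rejections = 0
        reps = 1000
        for seed in range(reps):
            table, _ = gen_cohort(14, 14, effect_config=cfg, seed=seed)
            res = group_compare(table["m_value"], table["group"], "t")
            rejections += res.p_value < 0.05
        assert abs(rejections / reps - 0.05) <= 0.015

    def test_m_k2_correlation_near_configured_value(self):
        table, _ = gen_cohort(n_t1d=1000, n_hc=1000, seed=2)
        t1d = table[table.group == "T1D"]
        rho = spearman(t1d["m_value"], t1d["k2_cortex"]).rho
        assert rho == pytest.approx(0.4, abs=0.08)

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError):
            gen_cohort(1, 5)


class TestPseudotime:
    def test_null_p_values_uniform(self):
        """With zero shift the KS p-values should be approximately uniform
        (KS distance of the p-value sample to U(0,1) below 0.05).  Cell
        counts must sit in the asymptotic regime of the test; 2000 cells
        per group is typical of scRNA pseudotime data."""
        ps = []
        for seed in range(1000):
            a, b, _ = gen_pseudotime(n_cells_per_group=2000, shift=0.0,
                                     seed=seed)
            ps.append(ks_2sample(a, b).p_value)
        ps = np.sort(ps)
        grid = (np.arange(1, 1001)) / 1000.0
        d = np.max(np.abs(ps - grid))
        assert d < 0.05

    def test_large_shift_drives_D_to_one(self):
        a, b, _ = gen_pseudotime(n_cells_per_group=400, shift=50.0, seed=1)
        assert ks_2sample(a, b).D > 0.999

    def test_seeded_reproducibility(self):
        a1, b1, _ = gen_pseudotime(seed=6)
        a2, b2, _ = gen_pseudotime(seed=6)
        np.testing.assert_array_equal(a1, a2)
        np.testing.assert_array_equal(b1, b2)
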