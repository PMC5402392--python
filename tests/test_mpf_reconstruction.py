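"""Single-point synthetic-reference MPF inversion and map reconstruction."""

import numpy as np
import pytest

from mpfkit.config import default_protocols
from mpfkit.field_relaxometry import estimate_field_maps
from mpfkit.mpf_reconstruction import (SinglePointConstraints, model_ratio,
                                       reconstruct_mpf_map, solve_mpf,
                                       solve_mpf_voxel, synthetic_reference)
from mpfkit.mt_physics import mt_spgr_steady_state, spgr_signal
from mpfkit.phantom import (PhantomSpec, make_phantom, simulate_acquisition)

CONSTRAINTS = SinglePointConstraints()


@pytest.fixture(scope="module")
def mt_prot():
    return default_protocols()["mt_w"]


class TestSyntheticReference:
    def test_is_ernst_signal_at_mt_settings(self, mt_prot):
        assert synthetic_reference(0.55, 1.0, mt_prot) == pytest.approx(
            spgr_signal(1.0, 0.55, 9.0, 0.022), rel=1e-12)

    def test_zero_pd_gives_zero(self, mt_prot):
        assert synthetic_reference(0.55, 0.0, mt_prot) == 0.0

    def test_direct_formula(self, mt_prot):
        a = np.deg2rad(9.0)
        e1 = np.exp(-0.022 * 0.55)
        expected = np.sin(a) * (1 - e1) / (1 - e1 * np.cos(a))
        assert synthetic_reference(0.55, 1.0, mt_prot) == pytest.approx(
            expected, rel=1e-12)


class TestSolveVoxel:
    def test_forward_model_round_trip(self, mt_prot):
        f_true, r1_obs = 0.13, 0.55
        ratio = float(model_ratio(f_true, r1_obs, 0.0, 1.0, CONSTRAINTS,
                                  mt_prot))
        f_est = solve_mpf_voxel(ratio, r1_obs, 0.0, 1.0, CONSTRAINTS, mt_prot)
        assert f_est == pytest.approx(f_true, abs=1e-4)

    def test_zero_f_boundary(self, mt_prot):
        r1_obs = 0.55
        ratio = float(model_ratio(0.0, r1_obs, 0.0, 1.0, CONSTRAINTS,
                                  mt_prot))
        f_est = solve_mpf_voxel(ratio, r1_obs, 0.0, 1.0, CONSTRAINTS, mt_prot)
        assert f_est == pytest.approx(0.0, abs=1e-4)

    def test_model_ratio_monotone_decreasing(self, mt_prot):
        fs = np.linspace(0.0, 0.45, 46)
        ratios = model_ratio(fs, 0.55, 0.0, 1.0, CONSTRAINTS, mt_prot)
        assert np.all(np.diff(ratios) < 0)

    def test_unbracketed_ratio_returns_nan(self, mt_prot):
        f = solve_mpf_voxel(0.9999, 0.55, 0.0, 1.0, CONSTRAINTS, mt_prot)
        assert np.isnan(f)

    @pytest.mark.parametrize("f_true", [0.05, 0.10, 0.15, 0.20, 0.25])
    @pytest.mark.parametrize("r1,b1,b0", [(0.3, 0.8, -200.0), (0.6, 1.0, 0.0),
                                          (1.2, 1.2, 200.0)])
    def test_round_trip_grid(self, f_true, r1, b1, b0, mt_prot):
        """Forward-simulate then invert over the full parameter grid."""
        ratio = float(model_ratio(f_true, r1, b0, b1, CONSTRAINTS, mt_prot))
        f_est = solve_mpf_voxel(ratio, r1, b0, b1, CONSTRAINTS, mt_prot)
        assert f_est == pytest.approx(f_true, abs=1e-4)


class TestReconstructMap:
    def test_noiseless_phantom_structure_means(self, small_phantom):
        acq = simulate_acquisition(small_phantom, sigma=0.0)
        v = acq.volumes
        qm = reconstruct_mpf_map(v["mt_w"], v["t1_w"], v["pd_w"],
                                 small_phantom.fields.b0_offset,
                                 small_phantom.fields.b1_scale)
        truth = small_phantom.structure_mean_mpf()
        for name, t in truth.items():
            est = np.nanmean(qm.mpf[small_phantom.structure_mask(name)])
            assert est == pytest.approx(t, abs=0.1), name

    def test_background_is_nan(self, small_phantom):
        acq = simulate_acquisition(small_phantom, sigma=0.0)
        v = acq.volumes
        qm = reconstruct_mpf_map(v["mt_w"], v["t1_w"], v["pd_w"])
        assert np.isnan(qm.mpf[~small_phantom.brain_mask]).all()

    def test_shape_mismatch_errors(self):
        a = np.ones((4, 4, 2))
        with pytest.raises(ValueError):
            reconstruct_mpf_map(a, a, np.ones((4, 4, 3)))

    def test_pd_scaling_invariance(self, small_phantom):
        """Scaling all three source images by one global factor leaves the
        MPF map unchanged."""
        acq = simulate_acquisition(small_phantom, sigma=0.0)
        v = acq.volumes
        qm1 = reconstruct_mpf_map(v["mt_w"], v["t1_w"], v["pd_w"],
                                  small_phantom.fields.b0_offset,
                                  small_phantom.fields.b1_scale)
        qm2 = reconstruct_mpf_map(7.3 * v["mt_w"], 7.3 * v["t1_w"],
                                  7.3 * v["pd_w"],
                                  small_phantom.fields.b0_offset,
                                  small_phantom.fields.b1_scale)
        m = small_phantom.brain_mask
        assert np.allclose(qm1.mpf[m], qm2.mpf[m], equal_nan=True,
                           atol=1e-10)

    def test_b1_correction_removes_systematic_error(self):
        """A phantom with a uniform 0.85 B1 scale reconstructs with a clear
        MPF bias when B1 is ignored, removed when the map is supplied."""
        spec = PhantomSpec(shape=(32, 32, 8),
                           b1_poly=(0.85,) + (0.0,) * 9,
                           b0_poly=(0.0,) * 10)
        ph = make_phantom(spec)
        acq = simulate_acquisition(ph, sigma=0.0)
        v = acq.volumes
        cc = ph.structure_mask("corpus_callosum")
        truth = ph.structure_mean_mpf()["corpus_callosum"]
        qm_nocorr = reconstruct_mpf_map(v["mt_w"], v["t1_w"], v["pd_w"])
        qm_corr = reconstruct_mpf_map(v["mt_w"], v["t1_w"], v["pd_w"],
                                      ph.fields.b0_offset,
                                      ph.fields.b1_scale)
        err_nocorr = abs(np.nanmean(qm_nocorr.mpf[cc]) - truth)
        err_corr = abs(np.nanmean(qm_corr.mpf[cc]) - truth)
        assert err_nocorr > 0.3
        assert err_corr < 0.01

    def test_estimated_fields_close_to_truth_fields(self, small_phantom,
                                                    protocols):
        """Reconstruction through the estimated (AFI + dual-TE) field maps
        agrees with reconstruction through the true fields."""
        acq = simulate_acquisition(small_phantom, sigma=0.0)
        v = acq.volumes
        te1, te2 = protocols["b0"].TEs
        fm = estimate_field_maps(v["afi1"], v["afi2"], v["b0_phase1"],
                                 v["b0_phase2"], small_phantom.spec.shape,
                                 protocols["afi"].TR, 0.065,
                                 protocols["afi"].flip, te1, te2,
                                 signal=v["afi1"], signal_threshold=1e-9)
        qm = reconstruct_mpf_map(v["mt_w"], v["t1_w"], v["pd_w"],
                                 fm.b0_offset, fm.b1_scale)
        truth = small_phantom.structure_mean_mpf()
        for name, t in truth.items():
            est = np.nanmean(qm.mpf[small_phantom.structure_mask(name)])
            assert est == pytest.approx(t, abs=0.1), name


class TestNoisyRecovery:
    def test_wm_gm_contrast_preserved_in_noise(self, small_phantom):
        """Corpus callosum keeps higher mean MPF than cortex in every noisy
        replicate."""
        for seed in range(5):
            acq = simulate_acquisition(small_phantom, sigma_fraction=0.01,
                                       seed=seed)
            v = acq.volumes
            qm = reconstruct_mpf_map(v["mt_w"], v["t1_w"], v["pd_w"],
                                     small_phantom.fields.b0_offset,
                                     small_phantom.fields.b1_scale,
                                     noise_sigma=acq.sigma)
            cc = np.nanmean(qm.mpf[small_phantom.structure_mask(
                "corpus_callosum")])
            cx = np.nanmean(qm.mpf[small_phantom.structure_mask("cortex")])
            assert cc > cx
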