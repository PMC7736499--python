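"""Light-microscopy quantification: VF, decay fits, diffusivity, FRAP,
profiles, ratiometric responses."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from papsim.errors import FitError, InputError
from papsim.optical import (
    FWHM_PER_SIGMA,
    LineScan,
    VFTrace,
    compute_frap_rate,
    compute_vf,
    estimate_point_source_diffusivity,
    fit_profile_fwhm,
    fit_saturation_binding,
    fit_vf_decay,
    iglusnfr_profile,
    ratiometric_response,
)
from papsim.synth import (
    gen_point_source_linescan,
    gen_uncaging_linescan,
    gen_vf_trace,
)


class TestComputeVf:
    def test_somatic_self_normalisation(self):
        assert compute_vf(100.0, 100.0, 0.0) == 1.0

    def test_physiological_range(self):
        # 6.5% of somatic fluorescence -> VF inside the measured 6-7% range
        assert compute_vf(6.5, 100.0, 0.0) == pytest.approx(0.065)

    @given(
        c=st.floats(min_value=0.01, max_value=1e4),
        roi=st.floats(min_value=0.0, max_value=50.0),
        bg=st.floats(min_value=0.0, max_value=10.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_scale_invariance(self, c, roi, bg):
        soma = 100.0
        v1 = compute_vf(roi, soma, bg)
        v2 = compute_vf(c * roi, c * soma, c * bg)
        assert v2 == pytest.approx(v1, rel=1e-9, abs=1e-12)

    def test_degenerate_normalisation(self):
        with pytest.raises(InputError):
            compute_vf(1.0, 5.0, 5.0)


class TestVfDecayFit:
    def test_noiseless_exact_recovery(self):
        trace, truth = gen_vf_trace(vf_ss=0.77, tau=14.0, noise_sd=0.0, seed=0)
        fit = fit_vf_decay(trace)
        assert fit.identifiable
        assert fit.vf_ss == pytest.approx(0.77, abs=1e-10)
        assert fit.tau == pytest.approx(14.0, rel=1e-8)
        assert fit.residual_rms < 1e-10

    def test_constant_trace_unidentifiable(self):
        trace = VFTrace(np.linspace(0, 30, 20), np.ones(20))
        fit = fit_vf_decay(trace)
        assert not fit.identifiable
        assert np.isnan(fit.tau)
        assert fit.vf_ss == pytest.approx(1.0)

    def test_median_bias_small_at_two_percent_noise(self):
        # repeated-fit simulation at the LTP-decay operating point
        vs, ts = [], []
        for seed in range(200):
            trace, _ = gen_vf_trace(
                vf_ss=0.77, tau=14.0, noise_sd=0.02, n_points=30, seed=seed
            )
            fit = fit_vf_decay(trace)
            if fit.identifiable:
                vs.append(fit.vf_ss)
                ts.append(fit.tau)
        assert abs(np.median(vs) / 0.77 - 1.0) < 0.03
        assert abs(np.median(ts) / 14.0 - 1.0) < 0.03

    def test_too_few_points_rejected(self):
        with pytest.raises(InputError):
            fit_vf_decay(VFTrace(np.arange(3), np.ones(3)))


class TestDiffusivity:
    def test_noiseless_recovery_exact(self):
        scan, t = gen_point_source_linescan(d_coeff=0.4, noise_sd=0.0, seed=0)
        fit = estimate_point_source_diffusivity(
            scan, t["source_position_um"], t["puff_time_ms"]
        )
        assert fit.d_eff == pytest.approx(0.4, rel=1e-6)

    @pytest.mark.parametrize("d_true", [0.1, 0.4, 1.0])
    def test_recovery_within_five_percent(self, d_true):
        scan, t = gen_point_source_linescan(d_coeff=d_true, seed=17)
        fit = estimate_point_source_diffusivity(
            scan, t["source_position_um"], t["puff_time_ms"]
        )
        assert fit.d_eff == pytest.approx(d_true, rel=0.05)

    def test_doubling_d_doubles_slope(self):
        fits = []
        for d in (0.2, 0.4):
            scan, t = gen_point_source_linescan(d_coeff=d, noise_sd=0.0, seed=1)
            fits.append(
                estimate_point_source_diffusivity(
                    scan, t["source_position_um"], t["puff_time_ms"]
                ).d_eff
            )
        assert fits[1] / fits[0] == pytest.approx(2.0, rel=1e-4)

    def test_early_line_w_near_zero(self):
        from papsim.optical.diffusion import _fit_line_w

        scan, t = gen_point_source_linescan(
            d_coeff=0.4, noise_sd=0.0, dt=0.25, duration=6.0, seed=0
        )
        i = np.searchsorted(scan.times, t["puff_time_ms"]) + 2
        w = _fit_line_w(scan.positions, scan.intensity[i])
        # early line: fitted w = D * t_elapsed, still small
        te = scan.times[i] - t["puff_time_ms"]
        assert w == pytest.approx(0.4 * te, rel=0.05)
        assert w < 0.3

    def test_amplitude_scaling_leaves_d_unchanged(self):
        d = []
        for amp in (50.0, 200.0):
            scan, t = gen_point_source_linescan(
                d_coeff=0.4, amplitude=amp, noise_sd=0.0, seed=2
            )
            d.append(
                estimate_point_source_diffusivity(
                    scan, t["source_position_um"], t["puff_time_ms"]
                ).d_eff
            )
        assert d[0] == pytest.approx(d[1], rel=1e-6)

    def test_source_outside_scan_rejected(self):
        scan, t = gen_point_source_linescan(seed=0)
        with pytest.raises(InputError):
            estimate_point_source_diffusivity(scan, 1e4, t["puff_time_ms"])


class TestFrap:
    def _trace(self, slope, n=100, bleach=(20, 30)):
        t = np.arange(n, dtype=float)
        y = np.full(n, 100.0)
        y[bleach[0]:bleach[1]] = 30.0
        rec = np.arange(n - bleach[1], dtype=float)
        y[bleach[1]:] = 30.0 + slope * rec
        return y, bleach

    def test_identical_to_reference_is_100_percent(self):
        y, b = self._trace(2.0)
        ref = compute_frap_rate(y, b).rate
        res = compute_frap_rate(y, b, reference_rate=ref)
        assert res.rate_percent_of_reference == pytest.approx(100.0)

    def test_sixty_two_percent_of_reference(self):
        y_ref, b = self._trace(2.0)
        ref = compute_frap_rate(y_ref, b).rate
        y_slow, _ = self._trace(2.0 * 0.62)
        res = compute_frap_rate(y_slow, b, reference_rate=ref)
        assert res.rate_percent_of_reference == pytest.approx(62.0, rel=1e-6)

    def test_zero_slope_zero_percent(self):
        y, b = self._trace(0.0)
        ref = 2.0
        res = compute_frap_rate(y, b, reference_rate=ref)
        assert res.rate_percent_of_reference == pytest.approx(0.0, abs=1e-9)

    def test_no_recovery_segment_rejected(self):
        y = np.full(30, 100.0)
        with pytest.raises(InputError):
            compute_frap_rate(y, (20, 29))

    def test_exponential_estimator_agrees_on_initial_slope(self):
        n, b1 = 200, 30
        t = np.arange(n - b1, dtype=float)
        y = np.full(n, 100.0)
        y[20:b1] = 20.0
        y[b1:] = 100.0 - 80.0 * np.exp(-t / 50.0)
        res_exp = compute_frap_rate(y, (20, 30), method="exponential")
        true_slope = (80.0 / 100.0) / 50.0
        assert res_exp.rate == pytest.approx(true_slope, rel=0.05)


class TestProfiles:
    def test_fwhm_sigma_identity_machine_precision(self):
        x = np.linspace(-3, 3, 301)
        prof = np.exp(-(x**2) / (2 * 0.1**2))
        fit = fit_profile_fwhm(prof, positions=x, center=0.0,
                               fit_baseline=False)
        assert fit.fwhm == pytest.approx(FWHM_PER_SIGMA * 0.1, rel=1e-9)

    def test_nine_percent_fwhm_change_scenario(self):
        pre, post, truth = gen_uncaging_linescan(
            sigma_pre=1.0, sigma_post=1.09, noise_sd=0.0, seed=0
        )
        xc = truth["uncaging_position_um"]
        n_pre = truth["n_pre_lines"]

        def fwhm(scan):
            prof = iglusnfr_profile(scan, (0, n_pre), (n_pre, scan.n_lines))
            return fit_profile_fwhm(
                prof, positions=scan.positions, center=xc
            ).fwhm

        change = fwhm(post) / fwhm(pre) - 1.0
        assert change == pytest.approx(0.09, abs=1e-4)

    def test_baseline_offset_leaves_fwhm_unchanged(self):
        x = np.linspace(-3, 3, 301)
        prof = np.exp(-(x**2) / (2 * 0.2**2))
        f1 = fit_profile_fwhm(prof, positions=x, center=0.0).fwhm
        f2 = fit_profile_fwhm(prof + 0.5, positions=x, center=0.0).fwhm
        assert f1 == pytest.approx(f2, rel=1e-6)

    def test_flat_profile_rejected(self):
        with pytest.raises(FitError):
            fit_profile_fwhm(np.ones(50))

    def test_identical_windows_zero_profile(self):
        scan, _, _ = gen_uncaging_linescan(noise_sd=0.0, seed=0)[0:3]
        prof = iglusnfr_profile(scan, (0, 10), (10, 20))
        np.testing.assert_allclose(prof, 0.0, atol=1e-12)

    def test_pure_function_repeatability(self):
        scan, _, truth = gen_uncaging_linescan(seed=4)
        a = iglusnfr_profile(scan, (0, 10), (20, 40))
        b = iglusnfr_profile(scan, (0, 10), (20, 40))
        np.testing.assert_array_equal(a, b)

    def test_overlapping_windows_rejected(self):
        scan, _, _ = gen_uncaging_linescan(seed=0)[0:3]
        with pytest.raises(InputError):
            iglusnfr_profile(scan, (0, 15), (10, 25))

    def test_gaussian_amplitude_recovered(self):
        pre, post, truth = gen_uncaging_linescan(
            amplitude=0.8, noise_sd=0.5, seed=9
        )
        prof = iglusnfr_profile(
            post, (0, truth["n_pre_lines"]), (truth["n_pre_lines"], post.n_lines)
        )
        peak = np.nanmax(prof)
        assert peak == pytest.approx(0.8, abs=0.1)


class TestRatiometric:
    def test_common_scaling_gives_zero(self):
        d = np.array([1.0, 2.0, 3.0, 4.0])
        a = 2.0 * d
        dr = ratiometric_response(d, a)
        np.testing.assert_allclose(dr, 0.0, atol=1e-12)

    def test_baseline_only_near_zero(self, rng):
        d = 10.0 + rng.normal(0, 0.01, 200)
        a = 20.0 + rng.normal(0, 0.01, 200)
        dr = ratiometric_response(d, a)
        assert abs(np.nanmean(dr)) < 0.01

    def test_titration_recovers_half_saturation(self, rng):
        kd = 0.6
        c = np.logspace(-2, 1, 12)
        y = 1.5 * c / (c + kd) + rng.normal(0, 0.005, len(c))
        fit = fit_saturation_binding(c, y)
        assert fit["kd"] == pytest.approx(kd, rel=0.05)

    def test_zero_acceptor_masked(self):
        d = np.ones(5)
        a = np.array([1.0, 0.0, 1.0, 1.0, 1.0])
        dr = ratiometric_response(d, a)
        assert np.isnan(dr[1])
        with pytest.raises(InputError):
            ratiometric_response(d, a, mask_zero_acceptor=False)


class TestLineScanContainer:
    def test_tiff_round_trip(self, tmp_path, rng):
        from papsim.optical import read_linescan_tiff, write_linescan_tiff

        scan = LineScan(rng.uniform(0, 100, (30, 64)), 2.0, 0.1)
        path = tmp_path / "scan.tif"
        write_linescan_tiff(path, scan)
        back = read_linescan_tiff(path, 2.0, 0.1)
        np.testing.assert_allclose(back.intensity, scan.intensity, rtol=1e-6)

    def test_invalid_matrix_rejected(self):
        with pytest.raises(InputError):
            LineScan(np.zeros((0, 5)), 1.0, 1.0)
        with pytest.raises(InputError):
            LineScan(np.ones((5, 5)), -1.0, 1.0)
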