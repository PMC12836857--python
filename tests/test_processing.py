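"""Processing chain: FT, phasing, integration, SNR, mode choice, pipeline."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, strategies as st

from slicelogp import synth
from slicelogp.errors import DomainError, QuantificationError
from slicelogp.processing import (
    IntegrationWindow,
    PipelineConfig,
    SNR_CAP,
    autophase,
    choose_mode,
    determine_o1p,
    extract_rows,
    fourier,
    integrate,
    logp,
    logp_error,
    run_pipeline,
    shift_and_sum,
    snr,
)


def _single_line(params, amp=1.0, shift=-73.0, fwhm=2.0, rng=None):
    return synth.synth_fid([(amp, shift, fwhm, None)], params, rng)


class TestFourier:
    def test_delta_fid_is_flat(self):
        params = synth.AcquisitionParams(td=1024, ns=1)
        fid = np.zeros(512, dtype=complex)
        fid[0] = 1.0
        spec = fourier(fid, params, zero_fill_factor=1)
        assert np.ptp(spec.real) < 1e-12  # constant level everywhere

    def test_lorentzian_fwhm(self):
        """A damped exponential transforms to a Lorentzian whose FWHM matches
        the damping constant within the grid resolution."""
        params = synth.AcquisitionParams(noise_sigma=0.0, o1p=-73.0)
        spec = fourier(_single_line(params, fwhm=4.0), params, zero_fill_factor=4)
        y = spec.real
        half = y.max() / 2.0
        above = np.nonzero(y > half)[0]
        width_hz = (above[-1] - above[0]) * spec.delta_ppm * spec.f_spec
        grid = spec.delta_ppm * spec.f_spec
        assert width_hz == pytest.approx(4.0, abs=2 * grid)

    def test_zero_fill_preserves_integrals(self):
        params = synth.AcquisitionParams(noise_sigma=0.0, o1p=-73.0)
        w = IntegrationWindow(-73.0, 1.0)
        i1 = integrate(fourier(_single_line(params), params, 1), w)
        i2 = integrate(fourier(_single_line(params), params, 2), w)
        assert i2 == pytest.approx(i1, rel=1e-3)


class TestAutophase:
    def test_recovers_rotation(self):
        params = synth.AcquisitionParams(noise_sigma=0.0, o1p=-73.0, phase0=37.0)
        spec = fourier(_single_line(params), params)
        _, phi, _ = autophase(spec)
        assert phi == pytest.approx(37.0, abs=0.5)

    def test_already_phased_unchanged(self):
        params = synth.AcquisitionParams(noise_sigma=0.0, o1p=-73.0)
        spec = fourier(_single_line(params), params)
        _, phi, _ = autophase(spec)
        assert abs(phi) <= 0.5

    def test_pure_noise_flagged_not_failed(self):
        params = synth.AcquisitionParams(td=4096, ns=1, noise_sigma=1e-6, seed=9)
        spec = fourier(synth.synth_fid([], params), params)
        phased, phi, warn = autophase(spec)
        assert np.all(np.isfinite(phased.data))
        assert any("low confidence" in w for w in warn)


class TestDetermineO1p:
    def test_clean_peak_located(self):
        params = synth.AcquisitionParams(
            td=4096, ns=1, sweep_width=490.0, o1p=-50.0, noise_sigma=0.0
        )
        spec = fourier(_single_line(params, shift=-75.0, fwhm=3.0), params)
        o1p, rescan = determine_o1p(spec, ns_used=1)
        assert o1p == pytest.approx(-75.0, abs=2 * spec.delta_ppm)
        assert not rescan

    def test_larger_of_two_peaks_chosen(self):
        params = synth.AcquisitionParams(
            td=4096, ns=1, sweep_width=490.0, o1p=-50.0, noise_sigma=0.0
        )
        fid = synth.synth_fid(
            [(5.0, -120.0, 3.0, None), (1.0, -75.0, 3.0, None)], params
        )
        o1p, _ = determine_o1p(fourier(fid, params), ns_used=1)
        assert o1p == pytest.approx(-120.0, abs=0.5)

    def test_weak_scout_requests_rescan(self):
        """An SNR~2 scout at a single transient triggers the rescan rule in
        at least 90% of seeds."""
        hits = 0
        for seed in range(100):
            params = synth.AcquisitionParams(
                td=4096, ns=1, sweep_width=490.0, o1p=-50.0,
                noise_sigma=1e-6, seed=seed,
            )
            # amplitude calibrated so peak ~ 4x the spectral noise RMS
            rms = math.sqrt(2048) * 1e-6 * params.dwell
            amp = 4 * rms / synth.peak_height_factor(3.0, params.acquisition_time)
            fid = synth.synth_fid(
                [(amp, -75.0, 3.0, None)], params, synth.rng_for(seed, 0)
            )
            _, rescan = determine_o1p(fourier(fid, params), ns_used=1)
            hits += rescan
        assert hits >= 90

    def test_empty_spectrum_rejected(self):
        from slicelogp.processing import Spectrum1D

        with pytest.raises(DomainError):
            determine_o1p(
                Spectrum1D(np.array([], dtype=complex), np.array([]), 0.0, 564.0),
                ns_used=1,
            )


class TestExtractRows:
    def test_identical_rows_identical_spectra(self, plan600, identity_sample,
                                              quiet_params):
        ds = synth.simulate_pseudo2d(identity_sample(0.0), plan600, quiet_params)
        ds.rows[1] = ds.rows[0]
        s0, s1, _ = extract_rows(ds)
        assert np.array_equal(s0.data, s1.data)

    def test_row_order_metadata_honored(self, plan600, identity_sample,
                                        quiet_params):
        ds = synth.simulate_pseudo2d(identity_sample(1.0), plan600, quiet_params)
        flipped = synth.PseudoSpectrum2D(
            rows=ds.rows[::-1].copy(),
            params=ds.params,
            plan=ds.plan,
            provenance={**ds.provenance, "row_order": "aqueous_first"},
        )
        a_oct, a_aq, _ = extract_rows(ds)
        b_oct, b_aq, _ = extract_rows(flipped)
        assert np.allclose(a_oct.data, b_oct.data)

    def test_missing_row_order_warns(self, plan600, identity_sample, quiet_params):
        ds = synth.simulate_pseudo2d(identity_sample(1.0), plan600, quiet_params)
        ds.provenance.pop("row_order")
        _, _, warn = extract_rows(ds)
        assert any("row order" in w for w in warn)

    def test_scaling_identity(self, plan600, identity_sample, quiet_params):
        """Peak-height ratio of the extracted spectra equals the FID
        amplitude ratio (identical scale factors for both rows)."""
        ds = synth.simulate_pseudo2d(identity_sample(2.0), plan600, quiet_params)
        s_oct, s_aq, _ = extract_rows(ds)
        assert s_oct.real.max() / s_aq.real.max() == pytest.approx(100.0, rel=1e-6)


class TestShiftAndSum:
    def test_zero_offset_exact_sum(self, plan600, identity_sample, quiet_params):
        ds = synth.simulate_pseudo2d(identity_sample(0.5), plan600, quiet_params)
        s_oct, s_aq, _ = extract_rows(ds)
        summed, warn = shift_and_sum(s_oct, s_aq)
        assert np.array_equal(summed.data, s_oct.data + s_aq.data)
        assert warn == []

    def test_manual_shift_resolves_overlap(self, plan600, quiet_params):
        """Coincident lines become two resolvable maxima after a 2 ppm
        manual displacement."""
        an = synth.Analyte("overlap", 1, -74.0, -74.0, 2.0, 2.0, 3.0, 3.0, 0.6, 0.6)
        ds = synth.simulate_pseudo2d(
            synth.PartitionSample(an, 0.0, 0.05), plan600,
            replace(quiet_params, o1p=-74.0),
        )
        s_oct, s_aq, _ = extract_rows(ds)
        summed, _ = shift_and_sum(s_oct, s_aq, manual_offset_ppm=2.0)
        from slicelogp.processing import pick_peaks

        i1, i2 = pick_peaks(summed, 2, min_separation=1.0)
        assert abs(summed.ppm[i1] - summed.ppm[i2]) == pytest.approx(2.0, abs=0.05)

    def test_integral_conserved_under_shift(self, plan600, identity_sample,
                                            quiet_params):
        ds = synth.simulate_pseudo2d(identity_sample(0.0), plan600, quiet_params)
        s_oct, s_aq, _ = extract_rows(ds)
        w = IntegrationWindow(-75.0, 1.0)
        before = integrate(s_aq, w)
        summed, _ = shift_and_sum(s_oct, s_aq, manual_offset_ppm=2.0)
        # aqueous line moved from -75.0 to -73.0; octanol line is at -72.5
        after = integrate(summed, IntegrationWindow(-73.0, 1.0)) - integrate(
            s_oct, IntegrationWindow(-73.0, 1.0)
        )
        assert after == pytest.approx(before, rel=1e-3)


class TestIntegrate:
    def test_lorentzian_capture_fraction(self):
        """A 1 ppm window at 376.5 MHz around a 2 Hz line captures the
        analytic Lorentzian CDF fraction (2/pi) atan(window/FWHM)."""
        params = synth.AcquisitionParams(
            proton_freq=400.13, o1p=-73.0, noise_sigma=0.0
        )
        spec = fourier(_single_line(params, amp=1.0 / params.ns, fwhm=2.0), params)
        got = integrate(spec, IntegrationWindow(-73.0, 1.0))
        window_hz = 1.0 * params.f_spec
        # halved first point scales every integral by 1/2
        expected = 0.5 * (2 / math.pi) * math.atan(window_hz / 2.0)
        assert got == pytest.approx(expected, rel=2e-3)

    def test_amplitude_linearity(self, quiet_params):
        spec1 = fourier(_single_line(quiet_params, amp=1.0), quiet_params)
        spec2 = fourier(_single_line(quiet_params, amp=2.0), quiet_params)
        w = IntegrationWindow(-73.0, 1.0)
        assert integrate(spec2, w) == pytest.approx(2 * integrate(spec1, w), rel=1e-12)

    def test_noise_window_zero_mean(self):
        vals = []
        for seed in range(200):
            params = synth.AcquisitionParams(td=4096, ns=1, noise_sigma=1e-6,
                                             seed=seed)
            spec = fourier(synth.synth_fid([], params), params)
            vals.append(integrate(spec, IntegrationWindow(params.o1p, 1.0)))
        vals = np.asarray(vals)
        assert abs(np.mean(vals)) < 3 * np.std(vals) / math.sqrt(len(vals))

    def test_out_of_bounds_window_rejected(self, quiet_params):
        spec = fourier(_single_line(quiet_params), quiet_params)
        with pytest.raises(DomainError):
            integrate(spec, IntegrationWindow(-64.5, 1.0))


class TestSnr:
    def test_noiseless_returns_cap(self, quiet_params):
        spec = fourier(_single_line(quiet_params), quiet_params)
        assert snr(spec, -73.0, (-69.0, -70.0)) == SNR_CAP

    def test_constructed_snr_recovered(self):
        """Noise scaled for SNR 10 measures 10 within 15% (100-seed mean)."""
        vals = []
        for seed in range(100):
            params = synth.AcquisitionParams(o1p=-73.0, seed=seed, ns=1)
            rms_target = 1.0 * synth.peak_height_factor(
                3.0, params.acquisition_time
            ) / 20.0
            sigma = rms_target / (math.sqrt(params.n_complex) * params.dwell)
            params = replace(params, noise_sigma=sigma)
            spec = fourier(
                _single_line(params, fwhm=3.0, rng=synth.rng_for(seed, 0)), params
            )
            vals.append(snr(spec, -73.0, (-69.0, -70.5)))
        assert np.mean(vals) == pytest.approx(10.0, rel=0.15)

    def test_snr_scales_with_sqrt_ns(self):
        means = {}
        for ns in (4, 16):
            vals = []
            for seed in range(50):
                params = synth.AcquisitionParams(
                    o1p=-73.0, seed=seed, ns=ns, noise_sigma=2e-4
                )
                spec = fourier(
                    _single_line(params, fwhm=3.0, rng=synth.rng_for(seed, 0)),
                    params,
                )
                vals.append(snr(spec, -73.0, (-69.0, -70.5)))
            means[ns] = np.mean(vals)
        assert means[16] / means[4] == pytest.approx(2.0, rel=0.15)

    def test_degenerate_noise_region_rejected(self, quiet_params):
        spec = fourier(_single_line(quiet_params), quiet_params)
        with pytest.raises(DomainError):
            snr(spec, -73.0, (-70.0, -70.0001))


class TestModeAndQuantification:
    @pytest.mark.parametrize(
        "snr_min,expected",
        [(35.66, "summed"), (8.01, "separate"), (10.0, "summed")],
    )
    def test_choose_mode_threshold(self, snr_min, expected):
        assert choose_mode(snr_min) == expected

    @pytest.mark.parametrize("io,ia,expected", [(1, 1, 0.0), (10, 1, 1.0)])
    def test_logp_values(self, io, ia, expected):
        assert logp(io, ia) == pytest.approx(expected)

    @given(st.floats(1e-6, 1e6), st.floats(1e-6, 1e6))
    def test_logp_matches_direct_ratio(self, io, ia):
        assert logp(io, ia) == pytest.approx(math.log10(io / ia))

    def test_nonpositive_integral_names_phase(self):
        with pytest.raises(QuantificationError, match="aqueous"):
            logp(1.0, -0.1)
        with pytest.raises(QuantificationError, match="octanol"):
            logp(0.0, 1.0)

    def test_error_closed_form(self):
        assert logp_error(10, 10) == pytest.approx(
            math.sqrt(2) / (10 * math.log(10))
        )
        assert logp_error(1e9, 1e9) < 1e-8

    @given(
        st.floats(1.0, 1e4), st.floats(1.0, 1e4), st.floats(1.01, 2.0)
    )
    def test_error_monotone_in_snr(self, s1, s2, k):
        assert logp_error(k * s1, s2) < logp_error(s1, s2)
        assert logp_error(s1, k * s2) < logp_error(s1, s2)


class TestPipeline:
    def test_noiseless_identity(self, plan600, identity_sample, quiet_params):
        ds = synth.simulate_pseudo2d(identity_sample(1.5), plan600, quiet_params)
        res = run_pipeline(ds, PipelineConfig(mode="separate"))
        assert res.logp == pytest.approx(1.5, abs=1e-6)
        assert res.sigma_logp is None  # noiseless: capped SNRs, no uncertainty

    def test_scale_invariance(self, plan600, identity_sample, quiet_params):
        ds = synth.simulate_pseudo2d(identity_sample(0.7), plan600, quiet_params)
        ref = run_pipeline(ds, PipelineConfig(mode="separate")).logp
        for c in (1e-3, 42.0):
            scaled = synth.PseudoSpectrum2D(
                rows=ds.rows * c, params=ds.params, plan=ds.plan,
                provenance=dict(ds.provenance),
            )
            assert run_pipeline(
                scaled, PipelineConfig(mode="separate")
            ).logp == pytest.approx(ref, abs=1e-9)

    def test_monotone_in_concentration_ratio(self, plan600, identity_sample,
                                             quiet_params):
        values = [
            run_pipeline(
                synth.simulate_pseudo2d(identity_sample(lp), plan600, quiet_params),
                PipelineConfig(mode="separate"),
            ).logp
            for lp in np.linspace(-1.0, 1.0, 7)
        ]
        assert np.all(np.diff(values) > 0)

    def test_low_snr_warning(self, plan600):
        sample = synth.default_sample("trifluorotoluene")
        params = synth.AcquisitionParams(o1p=-63.9, seed=3)
        sigma = synth.noise_sigma_for_snr(sample, plan600, params, 6.0, "row")
        ds = synth.simulate_pseudo2d(
            sample, plan600, replace(params, noise_sigma=sigma)
        )
        res = run_pipeline(ds)
        assert res.mode == "separate"
        assert any("below" in w for w in res.warnings)

    def test_short_d1_warning(self, plan600, identity_sample):
        params = synth.AcquisitionParams(o1p=-73.75, d1=3.0, noise_sigma=0.0)
        ds = synth.simulate_pseudo2d(identity_sample(1.0), plan600, params)
        res = run_pipeline(ds, PipelineConfig(mode="separate"))
        assert any("5 x T1" in w for w in res.warnings)

    def test_unresolved_overlap_raises(self, plan600, quiet_params):
        an = synth.Analyte("overlap", 1, -74.0, -73.9, 2.0, 2.0, 3.0, 3.0, 0.6, 0.6)
        ds = synth.simulate_pseudo2d(
            synth.PartitionSample(an, 0.0, 0.05), plan600,
            replace(quiet_params, o1p=-74.0),
        )
        with pytest.raises(QuantificationError, match="separate|manual"):
            run_pipeline(ds)

    def test_error_calibration_within_factor_two(self, plan600):
        """Empirical scatter of recovered log P stays within a factor 2 of
        the reported 1/SNR-propagated sigma (200 seeds, SNR ~15)."""
        sample = synth.default_sample("4-fluorophenol")
        vals, sigmas = [], []
        for seed in range(200):
            params = synth.AcquisitionParams(o1p=-124.5, seed=seed)
            sigma = synth.noise_sigma_for_snr(sample, plan600, params, 15.0, "row")
            ds = synth.simulate_pseudo2d(
                sample, plan600, replace(params, noise_sigma=sigma)
            )
            res = run_pipeline(ds)
            vals.append(res.logp)
            sigmas.append(res.sigma_logp)
        ratio = np.std(vals) / np.median(sigmas)
        assert 0.5 <= ratio <= 2.0
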