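"""Spectral processing: difference spectra, λmax, templates, A1/A2 unmixing."""

import numpy as np
import pytest

from opsinadapt import (
    SimSpectrumParams,
    SpectrumCurve,
    build_standard_template,
    difference_spectrum,
    estimate_lambda_max,
    fit_a1_a2_mixture,
    shift_template,
    simulate_spectrum,
)


def make_curve(lmax, phi=0.0, noise=0.0, seed=0, a2=None):
    return simulate_spectrum(SimSpectrumParams(
        lmax, a2 if a2 is not None else lmax + 40.0, phi, noise, seed=seed))


class TestDifferenceSpectrum:
    def test_dark_equals_bleached_gives_zero_curve(self):
        c = make_curve(500.0)
        diff = difference_spectrum(c, c)
        assert np.allclose(diff.absorbance, 0.0)

    def test_zero_bleached_returns_dark_unchanged(self):
        dark = make_curve(520.0)
        zero = SpectrumCurve(dark.wavelengths, np.zeros_like(dark.absorbance))
        diff = difference_spectrum(dark, zero)
        assert np.allclose(diff.absorbance, dark.absorbance)

    def test_difference_peak_sits_at_pigment_lambda_max(self):
        pigment = make_curve(540.0)
        # bleach product: flat baseline offset
        bleached = SpectrumCurve(pigment.wavelengths,
                                 np.full_like(pigment.absorbance, 0.1))
        dark = SpectrumCurve(pigment.wavelengths, pigment.absorbance + 0.1)
        diff = difference_spectrum(dark, bleached)
        lmax, _ = estimate_lambda_max([diff])
        assert abs(lmax - 540.0) < 1.0

    def test_disjoint_grids_rejected(self):
        c1 = SpectrumCurve(np.arange(400.0, 450.0), np.ones(50))
        c2 = SpectrumCurve(np.arange(500.0, 550.0), np.ones(50))
        with pytest.raises(ValueError, match="overlap"):
            difference_spectrum(c1, c2)

    def test_mismatched_grids_resampled_onto_overlap(self):
        c1 = SpectrumCurve(np.arange(400.0, 601.0), np.linspace(0, 1, 201))
        c2 = SpectrumCurve(np.arange(450.0, 651.0, 0.5), np.ones(402) * 0.25)
        diff = difference_spectrum(c1, c2)
        assert diff.wavelengths[0] >= 450.0
        assert diff.wavelengths[-1] <= 600.0


class TestLambdaMax:
    def test_noiseless_rod_a2_pigment_recovered_within_half_nm(self):
        curve = make_curve(503.0, phi=1.0, a2=523.0)
        lmax, se = estimate_lambda_max([curve])
        assert abs(lmax - 523.0) <= 0.5
        assert se == 0.0

    def test_translation_equivariance(self):
        c = make_curve(520.0)
        shifted = SpectrumCurve(c.wavelengths + 10.0, c.absorbance.copy())
        l0, _ = estimate_lambda_max([c])
        l1, _ = estimate_lambda_max([shifted])
        assert l1 - l0 == pytest.approx(10.0, abs=1e-9)

    def test_se_shrinks_with_replicates(self):
        # SE of the mean over 10 replicates ~ sd/sqrt(10)
        singles = [make_curve(530.0, noise=0.01, seed=s) for s in range(40)]
        estimates = [estimate_lambda_max([c])[0] for c in singles]
        sd_single = np.std(estimates, ddof=1)
        _, se10 = estimate_lambda_max(singles[:10])
        assert se10 < sd_single  # pooled SE must beat single-curve spread
        assert se10 == pytest.approx(sd_single / np.sqrt(10), rel=0.8)

    def test_boundary_peak_rejected(self):
        grid = np.arange(560.0, 700.0)
        rising = SpectrumCurve(grid, np.linspace(1, 0, grid.size))
        with pytest.raises(ValueError, match="bracket"):
            estimate_lambda_max([rising])


class TestStandardTemplate:
    def test_average_of_noisy_copies_recovers_clean_shape(self):
        clean = make_curve(540.0)
        noisy = [make_curve(540.0, noise=0.01, seed=s) for s in range(4)]
        tpl = build_standard_template(noisy)
        rebuilt = shift_template(tpl, 540.0)
        # compare on the clean curve's grid restricted to template coverage
        lo, hi = rebuilt.wavelengths[0], rebuilt.wavelengths[-1]
        mask = (clean.wavelengths >= lo) & (clean.wavelengths <= hi)
        interp = np.interp(clean.wavelengths[mask], rebuilt.wavelengths,
                           rebuilt.absorbance)
        rmse = np.sqrt(np.mean((interp - clean.absorbance[mask]) ** 2))
        assert rmse < 0.01 / np.sqrt(4) * 3  # noise/sqrt(4) with smoothing margin

    def test_shape_invariance_across_lambda_max(self):
        # same template shape placed at different peaks must collapse to it
        tpl0 = build_standard_template(
            [make_curve(520.0, noise=0.002, seed=s) for s in range(3)])
        curves = [shift_template(tpl0, lm) for lm in (510.0, 530.0, 550.0)]
        tpl = build_standard_template(curves)
        common = (max(tpl.delta_grid[0], tpl0.delta_grid[0]) + 1,
                  min(tpl.delta_grid[-1], tpl0.delta_grid[-1]) - 1)
        grid = np.arange(*common)
        a = np.interp(grid, tpl.delta_grid, tpl.shape)
        b = np.interp(grid, tpl0.delta_grid, tpl0.shape)
        assert np.max(np.abs(a - b)) < 0.02

    def test_single_curve_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            build_standard_template([make_curve(540.0)])


class TestShiftTemplate:
    @pytest.fixture()
    def template(self):
        return build_standard_template(
            [make_curve(540.0, noise=0.001, seed=s) for s in range(3)])

    def test_identity_at_reference(self, template):
        c = shift_template(template, template.reference_lambda_max)
        i = np.argmax(c.absorbance)
        assert abs(c.wavelengths[i] - template.reference_lambda_max) <= 1.0

    def test_round_trip_shift(self, template):
        up = shift_template(template, template.reference_lambda_max + 20.0)
        tpl2 = build_standard_template([up, up])
        back = shift_template(tpl2, template.reference_lambda_max)
        ref = shift_template(template, template.reference_lambda_max)
        grid = np.arange(back.wavelengths[0] + 2, back.wavelengths[-1] - 2)
        a = np.interp(grid, back.wavelengths, back.absorbance)
        b = np.interp(grid, ref.wavelengths, ref.absorbance)
        assert np.max(np.abs(a - b)) < 0.02

    def test_argmax_lands_on_target_at_fine_resolution(self, template):
        target = 531.7
        fine = np.arange(480.0, 580.0, 0.1)
        c = shift_template(template, target, wavelengths=fine)
        assert abs(fine[np.argmax(c.absorbance)] - target) <= 0.5

    def test_target_outside_grid_rejected(self, template):
        with pytest.raises(ValueError):
            shift_template(template, 531.0, wavelengths=np.arange(600.0, 700.0))


class TestMixtureFit:
    @pytest.fixture()
    def templates(self):
        # LWS endpoints: A1 at 544 nm, A2 at 595 nm
        a1 = make_curve(544.0, phi=0.0, a2=595.0)
        a2 = make_curve(544.0, phi=1.0, a2=595.0)
        return a1, a2

    def test_observed_at_a1_peak_gives_phi_zero(self, templates):
        a1, a2 = templates
        lmax, _ = estimate_lambda_max([a1])
        fit = fit_a1_a2_mixture(a1, a2, observed_lambda_max=lmax)
        assert fit.a2_fraction == pytest.approx(0.0, abs=0.011)

    @pytest.mark.parametrize("mode", ["peak-match", "curve-match"])
    def test_noiseless_half_mixture_recovered_exactly(self, templates, mode):
        a1, a2 = templates
        observed = make_curve(544.0, phi=0.5, a2=595.0)
        fit = fit_a1_a2_mixture(a1, a2, observed=observed, mode=mode)
        assert abs(fit.a2_fraction - 0.5) <= 0.011  # within one grid step

    def test_mixture_lambda_max_monotone_in_phi(self, templates):
        a1, a2 = templates
        lmaxes = []
        for phi in np.linspace(0, 1, 21):
            obs = make_curve(544.0, phi=float(phi), a2=595.0)
            fit = fit_a1_a2_mixture(a1, a2, observed=obs, mode="peak-match")
            lmaxes.append(fit.lambda_max)
        assert all(b >= a - 1e-9 for a, b in zip(lmaxes, lmaxes[1:]))

    def test_out_of_interval_observation_clamped_with_warning(self, templates):
        a1, a2 = templates
        with pytest.warns(UserWarning, match="clamp"):
            fit = fit_a1_a2_mixture(a1, a2, observed_lambda_max=500.0)
        assert fit.a2_fraction == 0.0
        with pytest.warns(UserWarning, match="clamp"):
            fit = fit_a1_a2_mixture(a1, a2, observed_lambda_max=650.0)
        assert fit.a2_fraction == 1.0

    def test_noisy_recovery_curve_match(self, templates):
        a1, a2 = templates
        errs = []
        for rep in range(25):
            obs = make_curve(544.0, phi=0.25, a2=595.0, noise=0.005, seed=rep)
            fit = fit_a1_a2_mixture(a1, a2, observed=obs, mode="curve-match")
            errs.append(abs(fit.a2_fraction - 0.25))
        assert np.mean(errs) <= 0.05
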