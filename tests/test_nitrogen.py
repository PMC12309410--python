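"""Piecewise exponential nitrogen-loss fit and derived fluxes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seepflux import (
    LossModelFit,
    SedimentProfile,
    ValidationError,
    areal_loss_flux,
    fit_loss_profile,
    loss_timescale,
    sediment_input_flux,
)
from seepflux.synthetic import GUAYMAS_DEMO, make_sediment


def _profile_from_tn(depth, tn):
    n = len(depth)
    return SedimentProfile("t", depth, np.ones(n), tn,
                           np.full(n, -22.0), np.full(n, 8.0))


class TestFitLossProfile:
    def test_noise_free_exact_recovery(self):
        """y0=1, a=0.9, x_b=7 sampled to 20 cm is recovered to 1e-6."""
        depth = np.arange(1.0, 21.0)
        tn = np.where(depth <= 7, 0.9 ** depth, 0.9 ** 7)
        fit = fit_loss_profile(_profile_from_tn(depth, tn))
        assert fit.y0 == pytest.approx(1.0, abs=1e-6)
        assert fit.a == pytest.approx(0.9, abs=1e-6)
        assert fit.x_b == pytest.approx(7.0)
        assert fit.f_loss == pytest.approx(1 - 0.9 ** 7, abs=1e-6)
        assert fit.f_loss == pytest.approx(0.5217, abs=1e-3)
        assert fit.rmse < 1e-8

    def test_f_loss_internal_identity(self):
        fit = fit_loss_profile(make_sediment(GUAYMAS_DEMO))
        assert fit.f_loss == pytest.approx(1 - fit.a ** fit.x_b, abs=1e-12)
        assert fit.y_refractory == pytest.approx(fit.y0 * fit.a ** fit.x_b)
        assert fit.y0 >= fit.y_refractory >= 0

    def test_constant_profile_flagged_no_loss(self):
        depth = np.arange(1.0, 11.0)
        fit = fit_loss_profile(_profile_from_tn(depth, np.full(10, 0.5)))
        assert fit.a == 1.0
        assert fit.f_loss == 0.0
        assert "no detectable loss" in fit.flags

    def test_too_few_samples_rejected(self):
        depth = np.array([1.0, 2, 3, 4])
        with pytest.raises(ValidationError):
            fit_loss_profile(_profile_from_tn(depth, 0.9 ** depth))

    def test_breakpoint_within_sampled_range(self):
        fit = fit_loss_profile(make_sediment(GUAYMAS_DEMO))
        assert 1.0 <= fit.x_b <= 20.0

    @settings(deadline=None, max_examples=20)
    @given(scale=st.floats(0.1, 10))
    def test_f_loss_invariant_under_unit_rescaling(self, scale):
        depth = np.arange(1.0, 21.0)
        tn = np.where(depth <= 7, 0.9 ** depth, 0.9 ** 7)
        f1 = fit_loss_profile(_profile_from_tn(depth, tn)).f_loss
        f2 = fit_loss_profile(_profile_from_tn(depth, scale * tn)).f_loss
        assert f1 == pytest.approx(f2, abs=1e-9)

    def test_recovery_under_noise_small_sample(self):
        """20 seeded noisy profiles: median |f_loss error| stays small.

        (The full 200-replicate study-condition check lives in the
        acceptance suite.)
        """
        rng = np.random.default_rng(0)
        errs = []
        for _ in range(20):
            a = rng.uniform(0.85, 0.98)
            x_b = rng.uniform(4, 10)
            params = GUAYMAS_DEMO.replace(a=a, x_b=x_b, y0=1.0,
                                          seed=int(rng.integers(2 ** 31)))
            fit = fit_loss_profile(make_sediment(params))
            errs.append(abs(fit.f_loss - (1 - a ** x_b)))
        assert np.median(errs) < 0.05


class TestTimescaleAndFluxes:
    def test_timescale_hand_arithmetic(self):
        assert loss_timescale(7.0, 0.25) == pytest.approx(28.0)
        assert loss_timescale(0.0, 0.1) == 0.0

    def test_timescale_brackets_printed_range(self):
        """x_b = 6.7 cm with SR 0.08-0.25 cm/yr gives 26.8-83.75 yr."""
        assert loss_timescale(6.7, 0.25) == pytest.approx(26.8)
        assert loss_timescale(6.7, 0.08) == pytest.approx(83.75)

    def test_bad_sr_rejected(self):
        with pytest.raises(ValidationError):
            loss_timescale(7.0, 0.0)

    def _fit(self, f_loss=0.54, y0=1.1):
        a = (1 - f_loss) ** (1 / 7.0)
        return LossModelFit(y0=y0, a=a, x_b=7.0, y_refractory=y0 * (1 - f_loss),
                            f_loss=f_loss, rmse=0.0)

    def test_areal_flux_reproduces_lower_bound(self):
        F = areal_loss_flux(self._fit(), SR=0.08, rho_dry=0.4)
        assert F == pytest.approx(4.30, abs=0.01)
        assert F == pytest.approx(4.33, rel=0.02)

    def test_areal_flux_reproduces_upper_bound(self):
        F = areal_loss_flux(self._fit(), SR=0.25, rho_dry=0.4)
        assert F == pytest.approx(13.44, abs=0.01)
        assert F == pytest.approx(13.52, rel=0.02)

    def test_zero_loss_zero_flux(self):
        assert areal_loss_flux(self._fit(f_loss=0.0), SR=0.1) == 0.0

    @settings(deadline=None, max_examples=30)
    @given(sr=st.floats(0.01, 1.0), rho=st.floats(0.1, 2.0), k=st.floats(0.1, 5.0))
    def test_linearity_in_sr_and_density(self, sr, rho, k):
        fit = self._fit()
        base = areal_loss_flux(fit, sr, rho)
        assert areal_loss_flux(fit, k * sr, rho) == pytest.approx(k * base, rel=1e-9)
        assert areal_loss_flux(fit, sr, k * rho) == pytest.approx(k * base, rel=1e-9)
        base_in = sediment_input_flux(1.0, sr, rho)
        assert sediment_input_flux(1.0, k * sr, rho) == pytest.approx(k * base_in, rel=1e-9)

    def test_input_flux_sr_ratio_matches_printed_ratio(self):
        """F_in(0.25)/F_in(0.08) = 3.125 = 11.65/3.73 for any N content."""
        r = sediment_input_flux(0.7, 0.25) / sediment_input_flux(0.7, 0.08)
        assert r == pytest.approx(3.125, rel=1e-9)
        assert r == pytest.approx(11.65 / 3.73, rel=0.01)

    def test_zero_content_zero_input(self):
        assert sediment_input_flux(0.0, 0.1) == 0.0

    def test_loss_to_input_ratio_independent_of_sr_and_density(self):
        fit = self._fit()
        r1 = areal_loss_flux(fit, 0.08, 0.4) / sediment_input_flux(0.7, 0.08, 0.4)
        r2 = areal_loss_flux(fit, 0.25, 1.1) / sediment_input_flux(0.7, 0.25, 1.1)
        assert r1 == pytest.approx(r2, rel=1e-9)
        assert r1 == pytest.approx(fit.f_loss * fit.y0 / 0.7, rel=1e-9)
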