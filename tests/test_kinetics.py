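"""Unit tests for the tracer-kinetic models, fits and conversions."""

import numpy as np
import pytest
from scipy.integrate import cumulative_trapezoid, solve_ivp

from dcecfm import kinetics as kin


def fine_trapezoid_convolution(kep_s, times, cp, dt_fine=0.01):
    """Independent oracle: trapezoidal exponential convolution on a fine grid
    of the piecewise-linear plasma curve."""
    tf = np.arange(times[0], times[-1] + dt_fine / 2, dt_fine)
    cpf = np.interp(tf, times, cp)
    out = np.empty_like(times)
    for i, t in enumerate(times):
        sel = tf <= t + 1e-12
        out[i] = np.trapezoid(np.exp(-kep_s * (t - tf[sel])) * cpf[sel], tf[sel])
    return out


class TestExpConv:
    def test_matches_fine_grid_trapezoid(self, times_2s, aif_2s):
        kep_s = 0.4 / 60.0
        ours = kin.exp_conv(kep_s, times_2s, aif_2s.cp)
        ref = fine_trapezoid_convolution(kep_s, times_2s, aif_2s.cp)
        assert np.max(np.abs(ours - ref)) / np.max(ref) < 1e-4

    def test_scalar_and_vector_paths_agree(self, times_2s, aif_2s):
        for rate in (0.0, 1e-9, 0.01, 0.5, 5.0):
            s = kin.exp_conv(rate, times_2s, aif_2s.cp)
            v = kin.exp_conv(np.array([rate]), times_2s, aif_2s.cp)[0]
            np.testing.assert_allclose(s, v, rtol=1e-12, atol=1e-12)

    def test_rejects_nonmonotone_times(self):
        with pytest.raises(ValueError):
            kin.exp_conv(0.1, np.array([0.0, 2.0, 1.0]), np.zeros(3))


class TestEtmForward:
    def test_vascular_only(self, times_2s, aif_2s):
        """Ktrans = 0 reduces the model to the pure plasma term vp*Cp."""
        ct = kin.etm_forward((0.0, 0.3, 0.07), times_2s, aif_2s.cp)
        np.testing.assert_allclose(ct, 0.07 * aif_2s.cp, atol=1e-15)

    def test_constant_plasma_closed_form(self, times_2s):
        """For constant Cp = C0 and vp = 0 the convolution integrates to
        ve*C0*(1 - exp(-kep t))."""
        c0, kt, ve = 3.0, 0.2, 0.4
        cp = np.full_like(times_2s, c0)
        ct = kin.etm_forward((kt, ve, 0.0), times_2s, cp)
        expected = ve * c0 * (1.0 - np.exp(-(kt / ve / 60.0) * times_2s))
        np.testing.assert_allclose(ct, expected, atol=1e-12)

    def test_pure_accumulation_limit(self, times_2s, aif_2s):
        """kep -> 0, vp = 0: Ct is Ktrans times the running integral of Cp."""
        kt = 0.15
        ct = (kt / 60.0) * kin.exp_conv(0.0, times_2s, aif_2s.cp)
        ref = (kt / 60.0) * cumulative_trapezoid(aif_2s.cp, times_2s, initial=0.0)
        np.testing.assert_allclose(ct, ref, rtol=1e-10, atol=1e-12)


class TestSpgr:
    def test_analytic_round_trip(self):
        """SPGR forward then inverse recovers a known concentration curve."""
        rng = np.random.default_rng(4)
        conc = np.concatenate([np.zeros(3), np.abs(rng.normal(0.8, 0.5, 47))])
        sig = kin.spgr_signal(conc, 1.0, 0.0056, 15.0)
        rec = kin.concentration_from_signal(sig, 1.0, 0.0056, 15.0,
                                            baseline_frames=3)
        assert np.max(np.abs(rec.ct - conc)) / np.max(conc) < 1e-9
        assert not rec.clipped.any()

    def test_no_enhancement_maps_to_zero(self):
        sig = np.full(20, 137.2)
        rec = kin.concentration_from_signal(sig, 0.8, 0.0056, 15.0)
        np.testing.assert_allclose(rec.ct, 0.0, atol=1e-12)

    def test_out_of_range_signal_is_clamped_and_flagged(self):
        sig = np.full(12, 100.0)
        sig[5] = 1e5  # beyond the SPGR asymptote
        rec = kin.concentration_from_signal(sig, 1.0, 0.0056, 15.0)
        assert rec.clipped[5]
        assert np.isfinite(rec.ct).all()

    @pytest.mark.parametrize("fa", [0.0, 90.0, 120.0])
    def test_rejects_invalid_flip_angle(self, fa):
        with pytest.raises(ValueError):
            kin.concentration_from_signal(np.ones(12), 1.0, 0.0056, fa)


class TestFitEtm:
    def test_noiseless_recovery(self, times_2s, aif_2s):
        """A noiseless forward curve is recovered to better than 0.1%."""
        truth = (0.27, 0.3, 0.04)
        ct = kin.etm_forward(truth, times_2s, aif_2s.cp)
        p = kin.fit_etm(ct, times_2s, aif_2s.cp)
        assert p.converged
        for got, want in zip((p.ktrans, p.ve, p.vp), truth):
            assert abs(got - want) / want < 1e-3

    def test_null_tissue(self, times_2s, aif_2s):
        p = kin.fit_etm(np.zeros_like(times_2s), times_2s, aif_2s.cp)
        assert p.ktrans == 0.0 and p.vp == 0.0

    def test_determinism(self, times_2s, aif_2s):
        rng = np.random.default_rng(9)
        ct = kin.etm_forward((0.1, 0.25, 0.02), times_2s, aif_2s.cp)
        ct = ct + rng.normal(0, 0.01, ct.shape)
        p1 = kin.fit_etm(ct, times_2s, aif_2s.cp)
        p2 = kin.fit_etm(ct, times_2s, aif_2s.cp)
        assert (p1.ktrans, p1.ve, p1.vp) == (p2.ktrans, p2.ve, p2.vp)

    def test_kep_equals_ktrans_over_ve(self, times_2s, aif_2s):
        ct = kin.etm_forward((0.5, 0.4, 0.1), times_2s, aif_2s.cp)
        p = kin.fit_etm(ct, times_2s, aif_2s.cp)
        assert abs(p.kep - p.ktrans / p.ve) <= 1e-9 * p.kep

    def test_preconditions(self, aif_2s, times_2s):
        with pytest.raises(ValueError):
            kin.fit_etm(np.zeros(5), times_2s[:5], aif_2s.cp[:5])
        with pytest.raises(ValueError):
            kin.fit_etm(np.zeros_like(times_2s), times_2s,
                        np.zeros_like(times_2s))


class TestDeriveCe:
    def test_identity_when_no_plasma_term(self, times_2s, aif_2s):
        ct = kin.etm_forward((0.2, 1.0, 0.0), times_2s, aif_2s.cp)
        np.testing.assert_allclose(kin.derive_ce(ct, aif_2s.cp, 1.0, 0.0), ct)

    def test_algebraic_inversion(self, times_2s, aif_2s):
        ce_true = kin.exp_conv(0.01, times_2s, aif_2s.cp)
        ct = 0.3 * ce_true + 0.05 * aif_2s.cp
        np.testing.assert_allclose(kin.derive_ce(ct, aif_2s.cp, 0.3, 0.05),
                                   ce_true, atol=1e-12)

    def test_vascular_only_gives_zero(self, times_2s, aif_2s):
        ct = 0.04 * aif_2s.cp
        np.testing.assert_allclose(kin.derive_ce(ct, aif_2s.cp, 0.3, 0.04), 0.0)

    def test_rejects_zero_ve(self, times_2s, aif_2s):
        with pytest.raises(ValueError):
            kin.derive_ce(aif_2s.cp, aif_2s.cp, 0.0, 0.0)


class TestFluxModel:
    TRUTH = dict(ve=0.3, psv=1e-3, jvv=1e-4, sigma_t=0.82)

    def _ivp_oracle(self, times, cp, ve, psv, jvv, sigma_t):
        cpi = lambda t: np.interp(t, times, cp)
        sol = solve_ivp(
            lambda t, y: (psv * (cpi(t) - y) + jvv * (1 - sigma_t) * cpi(t)) / ve,
            (times[0], times[-1]), [0.0], t_eval=times, rtol=1e-10, atol=1e-13)
        return sol.y[0]

    def test_forward_matches_ode_integration(self, times_2s, aif_2s):
        t = self.TRUTH
        ours = kin.flux_forward(t["ve"], t["psv"], t["jvv"], t["sigma_t"],
                                times_2s, aif_2s.cp)
        ref = self._ivp_oracle(times_2s, aif_2s.cp, t["ve"], t["psv"],
                               t["jvv"], t["sigma_t"])
        assert np.max(np.abs(ours - ref)) / np.max(ref) < 1e-5

    def test_recovery_from_noiseless_curve(self, times_2s, aif_2s):
        t = self.TRUTH
        ce = self._ivp_oracle(times_2s, aif_2s.cp, t["ve"], t["psv"],
                              t["jvv"], t["sigma_t"])
        fit = kin.fit_flux_model(ce, times_2s, aif_2s.cp, t["sigma_t"], t["ve"])
        assert abs(fit.ps_over_v - t["psv"]) / t["psv"] < 0.01
        assert abs(fit.jv_over_v - t["jvv"]) / t["jvv"] < 0.01

    def test_nested_pure_diffusion_model(self, times_2s, aif_2s):
        """With Jv/V = 0 the fit collapses onto the diffusion-only model."""
        ce = kin.flux_forward(0.3, 1e-3, 0.0, 0.82, times_2s, aif_2s.cp)
        fit = kin.fit_flux_model(ce, times_2s, aif_2s.cp, 0.82, 0.3)
        assert abs(fit.ps_over_v - 1e-3) / 1e-3 < 1e-3
        assert fit.jv_over_v < 1e-8
        assert fit.residual_norm < 1e-8 * np.max(ce) * np.sqrt(ce.size)

    def test_rejects_zero_aif(self, times_2s):
        with pytest.raises(ValueError):
            kin.fit_flux_model(np.zeros_like(times_2s), times_2s,
                               np.zeros_like(times_2s), 0.82, 0.3)


class TestRescaleLp:
    def test_uniform_map(self):
        jv = np.full((4, 4, 4), 2e-4)
        mask = np.ones((4, 4, 4), bool)
        out = kin.rescale_lp(jv, mask)
        np.testing.assert_allclose(out.lp_sv[mask], 2.1e-11 * 2.0e4)

    def test_linearity(self):
        """A voxel at twice the tumor-mean Jv/V gets twice the base Lp*(S/V)."""
        jv = np.ones(8)
        jv[0] = 14.0 / 6.0  # solves jv[0] = 2 * mean(jv)
        out = kin.rescale_lp(jv, np.ones(8, bool))
        assert jv[0] == pytest.approx(2.0 * out.mean_jv_over_v)
        np.testing.assert_allclose(out.lp_sv[0], 2.0 * 2.1e-11 * 2.0e4)

    def test_mean_preservation_random_map(self):
        rng = np.random.default_rng(12)
        jv = rng.lognormal(-9, 0.5, (6, 6, 6))
        mask = rng.random((6, 6, 6)) < 0.6
        out = kin.rescale_lp(jv, mask)
        target = 2.1e-11 * 2.0e4
        assert abs(out.lp_sv[mask].mean() - target) / target < 1e-9

    def test_rejects_all_zero(self):
        with pytest.raises(ValueError):
            kin.rescale_lp(np.zeros((3, 3, 3)), np.ones((3, 3, 3), bool))
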