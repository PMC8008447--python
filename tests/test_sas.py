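from dataclasses import replace

import numpy as np
import pytest

from nanocorona import synthgen as sg
from nanocorona.sas import (
    CoreShellModel,
    EllipsoidModel,
    core_shell_intensity,
    ellipsoid_intensity,
    fit_sas,
    schultz_average,
    sphere_kernel,
)
from oracles import (
    core_shell_intensity_radial_quadrature,
    ellipsoid_monte_carlo,
    schultz_monte_carlo,
)

Q20 = np.logspace(np.log10(0.008), np.log10(0.4), 20)


class TestSphereKernel:
    def test_limit_at_zero(self):
        assert sphere_kernel(np.array([0.0]))[0] == 1.0

    def test_value_at_pi(self):
        assert sphere_kernel(np.array([np.pi]))[0] == pytest.approx(3.0 / np.pi**2)

    def test_taylor_branch_continuous_with_direct(self):
        """The two evaluation branches agree through the 1e-3 switch point."""
        x = np.array([1e-4, 5e-4, 9.99e-4, 1.001e-3, 5e-3, 1e-2])
        taylor = 1.0 - x**2 / 10.0 + x**4 / 280.0
        np.testing.assert_allclose(sphere_kernel(x), taylor, rtol=1e-8)


class TestCoreShellIntensity:
    def test_zero_contrast_leaves_powerlaw_plus_background(self, spions_hsa_model):
        rho = 3.0e-6
        m = replace(
            spions_hsa_model, sld_core=rho, sld_shell=rho, sld_solvent=rho,
            polydispersity=0.0,
        )
        expected = m.powerlaw_amp * Q20**-m.powerlaw_exp + m.background
        np.testing.assert_allclose(core_shell_intensity(m, Q20), expected, rtol=1e-12)

    def test_forward_limit_q_to_zero(self, spions_hsa_model):
        m = replace(spions_hsa_model, polydispersity=0.0, powerlaw_amp=0.0,
                    background=0.0)
        r_t = m.r_core + m.t_shell
        v_c = 4 / 3 * np.pi * m.r_core**3
        v_t = 4 / 3 * np.pi * r_t**3
        expected = 1e8 * m.volume_fraction * (
            v_c * (m.sld_core - m.sld_shell) + v_t * (m.sld_shell - m.sld_solvent)
        ) ** 2 / v_t
        got = core_shell_intensity(m, np.array([1e-6]))[0]
        assert got == pytest.approx(expected, rel=1e-8)

    def test_matches_radial_fourier_quadrature(self, spions_hsa_model):
        """Independent 1-D integral of 4 pi r^2 rho(r) sin(qr)/(qr)."""
        m = replace(spions_hsa_model, polydispersity=0.0)
        got = core_shell_intensity(m, Q20, monodisperse=True)
        oracle = np.array(
            [core_shell_intensity_radial_quadrature(m, q) for q in Q20]
        )
        np.testing.assert_allclose(got, oracle, rtol=1e-6)

    def test_positive_everywhere(self, spions_hsa_model):
        assert np.all(core_shell_intensity(spions_hsa_model, Q20) > 0)

    def test_scale_equivariance_in_volume_fraction(self, spions_hsa_model):
        m = spions_hsa_model
        baseline = m.powerlaw_amp * Q20**-m.powerlaw_exp + m.background
        i1 = core_shell_intensity(m, Q20) - baseline
        i2 = core_shell_intensity(
            replace(m, volume_fraction=2 * m.volume_fraction), Q20
        ) - baseline
        np.testing.assert_allclose(i2, 2 * i1, rtol=1e-10)


class TestSchultzAverage:
    def test_z_from_polydispersity_index(self):
        # z = 1/p^2 - 1
        assert 1.0 / 0.6**2 - 1.0 == pytest.approx(1.778, abs=1e-3)

    def test_degenerate_limit_equals_monodisperse(self, spions_hsa_model):
        m = replace(spions_hsa_model, polydispersity=1e-4)
        q10 = np.logspace(np.log10(0.01), np.log10(0.3), 10)
        avg = schultz_average(m, q10)
        mono = core_shell_intensity(m, q10, monodisperse=True)
        np.testing.assert_allclose(avg, mono, rtol=1e-4)

    def test_p_zero_delegates_to_monodisperse(self, spions_hsa_model):
        m = replace(spions_hsa_model, polydispersity=0.0)
        q10 = np.logspace(-2, -0.5, 10)
        np.testing.assert_allclose(
            schultz_average(m, q10), core_shell_intensity(m, q10, monodisperse=True)
        )

    def test_quadrature_matches_monte_carlo(self, spions_hsa_model):
        """Fixed-node quadrature vs 1e6 seeded Schultz draws, p = 0.3."""
        m = replace(spions_hsa_model, polydispersity=0.3)
        q10 = np.logspace(np.log10(0.01), np.log10(0.3), 10)
        quadrature = schultz_average(m, q10, n_quad=128)
        mc = schultz_monte_carlo(m, q10, n_draws=1_000_000, seed=3)
        np.testing.assert_allclose(quadrature, mc, rtol=5e-3)

    def test_minimum_node_count_enforced(self, spions_hsa_model):
        with pytest.raises(ValueError, match="n_quad"):
            schultz_average(spions_hsa_model, Q20, n_quad=32)


class TestEllipsoidIntensity:
    def test_sphere_limit(self):
        R = 30.0
        ell = EllipsoidModel(a_minor=R, b_major=R, sld=2e-6, sld_solvent=6.36e-6,
                             volume_fraction=0.01)
        sphere = CoreShellModel(
            r_core=R, sld_core=2e-6, t_shell=0.0, sld_shell=2e-6,
            sld_solvent=6.36e-6, volume_fraction=0.01,
        )
        np.testing.assert_allclose(
            ellipsoid_intensity(ell, Q20),
            core_shell_intensity(sphere, Q20, monodisperse=True),
            rtol=1e-8,
        )

    def test_matches_monte_carlo_orientation_average(self, hsa_ellipsoid_model):
        q10 = np.logspace(np.log10(0.01), np.log10(0.3), 10)
        got = ellipsoid_intensity(hsa_ellipsoid_model, q10)
        mc = ellipsoid_monte_carlo(hsa_ellipsoid_model, q10, n_draws=100_000, seed=4)
        np.testing.assert_allclose(got, mc, rtol=5e-3)

    def test_forward_limit(self, hsa_ellipsoid_model):
        m = replace(hsa_ellipsoid_model, background=0.0)
        expected = 1e8 * m.volume_fraction * m.volume * (m.sld - m.sld_solvent) ** 2
        assert ellipsoid_intensity(m, np.array([1e-6]))[0] == pytest.approx(
            expected, rel=1e-8
        )

    def test_oblate_volume_convention(self, hsa_ellipsoid_model):
        assert hsa_ellipsoid_model.volume == pytest.approx(
            4 / 3 * np.pi * 22.0 * 72.0**2
        )


class TestFitSas:
    def test_refit_of_own_output_is_exact(self, spions_hsa_model):
        curve = sg.make_sans(spions_hsa_model)
        res = fit_sas(curve, spions_hsa_model, ["r_core", "t_shell"], n_starts=1)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)

    def test_recovery_from_offset_starts(self, spions_hsa_model):
        """r_core and t_shell recovered from +30% starts on a noiseless curve."""
        curve = sg.make_sans(spions_hsa_model)
        free = ["r_core", "t_shell", "sld_shell", "powerlaw_amp", "background"]
        start = replace(
            spions_hsa_model, **{k: getattr(spions_hsa_model, k) * 1.3 for k in free}
        )
        res = fit_sas(curve, start, free, seed=1)
        assert res.model.r_core == pytest.approx(25.0, abs=2.0)
        assert res.model.t_shell == pytest.approx(48.0, abs=1.0)

    def test_fixed_parameters_unchanged(self, spions_hsa_model):
        curve = sg.make_sans(spions_hsa_model)
        start = replace(spions_hsa_model, r_core=30.0)
        res = fit_sas(curve, start, ["r_core"], n_starts=1)
        assert res.model.sld_core == spions_hsa_model.sld_core
        assert res.model.polydispersity == spions_hsa_model.polydispersity

    def test_noisy_recovery_study(self, spions_hsa_model):
        """Median relative error of r_core, t_shell < 5% at 2% noise (30 seeds),
        polydispersity fixed at truth."""
        free = ["r_core", "t_shell"]
        start = replace(spions_hsa_model, r_core=25.0 * 1.15, t_shell=48.0 * 1.15)
        errs_r, errs_t = [], []
        for seed in range(30):
            noise = sg.NoiseSpec("multiplicative", 0.02, seed)
            curve = sg.make_sans(spions_hsa_model, noise=noise)
            res = fit_sas(curve, start, free, n_starts=1)
            errs_r.append(abs(res.model.r_core - 25.0) / 25.0)
            errs_t.append(abs(res.model.t_shell - 48.0) / 48.0)
        assert np.median(errs_r) < 0.05
        assert np.median(errs_t) < 0.05

    def test_ellipsoid_axes_recovered(self, hsa_ellipsoid_model):
        curve = sg.make_sans(hsa_ellipsoid_model)
        start = replace(hsa_ellipsoid_model, a_minor=22.0 * 1.3, b_major=72.0 * 1.3)
        res = fit_sas(curve, start, ["a_minor", "b_major"], seed=1)
        assert res.model.a_minor == pytest.approx(22.0, abs=0.5)
        assert res.model.b_major == pytest.approx(72.0, abs=2.5)


class TestModelValidation:
    def test_dilute_regime_enforced(self):
        with pytest.raises(ValueError, match="volume fraction"):
            CoreShellModel(r_core=25, sld_core=6.9e-6, t_shell=48,
                           sld_shell=2.1e-6, sld_solvent=6.36e-6,
                           volume_fraction=0.5)

    def test_axis_ordering_enforced(self):
        with pytest.raises(ValueError):
            EllipsoidModel(a_minor=72, b_major=22, sld=1.86e-6,
                           sld_solvent=6.36e-6, volume_fraction=0.01)
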