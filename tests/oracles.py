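"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the package's own evaluation paths: the core-shell
intensity is rebuilt as a direct 1-D Fourier integral of the radial sld
profile, polydisperse/orientation averages as Monte-Carlo sampling, and
reflectivity as an Abeles transfer-matrix product.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import quad

from nanocorona.nr import InterfaceModel, effective_sld
from nanocorona.sas import CoreShellModel, EllipsoidModel, CM_SCALE


def core_shell_intensity_radial_quadrature(model: CoreShellModel, q: float) -> float:
    """I(q) from F(q) = int_0^{r_t} 4 pi r^2 (rho(r) - rho_solv) sin(qr)/(qr) dr."""
    r_t = model.r_core + model.t_shell

    def integrand(r: float) -> float:
        rho = model.sld_core if r < model.r_core else model.sld_shell
        x = q * r
        sinc = np.sin(x) / x if x != 0 else 1.0
        return 4.0 * np.pi * r**2 * (rho - model.sld_solvent) * sinc

    amp1, _ = quad(integrand, 0.0, model.r_core, limit=200)
    amp2, _ = quad(integrand, model.r_core, r_t, limit=200)
    amp = amp1 + amp2
    v_t = 4.0 / 3.0 * np.pi * r_t**3
    form = CM_SCALE * (model.volume_fraction / v_t) * amp**2
    return form + model.powerlaw_amp * q**-model.powerlaw_exp + model.background


def schultz_monte_carlo(
    model: CoreShellModel, q: np.ndarray, n_draws: int = 1_000_000, seed: int = 0
) -> np.ndarray:
    """Sampling average over the Schultz core-radius distribution.

    The Schultz distribution with mean rbar and index p is the gamma
    distribution with shape z + 1 = 1/p^2 and scale rbar/(z + 1).
    """
    p = model.polydispersity
    z = 1.0 / p**2 - 1.0
    rng = np.random.default_rng(seed)
    radii = rng.gamma(shape=z + 1.0, scale=model.r_core / (z + 1.0), size=n_draws)
    total = np.zeros_like(q, dtype=float)
    for chunk in np.array_split(radii, max(1, n_draws // 20000)):
        # vectorized: evaluate the bare form factor for each radius in chunk
        from nanocorona.sas import _core_shell_amplitude

        amp, v_t = _core_shell_amplitude(
            q[None, :], chunk[:, None], model.t_shell,
            model.sld_core, model.sld_shell, model.sld_solvent,
        )
        total += np.sum(CM_SCALE * (model.volume_fraction / v_t) * amp**2, axis=0)
    avg = total / n_draws
    return avg + model.powerlaw_amp * q**-model.powerlaw_exp + model.background


def ellipsoid_monte_carlo(
    model: EllipsoidModel, q: np.ndarray, n_draws: int = 100_000, seed: int = 0
) -> np.ndarray:
    """Seeded Monte-Carlo orientation average over cos(theta) in [0, 1].

    Stratified sampling (one uniform draw per stratum) keeps the sampling
    error well below the comparison tolerance at 1e5 points.
    """
    from nanocorona.sas import sphere_kernel

    rng = np.random.default_rng(seed)
    u = (np.arange(n_draws) + rng.uniform(0.0, 1.0, size=n_draws)) / n_draws
    if model.shape == "oblate":
        r_pol, r_eq = model.a_minor, model.b_major
    else:
        r_pol, r_eq = model.b_major, model.a_minor
    r_eff = np.sqrt(r_pol**2 * u**2 + r_eq**2 * (1.0 - u**2))
    total = np.zeros_like(q, dtype=float)
    for chunk in np.array_split(r_eff, max(1, n_draws // 20000)):
        total += np.sum(sphere_kernel(q[None, :] * chunk[:, None]) ** 2, axis=0)
    avg = total / n_draws
    drho = model.sld - model.sld_solvent
    return (
        CM_SCALE * model.volume_fraction * model.volume * drho**2 * avg
        + model.background
    )


def abeles_reflectivity(model: InterfaceModel, q: np.ndarray) -> np.ndarray:
    """Transfer-matrix (Abeles) reflectivity with Névot-Croce roughness."""
    slds = (
        [model.incident_sld]
        + [effective_sld(l, model.solvent_sld) for l in model.layers]
        + [model.solvent_sld]
    )
    slds = np.asarray(slds)
    thick = np.asarray([0.0] + [l.thickness for l in model.layers])
    rough = np.asarray([l.roughness for l in model.layers] + [model.solvent_roughness])

    q = np.asarray(q, dtype=float)
    out = np.empty_like(q)
    for iq, qv in enumerate(q):
        kz = np.sqrt((qv / 2.0) ** 2 - 4.0 * np.pi * (slds - slds[0]) + 0j)
        M = np.eye(2, dtype=complex)
        for j in range(slds.size - 1):
            rj = (kz[j] - kz[j + 1]) / (kz[j] + kz[j + 1])
            rj = rj * np.exp(-2.0 * kz[j] * kz[j + 1] * rough[j] ** 2)
            beta = kz[j] * thick[j]  # zero for the incident medium
            C = np.array(
                [
                    [np.exp(1j * beta), rj * np.exp(1j * beta)],
                    [rj * np.exp(-1j * beta), np.exp(-1j * beta)],
                ]
            )
            M = M @ C
        r = M[1, 0] / M[0, 0]
        out[iq] = min(abs(r) ** 2, 1.0)
    return out
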