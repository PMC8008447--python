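"""Small-angle scattering forward models and fitting.

Dilute-limit (S(q) = 1) form-factor models for the two particle populations
seen in the corona study:

* a core-shell sphere (magnetite core + organic/protein shell) with Schultz
  polydispersity on the core radius and an additive power law for large-scale
  clusters:

      I(q) = 1e8 * (phi_p / V_t) * <F(q)^2> + A q^-alpha + bkg
      F(q) = V_c (rho_c - rho_sh) K(q r_c) + V_t (rho_sh - rho_solv) K(q r_t)

  with K the sphere amplitude kernel 3(sin x - x cos x)/x^3, r_t = r_c + d,
  V = (4/3) pi r^3, and 1e8 the Å^-1 -> cm^-1 conversion;

* an orientation-averaged homogeneous ellipsoid of revolution (free protein):

      I(q) = 1e8 * phi * V * drho^2 * int_0^{pi/2} K(q r_eff(theta))^2
             sin(theta) dtheta + bkg

  with r_eff(theta) = sqrt(a^2 cos^2 theta + b^2 sin^2 theta), theta the angle
  between q and the symmetry semi-axis a. In the oblate convention the
  symmetry semi-axis is the short one (a = a_minor) and the two equal
  equatorial semi-axes are long (b = b_major); prolate swaps the roles.

Schultz averaging is number-weighted: core radii follow a Schultz (gamma)
distribution with mean r̄ and width z = 1/p^2 - 1 where p = sigma/r̄ is the
polydispersity index; the shell thickness is held fixed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import lmfit

from nanocorona.dataio import ScatteringCurve

logger = logging.getLogger(__name__)

__all__ = [
    "CoreShellModel",
    "EllipsoidModel",
    "SasFitResult",
    "sphere_kernel",
    "core_shell_intensity",
    "schultz_average",
    "ellipsoid_intensity",
    "fit_sas",
]

#: Å^-1 -> cm^-1 absolute-intensity conversion.
CM_SCALE = 1e8


@dataclass
class CoreShellModel:
    """Core-shell sphere + power law + flat background.

    Lengths in Å, scattering length densities in Å^-2, intensities in cm^-1.
    ``polydispersity`` is the Schultz index p = sigma/mean on the core radius;
    ``powerlaw_amp`` is the power-law intensity at q = 1 Å^-1.
    """

    r_core: float
    sld_core: float
    t_shell: float
    sld_shell: float
    sld_solvent: float
    volume_fraction: float
    polydispersity: float = 0.0
    powerlaw_amp: float = 0.0
    powerlaw_exp: float = 1.5
    background: float = 0.0

    def __post_init__(self) -> None:
        if self.r_core <= 0:
            raise ValueError("core radius must be positive")
        if self.t_shell < 0:
            raise ValueError("shell thickness must be non-negative")
        if not 0 <= self.polydispersity < 1:
            raise ValueError("polydispersity must be in [0, 1)")
        if not 0 < self.volume_fraction <= 0.1:
            raise ValueError("volume fraction must be in (0, 0.1] (dilute regime)")
        if not 0 <= self.powerlaw_exp <= 4:
            raise ValueError("power-law exponent must be in [0, 4]")


@dataclass
class EllipsoidModel:
    """Homogeneous ellipsoid of revolution (oblate by default)."""

    a_minor: float
    b_major: float
    sld: float
    sld_solvent: float
    volume_fraction: float
    background: float = 0.0
    shape: str = "oblate"

    def __post_init__(self) -> None:
        if not (0 < self.a_minor <= self.b_major):
            raise ValueError("need 0 < a_minor <= b_major")
        if self.shape not in ("oblate", "prolate"):
            raise ValueError("shape must be 'oblate' or 'prolate'")

    @property
    def volume(self) -> float:
        """(4/3) pi a b^2 (oblate) or (4/3) pi a^2 b (prolate), ų."""
        if self.shape == "oblate":
            return 4.0 / 3.0 * np.pi * self.a_minor * self.b_major**2
        return 4.0 / 3.0 * np.pi * self.a_minor**2 * self.b_major


@dataclass
class SasFitResult:
    """Fitted model, per-parameter uncertainties, chi^2/dof, free mask."""

    model: CoreShellModel | EllipsoidModel
    errors: dict
    chi2: float
    chi2_reduced: float
    free: tuple[str, ...]
    lmfit_result: object = field(repr=False, default=None)


def sphere_kernel(x: np.ndarray) -> np.ndarray:
    """Sphere amplitude kernel 3(sin x - x cos x)/x^3, K(0) = 1.

    For x < 1e-3 the Taylor series 1 - x^2/10 + x^4/280 is used; the direct
    form loses all significance there from catastrophic cancellation.
    """
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = np.abs(x) < 1e-3
    xs = x[small]
    out[small] = 1.0 - xs**2 / 10.0 + xs**4 / 280.0
    xl = x[~small]
    out[~small] = 3.0 * (np.sin(xl) - xl * np.cos(xl)) / xl**3
    return out


def _core_shell_amplitude(
    q: np.ndarray, r_core: np.ndarray, t_shell: float,
    sld_core: float, sld_shell: float, sld_solvent: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Amplitude F(q) (Å^... scattering length units) and total volume V_t."""
    r_t = r_core + t_shell
    v_c = 4.0 / 3.0 * np.pi * r_core**3
    v_t = 4.0 / 3.0 * np.pi * r_t**3
    amp = v_c * (sld_core - sld_shell) * sphere_kernel(q * r_core) + v_t * (
        sld_shell - sld_solvent
    ) * sphere_kernel(q * r_t)
    return amp, v_t


def core_shell_intensity(
    model: CoreShellModel, q: np.ndarray, monodisperse: bool = False
) -> np.ndarray:
    """Absolute intensity I(q) in cm^-1 for the core-shell + power-law model.

    With ``monodisperse=True`` (or polydispersity 0) the single-size form is
    evaluated; otherwise :func:`schultz_average` is applied.
    """
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0):
        raise ValueError("q must be positive")
    if model.polydispersity > 0 and not monodisperse:
        return schultz_average(model, q)
    amp, v_t = _core_shell_amplitude(
        q, np.asarray(model.r_core), model.t_shell,
        model.sld_core, model.sld_shell, model.sld_solvent,
    )
    form = CM_SCALE * (model.volume_fraction / v_t) * amp**2
    return form + model.powerlaw_amp * q**-model.powerlaw_exp + model.background


def schultz_average(
    model: CoreShellModel, q: np.ndarray, n_quad: int = 128
) -> np.ndarray:
    """Number-weighted Schultz average of the core-shell intensity over r_core.

    The Schultz distribution with mean r̄ and index p = sigma/r̄ is the gamma
    distribution with shape z + 1 = 1/p^2 and scale r̄/(z + 1). Fixed-node
    Gauss-Legendre quadrature on [max(0, r̄ - 5 sigma), r̄ + 8 sigma]
    (n_quad >= 64) integrates the monodisperse intensity; shell thickness is
    held fixed. The power law and background are added after averaging.
    """
    q = np.asarray(q, dtype=float)
    p = model.polydispersity
    if p == 0:
        return core_shell_intensity(model, q, monodisperse=True)
    if not 0 < p < 1:
        raise ValueError("polydispersity must be in (0, 1) for Schultz averaging")
    if n_quad < 64:
        raise ValueError("n_quad must be >= 64")
    rbar = model.r_core
    z = 1.0 / p**2 - 1.0
    sigma = p * rbar
    lo = max(0.0, rbar - 5.0 * sigma)
    hi = rbar + 8.0 * sigma
    nodes, weights = np.polynomial.legendre.leggauss(n_quad)
    r = 0.5 * (hi - lo) * nodes + 0.5 * (hi + lo)
    w = 0.5 * (hi - lo) * weights

    # Schultz pdf, computed in log space for stability
    from scipy.special import gammaln

    logpdf = (
        (z + 1.0) * np.log((z + 1.0) / rbar)
        + z * np.log(np.where(r > 0, r, 1.0))
        - (z + 1.0) * r / rbar
        - gammaln(z + 1.0)
    )
    pdf = np.where(r > 0, np.exp(logpdf), 0.0)
    norm = np.sum(w * pdf)

    amp, v_t = _core_shell_amplitude(
        q[None, :], r[:, None], model.t_shell,
        model.sld_core, model.sld_shell, model.sld_solvent,
    )
    i_mono = CM_SCALE * (model.volume_fraction / v_t) * amp**2
    avg = np.sum(w[:, None] * pdf[:, None] * i_mono, axis=0) / norm
    return avg + model.powerlaw_amp * q**-model.powerlaw_exp + model.background


def ellipsoid_intensity(
    model: EllipsoidModel, q: np.ndarray, n_quad: int = 76
) -> np.ndarray:
    """Orientation-averaged ellipsoid intensity (cm^-1).

    Gauss-Legendre quadrature in u = cos(theta) over [0, 1], theta being the
    angle between q and the symmetry semi-axis. The symmetry semi-axis is
    a_minor for oblate and b_major for prolate particles.
    """
    q = np.asarray(q, dtype=float)
    if model.shape == "oblate":
        r_pol, r_eq = model.a_minor, model.b_major
    else:
        r_pol, r_eq = model.b_major, model.a_minor
    nodes, weights = np.polynomial.legendre.leggauss(n_quad)
    u = 0.5 * (nodes + 1.0)  # cos(theta) in [0, 1]
    w = 0.5 * weights
    r_eff = np.sqrt(r_pol**2 * u**2 + r_eq**2 * (1.0 - u**2))
    k2 = sphere_kernel(q[None, :] * r_eff[:, None]) ** 2
    avg = np.sum(w[:, None] * k2, axis=0)  # int_0^1 K^2 du == int K^2 sin dtheta
    drho = model.sld - model.sld_solvent
    return (
        CM_SCALE * model.volume_fraction * model.volume * drho**2 * avg
        + model.background
    )


# parameter bounds used when the caller supplies none
_DEFAULT_BOUNDS = {
    "r_core": (1.0, 500.0),
    "sld_core": (-1e-6, 2e-5),
    "t_shell": (0.0, 500.0),
    "sld_shell": (-1e-6, 2e-5),
    "sld_solvent": (-1e-6, 2e-5),
    "volume_fraction": (1e-6, 0.1),
    "polydispersity": (0.0, 0.95),
    "powerlaw_amp": (0.0, 1.0),
    "powerlaw_exp": (0.0, 4.0),
    "background": (0.0, 10.0),
    "a_minor": (1.0, 500.0),
    "b_major": (1.0, 1000.0),
    "sld": (-1e-6, 2e-5),
}


def _evaluate(model, q):
    if isinstance(model, CoreShellModel):
        return core_shell_intensity(model, q)
    return ellipsoid_intensity(model, q)


def fit_sas(
    curve: ScatteringCurve,
    model: CoreShellModel | EllipsoidModel,
    free: list[str],
    bounds: dict | None = None,
    n_starts: int = 5,
    seed: int = 0,
) -> SasFitResult:
    """Bounded weighted least-squares fit of a form-factor model.

    Minimizes sum(((I_obs - I_model)/dI)^2); when the curve carries no
    uncertainties the weights fall back to 1/I_obs (relative residuals).
    Multi-start: the supplied model is the first start; the remaining
    ``n_starts - 1`` starts perturb each free parameter by a seeded uniform
    +/-30%. Parameters not named in ``free`` stay fixed at their input value.
    """
    bounds = {**_DEFAULT_BOUNDS, **(bounds or {})}
    for name in free:
        if not hasattr(model, name):
            raise ValueError(f"unknown parameter {name!r}")

    q, I_obs = curve.q, curve.intensity
    dI = curve.uncertainty if curve.uncertainty is not None else np.abs(I_obs)

    def make_params(start_model):
        params = lmfit.Parameters()
        for name in free:
            lo, hi = bounds[name]
            val = float(np.clip(getattr(start_model, name), lo, hi))
            params.add(name, value=val, min=lo, max=hi)
        return params

    def residual(params):
        m = replace(model, **{n: params[n].value for n in free})
        return (_evaluate(m, q) - I_obs) / dI

    rng = np.random.default_rng(seed)
    start_models = [model]
    for _ in range(n_starts - 1):
        kw = {
            n: getattr(model, n) * (1 + rng.uniform(-0.3, 0.3))
            for n in free
        }
        kw = {
            n: float(np.clip(v, bounds[n][0] + 1e-12, bounds[n][1]))
            for n, v in kw.items()
        }
        start_models.append(replace(model, **kw))

    best = None
    reasons = []
    for sm in start_models:
        try:
            res = lmfit.minimize(residual, make_params(sm), method="least_squares")
        except Exception as exc:
            reasons.append(str(exc))
            continue
        if not res.success:
            reasons.append(res.message)
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None:
        raise RuntimeError(f"all fit starts failed: {reasons}")

    fitted = replace(model, **{n: float(best.params[n].value) for n in free})
    errors = {
        n: float(best.params[n].stderr) if best.params[n].stderr else float("nan")
        for n in free
    }
    dof = max(len(q) - len(free), 1)
    return SasFitResult(
        model=fitted,
        errors=errors,
        chi2=float(best.chisqr),
        chi2_reduced=float(best.chisqr) / dof,
        free=tuple(free),
        lmfit_result=best,
    )
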