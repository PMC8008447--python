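"""Fluorescence-quenching binding analysis.

Tryptophan fluorescence of a serum protein is quenched by titrated
nanoparticles. The linear Stern-Volmer relation

    F0/F = 1 + K_SV [Q]

yields the Stern-Volmer constant K_SV from the slope; dividing by the
fluorophore's mean lifetime tau0 gives the bimolecular quenching rate
K_q = K_SV / tau0, whose magnitude relative to the diffusion-controlled limit
(~2e10 M^-1 s^-1) discriminates static (ground-state complex) from dynamic
(collisional) quenching. For static quenching the double-log modified
Stern-Volmer plot

    log10((F0 - F)/F) = log10(K_a) + n log10([Q])

gives the binding constant K_a from the intercept and the number of binding
sites n from the slope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from nanocorona.dataio import XYCurve

logger = logging.getLogger(__name__)

__all__ = [
    "TitrationSeries",
    "QuenchResult",
    "DIFFUSION_LIMIT",
    "emission_peak",
    "stern_volmer_fit",
    "bimolecular_rate",
    "classify_quenching",
    "linearity_diagnostic",
    "modified_stern_volmer_fit",
]

#: Diffusion-controlled bimolecular rate limit (M^-1 s^-1) separating static
#: (above) from dynamic (below) quenching.
DIFFUSION_LIMIT = 2e10


@dataclass
class TitrationSeries:
    """Quencher concentrations with paired fluorescence intensities.

    ``quencher_conc`` is the nanoparticle molar concentration (M), strictly
    increasing and non-negative; ``F`` the fluorescence intensity at each
    concentration; ``F0`` the intensity at zero quencher. Quenching only:
    F <= F0 everywhere.
    """

    quencher_conc: np.ndarray
    F: np.ndarray
    F0: float
    dF: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.quencher_conc = np.asarray(self.quencher_conc, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.dF is not None:
            self.dF = np.asarray(self.dF, dtype=float)
        if self.F.shape != self.quencher_conc.shape:
            raise ValueError("F and quencher_conc must have equal length")
        if np.any(self.quencher_conc < 0):
            raise ValueError("quencher concentrations must be non-negative")
        if np.any(np.diff(self.quencher_conc) <= 0):
            raise ValueError("quencher concentrations must be strictly increasing")
        if np.any(self.F <= 0):
            raise ValueError("fluorescence intensities must be positive")
        if self.F0 <= 0:
            raise ValueError("F0 must be positive")
        if np.any(self.F > self.F0 * (1 + 1e-9)):
            raise ValueError("F must not exceed F0 (quenching only)")

    def __len__(self) -> int:
        return self.quencher_conc.size


@dataclass
class QuenchResult:
    """Full quenching analysis: constants, mechanism, and fit diagnostics."""

    K_SV: float
    K_q: float
    tau0: float
    mechanism: str  # "static" | "dynamic" | "indeterminate"
    K_a: float | None = None
    n: float | None = None
    r2_sv: float | None = None
    r2_msv: float | None = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        # conservation of definition
        if self.tau0 > 0 and not np.isclose(self.K_q, self.K_SV / self.tau0):
            raise ValueError("K_q must equal K_SV / tau0")


def _wls(x: np.ndarray, y: np.ndarray, w: np.ndarray | None):
    """Weighted linear LS; returns slope, intercept, r^2, residuals."""
    if w is None:
        w = np.ones_like(x)
    W = np.sqrt(w)
    A = np.column_stack([x * W, W])
    coef, *_ = np.linalg.lstsq(A, y * W, rcond=None)
    slope, intercept = coef
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(w * resid**2))
    ybar = float(np.sum(w * y) / np.sum(w))
    ss_tot = float(np.sum(w * (y - ybar) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return slope, intercept, r2, resid


def emission_peak(
    spectrum: XYCurve, search_window: tuple[float, float]
) -> float:
    """Emission-maximum wavelength (nm) with local quadratic refinement.

    The discrete maximum inside ``search_window`` is refined by fitting a
    parabola through the maximum and its two neighbours. A maximum on the
    window boundary (monotone spectrum) is an error; exact ties resolve to the
    lower wavelength and are logged.
    """
    lo, hi = search_window
    if lo < spectrum.x[0] or hi > spectrum.x[-1]:
        raise ValueError("search window outside spectrum range")
    mask = (spectrum.x >= lo) & (spectrum.x <= hi)
    x, y = spectrum.x[mask], spectrum.y[mask]
    if x.size < 3:
        raise ValueError("too few points in search window")
    imax = int(np.argmax(y))  # argmax takes the first (lowest-wavelength) tie
    if np.sum(y == y[imax]) > 1:
        logger.info("emission_peak: tie at maximum, lower wavelength returned")
    if imax == 0 or imax == x.size - 1:
        raise ValueError("maximum on window boundary: no interior peak")
    # vertex of the parabola through the maximum and its two neighbours
    xs = x[imax - 1 : imax + 2] - x[imax]  # centred for conditioning
    ys = y[imax - 1 : imax + 2]
    a, b, _ = np.polyfit(xs, ys, 2)
    if a >= 0:  # flat or concave-up: keep the discrete maximum
        return float(x[imax])
    return float(x[imax] - b / (2 * a))


def stern_volmer_fit(titration: TitrationSeries) -> dict:
    """Linear Stern-Volmer fit: F0/F vs [Q]; slope is K_SV (M^-1).

    Weighted by 1/dy^2 when ``dF`` is present (propagated to F0/F), unweighted
    otherwise. A negative fitted slope is reported as no quenching detected
    (K_SV = 0 with a flag).
    """
    if len(titration) < 4:
        raise ValueError("Stern-Volmer fit needs at least 4 titration points")
    q = titration.quencher_conc
    ratio = titration.F0 / titration.F
    w = None
    if titration.dF is not None:
        dratio = titration.F0 * titration.dF / titration.F**2
        w = 1.0 / dratio**2
    slope, intercept, r2, resid = _wls(q, ratio, w)
    # a slope whose contribution over the whole titration window is below
    # double-precision resolution of F0/F is numerically zero
    if abs(slope) * q.max() < 1e-10 * float(np.mean(ratio)):
        slope = 0.0
    out = {
        "K_SV": float(slope),
        "intercept": float(intercept),
        "r2": r2,
        "residuals": resid,
    }
    if slope < 0:
        logger.warning("negative Stern-Volmer slope: no quenching detected")
        out["K_SV"] = 0.0
        out["no_quenching"] = True
    return out


def bimolecular_rate(K_SV: float, tau0: float) -> float:
    """Bimolecular quenching rate K_q = K_SV / tau0 (M^-1 s^-1)."""
    if tau0 <= 0:
        raise ValueError("tau0 must be positive")
    return K_SV / tau0


def classify_quenching(K_q: float, threshold: float = DIFFUSION_LIMIT) -> str:
    """Static above, dynamic below the diffusion-controlled limit.

    Exact equality with the threshold returns ``"indeterminate"`` rather than
    silently picking a side.
    """
    if K_q < 0:
        raise ValueError("K_q must be non-negative")
    if K_q > threshold:
        return "static"
    if K_q < threshold:
        return "dynamic"
    return "indeterminate"


def linearity_diagnostic(titration: TitrationSeries) -> str:
    """Classify the Stern-Volmer plot as ``linear`` or ``superlinear``.

    Compares the residual sum of squares of the linear model
    ``F0/F = a + b[Q]`` against an exponential-growth alternative
    ``F0/F = a exp(c[Q])`` with the same parameter count. Because the
    exponential can mimic a straight line, the alternative must improve RSS by
    more than 10% to be declared superlinear (mixed static + dynamic
    quenching); otherwise the series is linear.
    """
    if len(titration) < 6:
        raise ValueError("linearity diagnostic needs at least 6 points")
    q = titration.quencher_conc
    ratio = titration.F0 / titration.F

    slope, intercept, _, resid = _wls(q, ratio, None)
    rss_lin = float(np.sum(resid**2))

    def expmod(x, a, c):
        return a * np.exp(c * x)

    try:
        popt, _ = curve_fit(
            expmod, q, ratio, p0=[max(ratio[0], 1e-6), max(slope, 0.1) / max(ratio[0], 1e-6)],
            maxfev=10000,
        )
        rss_exp = float(np.sum((ratio - expmod(q, *popt)) ** 2))
    except RuntimeError:
        return "linear"
    if rss_lin <= 0:
        return "linear"
    return "superlinear" if rss_exp < 0.9 * rss_lin else "linear"


def modified_stern_volmer_fit(titration: TitrationSeries) -> dict:
    """Double-log modified Stern-Volmer fit.

    Fits ``log10((F0-F)/F) = log10(K_a) + n log10([Q])`` by (weighted) linear
    least squares. Points with F = F0 (no quenching, log undefined) are
    excluded with a warning; fewer than 4 usable points aborts.

    Returns ``{"K_a", "n", "intercept", "r2", "n_excluded"}``.
    """
    q = titration.quencher_conc
    F = titration.F
    usable = (F < titration.F0) & (q > 0)
    n_excl = int(np.sum(~usable))
    if n_excl:
        logger.warning("excluded %d point(s) with F = F0 or [Q] = 0", n_excl)
    if np.sum(usable) < 4:
        raise ValueError("fewer than 4 usable points for modified Stern-Volmer fit")
    x = np.log10(q[usable])
    y = np.log10((titration.F0 - F[usable]) / F[usable])
    w = None
    if titration.dF is not None:
        # d/dF log10((F0-F)/F) = -F0 / (ln10 * F * (F0-F))
        dy = titration.F0 * titration.dF[usable] / (
            np.log(10.0) * F[usable] * (titration.F0 - F[usable])
        )
        w = 1.0 / dy**2
    slope, intercept, r2, _ = _wls(x, y, w)
    return {
        "K_a": float(10.0**intercept),
        "n": float(slope),
        "intercept": float(intercept),
        "r2": r2,
        "n_excluded": n_excl,
    }


def analyze_titration(
    titration: TitrationSeries, tau0: float, threshold: float = DIFFUSION_LIMIT
) -> QuenchResult:
    """Full pipeline: Stern-Volmer, rate, mechanism, and (if static) binding."""
    sv = stern_volmer_fit(titration)
    K_q = bimolecular_rate(sv["K_SV"], tau0)
    mech = classify_quenching(K_q, threshold)
    K_a = n = r2_msv = None
    if mech == "static":
        msv = modified_stern_volmer_fit(titration)
        K_a, n, r2_msv = msv["K_a"], msv["n"], msv["r2"]
    return QuenchResult(
        K_SV=sv["K_SV"],
        K_q=K_q,
        tau0=tau0,
        mechanism=mech,
        K_a=K_a,
        n=n,
        r2_sv=sv["r2"],
        r2_msv=r2_msv,
        diagnostics={"sv_intercept": sv["intercept"]},
    )
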