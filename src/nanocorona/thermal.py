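"""CD thermal-denaturation analysis.

The far-UV CD signal at 222 nm tracks secondary-structure loss during thermal
unfolding. The raw melt is normalized to a denatured fraction

    f(T) = (I(T) - I_0) / (I_f - I_0)

with I_0 the signal at the lowest and I_f at the highest measured temperature
(so f runs 0 -> 1 by construction), and a two-state sigmoid

    f(T) = 1 / (1 + exp(-(T - T_m)/w))

is fitted to extract the melting temperature T_m and transition width w.
Temperatures are in °C throughout. No sloping native/denatured baselines are
assumed by default (endpoint normalization only).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import lmfit

logger = logging.getLogger(__name__)

__all__ = [
    "MeltCurve",
    "FractionCurve",
    "MeltFit",
    "unfolded_fraction",
    "fit_melting",
    "delta_tm",
]


@dataclass
class MeltCurve:
    """Temperature-resolved CD signal (°C, millidegrees; may be negative)."""

    temperature: np.ndarray
    signal: np.ndarray

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.temperature.size < 10:
            raise ValueError("melt curve needs at least 10 points")
        if np.any(np.diff(self.temperature) <= 0):
            raise ValueError("temperature must be strictly increasing")
        if self.signal.shape != self.temperature.shape:
            raise ValueError("signal must match temperature in length")


@dataclass
class FractionCurve:
    """Normalized unfolded fraction vs temperature (dimensionless, 0 -> 1)."""

    temperature: np.ndarray
    fraction: np.ndarray


@dataclass
class MeltFit:
    """Two-state sigmoid fit result."""

    T_m: float
    T_m_err: float
    width: float
    width_err: float
    r2: float
    fraction: FractionCurve | None = None

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("transition width must be positive")


def sigmoid(T: np.ndarray, T_m: float, w: float) -> np.ndarray:
    """Two-state unfolded fraction 1/(1 + exp(-(T - T_m)/w))."""
    return 1.0 / (1.0 + np.exp(-(T - T_m) / w))


def unfolded_fraction(curve: MeltCurve) -> FractionCurve:
    """Endpoint-normalized denatured fraction.

    f = (I - I_0)/(I_f - I_0) with I_0/I_f the signals at the lowest/highest
    temperature; f is exactly 0 at T_min and 1 at T_max, and is invariant
    under any affine transform of the raw signal. Identical endpoint signals
    (no transition) abort with a diagnostic.
    """
    I0, If = curve.signal[0], curve.signal[-1]
    span = If - I0
    if span == 0:
        raise ValueError("no transition: identical endpoint signals")
    scale = np.max(np.abs(curve.signal)) or 1.0
    if abs(span) < 1e-6 * scale:
        raise ValueError("no transition: endpoint signal change below noise scale")
    return FractionCurve(
        temperature=curve.temperature.copy(),
        fraction=(curve.signal - I0) / span,
    )


def _initial_guesses(T: np.ndarray, f: np.ndarray) -> tuple[float, float]:
    """T_m from the interpolated f = 0.5 crossing; w from the 0.2-0.8 span."""
    idx = np.where(np.diff(np.sign(f - 0.5)) != 0)[0]
    if idx.size:
        i = idx[0]
        f0, f1 = f[i], f[i + 1]
        t0, t1 = T[i], T[i + 1]
        tm0 = t0 + (0.5 - f0) * (t1 - t0) / (f1 - f0) if f1 != f0 else 0.5 * (t0 + t1)
    else:
        tm0 = 0.5 * (T[0] + T[-1])
    inside = T[(f > 0.2) & (f < 0.8)]
    w0 = (inside.max() - inside.min()) / 4.0 if inside.size >= 2 else (T[-1] - T[0]) / 10.0
    return float(tm0), max(float(w0), 0.1)


def fit_melting(fraction: FractionCurve, n_starts: int = 5, seed: int = 0) -> MeltFit:
    """Least-squares two-state sigmoid fit of an unfolded-fraction curve.

    Multi-start: the first start uses the f = 0.5 crossing for T_m and a
    quarter of the 0.2-0.8 temperature span for w; the remaining starts are
    seeded +/-30% perturbations. Non-convergence of every start raises, with
    per-start termination reasons attached, rather than returning silently.
    The transition must span at least 0.2-0.8 in fraction.
    """
    T = np.asarray(fraction.temperature, dtype=float)
    f = np.asarray(fraction.fraction, dtype=float)
    if f.min() > 0.2 or f.max() < 0.8:
        raise ValueError("fraction curve must span at least 0.2-0.8")

    tm0, w0 = _initial_guesses(T, f)
    rng = np.random.default_rng(seed)
    starts = [(tm0, w0)]
    for _ in range(n_starts - 1):
        starts.append(
            (
                tm0 * (1 + rng.uniform(-0.3, 0.3)),
                w0 * (1 + rng.uniform(-0.3, 0.3)),
            )
        )

    def residual(params):
        return sigmoid(T, params["T_m"].value, params["w"].value) - f

    best = None
    reasons = []
    for tm_s, w_s in starts:
        params = lmfit.Parameters()
        params.add("T_m", value=tm_s, min=T[0], max=T[-1])
        params.add("w", value=w_s, min=1e-3, max=(T[-1] - T[0]))
        try:
            res = lmfit.minimize(residual, params, method="least_squares")
        except Exception as exc:  # pragma: no cover - defensive
            reasons.append(str(exc))
            continue
        if not res.success:
            reasons.append(res.message)
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None:
        raise RuntimeError(f"sigmoid fit failed for all starts: {reasons}")

    ss_res = float(best.chisqr)
    ss_tot = float(np.sum((f - f.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    # degenerate (flat) input shows up as a useless fit, not a crash
    if ss_tot < 1e-12 or r2 < 0.5:
        raise RuntimeError("sigmoid fit did not converge to a transition (flat or non-sigmoidal input)")

    p = best.params
    return MeltFit(
        T_m=float(p["T_m"].value),
        T_m_err=float(p["T_m"].stderr or np.nan),
        width=float(p["w"].value),
        width_err=float(p["w"].stderr or np.nan),
        r2=r2,
        fraction=fraction,
    )


def delta_tm(fit_a: MeltFit, fit_b: MeltFit) -> tuple[float, float]:
    """Melting-temperature shift T_m(b) - T_m(a) with propagated uncertainty."""
    shift = fit_b.T_m - fit_a.T_m
    errs = [e for e in (fit_a.T_m_err, fit_b.T_m_err) if np.isfinite(e)]
    err = float(np.sqrt(sum(e**2 for e in errs))) if errs else float("nan")
    return float(shift), err
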