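"""Seeded synthetic-data generators for every analysis stage.

Each generator inverts the model its matching fitter assumes, so
generator + fitter is the identity on parameters under zero noise. All
randomness flows through one ``numpy.random.Generator`` constructed from the
``NoiseSpec`` seed — no global state — so identical seed + parameters give
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from nanocorona.dataio import ScatteringCurve
from nanocorona.nr import ContrastSet, InterfaceModel, SOLVENT_SLD, reflectivity
from nanocorona.quenching import TitrationSeries
from nanocorona.sas import CoreShellModel, EllipsoidModel, core_shell_intensity, ellipsoid_intensity
from nanocorona.thermal import MeltCurve, sigmoid

__all__ = [
    "NoiseSpec",
    "make_titration",
    "titration_grid",
    "make_melt",
    "make_sans",
    "make_nr",
    "DEFAULT_SANS_QGRID",
    "DEFAULT_NR_QGRID",
]

#: 100 log-spaced q points covering the Guinier region, the form-factor
#: oscillations and the low-q power law (Å^-1).
DEFAULT_SANS_QGRID = np.logspace(np.log10(0.008), np.log10(0.4), 100)
#: 200 log-spaced q points for reflectometry (Å^-1).
DEFAULT_NR_QGRID = np.logspace(np.log10(0.008), np.log10(0.25), 200)

#: uncertainty floor relative to the curve maximum, keeps 1/dI weights finite
_DI_FLOOR = 1e-4


@dataclass
class NoiseSpec:
    """Noise model: ``none``, ``gaussian-additive`` (absolute sigma) or
    ``multiplicative`` (relative sigma); deterministic given the seed."""

    kind: str = "none"
    level: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "gaussian-additive", "multiplicative"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.level < 0:
            raise ValueError("noise level must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def apply(self, y: np.ndarray) -> np.ndarray:
        if self.kind == "none" or self.level == 0:
            return np.array(y, dtype=float, copy=True)
        rng = self.rng()
        eps = rng.standard_normal(y.shape)
        if self.kind == "gaussian-additive":
            return y + self.level * eps
        return y * (1.0 + self.level * eps)


def titration_grid(
    protein_conc: float = 3.0e-6, ratios: tuple[int, ...] = (100, 90, 80, 70, 60, 50, 40, 30, 20)
) -> np.ndarray:
    """NP molar concentrations for the 1:100 -> 1:20 NP:protein titration."""
    return np.array(sorted(protein_conc / r for r in ratios))


def make_titration(
    K_a: float,
    n: float,
    F0: float,
    conc_grid: np.ndarray,
    noise: NoiseSpec | None = None,
) -> TitrationSeries:
    """Static-quenching titration from the double-log binding relation.

    (F0 - F)/F = 10^(log10 K_a + n log10 [Q]) = K_a [Q]^n, inverted to
    F = F0 / (1 + K_a [Q]^n). With n = 1 the series also satisfies the linear
    Stern-Volmer relation with K_SV = K_a. Noise applies to F only.
    """
    if K_a <= 0 or n <= 0 or F0 <= 0:
        raise ValueError("K_a, n and F0 must be positive")
    conc = np.asarray(conc_grid, dtype=float)
    F = F0 / (1.0 + K_a * conc**n)
    if noise is not None:
        F = np.clip(noise.apply(F), 1e-12, F0)
    return TitrationSeries(quencher_conc=conc, F=F, F0=F0)


def make_melt(
    T_m: float,
    width: float,
    endpoints: tuple[float, float] = (-20.0, -5.0),
    T_grid: np.ndarray | None = None,
    noise: NoiseSpec | None = None,
) -> MeltCurve:
    """Two-state CD melt: signal = I_0 + (I_f - I_0) * sigmoid(T; T_m, w).

    Defaults mimic a 222 nm CD melt over 10-90 °C (native -20 mdeg, denatured
    -5 mdeg). Additive noise levels are interpreted relative to the endpoint
    span |I_f - I_0|.
    """
    if T_grid is None:
        T_grid = np.arange(10.0, 90.0 + 0.5, 1.0)
    T = np.asarray(T_grid, dtype=float)
    if not T[0] < T_m < T[-1]:
        raise ValueError("T_m must lie inside the temperature grid")
    I0, If = endpoints
    signal = I0 + (If - I0) * sigmoid(T, T_m, width)
    if noise is not None and noise.kind == "gaussian-additive":
        scaled = NoiseSpec("gaussian-additive", noise.level * abs(If - I0), noise.seed)
        signal = scaled.apply(signal)
    elif noise is not None:
        signal = noise.apply(signal)
    return MeltCurve(temperature=T, signal=signal)


def make_sans(
    model: CoreShellModel | EllipsoidModel,
    q_grid: np.ndarray | None = None,
    noise: NoiseSpec | None = None,
) -> ScatteringCurve:
    """Synthetic SANS curve from a form-factor model.

    Multiplicative noise of relative level s gives dI = s * I as the reported
    uncertainty, floored at 1e-4 of the curve maximum.
    """
    q = np.asarray(q_grid if q_grid is not None else DEFAULT_SANS_QGRID, dtype=float)
    if isinstance(model, CoreShellModel):
        I = core_shell_intensity(model, q)
    else:
        I = ellipsoid_intensity(model, q)
    dI = None
    if noise is not None and noise.kind != "none" and noise.level > 0:
        I_noisy = noise.apply(I)
        dI = np.maximum(noise.level * np.abs(I), _DI_FLOOR * np.max(np.abs(I)))
        I = np.maximum(I_noisy, 1e-12)
    return ScatteringCurve(x=q, y=I, dy=dI, meta={"stage": "sans"})


def make_nr(
    model: InterfaceModel,
    contrasts: tuple[str, ...] = ("H2O", "D2O", "SMW"),
    q_grid: np.ndarray | None = None,
    noise: NoiseSpec | None = None,
) -> ContrastSet:
    """Synthetic multi-contrast reflectivity sharing one structural truth.

    Each requested contrast re-evaluates the same box stack with its bulk
    solvent sld. Per-contrast noise streams are derived from the base seed so
    contrasts are independent but the whole set is reproducible.
    """
    q = np.asarray(q_grid if q_grid is not None else DEFAULT_NR_QGRID, dtype=float)
    curves = {}
    for i, name in enumerate(contrasts):
        if name not in SOLVENT_SLD:
            raise ValueError(f"unknown contrast {name!r}")
        R = reflectivity(model.with_contrast(SOLVENT_SLD[name]), q)
        dR = None
        if noise is not None and noise.kind != "none" and noise.level > 0:
            sub = NoiseSpec(noise.kind, noise.level, noise.seed + 1000 * (i + 1))
            R_noisy = sub.apply(R)
            dR = np.maximum(noise.level * np.abs(R), _DI_FLOOR * np.max(np.abs(R)))
            R = np.clip(R_noisy, 1e-12, 1.0)
        curves[name] = ScatteringCurve(x=q, y=R, dy=dR, meta={"contrast": name})
    return ContrastSet(curves=curves)
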