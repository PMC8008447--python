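"""Specular neutron reflectometry: box model and multi-contrast refinement.

A solid-supported lipid bilayer at the silicon/water interface is described as
an ordered stack of homogeneous boxes (thin solvent cushion, inner headgroups,
acyl chains, outer headgroups, optional adsorbate layer), each with a
thickness, an intrinsic scattering length density (sld), a solvent volume
fraction, and a Gaussian interfacial roughness with the preceding layer. The
effective sld of a box is the volume-weighted mix

    sld_eff = (1 - phi_solv) * sld + phi_solv * sld_solvent

so one structural parameter set predicts the reflectivity in every solvent
contrast (H2O, D2O, silicon-match water) simultaneously; co-refinement shares
all structural parameters across contrasts and lets only the bulk solvent sld
differ.

Reflectivity is computed by the Parratt recursion with Névot-Croce roughness
factors on each Fresnel coefficient; the silicon block is the semi-infinite
incident medium (no native-oxide layer by default) and the bulk solvent the
semi-infinite backing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import lmfit
from scipy.special import erf

from nanocorona.dataio import ScatteringCurve

logger = logging.getLogger(__name__)

__all__ = [
    "Layer",
    "InterfaceModel",
    "ContrastSet",
    "SOLVENT_SLD",
    "SILICON_SLD",
    "effective_sld",
    "reflectivity",
    "co_refine",
    "sld_profile",
]

#: Bulk solvent slds (Å^-2) for the three standard contrasts.
SOLVENT_SLD = {"D2O": 6.36e-6, "H2O": -0.56e-6, "SMW": 2.07e-6}
#: Silicon sld (Å^-2); SMW is mixed to match it.
SILICON_SLD = 2.07e-6

_emitted_warnings: set[str] = set()


def _warn_once(msg: str) -> None:
    # model objects are rebuilt thousands of times inside a fit; warn once
    if msg not in _emitted_warnings:
        _emitted_warnings.add(msg)
        logger.warning(msg)


@dataclass
class Layer:
    """One box: thickness (Å), intrinsic sld (Å^-2), solvent fraction,
    roughness (Å) of the interface with the preceding layer."""

    thickness: float
    sld: float
    solvent_fraction: float = 0.0
    roughness: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        if self.thickness < 0:
            raise ValueError("thickness must be non-negative")
        if not 0 <= self.solvent_fraction <= 1:
            raise ValueError("solvent fraction must be in [0, 1]")
        if self.roughness < 0:
            raise ValueError("roughness must be non-negative")


@dataclass
class InterfaceModel:
    """Ordered box stack from the silicon side to the bulk solvent.

    ``solvent_roughness`` is the roughness of the final layer/solvent
    interface; ``solvent_sld`` the bulk value for the contrast being
    evaluated. Roughness larger than twice the thinner adjacent layer is
    honored but warned about (the Névot-Croce approximation degrades there).
    """

    layers: list[Layer]
    solvent_sld: float
    incident_sld: float = SILICON_SLD
    solvent_roughness: float = 3.0

    def __post_init__(self) -> None:
        for i, layer in enumerate(self.layers):
            thinner = layer.thickness
            if i > 0:
                thinner = min(thinner, self.layers[i - 1].thickness)
            if thinner > 0 and layer.roughness > 2 * thinner:
                _warn_once(
                    f"layer {i} ({layer.name or '?'}): roughness "
                    f"{layer.roughness:.1f} Å exceeds twice the thinner adjacent "
                    f"thickness {thinner:.1f} Å; Névot-Croce validity is marginal"
                )

    def with_contrast(self, solvent_sld: float) -> "InterfaceModel":
        """Same structure, different bulk solvent."""
        return replace(self, solvent_sld=solvent_sld)


@dataclass
class ContrastSet:
    """Named contrasts with their bulk solvent slds and measured curves."""

    curves: dict  # name -> ScatteringCurve
    solvent_slds: dict = field(default_factory=lambda: dict(SOLVENT_SLD))

    def __post_init__(self) -> None:
        if not self.curves:
            raise ValueError("at least one contrast required")
        unknown = set(self.curves) - set(self.solvent_slds)
        if unknown:
            raise ValueError(f"no solvent sld for contrast(s) {sorted(unknown)}")


def effective_sld(layer: Layer, solvent_sld: float) -> float:
    """Volume-weighted sld of a solvent-penetrated box."""
    return (1.0 - layer.solvent_fraction) * layer.sld + layer.solvent_fraction * solvent_sld


def _stack_arrays(model: InterfaceModel):
    """Effective slds, thicknesses and interface roughnesses of the full stack.

    Media are [incident, layers..., solvent]; interface k sits between media k
    and k+1 and carries the roughness of the deeper medium's box (the spec's
    'roughness with the preceding layer' convention), the last one being
    ``solvent_roughness``.
    """
    slds = (
        [model.incident_sld]
        + [effective_sld(l, model.solvent_sld) for l in model.layers]
        + [model.solvent_sld]
    )
    thick = [l.thickness for l in model.layers]
    rough = [l.roughness for l in model.layers] + [model.solvent_roughness]
    return np.asarray(slds), np.asarray(thick), np.asarray(rough)


def reflectivity(model: InterfaceModel, q: np.ndarray) -> np.ndarray:
    """Specular reflectivity |r|^2 by the Parratt recursion.

    Névot-Croce Gaussian roughness factors exp(-2 k_j k_{j+1} sigma^2) multiply
    each Fresnel coefficient. The result is clipped to [0, 1].
    """
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0):
        raise ValueError("q must be positive")
    slds, thick, rough = _stack_arrays(model)
    n_media = slds.size

    kz0_sq = (q / 2.0) ** 2 + 0j
    # kz in each medium, measured relative to the incident medium
    kz = np.empty((n_media, q.size), dtype=complex)
    for j in range(n_media):
        kz[j] = np.sqrt(kz0_sq - 4.0 * np.pi * (slds[j] - slds[0]))

    # Parratt recursion from the solvent side up
    r = np.zeros(q.size, dtype=complex)
    for j in range(n_media - 2, -1, -1):
        kj, kj1 = kz[j], kz[j + 1]
        denom = kj + kj1
        fres = np.where(denom != 0, (kj - kj1) / np.where(denom != 0, denom, 1.0), 0.0)
        fres = fres * np.exp(-2.0 * kj * kj1 * rough[j] ** 2)
        if j < n_media - 2:
            phase = np.exp(2j * kj1 * thick[j])  # thick[j] is layer j's (medium j+1)
            r = (fres + r * phase) / (1.0 + fres * r * phase)
        else:
            r = fres
    return np.clip(np.abs(r) ** 2, 0.0, 1.0)


def sld_profile(
    model: InterfaceModel, z: np.ndarray | None = None, n_z: int = 500
) -> tuple[np.ndarray, np.ndarray]:
    """Error-function-smoothed sld depth profile for one contrast.

    z = 0 is the incident-medium/first-layer interface; z increases toward the
    solvent. The integral of (profile - solvent) over z is invariant to the
    roughness values (erf smoothing conserves area).
    """
    slds, thick, rough = _stack_arrays(model)
    z_if = np.concatenate([[0.0], np.cumsum(thick)])  # interface positions
    if z is None:
        pad = 4.0 * max(rough.max(), 1.0) + 10.0
        z = np.linspace(-pad, z_if[-1] + pad, n_z)
    z = np.asarray(z, dtype=float)

    profile = np.full_like(z, slds[0])
    for k in range(z_if.size):  # interface k between media k and k+1
        sig = max(rough[k], 1e-12)
        step = 0.5 * (1.0 + erf((z - z_if[k]) / (np.sqrt(2.0) * sig)))
        profile = profile + (slds[k + 1] - slds[k]) * step
    return z, profile


def co_refine(
    contrasts: ContrastSet,
    model: InterfaceModel,
    free: dict,
    bounds: dict | None = None,
    n_starts: int = 5,
    seed: int = 0,
    perturbation: float = 0.2,
) -> tuple[InterfaceModel, dict, float]:
    """Simultaneous multi-contrast refinement of a shared box model.

    ``free`` maps layer index to the list of fields to vary, e.g.
    ``{4: ["thickness", "sld", "solvent_fraction", "roughness"]}``. One
    structural parameter set is shared by all contrasts; only the bulk solvent
    sld differs per contrast. Minimizes the summed weighted chi^2 over all
    contrasts; curves without uncertainties contribute relative residuals.
    Multi-start with seeded +/-``perturbation`` offsets, as in the SAS fit.

    Returns the fitted model (evaluated view with the first contrast's
    solvent), a ``{(layer, field): stderr}`` dict, and the total chi^2.
    """
    default_bounds = {
        "thickness": (0.0, 300.0),
        "sld": (-1e-6, 1e-5),
        "solvent_fraction": (0.0, 1.0),
        "roughness": (0.0, 60.0),
    }
    bounds = {**default_bounds, **(bounds or {})}
    names = []
    for li, fields in free.items():
        if li >= len(model.layers):
            raise ValueError(f"layer index {li} out of range")
        for f in fields:
            names.append((li, f))

    def apply(params) -> InterfaceModel:
        layers = list(model.layers)
        for li, f in names:
            layers[li] = replace(layers[li], **{f: params[f"L{li}_{f}"].value})
        return replace(model, layers=layers)

    def residual(params):
        m = apply(params)
        chunks = []
        for name, curve in contrasts.curves.items():
            mc = m.with_contrast(contrasts.solvent_slds[name])
            r_model = reflectivity(mc, curve.q)
            if curve.uncertainty is not None:
                chunks.append((r_model - curve.intensity) / curve.uncertainty)
            else:
                # no uncertainties: compare decades symmetrically; reflectivity
                # spans ~8 orders of magnitude over the measured q range
                chunks.append(
                    np.log10(np.maximum(r_model, 1e-15))
                    - np.log10(np.maximum(curve.intensity, 1e-15))
                )
        return np.concatenate(chunks)

    rng = np.random.default_rng(seed)

    def make_params(offsets):
        params = lmfit.Parameters()
        for (li, f), off in zip(names, offsets):
            lo, hi = bounds[f]
            base = getattr(model.layers[li], f)
            val = base * (1.0 + off)
            if base == 0.0:
                val = off * (hi - lo) * 0.1
            # keep starts strictly inside the bounds: a solvent fraction of
            # exactly 1 (or a zero thickness) makes the layer invisible and
            # kills the gradient of every other parameter
            margin = 1e-3 * (hi - lo)
            val = float(np.clip(val, lo + margin, hi - margin))
            params.add(f"L{li}_{f}", value=val, min=lo, max=hi)
        return params

    starts = [np.zeros(len(names))]
    for _ in range(n_starts - 1):
        starts.append(rng.uniform(-perturbation, perturbation, size=len(names)))

    best = None
    reasons = []
    for offsets in starts:
        try:
            res = lmfit.minimize(residual, make_params(offsets), method="least_squares")
        except Exception as exc:
            reasons.append(str(exc))
            continue
        if not res.success:
            reasons.append(res.message)
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None:
        raise RuntimeError(f"co-refinement failed for all starts: {reasons}")

    fitted = apply(best.params)
    errors = {
        (li, f): (
            float(best.params[f"L{li}_{f}"].stderr)
            if best.params[f"L{li}_{f}"].stderr
            else float("nan")
        )
        for li, f in names
    }
    return fitted, errors, float(best.chisqr)
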