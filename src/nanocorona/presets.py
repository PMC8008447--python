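"""Reference parameter sets for the corona study.

These are the fitted structural models of the SPION/serum-albumin study this
package analyses: the SANS core-shell and ellipsoid models, the reflectometry
box models of the supported POPC/POPG/cholesterol (72/8/20) bilayer before and
after SPION/HSA adsorption, and the quenching/melting constants. They serve as
generator truth for synthetic data and as starting points for fits.

Quantities the study did not print (volume fractions, power-law amplitude,
background, the silicon-side solvent cushion) carry realistic defaults chosen
once and documented in docs/methods.md.
"""

from __future__ import annotations

from nanocorona.corona import CoronaGeometry, HSA_OBLATE_VOLUME, HSA_PRISM_VOLUME
from nanocorona.nr import SOLVENT_SLD, InterfaceModel, Layer
from nanocorona.sas import CoreShellModel, EllipsoidModel

__all__ = [
    "QUENCH_HSA",
    "MELT_TM",
    "SPIONS_HSA_CORE_SHELL",
    "SPIONS_CORE_SHELL",
    "HSA_ELLIPSOID",
    "pure_bilayer_model",
    "bilayer_with_adsorbate_model",
    "CORONA_DLS",
    "CORONA_SANS",
]

#: Fluorescence-quenching constants for the SPION/HSA system.
QUENCH_HSA = {
    "K_SV": 2.5e7,  # M^-1
    "tau0": 7.1e-9,  # s, mean HSA fluorophore lifetime (literature)
    "K_a": 6.2e8,  # M^-1
    "n": 1.2,  # binding sites
    "lambda_max_nm": 348.0,
    "protein_conc": 3.0e-6,  # M, ~0.2 mg/mL serum albumin
}

#: Melting midpoints (°C) for free HSA and the NP:HSA complex.
MELT_TM = {"HSA": 69.0, "NP:HSA": 73.0}

#: SANS core-shell + power-law model of the protein-coated particles.
SPIONS_HSA_CORE_SHELL = CoreShellModel(
    r_core=25.0,
    sld_core=6.9e-6,
    t_shell=48.0,
    sld_shell=2.1e-6,
    sld_solvent=SOLVENT_SLD["D2O"],
    volume_fraction=1.0e-3,
    polydispersity=0.6,
    powerlaw_amp=1.0e-7,
    powerlaw_exp=1.5,
    background=0.01,
)

#: Bare (organics-coated) particles, for comparison.
SPIONS_CORE_SHELL = CoreShellModel(
    r_core=27.0,
    sld_core=6.9e-6,
    t_shell=36.0,
    sld_shell=0.62e-6,
    sld_solvent=SOLVENT_SLD["D2O"],
    volume_fraction=1.0e-3,
    polydispersity=0.6,
    powerlaw_amp=0.0,
    powerlaw_exp=1.5,
    background=0.01,
)

#: Free serum albumin as an oblate ellipsoid.
HSA_ELLIPSOID = EllipsoidModel(
    a_minor=22.0,
    b_major=72.0,
    sld=1.86e-6,
    sld_solvent=SOLVENT_SLD["D2O"],
    volume_fraction=5.0e-3,
    background=0.01,
    shape="oblate",
)


def _cushion() -> Layer:
    # thin solvent layer between the silicon block and the bilayer;
    # solvent fraction pinned at 1 (pure solvent cushion)
    return Layer(thickness=4.0, sld=0.0, solvent_fraction=1.0, roughness=2.0,
                 name="solvent cushion")


def pure_bilayer_model(contrast: str = "D2O") -> InterfaceModel:
    """Supported POPC/POPG/Chol 72/8/20 bilayer before protein exposure."""
    return InterfaceModel(
        layers=[
            _cushion(),
            Layer(7.0, 1.65e-6, 0.45, 2.0, name="inner headgroups"),
            Layer(34.0, -0.15e-6, 0.010, 6.0, name="acyl chains"),
            Layer(7.0, 1.65e-6, 0.75, 2.0, name="outer headgroups"),
        ],
        solvent_sld=SOLVENT_SLD[contrast],
    )


def bilayer_with_adsorbate_model(contrast: str = "D2O") -> InterfaceModel:
    """Same bilayer after SPIONs/HSA adsorption (extra dilute adsorbate box)."""
    return InterfaceModel(
        layers=[
            _cushion(),
            Layer(6.7, 1.7e-6, 0.27, 2.0, name="inner headgroups"),
            Layer(32.0, -0.15e-6, 0.025, 3.0, name="acyl chains"),
            Layer(10.0, 1.50e-6, 0.62, 2.0, name="outer headgroups"),
            Layer(80.0, 2.65e-6, 0.86, 40.0, name="SPIONs/HSA adsorbate"),
        ],
        solvent_sld=SOLVENT_SLD[contrast],
    )


#: Corona geometries for the two measurement routes: DLS hydrodynamic radii
#: (8 -> 11 nm) with the oblate-ellipsoid protein volume, and SANS radii
#: (core + shell sums, 61 -> 73 Å) with the triangular-prism volume.
CORONA_DLS = CoronaGeometry(R_np=80.0, R_complex=110.0, V_protein=HSA_OBLATE_VOLUME)
CORONA_SANS = CoronaGeometry(R_np=61.0, R_complex=73.0, V_protein=HSA_PRISM_VOLUME)
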