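# nanocorona

Quantitative analysis of nanoparticle–protein corona experiments: a tested,
reusable Python pipeline for the multi-technique characterization of
superparamagnetic iron-oxide nanoparticles (SPIONs) interacting with serum
proteins (serum albumin, transferrin) and with model lipid membranes.

The package bundles five analysis stages that in the laboratory are usually
scattered across instrument software and spreadsheets:

1. **Fluorescence quenching** (`nanocorona.quenching`) — the Stern–Volmer
   relation *F₀/F = 1 + K_SV [Q]* gives the quenching constant from titration
   data; *K_q = K_SV/τ₀* against the diffusion-controlled limit
   (2 × 10¹⁰ M⁻¹ s⁻¹) classifies the mechanism as static or dynamic; for
   static quenching the double-log plot
   log₁₀((F₀−F)/F) = log₁₀K_a + n·log₁₀[Q] yields the binding constant K_a
   and site number n.
2. **CD thermal denaturation** (`nanocorona.thermal`) — the 222 nm CD melt is
   normalized to an unfolded fraction f = (I−I₀)/(I_f−I₀) and fitted with a
   two-state sigmoid f(T) = 1/(1+exp(−(T−T_m)/w)) for the melting temperature.
3. **Small-angle neutron scattering** (`nanocorona.sas`) — dilute-limit
   form-factor models: a core–shell sphere with Schultz polydispersity on the
   core radius plus a q^−α power law for clusters (the coated particle), and
   an orientation-averaged oblate ellipsoid (the free protein), with bounded
   multi-start least-squares fitting.
4. **Neutron reflectometry** (`nanocorona.nr`) — Parratt/Névot–Croce box model
   of the silicon-supported lipid bilayer with solvent-penetrated layers, and
   simultaneous co-refinement of H₂O/D₂O/silicon-match-water contrasts
   sharing one structural parameter set.
5. **Corona geometry** (`nanocorona.corona`) — bound-protein count
   N = (4/3)π(R³_complex − R³_NP)/V_protein, side-on monolayer capacity,
   Stokes–Einstein hydrodynamic radii and Smoluchowski zeta potentials.

A seeded synthetic-data module (`nanocorona.synthgen`) generates data with the
statistical structure each stage assumes, so the full pipeline runs and is
tested without instrument files.

## Worked example

Run the whole pipeline on synthetic data regenerated from the reference
models:

```sh
nanocorona all --seed 1 -o demo_out
```

which prints (abridged):

```json
{
  "quench": {
    "K_SV_per_M": 25000000.000000007,
    "K_q_per_M_per_s": 3521126760563381.5,
    "mechanism": "static",
    "K_a_per_M": 620000000.0000235,
    "n_sites": 1.2000000000000024
  },
  "melt": {
    "HSA":    {"T_m_C": 68.99182137670837},
    "NP:HSA": {"T_m_C": 72.96925714805917}
  },
  "sans": {"r_core_A": 24.999999999999897, "t_shell_A": 48.00000000000011},
  "nr":   {"adsorbate_thickness_A": 79.99999999999778},
  "corona": {"N_bound_DLS_route": 7, "N_bound_DLS_route_real": 7.181186868686869}
}
```

Reading the numbers: the Stern–Volmer constant 2.5 × 10⁷ M⁻¹ with a 7.1 ns
fluorophore lifetime gives K_q ≈ 3.5 × 10¹⁵ M⁻¹ s⁻¹, five orders of magnitude
above the diffusion limit, so quenching is static — the particle and protein
form a ground-state complex with K_a = 6.2 × 10⁸ M⁻¹ at a single class of
binding site (n = 1.2). The protein's melting midpoint shifts from 69 to
73 °C on binding, i.e. the adsorbed protein is slightly thermally stabilized.
SANS sees a 25 Å magnetite core under a 48 Å organic+protein shell; the
reflectometry co-refinement finds an 80 Å, 86%-hydrated particle layer resting
on an intact bilayer; and the shell volume between the 8 nm (bare) and 11 nm
(coated) hydrodynamic radii holds about 7 albumin molecules — an incomplete
corona, well below the ≈17–20 side-on monolayer capacity.

Per-stage subcommands (`quench`, `melt`, `sans-fit`, `nr-fit`, `corona`,
`simulate`) operate on plain-text column files; see `--help` of each and
`examples/demo.yaml`.

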