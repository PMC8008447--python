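# Demo configuration for `nanocorona all --config examples/demo.yaml`.
# Regenerates synthetic data for every stage from the reference models and
# refits them; the summary JSON collects K_SV, K_q, K_a, n, T_m, r_core,
# t_shell, the adsorbate-layer parameters, and the bound-protein count N.
seed: 1
stages: [quench, melt, sans-fit, nr-fit, corona]
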