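# Semi-empirical rice-paddy CH4 simulator, structural variant B.
# Differs structurally from variant A: a step redox gate instead of a linear
# ramp, plus its own oxidation fractions and production constant, so the
# two-variant spread reflects model structure, not just parameter jitter.
variant_id: B
vi: 0.33
q10: 2.5
t_ref: 30.0
eh_flood_min: -250.0
eh_oxic_max: 300.0
eh_rate_flood: 0.20
eh_rate_drain: 0.30
eh_gate: step            # f(Eh)=1 at or below eh_full, else 0
eh_full: -150.0
eh_zero: 0.0
exudate_coeff: 0.40
om_decay_rate: 0.025
ox_frac_plant: 0.45
ox_frac_diffusion: 0.70
ebullition_threshold: 0.15
k_b: 100.0
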