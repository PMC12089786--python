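# Semi-empirical rice-paddy CH4 simulator, structural variant A.
# Substrate pool + Q10 temperature response + linear redox (Eh) ramp.
# Units noted per entry; Eh in mV, rates per day, carbon in g C m-2.
variant_id: A
vi: 0.27                 # base CH4-C production per unit substrate index
q10: 3.0
t_ref: 30.0              # deg C
eh_flood_min: -250.0     # asymptote under flooding, mV
eh_oxic_max: 300.0       # asymptote under drainage, mV
eh_rate_flood: 0.16      # d-1, relaxation toward eh_flood_min
eh_rate_drain: 0.25      # d-1, relaxation toward eh_oxic_max
eh_gate: linear          # f(Eh)=1 below eh_full, ramps to 0 at eh_zero
eh_full: -150.0          # mV, full production at or below
eh_zero: 0.0             # mV, no production at or above
exudate_coeff: 0.45      # fraction of daily biomass increment -> substrate
om_decay_rate: 0.02      # d-1 decay of amended organic matter at t_ref
ox_frac_plant: 0.55      # oxidized fraction of plant-transported CH4
ox_frac_diffusion: 0.80  # oxidized fraction of soil-diffusing CH4
ebullition_threshold: 0.2  # g CH4-C m-2 d-1 of the non-plant pathway
k_b: 120.0               # g m-2, half-saturation biomass of the plant share
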