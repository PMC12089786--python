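# Manure-management-system emission parameters.  The system list is open:
# whatever labels appear in the activity dataset's share table must appear
# here.  mcf: % of the manure's maximum CH4 capacity (B0) realized;
# ef3: direct N2O-N emitted per kg N handled; frac_gas / frac_leach:
# volatilized and leached fractions of handled N.  ef4 / ef5 are the indirect
# factors applied to volatilized and leached N.

ef4: 0.010    # kg N2O-N per kg N volatilized and redeposited
ef5: 0.011    # kg N2O-N per kg N leached

systems:
  pasture_range:
    mcf: 1.5
    ef3: 0.020
    frac_gas: 0.07
    frac_leach: 0.03
  solid_storage:
    mcf: 4.0
    ef3: 0.020
    frac_gas: 0.30
    frac_leach: 0.02
  liquid_slurry:
    mcf: 17.0
    ef3: 0.010
    frac_gas: 0.40
    frac_leach: 0.001
  anaerobic_lagoon:
    mcf: 50.0
    ef3: 0.001
    frac_gas: 0.35
    frac_leach: 0.0
  daily_spread:
    mcf: 0.5
    ef3: 0.001
    frac_gas: 0.07
    frac_leach: 0.0
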