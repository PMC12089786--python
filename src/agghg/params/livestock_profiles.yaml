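# Per-category energy/nutrition profiles for the energy-balance (Tier 2 style)
# livestock emission route.  Major ruminants and swine carry a full
# gross-energy budget; poultry, rabbits, equids and camels use a simplified
# per-head route, mirroring common inventory practice where the energy-balance
# method is meant for the major fermenters.
#
# Units: ge MJ head-1 d-1; de % of GE digestible; ym % of GE as enteric CH4
# ("from_de" resolves through ym_table); ue_frac / ash_frac fractions;
# b0 m3 CH4 per kg volatile solids; cp_frac crude-protein fraction of diet;
# n_retention_frac fraction of N intake retained in product.
# Simplified route: enteric_ef / manure_ch4_ef kg CH4 head-1 yr-1,
# nex_rate kg N head-1 yr-1.

constants:
  energy_density_dm: 18.45      # MJ per kg dry matter
  ch4_energy_content: 55.65     # MJ per kg CH4
  ch4_density: 0.67             # kg CH4 per m3
  n_to_n2o: 1.5714285714285714  # 44/28
  protein_to_n: 6.25            # kg protein per kg N

# Default Ym lookup by digestibility for ruminants: list of [de_upper, ym];
# the last entry with null upper bound is the open tail.
ym_table_default:
  - [62.0, 7.0]
  - [71.0, 6.3]
  - [null, 6.0]

categories:
  dairy_cattle:
    route: tier2
    ge: 290.0
    de: 65.0
    ym: from_de
    ue_frac: 0.04
    ash_frac: 0.08
    b0: 0.24
    cp_frac: 0.16
    n_retention_frac: 0.20
  non_dairy_cattle:
    route: tier2
    ge: 250.0
    de: 60.0
    ym: from_de
    ue_frac: 0.04
    ash_frac: 0.08
    b0: 0.18
    cp_frac: 0.13
    n_retention_frac: 0.07
  buffalo:
    route: tier2
    ge: 240.0
    de: 57.0
    ym: from_de
    ue_frac: 0.04
    ash_frac: 0.08
    b0: 0.10
    cp_frac: 0.12
    n_retention_frac: 0.07
  sheep:
    route: tier2
    ge: 25.0
    de: 60.0
    ym: from_de
    ue_frac: 0.04
    ash_frac: 0.08
    b0: 0.19
    cp_frac: 0.12
    n_retention_frac: 0.10
  goats:
    route: tier2
    ge: 22.0
    de: 60.0
    ym: from_de
    ue_frac: 0.04
    ash_frac: 0.08
    b0: 0.18
    cp_frac: 0.12
    n_retention_frac: 0.10
  swine:
    route: tier2
    ge: 38.0
    de: 80.0
    ym: 1.0          # monogastric: low, fixed conversion
    ue_frac: 0.02
    ash_frac: 0.08
    b0: 0.29
    cp_frac: 0.16
    n_retention_frac: 0.30
  camel:
    route: tier2
    ge: 180.0
    de: 55.0
    ym: from_de
    ue_frac: 0.04
    ash_frac: 0.08
    b0: 0.26
    cp_frac: 0.10
    n_retention_frac: 0.05
  horses:
    route: simplified
    enteric_ef: 18.0
    manure_ch4_ef: 1.6
    nex_rate: 40.0
  mules:
    route: simplified
    enteric_ef: 10.0
    manure_ch4_ef: 0.9
    nex_rate: 25.0
  donkeys:
    route: simplified
    enteric_ef: 10.0
    manure_ch4_ef: 0.9
    nex_rate: 25.0
  poultry:
    route: simplified
    enteric_ef: 0.0
    manure_ch4_ef: 0.02
    nex_rate: 0.6
  rabbit:
    route: simplified
    enteric_ef: 0.0
    manure_ch4_ef: 0.08
    nex_rate: 1.2
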