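# Methods

`agghg` estimates agricultural non-CO2 greenhouse-gas emissions for four
subsectors — livestock CH4 (enteric fermentation + manure management),
livestock manure N2O, cropland N2O, and rice-paddy CH4 — on a single shared
activity foundation, links the manure nitrogen produced by livestock to the
nitrogen applied on cropland, aggregates everything to CO2-equivalents with
100-year global warming potentials, propagates input uncertainty by Monte
Carlo, and segments the 44-year national series into trend stages.  This
note records the models, the defaults and why they are what they are, what
the synthetic study world does and does not emulate, and the numerical
choices a maintainer would want to know about.

## The study world

The real inventory this framework is shaped for draws on national
agricultural yearbooks, livestock censuses, gridded livestock-distribution
maps and thousands of field observations.  None of those can be shipped, so
the package generates a structurally equivalent synthetic world with known
ground truth (`agghg.synthetic`):

- **Annual activity record, 1980–2023.**  Livestock head counts for 12
  categories (dairy cattle, non-dairy cattle, buffalo, sheep, goats, swine,
  camel, mules, donkeys, horses, poultry, rabbit), sown areas and synthetic-N
  application rates for 10 crop types, and rice areas for three season types
  (early/middle/late), resolved over six block regions of a toy raster
  (default 40×60 cells, the eastern blocks denser — a stand-in for the
  density divide of a real national domain).  Noise-free expectations are
  piecewise-exponential with stage breaks at 1997 and 2015; the default
  per-stage growth rates (livestock +5.0 %/yr, −4.0 %/yr, −0.1 %/yr;
  fertilizer-N rate +3.5, +5.0, −0.2 %/yr; crop area +1.0, +0.5, 0.0 %/yr;
  rice area 0.0, +1.0, −0.1 %/yr) encode a rapid-growth / slow-growth /
  stabilization staging in which livestock crest at the first break and
  fertilizer-driven cropland activity crests at the second.  Multiplicative
  lognormal noise with CV 0.02 (yearbook-like interannual statistical
  noise) keeps every series positive.
- **Breakpoint overshoot.**  Real national series show spike years at regime
  transitions (boom-bust overshoot; statistical-source revisions around
  censuses).  The generator adds a one-year log-level bump at each
  breakpoint, proportional to the drop in growth rate across it
  (`breakpoint_overshoot`, default 1.0, i.e. the full rate drop for one
  year).  This makes the configured breakpoint years genuine local maxima of
  the aggregate CO2-eq series; with the overshoot disabled the stage-wise
  log-slopes of the noise-free series equal the configured rates exactly
  (to 1e-10), which is how the trend mechanism is unit-tested.
- **Geography.**  A region-label raster (contiguous bands), two base-year
  spatial weight maps (nominal 2010 and 2015) normalized to sum to one
  within each region, a production-system raster labelling each cell
  cropland-based/mixed or livestock-only (mixed farming more common in the
  "eastern" regions; every region keeps at least one mixed cell so manure
  always has a destination), and a constant cell area.
- **Climate.**  Daily temperature per cell as a sinusoidal annual cycle
  (mean 18 °C, amplitude 10 °C) plus a north–south gradient, a static cell
  offset and daily noise; per-season water calendars (flooding from
  transplanting to harvest with a 7-day midseason aeration and 7-day final
  drainage).
- **Emission-factor observations.**  1705 rows (the corpus size of the
  data-driven EF literature this emulates), balanced over the 10 crop
  types, with covariates (N rate, mean annual temperature and
  precipitation, soil pH, SOC, clay fraction) drawn uniformly from realistic
  ranges and observed EFs equal to a known smooth surface times mean-1
  lognormal noise with CV 0.3, clipped to [0, 0.1].  The true surface is
  saturating in N rate and modulated by per-crop multipliers (0.15–7.0) and
  climate/soil terms.  The multipliers are deliberately wide: with
  multiplicative observation noise of CV c, no predictor can exceed a pooled
  holdout R² of Var(s)/(Var(s) + c²·E[s²]); the spread keeps that ceiling
  near 0.90 so that a skillful model can demonstrably reach the 0.8
  recovery floor.  What this world does *not* emulate: real spatial
  covariance of activity, reporting breaks other than the modelled spikes,
  crop rotation structure, or any real administrative geometry — so passing
  tests demonstrate the correctness and calibration of the machinery, not
  agreement with any real country's totals.

Random streams are split per output (activity / geography / climate /
observations / census / model seeds) from the master seed via a small FNV
hash, so regenerating one component never perturbs another.

## Activity harmonization

Regional livestock series are anchored to sparse census values (years 1996,
2006, 2016) by the ratio method: at each census year the factor
census/raw is formed, factors are interpolated linearly in time between
censuses and held constant outside the span, and the raw series is
multiplied through — it then passes exactly through the anchors while
preserving intercensal growth shape.  The final year's activity is the
one-step-ahead OLS linear-trend forecast from the previous five years
(floored at zero), while all emission factors for that year are frozen at
the penultimate year's values; a mild productivity drift (+0.2 %/yr on
per-head factors) makes the freeze observable.  Regional totals are spread
to the grid with the base-year weight maps interpolated linearly in time
between 2010 and 2015, constant outside, and re-normalized per region after
interpolation to guard against floating-point drift.

## Livestock (energy-balance Tier 2)

Per category, with GE the gross energy intake (MJ head⁻¹ d⁻¹) and DE the
digestible fraction (%):

- enteric CH4 EF = GE · (Ym/100) · 365 / 55.65 (kg head⁻¹ yr⁻¹), with the
  methane conversion factor Ym from a digestibility lookup (de ≤ 62 → 7.0;
  62 < de ≤ 71 → 6.3; de > 71 → 6.0; overridable per category);
- volatile solids VS = [GE·(1−DE/100) + UE·GE] · (1−ASH)/18.45
  (kg DM head⁻¹ d⁻¹), urinary-energy fraction UE 0.04 for ruminants, 0.02
  for swine, ash fraction 0.08;
- manure CH4 EF = VS · 365 · B0 · 0.67 · Σ_s MCF_s·MS_s, with B0 the
  maximum methane potential (m³ kg⁻¹ VS), MCF_s the system methane
  conversion factor and MS_s the manure-system share;
- N excretion Nex = (GE/18.45)·(CP/6.25)·(1−retention)·365;
- manure N2O: direct = Σ_s Nex·MS_s·EF3_s·44/28; indirect from volatilized
  (frac_gas·EF4) and leached (frac_leach·EF5) N.

Poultry, rabbits, equids use a simplified per-head route (fixed enteric and
manure CH4 EFs and Nex rates) — the energy-balance method is meant for the
major fermenters, and this mirrors common inventory practice.  All numbers
live in YAML parameter packs (`params/livestock_profiles.yaml`,
`params/manure_systems.yaml`), validated on load (DE ∈ (0,100), Ym < 15,
MCF ∈ [0,100], and EF3 + frac_gas + frac_leach ≤ 1 per system, otherwise
the nitrogen ledger would go negative).

**Nitrogen ledger.**  Per (year, region, category):
excreted = direct N2O-N + volatilized + leached + applied-to-cropland +
residual, closing to 1e-9 relative.  Applied manure N is a configurable
fraction (default 0.5) of the post-loss residual, credited only to regions
containing cropland-based/mixed cells, and is exactly the manure-N input the
cropland stage consumes — the cross-subsector link that motivates running
all four subsectors on one data foundation.

## Cropland N2O

Direct emissions are EF × N load × 44/28 per source — synthetic fertilizer
(rate × area), manure (from the ledger, allocated to crops proportional to
synthetic-fertilizer N), plus synthetic stand-in layers for deposition,
mineralization, crop residues and pasture fertilization (15/20/10/5 % of
fertilizer N by default).  The indirect pathway leaches a fraction of total
N (default 0.2) and emits at EF5 = 0.011.  Attribution per source is
retained and sums exactly to the total.

**The EF model.**  One random forest per crop type (500 trees,
min_samples_leaf 3) maps the six site covariates to the EF, trained on a
70 % split with holdout R²/RMSE recorded per crop and pooled.  Two
refinements beyond a plain forest, both motivated by the multiplicative
error structure of EF measurements:

1. forests are fit on log(EF + 1e-5) and predictions back-transformed with
   a smearing (half residual variance) factor, which stabilizes the
   variance of skewed EF data;
2. each crop's prediction is blended 50/50 in log space with a shared
   backbone forest trained on all crops' log-EFs after removing each crop's
   mean level.  The environmental response is largely common across crops
   while per-crop samples are sparse (~120 training rows), so this
   multi-task sharing markedly reduces estimation variance; per-crop
   sub-models (own forest + own level + the blend) remain the unit of
   prediction.

On the default observation set the pooled holdout R² is ≈ 0.80–0.89
depending on seed (mean ≈ 0.86), against a noise-imposed ceiling of ≈ 0.87–
0.91.  Predictions are clipped to [0, 0.1]: an EF of 10 % of applied N is
far beyond any reported cropland value, so anything larger is treated as
extrapolation error.  Rows with missing covariates predict as missing.

## Rice-paddy CH4

A daily semi-empirical substrate–redox–transport simulator, run as two
structural variants whose mean and spread stand in for a two-model
process-ensemble:

- **Substrate**: exudate_coeff × max(ΔBiomass, 0) plus an amended
  organic-matter pool decaying at om_decay_rate scaled by a Q10 temperature
  factor; the pool is decremented by what decays (mass closure: the total
  decayed converges to the amendment).  Biomass follows a logistic
  trajectory; senescence contributes no exudate.
- **Redox**: soil Eh relaxes toward −250 mV under flooding and +300 mV
  under drainage.  Each daily step applies the exact exponential decay
  factor for its regime, so the integrator matches the analytic solution on
  constant regimes and is continuous across switches.
- **Production**: vi × substrate × Q10^((T−30)/10) × f(Eh).  Variant A
  gates production with a linear ramp (full below −150 mV, zero at 0 mV);
  variant B uses a step gate at −150 mV together with its own production
  and oxidation constants — a structural, not merely parametric, contrast.
- **Transport**: the plant-mediated share rises with biomass as
  B/(B + k_b); plant-transported CH4 loses ox_frac_plant to rhizospheric
  oxidation; of the soil pathway, anything above the ebullition threshold
  bubbles out unoxidized and the rest diffuses with its own oxidation
  fraction.  Emitted + oxidized = produced to 1e-12 (carbon conservation).

Internal bookkeeping is in g CH4-C; the 16/12 conversion to g CH4 happens
only at the emission boundary.  All constants live in
`params/rice_variant_a.yaml` / `rice_variant_b.yaml` and are plausible
placeholders for a semi-empirical paddy model of this family; since no
published benchmark calibration ships with the package, the simulator is
exercised through conservation, monotonicity (drainage and amendment) and
step-size-robustness properties, never through agreement with real
regional totals.  Winter rice is not simulated.  In the pipeline the
simulator runs per (year, region, season, variant) on region-mean daily
temperature, and the per-area season total multiplies the rice area; this
keeps a 44-year two-variant national run in seconds, and nothing would be
learned by exercising it per cell, where the within-region temperature
spread is generated noise.

## Aggregation, uncertainty, trends

CO2-equivalents use GWP100 = 27 (CH4) and 273 (N2O).  Percentage shares are
rounded half-up to integer percent — the only rounding mode that reproduces
all five published share figures simultaneously from the published
subsector means.  Rollups to region/nation are exactly conservative.

**Monte Carlo** (10 000 draws): activity multipliers are uniform on
1 ± √3·cv, so the stated CV is the distribution's actual CV (truncated at
zero and flagged when cv > 1/√3); EF multipliers are normal(1, sd)
truncated at zero.  The propagation runs on national-series slices
(base series × activity multiplier × EF multiplier), which is exact for the
emission-factor subsectors because they are linear in both inputs; the rice
subsector's uncertainty is instead structural — the two-variant sd/mean —
and bypasses the Monte Carlo entirely.  Envelopes report mean, sd and the
2.5/97.5 percentile band, since published "±" conventions vary.

**Trends.**  Peaks are local maxima of the 5-year centered moving average
ranked by prominence (top 2), each refined to the raw-series maximum within
±2 years — smoothing displaces a kink's maximum by one or two years when
the rise and fall slopes are asymmetric, and the refinement undoes that.
Peak years can also be supplied manually (configured defaults 1997/2015).
Stages tile the record at the peaks; stage trends are OLS slopes of
emission on year with two-sided t-tests at 0.05.  Robustness: for each
stage, 10 distinct years are drawn without replacement from the stage
window extended by 3 years into the adjacent periods (1980–2000, 1994–2018,
2012–2023 for the default stages; a window shorter than 10 years is widened
to 10 within the record) and the OLS slope recorded, 1000 times.  Note the
percentile band of this subsampled-slope distribution collapses onto the
full-window fit as the window length approaches 10, so its bracketing
behaviour is only nominal for windows ≳ 24 years; the short-window study
windows are validated through the stage-ordering property instead.  Moving
windows use [c−5, c+4] for central year c (centers 1985–2019 on a
1980–2023 record — the convention consistent with that center range at both
ends).

## Pipeline and provenance

`run_pipeline` executes synthesize → harmonize → livestock → cropland →
rice → aggregate → uncertainty → trends; every saved artifact carries a
16-hex digest of the full configuration.  A zero-emission parameter pack
(all EFs zero) runs to completion with all-zero outputs and shares reported
as undefined.  Totals below 1e-12 Tg (≈1 mg nationally) are treated as
zero when forming shares, absorbing float residue from the log-space EF
back-transform.  Outputs are CSV/JSON by default; gridded period means and
rasters write as NetCDF3 via the SciPy backend.

## Known limitations

- The synthetic world's subsector mix (≈37/24/32/7 % of CO2-eq) is
  livestock-CH4-led but weights cropland N2O more heavily than real
  inventories of this kind; the mix is a by-product of keeping the trend
  staging and the EF-recovery ceiling simultaneously realistic.
- Manure application to crops is allocated proportional to synthetic-N
  fertilizer; real manure practice is far patchier.
- The rice variants differ structurally but both descend from the same
  substrate formulation; a true multi-model ensemble would disagree more.
- Monte-Carlo inputs are treated as independent (no correlated draws, no
  variance decomposition).
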