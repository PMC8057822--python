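# Methods

## Scope and data model

`airburden` computes the disease burden attributable to ambient PM2.5 and
ozone exposure from gridded concentration fields, and compares policy
scenarios against a control. The pipeline is deliberately agnostic to where
the concentration fields come from: any CF-style NetCDF with hourly (or
pre-aggregated annual) values on a regular lat/lon grid is accepted, and a
synthetic generator produces internally consistent stand-ins for
chemistry-transport output, population and health data.

Spatial indexing is 0-based `[lat, lon]` on cell centers. PM2.5 is carried
in μg m⁻³ and ozone in ppb; readers convert recognised unit spellings
(e.g. `ppm` → ×1000) and refuse unknown ones rather than guessing.

## Exposure metrics

**Annual-mean PM2.5** is the plain arithmetic mean over all time steps of
the year.

**6mDM8h ozone** is computed per cell as: (i) the mean of hours
[h, h+8) for every start hour, dropping windows that would run past the
year end (no padding: truncated windows would fabricate data); (ii) the
daily value, the maximum over the up-to-24 windows starting that day;
(iii) twelve candidate means of the daily values over 6 consecutive
calendar months, wrapping within the single simulated year (the
August-start window averages Aug–Dec plus the same year's January); and
(iv) the maximum candidate. Wrapping is the default because only one year
is simulated; a non-wrapping mode restricted to the 7 windows that fit in
the calendar is available (`wrap=False`) and can only return a value ≤ the
wrapped result.

Numerically, the 8-h window means are accumulated in the same pairwise
order as an 8-element `np.mean`, and the 6-month candidates are reduced per
cell as 1-D day series. This makes the vectorized implementation
bit-identical to a direct per-cell computation — the property the oracle
tests assert exactly, with no tolerance.

## Exposure–response and burden

PM2.5 risk uses the GEMM NCD+LRI hazard function with age-specific θ
(declining with age) and shared α = 1.6 μg m⁻³, μ = 15.5 μg m⁻³,
ν = 36.8 μg m⁻³, counterfactual 2.4 μg m⁻³. The parameters live in a
packaged, editable CSV (`airburden/data/gemm_ncd_lri.csv`, bounds
θ ± 1.96·se) so alternative fits can be swapped in without touching code;
nothing in the algorithm hard-codes them. Brackets absent from the age
structure (under-25) simply contribute no burden.

Ozone risk is log-linear for COPD: HR = 1.06 (95UI 1.02–1.10) per 10 ppb
above 35.7 ppb. The attributable fraction is 1 − exp(−z·ln(HR)/10): the
negative exponent is the only sign consistent with a non-negative
attributable fraction and a counterfactual below which no excess risk is
assumed (at z = 10 it reduces to 1 − 1/HR exactly).

Baseline rates are ingested per 100,000 and divided by 100,000 exactly
once, at ingestion; all internal arithmetic is per person. MORT/YLL/YLD are
attributable count × per-person rate; DALYs = YLL + YLD by construction,
an exact identity at every cell, bracket and variant. The whole chain is
linear in population and in rates, which the tests assert at 1e-12
relative tolerance.

### Uncertainty

Three sources carry bounds: θ (or HR), baseline rates and age fractions.
The default 95UI evaluates all three simultaneously at their lower (resp.
upper) bounds. Because the chain is monotone in each source, this envelope
equals the min/max over all 3³ mixed combinations (asserted by brute force
in the tests) and is conservative relative to any independence assumption.
A Monte-Carlo alternative (`monte_carlo_regional`, seeded, 200 draws by
default) samples θ per bracket and ln HR from normals matched to the
bounds, and scales rates and age fractions by normal factors; it operates
on regional aggregates rather than per-cell fields to keep memory bounded.

## Evaluation and bias adjustment

NMBF and NMAEF use the piecewise-denominator factor definitions: when the
model mean exceeds the observed mean, both are normalised by ΣO, otherwise
by ΣM. This gives the factor symmetry the tests check (a model high by a
factor F scores NMBF = F − 1; low by F scores −(F − 1)), scale invariance,
antisymmetry under swapping model and observations, and NMAEF ≥ |NMBF|.
Stations are matched to the nearest grid cell by great-circle distance
(ties to the lower index); the comparison pairs station annual means
against the model annual metric by default, with an hourly pairing mode
available. Missing observations are NaN and excluded pairwise.

Bias adjustment is `adjusted = S × (1 − NMBF)`, the single linear form
consistent with adjusting a positively biased exposure down and a
negatively biased one up. Reported values round half-up to integers, as do
percent exposure changes (computed as 100 × Δ / control); aggregate counts
report to the nearest 100.

## Synthetic study world

The generator is a linear source surrogate, not a chemistry emulator.

* **Domain:** 24 × 36 cells (1°) over a China-like extent, one hourly
  calendar year (2015, 8,760 h).
* **Population:** smooth rural field plus Gaussian urban peaks at 8 random
  centers, 60% urban share, normalised to 1.37 × 10⁹ persons; adult (25+)
  share 0.664 split over twelve 5-year brackets with ±3% bounds.
* **Baseline rates:** synthetic NCD+LRI and COPD MORT/YLL/YLD tables per
  bracket, rising steeply with age and of realistic magnitude, ±8% bounds.
* **Concentrations:** per pollutant, control = background + Σ sector
  components + AR(1) noise (ρ = 0.9 hourly), clipped at zero with clip
  events counted. Each sector component is separable: a spatial kernel
  (population-following for industry/transport, inverse-population for
  agriculture, blended for residential) times a positive diurnal/seasonal
  modulation. Components are normalised so the national population-weighted
  annual-mean contribution of sector k equals its configured share of the
  sector budget (60 μg m⁻³ PM2.5, 28 ppb ozone over a 12 μg m⁻³ / 30 ppb
  background), yielding control exposures of roughly 72 μg m⁻³ PM2.5 and
  70 ppb 6mDM8h ozone — high-pollution study conditions.
* **Sector shares (PM2.5 / O3):** residential 0.35/0.15, industry
  0.20/0.25, transport 0.05/0.30, agriculture 0.15/0.05, other 0.25/0.25.
  Residential is the largest PM2.5 contributor and transport the largest
  ozone-precursor contributor, mirroring the qualitative structure of
  Chinese emission inventories.
* **Scenarios:** four archetypes — residential −50% and agricultural −30%
  outside the focal ("GBA-like") sub-domain, industrial −10% and transport
  −80% nationwide. A scenario subtracts scale × component inside its
  domain. Ozone responds with an explicit signed regime map for precursor
  sectors (transport, agriculture): the densest 30% of cells by population
  are "VOC-limited" and respond to cuts with an ozone *increase*, the rest
  decrease. This reproduces, qualitatively, the real dichotomy where NOx
  cuts raise urban ozone while lowering PM2.5.
* **Stations:** 50 sites placed population-weighted (shared cells
  allowed), observing the true cell series times (1 + bias) plus additive
  noise with 5% missing hours. Station randomness uses a sub-stream
  independent of field noise, so adding stations never perturbs the
  fields.

Every output is a pure function of the seed (verified bit-identical), and
the component bookkeeping identity control = background + Σ components
(+ noise, before clipping) is exact.

**What the generator does not emulate:** meteorology and pollution
transport (an outside-domain cut has exactly zero effect inside the
domain, unlike reality where winter transport matters), nonlinear
chemistry, seasonal regime shifts, and correlated rate uncertainty.
Passing tests therefore demonstrate the correctness of the assessment
arithmetic and the qualitative scenario logic, not the realism of any
particular avoided-burden magnitude.

## Numerical and design choices

* Region rasterization defaults to strict cell-center containment;
  fractional-area overlap is available (`method="area"`, planar
  degree-space areas). A mask set declared a partition must sum to 1 per
  cell within 1e-9.
* Nearest-cell matching uses the haversine great-circle distance; the
  first (lowest-index) minimum wins ties.
* NetCDF I/O uses xarray's scipy backend (NetCDF3 classic) with CF-style
  attributes; float64 fields round-trip bit-identically. A `units`
  attribute is mandatory on read.
* Avoided burden differences bound-to-bound (lower − lower, upper −
  upper), matching the simultaneous envelope; an ozone term may be
  negative when a scenario raises ozone exposure, and combined avoided
  deaths are the additive sum of the PM2.5 and ozone terms.
* Counts are aggregated before rates are formed — never averaged rates —
  so regional rates are exactly counts / population × 100,000.
* Degenerate inputs fail loudly: zero weighted population, empty time
  axes, non-monotonic axes, partial years for 6mDM8h, NMBF with
  non-positive sums, and bias factors ≤ −1 all raise typed errors.

## Problem sizes

The default synthetic scale (24 × 36 × 8,760 h, four scenarios) runs end to
end in a few seconds on one core and is the scale used by the acceptance
script and the end-to-end tests; the oracle comparisons use 20 independent
random years on a single cell. These sizes were chosen as the smallest at
which the spatial (urban/rural, inside/outside-domain) and temporal
(diurnal, seasonal, calendar-month) structure of the problem is fully
exercised.

## Known limitations

* The GEMM is the only PM2.5 exposure–response option (no IER or
  log-linear alternatives), and COPD the only ozone outcome.
* The envelope 95UI treats the three uncertainty sources as perfectly
  co-monotone, which widens intervals relative to independent combination;
  the Monte-Carlo mode quantifies that difference but is not the default.
* Linear scenario surrogates cannot capture chemistry-driven
  non-additivity between sectors; comparisons between scenario magnitudes
  should be read qualitatively.
* Fractional-area rasterization uses planar degree areas, slightly biased
  at high latitudes; the default center-containment method is unaffected.
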