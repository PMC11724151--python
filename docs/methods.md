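# Methods

## Model overview and assumptions

`thermarange` simulates a single species' metapopulation on a regular
grid.  Cells hold local populations; a timestep (nominally one year)
applies, in order: habitat suitability → metabolic scaling of
demographic rates → local reproduction and mortality → seed dispersal →
recruitment.  The next abundance is survivors + recruits, so abundance
at step *t* already includes immigration that happened during step *t*.
Recorded outputs (abundance, habitat suitability h, suitability-scaled
carrying capacity K_h, growth rate, mortality) are the fields of that
step, post-update.

Key assumptions: populations are unstructured (no age or stage);
individuals within a cell are identical; the environment acts on
demography only through temperature (metabolic scaling) and through the
suitability product/minimum (capacity scaling); dispersal is isotropic
and memoryless; only one species is simulated at a time.

## Habitat suitability

Each niche variable with cardinal limits (v_min, v_opt, v_max) is
scored with the beta-type cardinal curve (see README).  Values at or
outside the limits map to exactly 0 — no extrapolation — and the
fractional exponent is only ever applied to a non-negative base.
Computed suitabilities below 1e-12 are flushed to 0 so that "suitable
cell" predicates (initialisation, cell classification) are stable.
Because the curve uses only differences of v, temperature may be given
in Celsius or Kelvin as long as environment and limits agree; the
reader converts both to Kelvin (auto-detected: means above 150 are
taken as Kelvin, overridable with the `temperature_unit` config key).
Layers combine by cell-wise minimum (default) or multiplication;
restriction layers (land-use masks etc., already in [0, 1]) are folded
in last by the same rule.  NaN cells are permanently uninhabitable:
h = 0, abundance forced to 0.

Suitability is always recomputed per timestep, whether or not metabolic
scaling is enabled; the two mechanisms are independent.

## Metabolic scaling

Each of growth rate, mortality and carrying capacity (and the Allee
threshold, when present) has its own allometric exponent a and
activation energy E.  The literature rarely reports these per species,
so the defaults are the canonical values: a = −1/4, E = +0.65 eV for
rates (warmer cells → faster turnover), a = −3/4, E = −0.65 eV for
carrying capacity (warmer cells → fewer individuals supported); the
Allee threshold follows the capacity law.  All are overridable per
species file (`exponent_growrate`, `energy_carry`, ...).  The
Boltzmann constant is used in eV K⁻¹ so energies are entered in eV.
Anchoring b0 at the species' optimum temperature makes every scaled
field equal its reference value wherever T = T_opt, which is also the
basis of the identity tests.  Scaled mortality above 1 is clamped to 1
(it is a probability); fields are recomputed each timestep from that
step's temperature grid.

## Local demography and integerisation

The Beverton–Holt-with-mortality map is decomposed into survivors
N(1−m), floored, and a real-valued seed crop
N·r / (1 + N(r−m)/(K_h·m)).  The density-dependent denominator is
calibrated so the real-valued closed-cell composite has its unique
positive fixed point exactly at K_h; iteration from any positive start
converges monotonically to it.  Cells with r ≤ m, K_h = 0 or m = 0
produce no seeds (the limiting behaviour of the map).  Survivors and
seeds are computed from the same N_t (simultaneous census).

Integerisation is deliberate and minimal: survivors are floored at the
demographic step; seeds stay real through dispersal and are floored (or
Poisson-sampled) only at recruitment.  Flooring twice costs on average
about one individual per cell per step, so the *integer* closed-cell
equilibrium sits a constant handful of individuals (≈ 3–6) below K_h
regardless of K — negligible at realistic carrying capacities
(relative error < 0.5% for K in the hundreds of thousands, ≈ 0.5% at
K = 1000).  Exact ±1 convergence to K_h is a property of the
real-valued recurrence (`beverton_map`), which the package exposes for
equilibrium analysis; tests check both forms at their own tolerances.

Ricker (N·exp(r(1−N/K_h))) and Ricker–Allee
(N·exp(r(1−N/K_h)(N−A)/K_h)) variants use the classic maps decomposed
into the same survivors + seeds form, so the process order is uniform
across reproduction models.  The Allee threshold must lie below the
carrying capacity (validated at load).

## Dispersal and recruitment

The kernel is exp(−d/α) evaluated at Euclidean cell-centre distances,
truncated at the maximum dispersal distance and renormalised; α is half
the mean dispersal distance because a 2-D negative-exponential
displacement has mean 2α.  Renormalisation means truncation never loses
seeds; only the absorbing grid boundary does (a buffer rim wider than
the kernel radius eliminates edge loss).  Discretisation at cell
centres recovers the trait mean distance within ~15% when truncation is
mild; species with mean distance far below one cell (e.g. the packaged
orchid at 0.0005 cells) retain essentially all seeds at the origin.
Seeds may land in h = 0 cells; they recruit there and subsequently die,
which is the intended source–sink behaviour.  Dispersal is a direct
(non-FFT) 2-D convolution — exact to rounding, and fast at the
landscape sizes targeted.

One seeded generator (config `randomseed`) drives all stochasticity;
Poisson recruitment consumes cells in row-major order, so runs are
bit-reproducible for a fixed seed, including across sequentially
simulated species.

## Initialisation and burn-in

`habitat` (default): N0 = round(K·h) in every cell with h > 0; `all`:
N0 = round(K) in every habitable cell; `random`: suitable cells are
occupied independently with probability 0.5 (an arbitrary, documented
constant) at N0 = round(K·h).  Burn-in is a data pattern, not an engine
flag: prepend repeated environment slices (the `climate_trend_series`
helper does this with its `onset` argument) and let the metapopulation
equilibrate before the trend begins.

## Synthetic data

The neutral-landscape generator smooths white noise with a Gaussian
filter (correlation length 3 cells by default — smooth at the 20×20
demo scale) and then affinely standardises, so the sample mean and
(population, ddof = 0) standard deviation match their targets to
machine precision for every seed.  Only the moments are contractual;
the autocorrelation structure is a free choice.

The demo experiment is a 20×20 static landscape (temperature
293.15 ± 2.5 K, precipitation 500 ± 100 mm yr⁻¹, internal seed 42, 25
timesteps) with an orchid-like species whose niche is centred on that
climate and whose dispersal is raised to mean 1 / max 3 cells so that
dispersal is visible at this scale.  The packaged example folders place
the real orchid trait file on a synthetic landscape centred on its
niche (10 km cells); the environmental-change example runs 40 steps
with a 10-step burn-in and +0.1 K per step of warming thereafter.

The dispersal-contrast scenario emulates a warming range shift with
refugia: a west–east temperature gradient spanning the tolerance
window, warmed uniformly after burn-in, so warm-edge cells decline
while cool cells improve.  Metabolic scaling is switched off there to
isolate the suitability-and-dispersal mechanism.  What these synthetic
settings do *not* emulate: real spatial covariance of climate,
topography, fragmented habitat, parameter uncertainty, or observation
error — passing tests demonstrate mechanistic correctness and
qualitative source–sink behaviour, not forecast skill on real
landscapes.

## Numerical choices

- Suitability flush threshold 1e-12; kernel normalisation checked to
  1e-12; interior dispersal conservation holds to 1e-9.
- Kelvin auto-detection threshold 150 (no terrestrial climate is
  ambiguous under it).
- Output TSV stores floats at full round-trip precision and abundances
  as integers; the reader uses exact (round-trip) float parsing, so
  write → read is lossless.
- Environment folders are ordered by natural numeric filename sort
  (t2 before t10); ties break lexicographically.
- Problem sizes in tests and the acceptance script (20×20 grids, ≤ 40
  timesteps, 10⁵ Poisson draws, 10³ random scaling laws) are chosen so
  the full suite runs in seconds while keeping sampling error far below
  the asserted tolerances.

## Known limitations

Single-species only; absorbing edges only (reflecting/periodic
boundaries would suit small or continuous landscapes better); no
age/stage structure; no biotic interactions; CSV-only I/O (no raster
formats); the cardinal curve is the only tolerance shape.  Mortality is
density-independent, and the Allee threshold's metabolic scaling
follows the capacity law — a modelling convention, not an empirical
result.
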