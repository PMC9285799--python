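# Methods

## Model overview

`feiso` integrates a dual-isotope iron cycle in a 1-D water column.  Every
Fe reservoir is represented by a pair of amounts (⁵⁶Fe, ⁵⁴Fe); totals and
deltas are derived quantities.  This choice makes conservation of each
isotope exact by construction — fluxes are split so that the light
component is the bulk flux minus the heavy component — and it is why the
per-step budget closes to solver roundoff (~10⁻¹² relative over a 50-year
run) rather than to a tolerance of the delta algebra.  ⁵⁷Fe and ⁵⁸Fe are
neglected; "⁵⁴Fe" therefore stands for all non-⁵⁶Fe iron.  The reference
ratio defaults to 15.67 (IRMM-014) and is configurable; natural-abundance
initialisation derives the heavy fraction from r/(1+r) (~0.9400), never
from the rounded 94 %/6 %.

### Flux splitting

Two rules convert bulk fluxes to isotope pairs:

* **Source rule** — an external flux J with endmember δ carries
  J⁵⁶ = J·R/(R+1), R = r·(δ/1000+1).  The recombined delta equals the
  endmember to <10⁻¹⁰ ‰ and the bulk input strength is untouched.
* **Process rule** — an internal transfer J from a donor pool with ratio
  R = ⁵⁶Fe/⁵⁴Fe and fractionation factor α carries
  J⁵⁶ = J·Rα/(Rα+1).  The transferred ratio is exactly Rα, so for a donor
  at 0 ‰ the transferred delta is exactly (α−1)·1000; to first order the
  offset from the donor is (α−1)·1000 for any donor delta.  Stepwise
  removal at constant α reproduces Rayleigh distillation,
  δ(f) ≈ δ₀ + 1000(α−1)·ln f, within 1 % down to f = 0.1 (tested).

α is applied to the donor's *instantaneous* ratio each step.  When a
discrete step would overdraw a donor pool, the transfer is clipped
proportionally (both isotopes by the same factor, preserving its delta)
and a warning is logged; the dissolved pool additionally keeps 10 %
headroom so its ratio stays defined.

### Speciation and internal cycling

Dissolved Fe partitions between free Fe′ and ligand-bound FeL assuming
1:1 equilibrium, K′ = [FeL]/([Fe′][L′]), solved in the numerically stable
closed form 2·FeT·LT/(b+√(b²−4·FeT·LT)) with b = FeT+LT+1/K′.  Default
ligand field: L_T = 1.2 nM prognostic (first-order production/decay
around that value) and K′ = 10¹¹ M⁻¹; 50 % of FeL is treated as
colloidal.

Only two processes fractionate (standard configuration):

* phytoplankton uptake, α = 0.9995, both size classes, drawing on the
  *bulk* dissolved pool's ratio (the simplest reading of a single uptake
  α when uptake spans Fe′ and FeL);
* organic complexation, α = 1.0006, applied *indirectly*: colloidal
  pumping removes the colloidal half of FeL with α, particle scavenging
  removes Fe′ with α⁻¹.  The dissolved pool carries one isotope pair —
  Fe′ and FeL deltas are not tracked separately, so "FeL is heavier than
  Fe′" is an emergent interpretation of the removal pathways, not model
  state.

Remineralization of both particle classes, zooplankton recycling and
losses, and bacterial uptake (routed to small particles) are all
delta-preserving (α = 1).  Any isotopic effect of remineralization is
inherited from the particles being lighter (or heavier) than ambient
dFe.

### Sources

* **Dust** (top cell): fixed endmember, default +0.09 ‰ (crustal);
  default flux 3 × 10⁻¹² mol Fe m⁻² s⁻¹ (~95 µmol m⁻² yr⁻¹, a
  moderately dusty open-ocean setting).
* **Sediment** (bottom cell and any configured margin-adjacent cells):
  flux = F_max · F_sed(z) · %_sed (defaults F_max = 10⁻¹¹ mol m⁻² s⁻¹,
  %_sed = 1).  The endmember mixes a reductive (δ_RD = −1 ‰) and a
  non-reductive (δ_NRD = +0.09 ‰) component weighted by the local
  oxygenation proxy: F_sed(z) in the standard scheme, C_exp/(K+C_exp)
  with K = 60 nmol m⁻² s⁻¹ in the carbon-export scheme, or a uniform
  value.  The Fe *flux* stays depth-dependent in every scheme.
* **Hydrothermal** (cell containing the configured vent depth, default
  2300 m): Fe = 10⁷ × the ³He flux, with 0.5-fold ligand co-injection;
  fixed endmember (−0.5 ‰ standard).  Co-injected ligands carry no Fe.
* **River** (top cell): fixed at 0 ‰; off by default in open-ocean
  columns.  **Sea ice**: non-fractionating exchange at the local
  dissolved pool's delta; off by default.

F_sed(z) is piecewise: 1 for z ≤ 400 m, then
0.003 + 0.997·exp(−(z−400)/250 m), matching the anchors "1 on the shelf"
and "~0.003 at depth" and falling below 0.01 by 2000 m.  The e-folding
scale is a package choice (the metamodel behind the anchors does not
publish a closed form) and is exposed in the configuration.

### Host column

31 levels (bounds 0, 10, …, 5500 m), truncatable for shelf stations.
Time step 1 day on a 360-day calendar (twelve 30-day months).  Transport:
implicit upwind sinking for particles (w = 3 and 50 m d⁻¹; the seafloor
flux is booked as burial) and implicit vertical diffusion for dissolved
tracers (K_z = 10⁻³ m² s⁻¹ inside the seasonally varying mixed layer,
10⁻⁵ below).  Both schemes are unconditionally stable and conserve the
column inventory exactly up to linear-solver roundoff.

The ecosystem is prescribed forcing, not prognostic: biomass decays over
60 m vertically and follows a cosine seasonal cycle (amplitude 0.8,
bloom month 7); Fe demand is V_max·B·dFe/(K_m+dFe) with
V_max = 3 × 10⁻¹³ mol m⁻³ s⁻¹ and K_m = 0.2 nM.  Particle load for
scavenging is a static profile (1 at the surface decaying to 0.1).
Rate constants (k_scav = 10⁻⁵ s⁻¹ × load on Fe′, k_colloidal =
5 × 10⁻⁹ s⁻¹ on colloidal FeL, remineralization 0.05/0.02 d⁻¹,
phytoplankton loss 0.1 d⁻¹ split 60 % recycled / 40 % to particles)
were chosen once to give realistic dFe (0.1–0.7 nM), sub-annual surface
and multi-year deep residence times, and scavenging-over-pumping
dominance below the surface layer.  They are host-model plumbing, not
the package's contribution, and all are configurable.

The random seed controls only optional lognormal forcing noise; the core
model is fully deterministic (bit-identical repeat runs are tested).

### Spin-up and convergence

Desk-scale runs use 20–50 column-years instead of the centuries a global
model needs; convergence is asserted by metric, not duration.  The
stability metric is the largest decadal change of the annual-mean
δ⁵⁶Fe_diss profile; the standard 50-year run reaches 0.006 ‰/decade
(threshold 0.01).  Runs that miss the threshold are flagged, not fatal.

## Diagnostics

The net effect of remineralization versus abiotic removal (scavenging +
colloidal pumping) at each depth is the delta of the *differenced*
isotope fluxes; net-loss points carry the negated value, since that net
pool is being removed.  Points with |net bulk flux| below 5 nmol m⁻³
yr⁻¹ are excluded before any delta is computed (near-cancelling fluxes
give arbitrarily large deltas); a vanishing ⁵⁴Fe difference with
non-vanishing ⁵⁶Fe difference is likewise flagged.  Layer averages are
reported two ways: the mass-consistent pooled value (delta of summed
pairs, the default) and the plain mean of per-cell deltas, because
plotting conventions differ.

## Model-observation protocol

Observations (flat CSV, one row per sample) are binned onto a 1°×1°
horizontal grid and the model's vertical levels, averaging duplicates
per (cell, level, month); a section-display mode pairs the top 16 levels
(upper 197 m) two at a time.  Binning is idempotent.  Model values are
paired by level and sampling month and scored with OLS — by default the
model is regressed on the observations (the orientation is flippable) —
with dFe compared in log10 space.  Reported: n, mean and SD of both
sides, RMSE, Pearson R, slope, intercept.

The synthetic-observation generator samples stations and depths from a
model field and perturbs deltas with Gaussian noise (default 0.05 ‰, the
middle of the 0.04–0.07 ‰ analytical range; doubled above 100 m where
surface measurements are less certain) and dFe with lognormal noise.
What it emulates: sparse, noisy section sampling with month stamps.
What it does not: real horizontal water-mass structure (all stations
sample the same column), correlated errors, detection limits, or
sampling biased toward features.  Passing the recovery tests therefore
demonstrates the statistical pipeline is unbiased at realistic noise,
not that the column reproduces any real section.  Note one intrinsic
property of the default orientation: with noise σ on the observations,
the expected slope is var(field)/(var(field)+σ²), so an unattenuated
slope requires the field's spread to dominate the noise — the recovery
tests use multi-regime fields with SD ≈ 0.3–0.6 ‰ for this reason.

## Numerical choices and degenerate inputs

* Deltas are reported in ‰; a delta is undefined (raised as an error)
  for a pool with no ⁵⁴Fe, and endmembers ≤ −1000 ‰ are rejected.
* The speciation quadratic uses the cancellation-free root; total dFe is
  conserved to ≤1 ulp.
* Fractionation factors outside (0.9, 1.1) are rejected unless
  explicitly overridden (sensitivity-run escape hatch).
* A pool going negative after clipping is a hard error (time step too
  large), never silently zeroed — zeroing would break the budget.

## Known limitations

* 1-D: no lateral transport, subduction, or water-mass pathways; basin-
  scale gradients and global skill statistics are out of reach by
  design.
* The ligand reactivity continuum is reduced to one class with
  first-order dynamics; photochemistry and variable uptake α under Fe
  stress are not represented.
* Near-field vent and porewater chemistry (sulfide precipitation, Fe(II)
  oxidation) is integrated into effective source endmembers.
* The carbon-export sediment scheme in a single column uses one
  configured seafloor export value; the horizontal endmember variability
  that scheme exists to capture only appears across separately
  configured columns.
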