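# Methods

`amocrange` assesses how abrupt Atlantic meridional overturning circulation
(AMOC) weakening, superimposed on a high-warming trajectory, would contract
species ranges and deplete assemblage richness — and it ships the synthetic
test-bed that makes every stage of that assessment verifiable against a
known ground truth. This note documents the models, the parameters that
matter, the numerical conventions, and what the synthetic world does and
does not establish.

## The assessment pipeline

**Climate.** Inputs are monthly `tmin`/`tmax`/`tmean` (°C) and `prec`
(mm/month) cubes on a regular lon-lat grid: one observed baseline
climatology, one model baseline, and one model trajectory per scenario.
Future conditions at a horizon year are 30-year per-calendar-month means
(half-open window `[h-15, h+15)`), delta-bias-corrected against the
baseline period: `corrected = target − (model_baseline − obs_baseline)`,
per month per cell, additively for all variables, with precipitation
clamped at zero after shifting. The correction is exact by construction:
applied to the model baseline itself it returns the observed baseline to
machine precision (temperature; precipitation wherever the clamp is
inactive). The bias is computed per calendar month, not per index, so the
correction preserves seasonality. Corrected climatologies are reduced to
five bioclimatic indices: bio1 (annual mean temperature, °C), bio5 (max
temperature of the warmest month), bio6 (min temperature of the coldest
month), bio12 (annual precipitation, mm), bio15 (precipitation
seasonality, %). bio15 follows the ANUCLIM convention — coefficient of
variation of monthly precipitation after adding 1 mm to each month, sample
standard deviation (n−1), in percent. Grids can be up-scaled by block
means of unmasked cells (a fully masked block stays masked); analysis runs
at 0.33° with assemblage stacking at 1° (3×3 blocks).

**Species data.** A species enters modeling only if endemic to a single
biogeographic realm and occupying ≥ 50 grid cells; exclusions are logged
(`min_presence`, `not_endemic`, `outside_grid`) and the log plus the
retained set exactly partition the input. The species' realm is its
background area: pseudoabsences are drawn uniformly without replacement
from realm cells outside the range, three per presence, once per species
(the ten runs share one pseudoabsence set and differ only in the random
70/30 calibration/validation split, with `floor(0.7 n)` training cells
taken independently from presences and pseudoabsences so the 1:3 balance
carries into both sides).

**Learners.** Three suitability models per species × run, all consuming
the five bioclim variables standardized with training-split statistics:

- *MAXENT* — l1-penalized logistic regression (C = 1) over a MaxEnt-style
  feature expansion: linear, quadratic, pairwise products, and per-variable
  hinge features with knots at the training deciles. For a Gaussian niche,
  log-suitability is quadratic in the environment, so this family contains
  the truth of the synthetic world.
- *BRT* — gradient-boosted classification trees, shrinkage 0.01, depth 3,
  subsample 0.8, up to 400 trees with early stopping (patience 15 on a 20%
  internal validation split).
- *CART* — one classification tree, minimum leaf 5, cost-complexity
  pruning with the α chosen by 3-fold cross-validated AUC over (at most 8
  points of) the pruning path.

The registry is extensible; unknown names are rejected. Validation per run
uses rank-based (Mann–Whitney) AUC — fraction of presence/background score
pairs ranked correctly, ties counting ½ — plus sensitivity, specificity,
TSS, Cohen's kappa and omission at the same threshold criterion used
downstream (the evaluation threshold is otherwise under-determined).
Species × algorithm combinations with mean cross-run TSS ≤ 0.4 are
excluded and logged; exclusion uses the cross-run mean because per-run
skill fluctuates on 30%-holdouts of small ranges.

**Binarization.** Thresholds are computed from the run-averaged
suitability per species × algorithm (one binary map per algorithm and
climate, rather than ten), using the species' presences and
pseudoabsences as the labeled training scores. Criteria: MTP (minimum
training presence), P10TP (nearest-rank 10th percentile of training
presence scores — the reported criterion), ESS (|sensitivity −
specificity| minimized), MSS (sensitivity + specificity maximized,
equivalently maximal TSS). Presence is inclusive at the threshold
(suitability ≥ t), which makes MTP training omission exactly zero and
bounds P10TP training omission by 10% + 1/n. ESS/MSS scan every unique
observed score and break ties toward the lower threshold. Cells outside
the realm background are absent regardless of suitability.

**Impacts.** For each species × algorithm × scenario × horizon the range
change is `q = (p1 − p2)/p1` with p1 the current and p2 the future
predicted presence count; under no dispersal the future range is first
intersected with the current one (so q ≥ 0), under full dispersal the
species may claim any realm cell (q can be negative). An empty current
range is an error, flagged per species, never silently q = 1. Per-species
q is averaged arithmetically across retained algorithms (`ENSEMBLE`);
group summaries report the median with a seeded percentile-bootstrap 95%
CI (1000 resamples by default), restricted to contracting species
(q > 0) after ensembling, within each scenario × horizon × dispersal cell.
The bootstrap was chosen because the CI estimator for a median of a
strongly skewed q distribution has no convenient closed form; the
contracting-only filter is applied after ensembling so that "species
contracting their ranges" refers to the ensemble estimate.

**Assemblages.** Binary maps are aggregated 0.33° → 1° by the any-subcell
rule (a species occupying any part of a coarse cell is present there) and
summed into richness; the diversity deficit per cell is
`100·(S_now − S_future)/S_now`, masked (NaN) where current richness is
zero, bounded above by 100, and within [0, 100] under no dispersal
because subset stacking makes future richness cellwise ≤ current.
Per-algorithm deficit maps are averaged cellwise over unmasked values; a
cell stays masked only where all algorithms mask it.

## The synthetic world

The generator emulates the *structure* of the real study inputs, not
their geography. Smooth latitudinal temperature and precipitation
gradients with latitude/longitude-dependent seasonality give the five
bioclim indices real spatial variation; realms are contiguous
longitudinal blocks (named with the six canonical realm names when six
are requested). The observed baseline is stationary in expectation; the
model baseline adds a fixed smooth bias field (~1 °C, ~±10 mm/month) so
the delta correction has something to remove; scenario cubes add a
warming trend from the baseline end plus, for hosing scenarios, a
regional anomaly that ramps linearly over the 2020–2070 forcing window
and persists afterwards, reflecting the century-scale non-recovery of a
weakened AMOC. Temperature noise is additive Gaussian (sd 0.4 °C);
precipitation noise is multiplicative log-normal (log-sd 0.08, mean 1),
keeping precipitation non-negative; the tmin ≤ tmean ≤ tmax ordering
holds pointwise by construction.

Scenario amplitudes are free parameters of the test-bed (nothing at this
scale can be calibrated to a coupled ocean–atmosphere model): warming
0.4 °C/decade; hosing cooling 1.0 °C per Sv and drying −0.9 fraction per
Sv at full ramp, both confined to the configured hosing realm. The split
matters: the drying is the ecologically dominant stressor, and the
cooling is deliberately small relative to the accumulated warming so
that a hosing scenario always adds net climate stress over the control
instead of partially cancelling it — with a large cooling amplitude the
weakest forcing (0.11 Sv) can pull the hosing-realm climate *back toward*
the species' baseline niches and invert the scenario ordering the design
is meant to exhibit. Directionality comparisons are made at the 2070
horizon, where the forcing window is fully realized; at 2030 the ramp is
~20% and anomalies are within climatological noise.

Virtual species have Gaussian niches over the five bioclim variables:
`s(x) = exp(−Σ_v (x_v − μ_v)²/(2σ_v²))`, with the optimum anchored at a
random realm cell's climate (jittered by 0.15 realm-sd), breadths drawn
as 0.6–1.2 × the realm-wide sd of each variable, and a suitability
cutoff s* in 0.2–0.5. The realized range is the *deterministic* set of
realm cells with s ≥ s* — not a Bernoulli draw — so the true range change
under any future climate is an exact, enumerable oracle. Candidates whose
range falls below 50 cells or above 20% of the realm are redrawn (the cap
guarantees the background can supply three pseudoabsences per presence);
generation fails loudly, naming the realm, if the retry budget (200) is
exhausted. IUCN-like status labels are drawn with fixed plausible weights
and are bookkeeping only — they do not influence the niche.

**What passing tests show, and what they do not.** Parameter recovery on
this world demonstrates that the pipeline's estimate chain — sampling,
learning, thresholding, ensembling, Eq.-1 arithmetic — recovers a known
truth under a correctly specified niche with equilibrium occupancy and
noise-free detection. Real range maps violate most of this: occupancy is
not at climatic equilibrium, detection and mapping error are structured,
niches are not Gaussian nor five-dimensional, and dispersal is neither
zero nor unlimited. The synthetic results validate the machinery, not the
ecological realism of any particular projection.

## Problem sizes

The study configuration used by the analysis drivers, the acceptance
checks and the worked example is a 42×81 grid (divisible by the 3×3
aggregation blocks), two realms, 36 species, the control plus all four
hosing scenarios, horizons 2030 and 2070, ten runs, and 200–1000
bootstrap resamples. These sizes keep a full run in single-digit minutes
on one core while leaving ≥ 18 species per realm for medians.
Reproducibility is by a single master seed: every stochastic stage
derives its own 31-bit seed by hashing the master seed with the stage
name and species id, so adding a species or reordering stages never
perturbs unrelated draws, and a rerun with the same config reproduces
every CSV byte for byte.

## Known limitations

- The MaxEnt-style learner is a penalized logistic approximation on
  expanded features, not the reference Java implementation; BRT/CART
  cannot extrapolate beyond the training hull, which biases projected
  losses downward under strong climate displacement (visible in the
  scenario-D/2070 recovery error).
- Pseudoabsences are drawn once and shared across runs; resampling per
  run would propagate background-choice uncertainty into the CIs.
- Thresholds derive from run-averaged suitability; per-run binarization
  would yield a distribution of binary maps instead of one.
- Realms are abstract blocks; no coastlines, elevation, or spatial
  autocorrelation structure beyond the smooth gradients.
- The assemblage stage stacks potential (not occupancy-corrected)
  presences, the standard caveat of stacked SDM richness.
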