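# Methods

## Model structure and assumptions

The kinetic model describes a cell's mitochondrial population as four
well-mixed classes — healthy unfused (HU), deviant unfused (DU; the
mutation-prone derivatives), healthy fused (HF) and deviant fused (DF) —
exchanging by fusion and fission, plus a single ATP pool.  Its assumptions:

* Fusion and fission are one-to-one class conversions (HU↔HF, DU↔DF);
  healthy and deviant mitochondria share the same fusion/fission kinetics,
  which scale with the measured OPA1 and DRP1 levels: F = F₀·[OPA1],
  K = K₀·[DRP1].
* Both conversions consume ATP, so their fluxes are proportional to [ATP];
  under nutritional stress s fusion is amplified by e^s and fission damped
  by e^(−s) (starving cells fuse to escape mitophagy), so the serum-fed
  condition is the s = 0 limit in which both factors are exactly 1.
* Only unfused mitochondria are cleared by mitophagy (rates M_H, M_D);
  fused networks are protected.  Biogenesis B is uniform across classes
  and, in the default *balance* mode, is recomputed at every instant so
  that B·(total) equals the instantaneous mitophagy flux M_H·N_HU +
  M_D·N_DU.  The balance relation is stated as an identity, not an initial
  condition, so recomputing B pointwise is the only way to satisfy it along
  the whole trajectory; it makes the total mitochondrial number an exact
  invariant (the constant-B alternative is provided and can grow without
  bound, which is why the integrator carries a blow-up cap).
* Every mitochondrion produces ATP at a rate proportional to the
  ultrastructural factor θ = (c_n + e^{m_p})/(c_w + c_jw): ATP output rises
  with cristae density and membrane potential and falls with cristae and
  crista-junction width (thin cristae and tight junctions concentrate
  protons where ATP synthase sits).  Healthy mitochondria out-produce
  deviant ones by α ≥ 1 and fused out-produce unfused by ε ≥ 1.  A constant
  cellular demand μ drains the pool.

Initial conditions are one mitochondrion per class and zero ATP.  Units are
model units throughout: the ultrastructure parameters are normalized to
[0, 1]-scale measurements and time is unitless, so ATP levels are
meaningful only relative to each other (no thermodynamic calibration is
attempted).

## Parameters

Per-scenario measured inputs (packaged preset table; five cell lines × two
conditions): c_w, c_n, c_jw, m_p, OPA1, DRP1.  The SS row of OVCAR3 lacks
one printed value; inspecting the condition-wise trends of every other cell
line (c_w falls, c_n rises, c_jw falls, OPA1 rises, DRP1 falls under SS)
leaves the membrane potential as the only column the five printed values
cannot fill while preserving those trends, so the packaged table marks
`m_p` missing for that row.  The loader refuses to build the scenario
unless the explicit fill rule `fill_missing="plus_serum"` (reuse the +S
value, 0.99) is enabled — a missing measurement is never invented silently.

Free constants (defaults; all configurable per scenario):

| constant | default | why |
|---|---|---|
| F₀, K₀ | 1.0 | base conversion rates; OPA1/DRP1 carry the scenario dependence |
| M_H, M_D | 0.1, 0.5 | deviant (mutation-prone) mitochondria are cleared faster by quality control |
| α, ε | 2.0 | smallest simple factors strictly above 1 for "healthy more efficient" and "fused more efficient" |
| μ | 3.0 | reference cellular ATP demand |
| stress s | 0 (+S), 2.5 (SS) | see below |

**Choice of the SS stress level.** The unfused/fused flux balance gives a
quasi-steady unfused:fused ratio of (K/F)·e^(−2s) per class, independent of
the ATP level.  The depletion of unfused mitochondria under starvation —
the regime the model is built to describe — therefore requires s large
enough that this ratio is small for *every* phenotype; the worst case
(OVCAR3-SS, DRP1/OPA1 = 3.33) needs s > 2.07 before the unfused fraction
falls below 5%.  The default s = 2.5 places all ten presets in that regime
(maximum terminal unfused fraction ≈ 2.2%) while keeping the system
non-stiff over the default horizon.  The qualitative panel readouts
(ATP higher under SS in all five lines, fused counts ranking highest in the
mesenchymal and lowest in the epithelial line under serum) hold at these
defaults, and the sweep module quantifies their robustness across the free
constants.

## Numerics

* Default integrator: scipy's adaptive RK45 with rtol 1e-9 / atol 1e-12,
  dense equispaced output (501 samples over t ∈ [0, 10]).  Fixed-step
  classical RK4 and forward Euler are provided as cross-checks; the test
  suite compares the adaptive solution against an *independently written*
  Euler reference (plain-float reimplementation of the equations) at
  dt = 1e-5 on all presets over t ∈ [0, 5].
* Population counts and ATP are physical nonnegative quantities; marginal
  negative excursions are integration artifacts at these tolerances and are
  clipped to zero in the stored trajectory with a logged warning (policies
  `clip_warn`/`floor_zero_warn`; `error`/`allow` available).  Clipping is a
  presentation step — the dynamics themselves are integrated unmodified, so
  solver cross-checks remain exact.
* Any state component beyond 1e12 raises a divergence error carrying the
  last valid time (reachable in constant-biogenesis mode, whose linear
  birth terms permit unbounded growth).
* Time queries on trajectories use the nearest stored sample, never
  extrapolation; ranking ties are broken lexicographically by cell-line
  identifier.
* Degenerate inputs: θ with c_w + c_jw = 0 raises a named error; the
  balance-mode biogenesis of an empty system is defined as 0; an empty time
  span returns the initial state.

## Enrichment filter

QC requires ≥ 2 peptides, ≥ 10% sequence coverage and detection in ≥ 2 of
3 replicates of at least one condition.  Exclusivity (≥ 2/3 detections in
one condition, 0/3 in the other) is decided before any ratio.  Otherwise
the fold change is the ratio of raw replicate means (a log-ratio option
exists) and significance is a two-sided Welch t-test on log2 intensities at
α = 0.05 with no multiple-testing correction — the simplest defensible test
for triplicate LFQ data; the threshold rules (FC > 2 up, FC < 0.5 down) are
unambiguous while the choice of test is a documented package decision, and
all three knobs are configurable.  A fold change that crosses a threshold
but cannot be tested (fewer than two valid replicates on a side) is
reported `not_evaluable` rather than called.  Intensities of exactly 0 are
treated as missing detections (the convention of standard LFQ output),
configurable at ingest.  "Enriched" proteins are the union of SS-exclusive
and SS-upregulated calls.

## Bioassay scores

* Relative mtDNA content: 2·2^ΔCt with ΔCt = nuclear Ct − mitochondrial Ct,
  triplicate reactions aggregated by mean Ct before ΔCt (per-replicate use
  is possible by constructing pairs directly).  The identity
  content(ΔCt)·content(−ΔCt) = 4 is a test invariant.
* Tumor volume: 0.5·length·width² (mm³), homogeneous of degree 3.
* Tumor inhibitory score: (%PKHhi+%PKHlow)/volume of the vehicle control
  minus the same quantity for the treated group.  The formula gives 0 for a
  test identical to control; a separately labelled *control-anchored*
  display mode adds 1 so the control sits at 1 (a figure-caption
  convention), without altering the underlying formula.  The raw score is
  antisymmetric under swapping control and test.

## Synthetic data

The generators emulate the *structure* of the study's inputs, not their
full messiness:

* LFQ: per-protein base intensity log2-normal (mean 23, sd 1.5 — typical
  LFQ magnitudes), replicate noise 0.1 log2 units, planted effects at FC 4
  and 0.25 (well clear of the 2×/0.5× thresholds so exact recovery is the
  correct outcome), exclusives all-missing in the opposite condition, and a
  configurable fraction of background records failing QC by construction.
  Real LFQ data add heavy missingness, correlated batch effects and
  moderated-statistics concerns that these tables deliberately do not
  model — passing recovery tests shows the filter implements its rules
  exactly, not that the rules are optimal for noisy deposits.
* qPCR: replicate Ct values Gaussian around a true pair (sd 0.1 cycles),
  default true ΔCt = 2.
* Xenografts: group-wise Gaussian draws (n = 4/group) truncated to valid
  ranges; the planted regimen means give the antibiotic+chemotherapy
  combination the lowest label-retaining burden per volume, hence the top
  inhibitory score.
* Preset perturbation: mean-preserving multiplicative log-normal noise of
  chosen CV on the measured fields, for robustness probes of the panel's
  qualitative claims.

One integer seed drives independent substreams per generator, so outputs
are bit-reproducible stage by stage.

## Problem sizes

Default test and acceptance runs use the ten packaged scenarios over
t ∈ [0, 10] (oracle comparisons over [0, 5]), a 200-protein LFQ table,
20-sample qPCR batches and 4-per-group cohorts — sizes at which every
check completes in seconds while exercising each code path.

## Known limitations

* The model is deterministic and well-mixed: no spatial network structure,
  no stochastic birth–death effects at small counts, no mtDNA heteroplasmy
  genetics.
* ATP units are relative; contrasts and ratios between conditions are the
  meaningful outputs, not absolute levels.
* The free constants are not fitted to data (the underlying study's figure
  curves are not available as numbers); phenotype-ordering claims are
  therefore reported as diagnostics conditional on the documented defaults,
  with the sweep module mapping where in constant-space they hold.
* The enrichment filter implements plain Welch testing; moderated
  (empirical-Bayes) statistics used by some proteomics platforms may call
  borderline proteins differently.
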