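# Methods

This note documents the models and procedures implemented in
`evoprofiler`, the defaults they use, and the design decisions taken where
the methodology left genuine choices open.

## Study design being modeled

A knockout lineage consists of a pre-evolved reference strain (Ref), an
unevolved knockout (uKO), and one or more evolved knockout endpoints
(eKO), each measured in replicate for metabolite concentrations
(arbitrary concentration units), transcript levels (arbitrary abundance
units), and reaction fluxes (mmol·gDCW⁻¹·h⁻¹-like units), alongside
per-sample growth rates (h⁻¹).  All analyses operate on the ordered
(Ref, uKO, eKO) triple of per-strain replicate means — a deliberately
unitless, change-based representation that lets heterogeneous datatypes
be compared on one footing.

## Profile classification

The twelve signed templates are fixed integer encodings of the triple
(see `profiles.TEMPLATES`).  A component is assigned the template with the
maximal Pearson correlation *iff* that correlation strictly exceeds the
threshold (default 0.88).  Relevant geometry: the largest correlation
between two *distinct* templates is √3/2 ≈ 0.8660, so the 0.88 cone
around each template is exclusive — but a noisy triple can still exceed
0.88 for two templates simultaneously (the inter-template angle is 30°
while the cutoff cone half-angle is ≈28.4°), so ties within 10⁻¹² of the
maximum are conservatively reported unassigned with a `tie` annotation.
Zero-variance triples are unassigned (`degenerate`).  Opposite-direction
templates are exactly anticorrelated (r = −1), which gives the
sign-antisymmetry property: negating a triple maps T⁺ ↔ T⁻.

Replicate handling: per-strain arithmetic means enter the 3-point
correlation (the alternative of repeating encoding values per replicate is
available through `classify_component` on user-built triples).  Each eKO
endpoint is classified independently.  By default only components passing
the differential screen are classified (`not_tested` otherwise);
`classify_all` overrides.

## Differential screens

* **Metabolites**: two-sample t-test on glog-transformed values
  (glog(y) = log((y + √(y² + λ))/2), λ = 1.0 by default — the transform
  parameter is not identifiable from our synthetic data and is exposed in
  config), Bonferroni-adjusted p < 0.01, |log2 FC| > 1.  The widely
  printed fold-change band "0.5 < FC < 2.0" selects the *unchanged* band
  if read literally; the default implements its evident intent
  (|log2 FC| > 1), and `literal_fc_band=True` restores the literal
  reading.
* **Transcripts**: t-test on log2 levels, Benjamini–Hochberg p < 0.05,
  |log2 FC| > 1.  (A dedicated RNA-seq differential tool would normally
  stand here; the t-test keeps the artifact self-contained and is
  adequate for the synthetic abundance scale.)
* **Fluxes**: permutation test on the absolute difference of group means —
  exact enumeration of all label splits when there are ≤ 2000 of them,
  otherwise 2000 seeded Monte-Carlo permutations with the identity
  included (p = (1+#extreme)/(1+B)) — gated at p < 0.01 together with
  |geometric fold-change| > 0.001, where the geometric fold-change is the
  log10 ratio of geometric means of absolute fluxes with an additive
  ε = 10⁻⁹ guarding zeros.  Demand/exchange, nucleotide-salvage, and
  oxidative-phosphorylation subsystems are excluded from flux calls by
  default.
* **Mutations**: frequency > 0.1 pass-through.

Zero-variance groups get deterministic p-values (1.0 for equal means,
10⁻³⁰⁰ otherwise).  Multiple-testing adjustments are delegated to
statsmodels and property-tested against the textbook definitions.

A sizing note: an exact two-sided permutation test at 3-vs-3 has a p-value
floor of 2/20 = 0.1, so the 0.01 flux gate is unattainable at triplicate
scale.  The pipeline therefore defaults to n = 6 samples per strain —
triplicate cultures measured in analytical duplicate, the usual n for this
kind of metabolomics/fluxomics design — where the floor is 2/924 ≈ 0.0022.

## Sample-trend analysis

Matrices are univariate-scaled (unit column variance) and centered;
zero-variance features are dropped and recorded.  PCA is a plain SVD with
a deterministic sign convention (largest-|loading| entry positive).
PLS-DA is NIPALS PLS2 against one-hot class indicators
(scikit-learn `PLSRegression` on the pre-scaled matrix); the canonical
powered PLS variant used in some R workflows is deliberately not
reimplemented — the trend criterion depends only on axis-1 geometry, which
standard PLS2 reproduces.  Q² is estimated by cross-validation
(leave-one-out for n ≤ 10, else seeded 10-fold); folds that lose a class,
or degenerate fits (zero X–Y covariance), fall back to predicting the
training-class mean, which yields Q² ≤ 0 for uninformative data.

The trend rule: relative distance = |t₁(uKO) − t₁(eKO)| / |t₁(Ref) −
t₁(uKO)| on axis-1 group centroids (arithmetic means of replicate scores),
matched when > 0.70.  Absolute distances are used, so an endpoint that
overshoots past the reference still counts as matching.  Axis 1 is
oriented so the Ref centroid lies below the uKO centroid, removing sign
ambiguity; the result is invariant to global score negation.

Loading-based feature selection takes features whose |axis-1 loading| is
within the top quartile (ties at the boundary all included) *and* whose
profile correlation exceeds 0.88.

## Flux graphs and path-change calls

Each strain's flux state (means with 95% CI bounds) induces a directed
bipartite graph: substrate → reaction → product edges, weight 1/|mean
flux|, orientation following the flux sign for reversible reactions,
zero-flux reactions omitted (equivalent to infinite weight for shortest
paths, with simpler invariants).  Carbon-free species and currency
metabolites are excluded or the shortest paths would tunnel through the
ATP/NADH pools; in the toy model the currency list is exactly the
`carrier` category, and it is user-extensible (plus an alias map for
model-specific metabolite substitutions).

Shortest paths use an A* search with a null heuristic (uniform-cost /
Dijkstra), and the metabolite distance is (#edges)/2 − 1 — the number of
intervening metabolites.  This edge-count reading is forced by parity:
bipartite metabolite-to-metabolite paths always have an even edge count,
so the distance is always an integer, whereas a node-count reading yields
non-integers.  Self-pairs report 0 with a flag rather than the formula's
−1; unreachable pairs are a no-path result, not an exception.

Change calls compare reaction-id sequences exactly (set comparison and
weighted-length comparison are available as options): a change (different
sequence or different distance) between uKO and eKO ⇒ *changed flux
distribution*; a change between Ref and uKO that eKO retains ⇒ *changed
flux capacity*; otherwise *unaffected*.

## Regulatory consistency and activation

Interactions are signed Boolean edges; for metabolism, reactant→reaction
edges are encoded positive and product→reaction negative.  The decision
variable for an edge is the Pearson correlation between the two
components' mean triples (the same 3-point statistic as profile matching);
agreement requires r > 0.88 with positive mode or r < −0.88 with negative
mode, the inverse pattern is disagreement, |r| ≤ 0.88 indeterminate.
Since TF *activity* is not a measured component, the pipeline scores
composite effector→gene relations whose mode is the product of the
metabolite→TF and TF→gene modes; genuinely dual-mode regulators are
represented by two opposite-mode edges and surface as persistent
disagreements rather than being suppressed.

Unmeasured nodes receive consensus categories: each measured neighbor
votes its signed profile (flipped through a negative edge) with weight
|r|/(nEPs·nRegulators); the consensus is the top-weight category, exact
ties give no consensus.  Regulator activation uses the same kernel summed
over endpoints and regulated entities; the confidence score is bounded by
the number of regulated entities (per-entity endpoint weights sum to
≤ 1).  The analysis runs first on entities with a single annotated
regulator — the unconfounded case — before expanding to all entities, and
a diagnostic table comparing TF expression profiles with TF consensus
activation is emitted by the analysis driver.

## Enrichment and biomass correlation

Set enrichment is the exact upper-tail hypergeometric probability
P[X ≥ k] at the raw p < 10⁻³ gate — enrichment only, no depletion, no
multiplicity adjustment by default (a BH option exists).  The universe
defaults to all *measured* components of the datatype; annotated sets are
intersected with it.  Biomass correlation restricts to biomass-pathway
components (optionally further to the growth-associated profiles
restored−, novel+, overcompensation−, partially restored−, reinforced+,
whose shapes track a growth dip and recovery) and counts components whose
triple correlates with the growth triple beyond ±0.88.

## Synthetic data: what it emulates and what it does not

`generate_lineage_dataset` plants each component as an affine transform
a·(encoding/range) + b of its template (a ~ U(2, 6), b ~ U(0.5, 1.5)) with
Gaussian noise of the configured sd added on the unit-range template scale
before the affine map — so the stated sd means the same signal-to-noise
for every component, and since Pearson matching is affine-invariant the
classifier, not the scale, is what gets tested.  The amplitude/baseline
ranges give planted components ≥ 2.3-fold strain changes (clearing the
2-fold screens), and half of all components are planted flat ("none"),
which puts per-comparison significant fractions near the ~25–30% seen in
real knockout lineages.  A log-normal multiplicative noise mode exists for
concentration-like data.  Growth rates dip at the knockout (0.90 → 0.35
h⁻¹) and recover (0.85 h⁻¹) with sd 0.005.  Components carry synthetic
set annotations with planted contrast (perturbed vs housekeeping sets at
90% bias) so enrichment has recoverable truth.

Flux states are hand-balanced steady states (S·v = 0 to < 10⁻⁹) for three
pathway usages of the probe pair g6p → pyruvate — EMP glycolysis, the ED
route, and a cyclic oxPPP/non-oxPPP route — combined into three scenarios
(baseline, reroute, capacity shift).  Randomness enters only as a global
per-strain scale factor (U(0.9, 1.1)), because per-reaction jitter would
violate mass balance.  CI bounds are ±10% of the mean.

The mode-1 trend condition is encoded once as `MODE1_TEMPLATE_MIX`
(restored 0.70, partially restored 0.20, overcompensation 0.10 — all
reverting shapes); it defines "lineages where the eKO means revert toward
the reference", the regime in which the 0.70 rule is expected to fire.

What the generator does *not* emulate: realistic covariance between
components (components are independent given their templates), between
datatypes (no GPR coupling between transcripts and fluxes), missingness
patterns, batch effects, or mutation spectra.  Passing tests therefore
demonstrate that the statistical machinery recovers planted structure at
realistic effect and noise scales — not that it is robust to every
pathology of real LC–MS/RNA-seq/MFA data.

## Problem sizes and numerics

Default synthetic scale: 3 lineages × (60 metabolites + 120 transcripts +
40 fluxes) × 30 samples, 3 eKO endpoints, which keeps a full pipeline run
in seconds and the complete test suite under a minute on one CPU.
Sub-seeds are drawn below 2³¹ from a master seed; every generator refuses
to run unseeded.  Tolerances: template tie tolerance 10⁻¹², mass-balance
residual 10⁻⁹, score orthogonality 10⁻⁸, hypergeometric oracle agreement
10⁻¹².

## Known limitations

* The transcript screen is a t-test stand-in, not a count-model test.
* The permutation flux test needs ≥ 6 samples per group for the 0.01 gate
  to be reachable; smaller designs should use the 0.05 gate explicitly.
* Path-change calls depend on the currency-metabolite exclusion list;
  an under-excluded list produces shortcut routes through cofactor pools.
* Consensus voting weights all neighbor kinds equally; no edge-type
  priors are implemented.
* The toy model is a teaching-scale network; genome-scale models work
  through the same interfaces but shortest-path semantics there depend
  heavily on the exclusion/alias configuration.
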