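# Methods

This note documents the models, parameter choices, and numerical
conventions behind `otomap`, and what the synthetic-data experiments do
and do not demonstrate.

## Coordinate and angle conventions

All geometry is expressed in a right-handed anatomical frame in
micrometres: ml (positive = lateral), rc (positive = rostral), dv
(positive = dorsal). Input frames are declared as an axis permutation +
sign map with a uniform unit scale; this mapping is an isometry up to the
scale, so all distances and angles are frame-independent. Tuning angles
live in the horizontal (rc, ml) plane, measured counterclockwise from
rostral (0°) toward lateral (90°), in [0, 360). Circular statistics use
the resultant-vector definition throughout; a resultant of numerically
zero length (below 1e-12 of the total weight) is treated as undefined
tuning rather than an arbitrary direction.

## Hair-cell polarity and tuning propagation

The polarity vector runs from the centroid of the stereocilia base
positions (measured at the epithelial plane) to the kinocilium base. Only
its horizontal projection defines the tuning direction; the dorsoventral
component and pre-normalization magnitude are kept as QC quantities, since
on a near-horizontal macula the dv component should be small. Cells whose
horizontal projection vanishes are flagged degenerate and excluded from
tuning analyses rather than silently assigned a direction.

Afferent tuning is the ribbon-count-weighted resultant of the convergent
hair-cell unit vectors. This is an *anatomical* inference: it assumes
synaptic drive proportional to ribbon count and ignores synaptic weight
variation, process morphology, and hair-cell gain differences. Central
neurons average their afferents' unit vectors **unweighted** by default —
contact-count weighting is available as an explicit option
(`central_weighting="synapse_count"`) and the two modes are never mixed
within a fit. Where a population opposition angle is needed (e.g.
Mauthner vs commissural escape), it is computed between population
resultants; a mean of pairwise differences is trivially obtainable from
the per-neuron tables.

Tuning similarity between two cells is the cosine of their angle
difference, binned against the 3-D Euclidean distance between kinocilium
positions (hair cells) or soma centers (afferents). Distance bins default
to 10 µm width from 0 to the 99th percentile of pairwise distances, and
are configurable. Position correlations are Pearson r over connected
(hair cell, afferent) pairs on a chosen axis; the `ribbon_count` mode
replicates each pair by its contact count and uses the replicate count as
the effective n of the t-approximation p-value, which therefore
overstates significance when contacts within a pair are dependent — it
exists for comparability, with `per_pair` as the default.

## Maturity classification

Kinocilium length K and tallest-stereocilium length S partition cells
into immature (K < 5.0 µm AND S ≤ 4.8 µm), striolar (S > 4.8 µm AND
K/S ≤ 1.7), else extrastriolar. The three length criteria overlap for K
in (4.8, 5.0) µm; precedence is resolved by requiring *both* cilia short
for immaturity, so a K = 4.9, S = 5.2 µm cell is striolar. This makes the
rule total and deterministic. All four thresholds are configuration
parameters because the field's published length bands may have been drawn
around clusters rather than applied as hard cutoffs; the defaults
reproduce the published bands. The rule is scale-consistent: scaling both
lengths and both length thresholds by any c > 0 preserves the class.

## Line of polarity reversal (LPR)

Cells medial to the LPR point laterally (positive ml vector component)
and vice versa, so the provisional side label is the sign of the ml
component. The boundary is fitted deterministically and seedlessly:
rostrocaudal quantile bins (6 by default, shrunk for small samples), the
misassignment-minimizing ml split within each bin, then isotonic
(monotone) smoothing of the per-bin splits weighted by occupancy, and
linear interpolation between bin centers. Final side labels are
side-of-boundary; the count of provisional/final disagreements is
reported. Cells with purely rostrocaudal vectors get no provisional side
and are labeled by the boundary alone. If every provisional label falls
on one side the boundary is undefined; the single-side labeling is
returned with a warning. The monotone-boundary assumption matches the
generator's straight (or linearly tilted) LPR; a strongly S-shaped
boundary would need more bins and would violate the isotonic smoothing.

## Developmental composition

An afferent's input composition is the fraction of its ribbon contacts
(or, alternatively, of its distinct presynaptic hair cells) from each
maturity class; the two bases coincide exactly when all counts are 1.
Pathway composition weights each central contact by its afferent's
fractions, i.e. a contact-count-weighted mean, which is associative:
pooling populations equals contact-weighting their separate compositions.
The escape pathway pools ipsilateral-Mauthner and commissural-escape
contacts by default (both per-population and pooled outputs exist). The
myelinated input fraction counts contacts by default; a
distinct-afferent mode is provided. Group tests mirror standard practice
for non-normal count data: two-sided Wilcoxon–Mann–Whitney (exact
enumeration below 25 per tie-free group, normal approximation otherwise),
one-way ANOVA as the omnibus across classes with pairwise rank-sum
follow-ups (optional Bonferroni), and chi-squared for categorical splits.

## Synaptic clustering and null models

Arbors are regularized to a target internode spacing s (default 1 µm):
branch points, leaves, and the root are preserved exactly; each unbranched
path is re-divided into max(1, round(L/s)) equal arc-length steps, so
every edge is at most 1.5 s and cable length is preserved to well within
1% at realistic curvature (a pathological, maximally tortuous polyline
can lose more to chord-vs-arc shortening; EM skeletons regularized from
denser node sequences are far from this regime). Each synapse is
associated with the nearest node of the *resampled* skeleton. Geodesic
distances are computed on the weighted tree with Dijkstra (exact on a
tree). The clustering statistic is the unweighted across-neuron average
of per-neuron mean pairwise synapse distance, coincident synapses
included; neurons with fewer than two synapses are excluded with a
warning.

Null models redistribute each neuron's k observed synapses over its own
arbor nodes with probability proportional to a per-node score:

* **unweighted** — 1 everywhere;
* **radius50** — the number of afferent synapse nodes within 50 µm
  (Euclidean), minus 1 (clamped at 0) to discount the node's own apposed
  afferent;
* **kernel5** — Σ over afferent nodes of max(0, 1 − d/5 µm).

Sampling is **with replacement**, which keeps the per-node probability
law exactly proportional to the score and permits coincident synapses, as
occur in real data; a without-replacement mode (Gumbel top-k) exists
behind a flag. A neuron whose scores are all zero under a weighted model
falls back to uniform placement and is listed in the result's QC field —
excluding it would silently change n. Default iterations are 100,000;
the 95% CI is the 2.5–97.5 percentile band of the across-neuron average,
and the empirical p uses the (1 + hits)/(iterations + 1) estimator so it
is never exactly zero. The generator is keyed per (seed, neuron index),
making per-neuron draws independent of neuron order and the whole run
reproducible from one seed.

## Synthetic data: what it emulates

The generator produces the study conditions at their reconstructed scale:
91 hair cells on a 60 × 45 µm macula sheet, LPR at ml = 34 µm (≈75% of
cells medial), a polarity field rotating smoothly through 140° across the
rostrocaudal extent with reversal across the LPR, von Mises angular noise
with concentration κ = 20, a radial maturity gradient (≈25% striolar near
the striola center, ≈57% extrastriolar, ≈18% immature at the periphery),
per-class ciliary length distributions clipped clear of the
classification thresholds (striolar S ≈ 6.0 ± 0.4 µm with K/S ≈ 1.4;
extrastriolar S ≈ 3.4 ± 0.5 µm with K/S ≈ 2.4; immature K ≈ 3.4 ± 0.6
µm), and Poisson ribbon counts whose mean falls from 14 at the macula
center to 3 at the edge. Cilia are emitted as mostly-dorsal polylines
whose segment lengths sum exactly to the drawn length, so polyline
summation is exercised nontrivially; stereocilia bases are placed in
symmetric ± pairs so the centroid — and hence the planted angle — is
realized exactly.

The circuit draws 105 afferents, each sampling ~3.0 ± 1.5 hair cells from
a Gaussian spatial neighborhood (10 µm scale) strictly on one side of the
LPR; per-edge ribbon counts are ≥ 1 and sum to each cell's ribbon total.
Ganglion somata inherit the mean rostrocaudal position of their inputs
plus 4 µm Gaussian jitter; myelination probability rises with striolar
input fraction (calibrated so ~15% of afferents are myelinated), and
myelinated somata sit 6 µm more laterally (jitter 2.5 µm). Central
populations (1 Mauthner, 4 commissural escape, 12 SVN, 11 tangential, 19
vestibulospinal) draw per-contact events from exponentially tilted
afferent weights solved so the expected contact-weighted striolar input
fraction equals the planted target (0.65 for escape pathways, 0.30
otherwise); the exact expectation under the realized weights is recorded
in the ground truth, so recovery can be scored against it rather than
against the nominal target. Mauthner inputs are restricted to
medial-side afferents and commissural-escape inputs to lateral-side
afferents, producing the near-180° tuning opposition between the two
escape routes.

Test arbors are random branched trees (2 µm growth steps, 12% branch
probability per step, ~300 µm cable) spaced 500 µm apart so proximity
scores never mix neurons. Uniform synapse placement draws nodes of the
1 µm-regularized arbor uniformly — the same law as the unweighted null,
which is what makes the p-value calibration experiment exact. Clustered
placement scatters synapses with 3-D Gaussian spread (total scale 3 µm)
around randomly chosen afferent-apposition points.

What the synthetic data does **not** emulate: hair-bundle mechanics and
physiological gain, true birth dates (only the proxies), curved or
interrupted maculae, reconstruction errors (split/merged skeletons,
missed synapses), correlated annotation noise, and volumetric dendrite
geometry. Passing tests therefore demonstrate correctness of the
*computations* under the stated generative assumptions, not robustness of
the biological conclusions to reconstruction artifacts.

## Problem sizes and determinism

Default analyses run at the reconstructed-circuit scale in well under a
minute. The test suite runs the Monte Carlo machinery at reduced scale —
2,000 iterations, 5–20 arbors of ~300 nodes, 200 calibration replicates —
which keeps the full suite under a minute of Monte Carlo time while
leaving the estimator defaults at 100,000 iterations. Every stochastic
component takes an explicit integer seed; identical configuration + seed
reproduces outputs bit-for-bit, and the pipeline report records a hash of
the analysis configuration (excluding output paths), the seed, and the
package version.

## Known limitations

* The LPR fit assumes a monotone boundary in (rc, ml).
* Ribbon-replicated correlation p-values assume independent replicates.
* The clustering statistic weights every neuron equally regardless of its
  synapse count; a count-weighted variant would change the null and is
  not provided.
* The JSON skeleton dialect mirrors a CATMAID-style export but real
  exports vary; the ingest layer may need a thin adapter for a given
  server's field names.
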