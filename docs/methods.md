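# Methods

This note records the models, conventions and numerical choices behind
each stage of the pipeline, what the synthetic generators do and do not
emulate, and the known limitations.

## Connectivity model and thresholding

Connectivity is a directed multigraph collapsed to weighted edges: one
edge per (presynaptic, postsynaptic) neuron pair carrying the summed
synapse count. Identifiers are opaque strings (connectome body ids
overflow 32-bit and sometimes 53-bit integer handling); laterality and
cell class live on the neuron annotation, never in the id. Orphan and
undetermined fragments are representable so that raw totals can include
them, but they are excluded from class demographics.

**Partner-inclusion threshold.** A partner is significant when its
summed per-pair weight reaches the threshold (inclusive). The threshold
applies to the aggregate pair weight, not per synapse site, consistent
with connection-count summaries of EM reconstructions.

**Cross-volume rescaling.** Reconstruction completeness differs between
EM volumes, so a threshold calibrated in a reference volume is rescaled
by the ratio of total connection counts onto the same focal cells:
`round(base × Σtarget/Σref)`, rounded half away from zero and floored at
1. Rounding convention is immaterial for the packaged reference counts
(9.83 → 10, 3.27 → 3) but is fixed for determinism. For the downstream
direction the reference total includes undetermined bodies as well as
valid neurons, because downstream reconstruction in the target volume
was itself pre-filtered on an initial synapse count; which total is used
is an explicit argument, never inferred. The packaged summary table
separates orphans from undetermined bodies; the downstream reference sum
uses valid + undetermined only, with the orphan column available to
callers who want the wider total.

**DN-type summary.** Type-to-type connectivity sums the weights from all
DNs of one type onto all focal cells of one group; a type is reported
individually when its fraction of the group's total DN input is ≥ 5 %
for *any* group (inclusive boundary), and all remaining types pool into
`DN_sum`, so reported fractions sum to 1 per group. The inclusive
reading of the 5 % rule is a deliberate choice where both readings are
defensible.

**Shared-input partition.** Each above-threshold partner is assigned the
exact subset of focal neurons it contacts; subsets (signatures)
partition the partner set, and per-signature neuron counts and summed
synapse counts feed graph plots. The partition is purely combinatorial —
no statistical test is attached, mirroring the descriptive use of these
graphs.

## Effective connection strength

Weights are collapsed by group (cell type, or anatomical subclass for
sensory neurons) *first*, then converted to input fractions — each
column of the group matrix divided by its own sum, so F(g→h) is the
fraction of group h's entire collapsed input contributed by group g. The
denominator includes every group in the connectome, including groups
outside the analysis subset and within-group (recurrent) connections;
recurrent entries are counted in denominators but never as intermediary
steps.

Effective strength at path length 2 is E(s,t) = Σₘ F(s→m)·F(m→t) over
intermediaries m excluding (a) descending and sensory classes — their
drive originates outside the network under study (descending neurons are
driven in the brain, sensory neurons peripherally) — and (b) the source
and target groups themselves. Ascending sensory neurons are treated as
sensory for this exclusion. Because each factor is an input fraction,
E ∈ [0, 1] and is monotone in any single fraction on an allowed path.
The implementation is a submatrix product `F[S, M] @ F[M, T]`; tests
verify exact agreement (≤ 1e-12) with explicit path enumeration up to
50 groups.

**ROI polarity profiles.** Left/right neuropil counts are merged by base
name (trailing `_L`/`_R` or ` (L)`/` (R)`, configurable regex), each
neuron's presynaptic and postsynaptic count vectors are normalized to
sum 1 independently, and profiles are averaged per type. Motor-neuron
presynaptic counts can be forced to zero before normalization (default
on): presynaptic annotations on motor neurons in EM volumes are
unreliable detections. Neurons with no sites at all are excluded rather
than producing NaN rows.

## Morphology matching

Skeletons are SWC trees validated for a single root and acyclic parent
pointers. Coordinates are stored as read with an explicit units flag;
`rescale_to_microns` is the only conversion and is idempotent on μm
input.

**Pruning** removes terminal twigs (leaf back to the nearest branch
point) whose cable length is < 10 μm, iterating to a fixed point:
removing a twig can expose a newly sub-threshold twig, and a fixed point
makes the operation idempotent — the property the tests rely on. A
single-pass variant would leave such exposed twigs; the fixed-point
reading was chosen as the more faithful "reduce spurious short
projections" behaviour. An unbranched skeleton has no twigs and is never
pruned; if pruning would delete everything, the longest root-to-leaf
path is returned with a warning.

**Dotprops.** Each node contributes one point; its tangent is the
dominant principal direction of its k = 5 nearest nodes (SVD of the
centred neighbourhood). Tangent signs are canonicalized (first nonzero
component positive) purely for determinism — scoring uses |dot|, so the
sign never affects a score. Resampling to uniform spacing before
conversion is available but off by default.

**Scoring.** The raw score of query Q against target T is
Σ_{p∈Q} S(d(p, nn_T(p)), |t_p · t_{nn_T(p)}|) with S a binned log-odds
table (distance bins open-ended above, |dot| bins on [0,1]). The
nearest-neighbour search uses a k-d tree and is exact — tests pin it to
the O(N·M) brute-force computation. Trained fly-neuron score tables are
*not* reproduced here; they are a separately published trained artifact
and load from CSV (`read_scoring_matrix`). The packaged default
(`ScoringMatrix.smooth_default`, also shipped as
`data/nblast_scores_synthetic.csv`) is a synthetic smooth surface —
4·exp(−d/5)·|dot| − 0.5 at bin midpoints — with the qualitative shape of
the trained matrices: monotone decreasing in distance, increasing in
alignment, positive near (0, 1). Normalized scores divide by the query
self-score, so an exact duplicate scores exactly 1.

**Ranking.** Match reports rank by the forward (query-normalized) score;
the mean of forward and reverse normalized scores is computed and
reported alongside but not used for ranking — the choice among
forward/reverse/mean was open, and forward is the variant that
normalizes by the one fixed reference neuron. Pooled pair reports drop
self-matches, keep each candidate once at its best score, and break score
ties by candidate id for determinism. Spatial registration between
volumes is consumed as an optional user-supplied transform (identity by
default); template symmetrization is out of scope.

## Transcriptome filter and clustering

The candidate filter runs on **raw** counts, before any normalization: a
cell passes with Hdc ≥ 2, a strictly dominant Hox gene (Antp or Ubx)
≥ 2, and dominant:minor ratio ≥ 15 (inclusive). A zero minor count
passes — the published candidate table contains cells with a normalized
0 in the minor Hox gene — and exact Antp = Ubx ties reject. The filter
is monotone: raising Hdc or the dominant Hox count never turns a pass
into a reject.

Normalization is counts-per-million followed by log2(n+1); zero-total
cells are excluded with a warning rather than producing NaN. The
transform is exactly invertible back to per-cell proportions, which the
tests verify to 1e-9.

Panel clustering is complete-linkage agglomeration on Euclidean
distance, applied to genes and cells independently. The agglomeration is
implemented in-package (O(n³), fine at panel scale) because dendrogram
determinism requires a canonical tie-break — among equal-distance
merges, the pair containing the lexicographically smallest member labels
merges first, and the child holding the smallest label is placed first —
making tree topology and leaf order invariant to input row order. On
tie-free data it agrees step-by-step with scipy's complete linkage,
which serves as the independent cross-check. Output uses the scipy
linkage-matrix convention; dendrograms export to Newick. Gene panels are
plain configuration lists, not hard-coded.

## ΔF/F

Background is subtracted frame-by-frame (more general than a scalar
offset; removes shared slow drift), the baseline F0 is the mean
*corrected* fluorescence over the 5 s before stimulus onset, and
ΔF/F = (F_corr − F0)/F0. Taking the baseline on the corrected rather
than the raw trace follows the order of operations
(subtract-then-normalize); the raw-baseline variant is available behind
a flag. F0 ≤ 0 is an error (focal ROI darker than its background
region). ΔF/F is invariant to adding a common constant to both traces
and to common gain, which the tests assert. Aggregation is the
pointwise mean of stimulus-aligned traces, with linear-interpolation
resampling when frame rates differ; individual traces are preserved for
overlay export. Motion correction and ROI segmentation are out of
scope — inputs are assumed registered.

## Synthetic generators

Each generator is a pure function of its arguments; RNG streams are
derived from the master seed via fixed per-generator labels
(`SeedSequence([seed, label])`), so adding a generator never perturbs
another's output.

**Connectome** (defaults: 60 DN, 100 IN, 20 AN, 20 ASN, 40 SN, 30 MN
background neurons around 2 focal pairs). Half of the DNs
(`convergence_fraction = 0.5`) are planted as common input onto every
focal cell with weights 10–30 synapses — comfortably above the 3-synapse
threshold, mirroring the majority-DN convergent input the demographic
analyses expect. Each focal pair drives 4 dedicated interneurons with
20–40 synapses each, which drive every motor neuron of a pair-specific
group (wing-like for the first pair, leg-like for the second) at the
same weight scale. Background edges are sampled independently at
density 0.02 with geometric(0.35) weights (heavy right tail, mode 1,
mimicking connectome weight spectra); motor neurons emit no background
output and sensory classes receive none, matching their circuit roles.
Synapse sites onto focal cells are drawn inside disjoint per-class
coordinate boxes so the location-by-class export has visible spatial
structure. The generator does **not** emulate real volumes' neuron
counts, degree distributions, spatial embedding or full weight spectra —
passing recovery tests demonstrates correctness of the analysis code on
the planted structure, not performance on real connectomes, where
thresholds and annotation quality dominate.

**Skeletons.** A straight trunk (50 μm default, 1 μm node spacing) with
twigs attached at distinct nodes in the proximal half, each subdivided
so its cable length is *exactly* the requested value; `n_branches`
counts linear segments, so it must equal `1 + len(twig_lengths)` and
`n_branches=1` is a bare cable. Twig directions are random with reduced
trunk-axis component. Real neurites' tortuosity and radius taper are not
modelled.

**Expression.** Background counts are negative binomial (r = 0.5,
p = 0.4; sparse, overdispersed). Background cells' marker-gene counts
are 0/1 ambient contamination only: histamine-pathway and Hox markers
are cell-type specific, so unplanted cells never reach the 2-count
filter floor. This reflects marker specificity and makes planted-set
recovery a structural property of the generator rather than a
probabilistic one; real atlases, with doublets and ambient RNA, would
produce borderline cells that this generator deliberately does not.
Planted cells carry their planned marker counts verbatim; ground truth
lists the planted cells whose planned counts satisfy the filter.

**Traces.** Focal trace = baseline + background offset + stimulus-locked
exponential transient (amplitude a at onset, decay τ = 2 s);
background trace = the constant offset; independent Gaussian noise on
both. The noiseless peak ΔF/F is exactly a/baseline, giving a closed
form for recovery tests; with noise, the Monte-Carlo mean peak is
unbiased within sampling error. Defaults (30 Hz, 20 s, amplitude 50 on
baseline 100 → peak ΔF/F 0.5) are in the range of strong indicator
responses; photobleaching, motion and indicator nonlinearity are not
modelled.

## Problem sizes and tolerances

Test and acceptance runs use the default generator sizes above, 200
(tests) / 50 (script) random group matrices of ≤ 50 groups for the
path-enumeration check (tolerance 1e-12 absolute), point clouds of ≤ 200
points for the NBLAST brute-force check (1e-9), 100 random skeletons for
pruning idempotence (exact frame equality), 2,000 cells × 200 genes with
20 planted candidates for the filter (exact set equality), 50 instances
of ≤ 30 items for the clustering cross-check (exact merge heights on
tie-free data), and 100 noisy traces for ΔF/F recovery (3 standard
errors). Fraction normalizations are asserted at 1e-9.

## Known limitations

- No live CATMAID/neuprint clients; all connectivity arrives as tables.
- Path lengths > 2 are not computed; no signed or
  neurotransmitter-weighted connectivity.
- Trained NBLAST score tables must be supplied; the packaged matrix is
  synthetic and suitable only for testing and relative comparisons.
- The transcriptome stage accepts an optional upstream cell whitelist
  (e.g. an atlas cluster assignment) rather than re-deriving cluster
  membership.
- Headline percentages from real volumes (e.g. DN input fractions of
  50–68 %) require the full datasets and are covered only qualitatively
  by planted-structure recovery.
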