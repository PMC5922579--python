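# Methods

This note documents the model implemented in `connalign`, the numerical and
design choices that were genuinely open, what the synthetic-data generator
does and does not emulate, and the package's known limitations.

## Model and derivation

**Local alignment.** A cortical field (searchlight) with m loci defines an
m-dimensional space in which each connectivity pattern (or response pattern)
is a vector. Per field, subjects are aligned by orthogonal transforms —
improper rotations permitted, no isotropic scaling, no translation term —
found in closed form as R = UVᵀ from the SVD of BᵀM. Translation removal is
handled upstream by column z-scoring (population-SD convention, i.e. divide
by n; correlations are invariant to this choice, which is fixed for
determinism). The group solution uses a three-level iteration:

1. *Level 1.* Subject 2 is aligned to the reference subject; each later
   subject to the running target (previous subject's aligned data + previous
   target)/2 — a literal halving, not a count-weighted mean. The result
   depends on subject order, which is therefore recorded in provenance.
2. *Level 2.* Each subject is re-aligned, from its original data, to the
   equally weighted mean of all other subjects' level-1 aligned data;
   level-1 transforms are then discarded and the model is the mean of
   level-2 aligned data.
3. *Level 3.* Final transforms are recomputed against that model, and the
   model is refreshed as the mean of the final aligned data, so the stored
   model always equals the mean of the stored transformed matrices.

Rank-deficient cross-products (rows < columns, common in searchlights) are
handled by the full SVD, whose orthonormal completion of the null space is
deterministic for a given input. When subjects' column counts differ, the
narrower matrix is zero-padded on the right (ascending index), mapping
everything into the reference subject's dimensionality.

**Whole-cortex aggregation.** One searchlight is centred on every mesh node
(default radius 20 mm). Local transforms are summed after zero-padding to
the full m × m size; overlapping searchlights therefore contribute multiple
estimates per locus/dimension pair, weighting nearby pairs (which co-occur
in more searchlights) more heavily, and pairs beyond twice the searchlight
radius are structurally zero. The aggregate is sparse, stored in canonical
sorted-index order with explicit zeros dropped (serialization is
byte-stable), and non-orthogonal by design: this is the locality constraint.
Transforms are applied to column-z-scored data only, and only to sessions
that played no role in the derivation; the model object refuses data carrying
the derivation session's label.

**Connectivity targets.** Derivation uses a reduced target set for
tractability. Coarse target searchlights (13 mm radius) are centred on an
icosahedral grid roughly a quarter the fine grid's density (1284 centres at
full scale). Because a naive per-subject PCA would not give functionally
corresponding components, each target searchlight's loci are first
hyperaligned across subjects using their correlations with the mean time
series of *all* target searchlights; the SVD of the group-mean matrix then
yields the top 3 component weight vectors (sign fixed by making the
largest-|weight| element positive — the SVD sign is otherwise arbitrary and
platform-dependent). Each subject's component time series is the
corresponding weighted sum of its own member loci; these series are
z-scored before use as connectivity targets (the alternative — using raw
weighted sums — differs only by column scales that correlations ignore, but
the flag is fixed and recorded). Derivation connectivity matrices (targets ×
loci, Pearson) are column z-scored before alignment. Validation uses the
full connectome (targets = all loci; the unit self-correlation diagonal is
retained). Correlations of constant series are defined as 0 with a warning.

**Feature selection** (off by default, matching an all-nodes pipeline;
optional for dilated-mask pipelines): per searchlight, each locus is scored
by the correlation of its training series with the across-subject mean at
the same locus, and the top ⌈fraction · m⌉ loci are retained (default
fraction 0.70), ties to the lowest index. Model dimensions follow the
reference subject's retained loci.

## Geometry

Synthetic cortical sheets are icosahedral spheres; a bilateral mesh is two
spheres with disjoint node ranges and no connecting edges, translated apart
so Euclidean nearest-node queries cannot cross hemispheres. Geodesic
distance is the graph shortest path along mesh edges weighted by Euclidean
length — exactly testable against a Dijkstra oracle, and consistent with
node-spacing-based distance reporting; no polyhedral geodesic is attempted
(on these nearly uniform meshes the two differ by a few percent at most).
Node indices are 0-based everywhere, with all ties broken by lowest index.

Distance bins for point-spread functions take a list of nominal distances
(default 0, 3, 6, 9, 12 mm, matching a ~3 mm-spacing grid); membership uses
half-open intervals of half the nominal gap around each distance and bin 0
is the node itself. On synthetic meshes whose spacing is not 3 mm,
`DistanceBins.from_mesh(mesh, n_bins=k)` sets the nominal distances to
multiples of the mean edge length, so bins are populated by successive
neighbor rings.

## Validation statistics

All leave-one-out statistics compare one subject with the plain
(raw-correlation) mean of the others; only the resulting correlation values
are Fisher-z transformed (clipped at |r| ≤ 1 − 1e-7) before averaging across
subjects and folds. PSF curves average pair correlations within bins per
subject first, then Fisher-average across subjects; the slope is the negated
OLS coefficient of bin mean against nominal distance (units 1/mm), so a
steeper fall-off gives a larger positive slope. Because the within-bin pair
average happens before the across-subject Fisher average, the bin-0 value
agrees with the mean of the ISC map only up to Jensen-gap differences
(empirically < 0.02). bsMVPC uses a 1-nearest-neighbor classifier by
correlation distance over sliding windows (default 6 samples); every sliding
start is a candidate — near-overlapping starts are not excluded — ties go to
the lowest start index, and chance is 100/n_candidates. The filter control
derives one model per reference subject and maps subject k through the model
referenced on subject k+1 (cyclically), so every connectome is
hyperalignment-filtered while the across-subject correspondence remains
node-index only. Bootstrap CIs are subject-level percentile intervals over
resampled means (default 10,000 resamples, 95%), seeded. No multiple-testing
correction is applied anywhere; uncertainty is reported as bootstrap CIs.

## Synthetic cohorts

The generator emulates the structure the method assumes: a latent functional
time series per node shared by all subjects within a session, remixed into
each subject's native space by an individual, session-stable orthogonal map
acting within non-overlapping local neighborhoods, plus i.i.d. Gaussian
noise. The latent series is a sum of a spatially smooth component (white
noise mixed through a column-normalized Gaussian geodesic kernel) and a
node-unique fine component, in equal variance shares by default.

The mixing blocks fix the constant vector within each neighborhood (they are
Haar-random on its orthogonal complement). This is deliberate: individual
topographic idiosyncrasy rearranges fine-scale structure but leaves
local-average activity in register across anatomically aligned brains —
that residual coarse-scale correspondence is exactly what anatomical
alignment captures, and what makes target searchlight mean series
comparable across subjects during target derivation. Fully unconstrained
random rotations would scramble local means too, which corresponds to data
with *no* anatomical correspondence at any scale — a regime in which no
anatomy-seeded alignment method is applicable.

Default study conditions: bilateral subdivision-8 icosphere (1284 nodes) of
50 mm radius (≈ 7.5 mm node spacing), 10 subjects, 400 time points in each
of 2 sessions, 10 mm mixing neighborhoods (half the 20 mm searchlight
radius, so the misalignment is recoverable by construction), 15 mm
smoothness length, and noise SD 0.4 relative to unit signal SD (a moderately
clean regime; the alignment-vs-filtering ordering is qualitatively stable in
noise up to at least SD 1.5). Sessions redraw the latent series from the
same spatial model while the mixing maps persist, mimicking
acquisition-to-acquisition variation around a stable individual connectome;
within a session the latent series is common to all subjects, so the same
cohorts also exercise response hyperalignment.

What the generator does *not* emulate: temporal autocorrelation and
hemodynamics (the statistics under test are correlation-based, not temporal
inference), folded cortical geometry (distances are what matter),
inhomogeneous SNR across cortex, and real between-subject variation that is
not an orthogonal remix (e.g. genuinely missing areas). Passing tests on
synthetic cohorts therefore demonstrate correctness of the machinery and
recoverability under the model's own assumptions, not effect sizes on real
fMRI data; the headline effect sizes reported for real datasets are outside
what desk-scale synthetic data can reproduce.

## Problem sizes and calibration checks

Tests and the acceptance script use desk-scale problems chosen so every
structural feature (searchlight overlap, locality, hemispheres, bins) is
exercised: aggregation equivalence is verified exhaustively on meshes up to
200 nodes against dense zero-padded summation; the end-to-end run uses the
default 1284-node cohort; solver optimality is checked on 100 random
problems against a 3600-angle rotation/reflection grid (2-D) or 10,000
random orthogonal candidates (higher dimensions). The full-scale geometry
(10,242 nodes per hemisphere, 20,484 searchlights, 1284 coarse targets ×
3 components = 3852 target profiles) is constructed once to verify the
counts analytically.

Bootstrap calibration draws 1,000 Gaussian cohorts of 100 subjects and
checks 95% CI coverage with 2,000 resamples. The cohort size is chosen in
the regime where the percentile interval's nominal validity applies: the
percentile bootstrap is known to undercover for small samples (~92.5%
empirical coverage at n = 20 for nominal 95%), which is a property of the
method, not of the implementation the check is meant to validate.

## Known limitations

- Derivation cost scales with searchlights × subjects × iterations; the
  implementation is single-process NumPy and comfortable at desk scale
  (seconds) and at tens of thousands of nodes (minutes to hours), but has no
  out-of-core path for very large meshes.
- The filter control re-derives a model per reference subject (N full
  derivations), faithful to its definition but the most expensive step of a
  validation run.
- Level-1 results depend on subject order; order and reference are recorded
  in provenance, and the level-2/3 passes reduce (but do not eliminate) the
  dependence.
- CHA's target derivation assumes coarse-scale anatomical correspondence of
  target searchlight mean series; on data lacking any such correspondence
  the derived targets stop being comparable across subjects and alignment
  quality degrades (demonstrated by the generator with unconstrained
  rotations).
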