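# Methods

## Model and assumptions

The package treats a brain region as a union of unknown functional units
and assumes that the set of enhancers active at a location is (a) nearly
constant within a unit and (b) discriminative between units, provided the
driver-line collection is large enough that every pair of units differs in
at least a few lines. Under these assumptions the per-voxel line sets
cluster by unit, and spatial compactness and mirror symmetry emerge from
the clustering even though voxel coordinates are never used as features.

The analysis consumes registered volumes as-is. Registration error is not
corrected, only tolerated: it blurs unit boundaries at the scale of a few
micrometres, which is why the analysis grid is usually coarser than the
acquisition grid.

## Occupancy and binarization

Expression is binarized by a single global intensity threshold (default
20 on an 8-bit scale, config-exposed). The threshold is applied after
optional mean-pooling by an integer factor; a pooled voxel belongs to the
region when at least half of its block does, and pooled ground-truth
labels take the block majority (ties to the smaller label). Voxels with
no expressing line are removed before clustering (default `min_lines` = 1)
so the Dice denominator is always positive. Graded intensities are kept
alongside the boolean matrix but do not enter the distance; an
intensity-weighted variant was deliberately left out of the distance
definition to keep the substrate a set-overlap statistic.

## Distances

`d(u, v) = 1 − 2|L_u ∩ L_v| / (|L_u| + |L_v|)`. Intersections are
accumulated as integer counts via float32 matrix products (exact below
2^24 lines) and the division runs in float64, so results are independent
of the internal blocking. The full condensed vector for n voxels costs
n(n−1)/2 float64; at the default desk scale (20³ = 8000 analysis voxels)
that is ~256 MB transiently, which bounds the practical n at roughly
30–40k voxels on a 8 GiB machine.

## k-medoids

Alternating (Voronoi-style) iteration: seeded uniform initialization
without replacement, nearest-medoid assignment (ties → lowest cluster
index), then each medoid moves to the member minimizing total
within-cluster distance (ties → lowest voxel index), until labels and
medoids are stable or `max_iter` (default 100). The cost trace is recorded
and is non-increasing by construction.

Two deliberate additions beyond the textbook loop:

* **Empty-cluster repair.** When a medoid wins no voxel (common when two
  medoids initialize on voxels with identical line sets — frequent under
  zero noise, where whole units are duplicates), the redundant medoid is
  reseeded at the voxel farthest from its assigned medoid (ties → lowest
  index). This is deterministic, never increases the cost, and in
  separable data provably migrates redundant medoids into uncovered
  units — it is why the zero-noise phantom is recovered exactly.
* **Restarts.** `n_restarts` independent streams `default_rng([seed, r])`;
  the lowest-cost restart wins, ties to the lowest restart index. The
  pipeline default is 5 restarts.

A deterministic PAM (greedy BUILD + best-improvement SWAP) mode exists
behind `method="pam"` for small problems; the alternating mode is the
default because it scales to tens of thousands of voxels and matches the
random-seed semantics of repeated-run consistency checks.

## Agglomeration

UPGMA over the k singletons with inter-cluster distance = mean of all
cross-pair voxel distances, implemented with the weighted-average update
so the initial k×k table is aggregated once from the full distance matrix.
Average linkage was chosen because it guarantees monotone merge heights on
a semimetric and empirically repairs oversplit units: when a true unit is
split across two singletons, those siblings almost always join before
either touches a foreign singleton. Ties in the minimal linkage break on
the lexicographically smallest id pair; merged clusters are numbered
k, k+1, … and named C{k}, C{k+1}, … continuing the singleton names.
The tree exports as JSON and as Newick with branch lengths derived from
merge heights.

## Reporting

Per cluster and line: `coverage_in` (fraction of cluster voxels covered)
and `coverage_out` (fraction of region voxels outside the cluster
covered); specificity = `coverage_in × (1 − coverage_out)`. The product
form is bounded in [0, 1], zero for fully broad lines, and free of the
degeneracies of difference or odds-ratio scores. "Strongly expressing,
not broad" defaults to `coverage_in ≥ 0.5` and `coverage_out ≤ 0.1`
(inclusive, config-exposed); these operationalize qualitative notions and
deserve tuning per collection. Average images are voxelwise means of the
selected lines' full stacks over the whole template.

## Evaluation

* **Overlap**: Dice between cluster and ground-truth structure voxel
  sets; per-structure best cluster (greedy, matching how a reader pairs
  structures with clusters; Hungarian assignment was considered and
  rejected as harder to interpret per structure); "recovered" counts
  structures with best Dice ≥ τ (default 0.5).
* **ARI** via scikit-learn, restricted to voxels with a nonzero truth
  label when a truth volume is supplied.
* **Symmetry**: per cluster, the fraction of voxels whose mirrored
  coordinate (default reflection x → W−1−x; any coordinate map can be
  supplied) is an analysis voxel with the same label; mirrors landing
  outside the voxel set leave the denominator.
* **Compactness**: fraction of the cluster in its largest 26-connected
  component.
* **Run consistency**: greedy one-to-one cluster matching by descending
  Dice plus the ARI of the two partitions.

## Phantom generator

`PhantomSpec` defaults define the package's study conditions: a 40³ grid
(unit µm voxels), K = 10 space-filling Voronoi units, L = 300 lines,
per-unit inclusion probability 0.2, 5% broad lines, 2% voxel false
positives, 10% false negatives, intensity 100 ± 10 over background 0 ± 10
(8-bit-like scale), and a per-line integer translation with 1-voxel sd
emulating template-registration error. These sizes were chosen so a full
clustering run finishes in seconds-to-minutes on one CPU while keeping
per-voxel line counts (~50) high enough that Dice distances are stable,
i.e. the same regime that makes the method work on genome-scale
collections. The `blobs` mode places non-overlapping ellipsoids with a
buffer (≥ 1 background voxel) for dispersed-unit regimes; `mirror=True`
generates one half and reflects it, paired units sharing an id.

What the phantom does **not** emulate: real enhancer patterns are not
unit-aligned Bernoulli draws — lines respect neither unit boundaries nor
independence; intensity structure (point-spread, depth attenuation,
staining variation) is absent; jitter is a rigid integer translation, not
elastic deformation; units have no internal substructure. Passing the
synthetic benchmarks therefore demonstrates the pipeline's correctness
and noise tolerance under its own model, not performance on any real
collection.

## Numerical choices and degenerate inputs

All randomness flows through `numpy.random.default_rng` seeds; every
tie-break is by lowest index, so outputs are bit-reproducible. Analysis
runs default to mean-pooling factor 2 of the 40³ phantom (8000 analysis
voxels). Pathological inputs fail loudly: multi-channel stacks, grids
that do not match the mask (named offending line), empty regions after
filtering, k outside 1..n, cuts outside 1..k, overlapping member sets in
linkage queries.

## Known limitations

* Pairwise distances are materialized; beyond ~40k voxels memory becomes
  the bottleneck and an on-demand bit-set backend would be needed.
* The alternating k-medoids finds local optima; restarts mitigate but do
  not eliminate this (the small-n exhaustive benchmark measures the
  residual gap).
* No automatic choice of k: the intended workflow is to over-split and
  read the hierarchy, not to optimize a model-selection criterion.
* Statistical significance of overlaps (permutation tests) is out of
  scope; reported Dice/ARI values are descriptive.
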