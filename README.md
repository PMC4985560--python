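# braincode

Automatic parcellation of registered 3D brain regions into putative
functional units — glomeruli, nuclei, fiber tracts — from collections of
enhancer-driver (GAL4) expression volumes.

The premise: voxels inside one anatomical unit share a characteristic set
of active enhancers, so clustering voxels by the similarity of their
expressing-line sets recovers the unit boundaries without any spatial
prior. The package is aimed at neuroanatomists working with genome-scale
driver-line image collections (thousands of stacks registered to one
template brain) who want data-driven segmentations of a region of interest
plus candidate driver lines targeting each segment.

## Method

Given L registered single-channel stacks (one per driver line) and a
boolean region mask, the pipeline:

1. **Occupancy matrix** — binarize each stack at a global intensity
   threshold (optionally after integer-factor mean-pooling to an analysis
   grid) and compile, for each analysis voxel *u*, its line set
   *L<sub>u</sub>* = {lines expressing at *u*}.
2. **Dice distance** — for voxels *u*, *v*:
   *s*(*u*, *v*) = 2|*L<sub>u</sub>* ∩ *L<sub>v</sub>*| /
   (|*L<sub>u</sub>*| + |*L<sub>v</sub>*|), distance *d* = 1 − *s*.
3. **k-medoids** — partition the voxels into k "singleton" clusters
   (C00…C(k−1), default k = 60) by seeded alternating k-medoids on the
   precomputed distances; deterministic given (distances, k, seed).
4. **Agglomeration** — merge the singletons by UPGMA (mean cross-pair
   voxel distance) into a hierarchy; merged clusters continue the
   numbering (C60, C61, …). Over-split units re-join at low heights, so
   the tree resolves lumping-versus-splitting questions.
5. **Reporting** — rank driver lines per cluster by specificity
   = coverage_in × (1 − coverage_out), select strongly-and-specifically
   expressing lines, and build average images.
6. **Evaluation** — voxel-set Dice overlap against a labeled ground
   truth, adjusted Rand index, per-cluster 26-connected compactness,
   mirror-symmetry scores, and greedy cluster matching across runs.

A synthetic phantom generator produces line collections over known units
(space-filling Voronoi cells or dispersed ellipsoidal blobs, optionally
mirror-symmetric) with false positives/negatives, intensity noise, broad
lines and per-line registration jitter, so the whole pipeline is testable
end-to-end without the multi-terabyte source collections.

## Worked example

```python
import braincode as bc

spec = bc.PhantomSpec(shape=(20, 20, 20), K=5, L=120, p_incl=0.25, seed=42)
ds = bc.generate(spec)
m = bc.filter_voxels(bc.build_matrix(ds.volumes, ds.line_ids, ds.mask))
d = bc.pairwise_distances(m)
c = bc.kmedoids(d, k=5, seed=0, n_restarts=5)
tree = bc.agglomerate(c, d)

truth = bc.labels_from_volume(ds.truth, m.voxels)
print(f"voxels: {m.n_voxels}, lines: {m.n_lines}")
print(f"k-medoids cost: {c.cost:.1f} after {c.n_iter} iterations")
print(f"ARI vs ground truth: {bc.adjusted_rand(c.labels, truth):.3f}")
print(f"units recovered at Dice>=0.5: {bc.overlap(c.labels, truth).recovered}/5")
top = bc.score_lines(m, c, 0)[0]
print(f"top line for C00: {top.line_id} (coverage_in={top.coverage_in:.2f}, "
      f"coverage_out={top.coverage_out:.2f}, specificity={top.specificity:.2f})")
```

prints

```
voxels: 8000, lines: 120
k-medoids cost: 1812.8 after 2 iterations
ARI vs ground truth: 0.943
units recovered at Dice>=0.5: 5/5
top line for C00: line_0067 (coverage_in=0.84, coverage_out=0.05, specificity=0.81)
```

The ARI of 0.94 says the five noisy synthetic units were recovered almost
exactly (1.0 would be a perfect match); all five units overlap their best
cluster at Dice ≥ 0.5; and the top-ranked line for cluster C00 covers 84%
of that cluster while touching only 5% of the rest of the region — a good
candidate driver for that unit.

The same run from the shell:

```sh
braincode phantom --out data/           # synthetic collection + ground truth
braincode run --config config.yaml      # full pipeline into a run directory
```

where `config.yaml` names the manifest, mask, optional truth volume, and
the run parameters (`k`, `seed`, `threshold`, `downsample_factor`, …). The
run directory contains `clustering.json`, `labels.nrrd`,
`cluster_names.tsv`, `tree.json`/`tree.newick`, `line_scores.tsv`,
`evaluation.json` and a `run.log` echoing the full configuration.

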