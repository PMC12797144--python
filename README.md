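# connectopy

Local-global connectopic gradient mapping for seed-region functional
connectivity, with the downstream analyses needed to compare what the
different fingerprinting routes actually measure.

A seed region's voxels are characterized by connectivity fingerprints,
turned into a voxel-to-voxel similarity matrix, and embedded into a small
number of smooth spatial *gradients*. Four fingerprint variants are
implemented:

| variant | fingerprint | captures |
|---|---|---|
| `original` | correlation against SVD spatial modes of the target | **local** within-seed structure |
| `rescaled` | the same, with each mode re-weighted by its singular value | **global** seed-to-target structure |
| `voxelwise` | correlation against every target voxel (no SVD) | global (lossless reference) |
| `within_seed` | none — within-seed FC used directly as similarity | local (direct reference) |

With cosine similarity and a full-rank target these satisfy two exact
identities — `original` ≡ `within_seed` and `rescaled` ≡ `voxelwise` —
which the test suite verifies both algebraically and end-to-end on
synthetic cohorts with planted gradient structure.

On top of the embeddings (Laplacian eigenmap, diffusion map, PCA, each
after row-wise top-10% sparsification) the package provides:

- **group templates and alignment** — mean-similarity group gradients,
  Hungarian matching of individual components (cost `1 − |r|`), orthogonal
  Procrustes alignment, and the stability-based gradient retention rule
  (mean individual-to-group |r| > 0.5);
- **geometry analyses** — Mantel-style RSA of gradient dissimilarity
  against Euclidean voxel distance with a permutation null, and spatial
  map correlations against external reference maps;
- **prediction** — LDA nucleus classification with stratified 5-fold CV
  and a permutation chance level, and nested-CV LASSO phenotype prediction
  (inner-loop penalty selection, Spearman performance, weight-map and
  per-nucleus contribution summaries);
- **synthetic cohorts** — a generator that plants a smooth connectopic
  axis, a toy 6-nucleus parcellation, and phenotypes driven by per-subject
  latent parameters, so every pipeline stage is testable offline.

## CLI

```bash
connectopy simulate  --out cohort/ --subjects 20 --seed 2024
connectopy gradients --data-dir cohort/ --out-dir grads/ \
                     --variant original --method DE --sparsity 0.9 --g 3
connectopy group     --in-dir grads/ --out-dir group/
connectopy compare   --data-dir cohort/ --out-dir compare/
connectopy rsa       --gradients grads/sub-000_gradients.tsv \
                     --coords cohort/coords.tsv --out rsa.json
connectopy classify  --gradients group/group_gradients.tsv \
                     --labels cohort/labels.tsv --out cls.json
connectopy predict   --in-dir group/ --phenotypes cohort/phenotypes.tsv \
                     --metric cog_metric --out pred.json
```

All matrix inputs/outputs are TSV with a voxel-id header; 4D NIfTI
timeseries plus integer label masks are supported through
`connectopy.io.extract_timeseries`. Every output carries JSON provenance
(config, seeds, package version, voxel ordering convention).

## Library sketch

```python
from connectopy import (SyntheticConfig, generate_cohort, build_similarity,
                        gradients_from_similarity, group_template)

cohort = generate_cohort(SyntheticConfig(n_subjects=20))
sims = [build_similarity(s, t, "rescaled")            # global gradients
        for s, t in zip(cohort.seed_ts, cohort.target_ts)]
template = group_template(sims, method="DE", g=3)
template.group_gradients.gradients                    # (voxels, 3)
```
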