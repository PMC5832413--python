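# rsapipe

A representational similarity analysis (RSA) pipeline for object-evoked
fMRI patterns, built around behavior-based similarity models:

- **behavior models** — a visual model RDM from pairwise Likert similarity
  ratings (catch-trial rater exclusion, per-pair means, min–max
  normalization, `1 − normalized mean`), a conceptual model RDM from
  feature-generation norms (production-count reliability filtering,
  visual-form/color tag removal, `1 − cosine` over count vectors), and an
  embedding model RDM from precomputed word vectors (`1 − cosine`).
- **glm** — per-run object pattern estimation: delta onsets convolved with
  a double-gamma HRF, OLS with nuisance covariates, `t = β/SE`, run
  averaging into object × voxel pattern sets.
- **rsa** — first-level correlation-distance RDMs (`1 − Pearson r`) and
  within-object cross-context pattern correlations.
- **inference** — second-level statistics: tie-aware Kendall tau-a,
  stimulus-label randomization tests, one-sided Wilcoxon signed-rank
  (exact for n ≤ 25, tie-corrected normal approximation above),
  `r = sin(½π·tau)` and Fisher-z transforms, 2×2 repeated-measures ANOVA,
  Bonferroni correction.
- **searchlight** — k-nearest-voxel neighborhoods (Euclidean in world
  coordinates, or geodesic along a supplied mesh), local RDM → tau-a →
  Fisher-z similarity maps.
- **group** — within-mask standardization, one-sample t → z, threshold-free
  cluster enhancement (TFCE), max-TFCE Monte-Carlo permutation null for
  family-wise error control, cluster tables, and voxel-overlap analysis.
- **synth** — synthetic data for every stage: near-orthogonal chained-pair
  model RDMs, rating tables with catch trials, feature norms with
  controlled cosine geometry, leaky embeddings, BOLD series, and
  multi-subject multi-voxel patterns whose expected geometry is a weighted
  mixture of the two model RDMs across configurable regional regimes.

## CLI

All stages are exposed through one entry point:

```bash
# emit a complete synthetic fixture (tables, masks, pattern stacks)
rsapipe sim --out fixture/ --seed 1 --n-objects 20 --n-subjects 8

# behavior-based model RDMs from rating/norm/embedding tables
rsapipe behav-rdm --ratings fixture/ratings.tsv --norms fixture/norms.tsv \
    --embeddings fixture/embeddings.tsv --min-count 4 \
    --exclude-tags visual_form,color --out rdms/

# GLM t-patterns, first-level RDMs, within-object similarity
rsapipe glm --bold bold.nii --events fixture/events.tsv --run 0 --out pat.nii
rsapipe rsa-roi --patterns fixture/patterns/sub00_visual.nii \
    --mask fixture/masks/prc_like.nii --out rdm.csv
rsapipe rsa-within --patterns-a sub00_visual.nii --patterns-b sub00_conceptual.nii \
    --out within.tsv

# searchlight map, group z map, overlap
rsapipe searchlight --patterns sub00_visual.nii --model rdms/visual_rdm.csv \
    --mask fixture/masks/volume.nii --k 100 --out map.nii
rsapipe overlap --maps sig_a.nii --maps sig_b.nii --out overlap/

# full staged pipeline from a YAML config
rsapipe report --config config.yaml
```

A minimal pipeline config:

```yaml
fixture_dir: fixture
out_dir: out
seed: 1
n_iter: 1000        # randomization-test iterations
k: 30               # searchlight neighborhood size
do_searchlight: true
n_subject_null: 20  # per-subject null maps
n_group: 500        # group null assemblies
```

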