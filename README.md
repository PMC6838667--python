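# connspace

Spectral embedding of seed-voxel connectivity profiles: connectivity
gradients, Laplacian eigenmaps, and convergence-zone detection.

`connspace` is for researchers who have tractography-derived connectivity
profiles — for each seed voxel, the map of streamline counts to every
target voxel in the brain — and want to know how connectivity is organised
across the seeded region: does it break into discrete clusters, or shift
gradually along gradients, and which seeds have the least distinct
connectivity of all (the "convergence zone")?

## The method

Given an n × m profile matrix (n seeds, m targets), the pipeline:

1. post-processes per-subject profiles: threshold at 0.05% of the
   profile-set maximum, binarize, block-downsample the target grid by 2
   per dimension, average across subjects;
2. computes the n × n cosine similarity matrix of the profiles and treats
   it as a weighted graph adjacency **A**, with degree matrix
   **D** = diag(row sums) and Laplacian **L = D − A**;
3. solves the generalized eigenproblem **L X = D X Λ** (the normalized-cut
   formulation of Laplacian eigenmaps). The zero eigenvalue's multiplicity
   counts the graph's connected components; a smoothly rising spectrum
   with no large eigengap indicates graded organisation. The eigenvectors
   of the three smallest non-zero eigenvalues place every seed in a 3-D
   connective-similarity space;
4. colours each seed by feature-scaling the coordinates to RGB,
   **RGB = (X − 1·Xmin)/(Xmax − Xmin)** (plus an outlier-robust rank-order
   variant), so a voxel keeps its colour as it moves between similarity
   space and anatomical space;
5. finds the convergence zone: the seeds within the closest 10th
   percentile of Euclidean distance to the centre of mass of the raw
   similarity-space cloud — the seeds whose connectivity profiles are most
   similar, on average, to all others.

Because real tractography cohorts cannot be redistributed, the package
includes generators for synthetic profile sets with planted structure
(a graded latent axis, a distinctly-connected cluster, hub seeds built as
mixtures of the gradient extremes, multi-subject noise) so every stage can
be validated against known ground truth. See `docs/methods.md` for the
full model description and design choices.

## Worked example

```python
import connspace as cs

# a 200-seed gradient over 2000 targets, plus 20 planted hub seeds
base = cs.generate_graded_profiles(n_seeds=200, m_targets=2000,
                                   noise_sd=0.05, rng_seed=7)
profiles, truth = cs.generate_hub_profiles(*base, n_hub=20, rng_seed=13)

results = cs.ConnectivityGradientModel(profiles).fit()
print(results.summary())
```

```
Connectivity gradient embedding
===============================================
seeds analysed:          220
target dimensions:       2000
connected components:    1
algebraic connectivity:  0.7805
eigenvalues (leading):   0.0000, 0.7805, 0.9997, 0.9997, 0.9997, 0.9997, 0.9997, 0.9997
largest eigengap after:  index 0
embedding dimensions:    3
zone percentile:         10  (cut 0.004032, retained 22/220)
```

One connected component (a single zero eigenvalue) means every seed's
connectivity overlaps somewhere with the rest; the largest eigengap
sitting immediately after the zero, with no cluster of near-zero
eigenvalues, is the graded-organisation signature — the profiles shift
gradually rather than splitting into discrete clusters. Of the 22 seeds
retained in the 10th-percentile convergence zone, 6 are planted hubs
(`results.zone.mask[truth.hub_mask].sum()`), a 30% hit rate against a 10%
chance rate — the mixture seeds crowd the centre of the similarity space.

`results.to_frame()` gives the per-seed table (coordinates, raw and
ranked RGB, distance to the centre of mass, zone membership);
`results.save_volumes(outdir)` writes RGB and zone-mask NIfTI volumes;
`results.plot_similarity_space("space.png")` renders the coloured 3-D
embedding.

The same pipeline runs from the shell:

```bash
connspace simulate --n-seeds 200 --m-targets 2000 --n-hub 20 --seed 7 --out profiles.h5
connspace embed profiles.h5 --out embedding.csv
connspace zone embedding.csv --out zone.csv
connspace run --config run.yaml --seed 7     # full run with manifest
```

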