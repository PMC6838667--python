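# Methods

## The model

`connspace` analyses *connectivity profiles*: for each of n seed voxels, a
non-negative vector of streamline counts (or binarized hits) over m target
voxels — the seed's connectional fingerprint. The analysis asks whether
connectivity across a region changes in discrete clusters or along graded
transitions, and which seeds are least connectionally distinct from the
rest.

1. **Post-processing.** Per-subject profiles are thresholded at a small
   fraction (default 0.05%) of the maximum value in the subject's profile
   set, binarized, block-mean downsampled by 2 per spatial dimension, and
   averaged across subjects, giving per-seed connection probabilities in
   [0, 1]. Seeds whose processed profile is entirely zero are dropped (a
   zero vector has no direction, so cosine similarity is undefined).

2. **Similarity graph.** Pairwise similarity is the cosine of the angle
   between profile vectors; for non-negative profiles all entries lie in
   [0, 1] with unit diagonal. The similarity matrix is treated as a
   weighted adjacency A, with degree matrix D = diag(row sums of A) and
   Laplacian L = D − A.

3. **Spectral embedding.** The generalized eigenproblem
   L X = D X Λ (the normalized-cut / Shi–Malik formulation of Laplacian
   eigenmaps) is solved via the symmetric substitution
   M = D^{−1/2} L D^{−1/2}; eigenpairs (λ, y) of M back-transform to
   generalized pairs (λ, D^{−1/2} y). Eigenvalues lie in [0, 2]; the zero
   eigenvalue's multiplicity equals the number of connected components,
   and a spectrum that rises smoothly (no large gap after the near-zero
   leading values) indicates graded rather than clustered organisation.
   The eigenvectors of the three smallest non-zero eigenvalues — skipping
   *all* null-space vectors — are the seed coordinates in a 3-D
   connective-similarity space.

4. **Colour mapping.** Coordinates are feature-scaled to RGB with a single
   global affine map, RGB = (X − 1·Xmin)/(Xmax − Xmin), where Xmin/Xmax
   are the scalar minimum/maximum over the whole matrix; this preserves
   relative spread between axes (a per-column variant exists behind a
   flag). Because raw eigenvectors are outlier-sensitive, a "ranked"
   variant replaces each column by its average-rank order before
   per-column scaling to [0, 1].

5. **Convergence zone.** The centre of mass (unweighted mean) of the raw
   coordinates is computed; seeds whose Euclidean distance to it falls at
   or below the 10th percentile of the distance distribution are retained.
   These are the seeds whose connectivity is least distinct from all
   others — the operationalisation of a graded hub.

## Parameters

| parameter | default | units | why |
|---|---|---|---|
| `threshold_fraction` | 0.0005 | fraction of set max | removes very low-level tractography noise |
| `threshold_scope` | `"set"` | — | the reference analysis scopes "the maximum value" to the subject's whole profile set; per-seed max available as `"seed"` |
| `downsample_factor` | 2 | per dimension | memory reduction; block mean preserves connectivity mass up to scale |
| `n_dims` | 3 | — | matches the RGB colour mapping; the leading eigengap concentrates the signal in the first eigenvector, further dimensions add nuance only |
| `k` | zero multiplicity + 8 | eigenpairs | lets diagnostics report gaps beyond the embedding dimensions |
| `percentile` | 10 | % | convergence-zone retention |
| `zero_diagonal` | `False` | — | keep A's unit self-similarity diagonal when forming D; L is identical either way, D is not — the default follows the similarity matrix as computed, the switch documents the sensitivity |

## Numerical choices

* **Zero tolerance.** An eigenvalue counts as zero when
  λ < 1e−8 · max(1, λmax). Component counting uses this rule.
* **Threshold strictness.** "≥ cut survives": the maximum itself is always
  kept; thresholding is idempotent on already-binary input.
* **Sign convention.** Each eigenvector is oriented so its
  largest-absolute entry is positive (ties to the lowest index);
  eigensolver sign ambiguity is thereby removed and runs are
  reproducible. Repeated (near-degenerate) non-zero eigenvalues leave the
  basis within the eigenspace solver-dependent; tests assert only
  subspace-level properties in that situation.
* **Percentile definition.** Linear interpolation between order
  statistics; ties at the cut are all retained, so the retained fraction
  can exceed the nominal value by up to the tie mass (for untied
  distances it is within 1/n).
* **Rank ties.** Average ranks.
* **Odd grids.** Zero-padded to even before 2×2×2 block aggregation.
* **Degenerate inputs.** All-zero profile sets abort; constant embeddings
  abort RGB scaling (Xmax = Xmin); zero-degree nodes abort the
  eigensolve, each with a named-seed diagnostic.

## The synthetic generator

Real seed-voxel tractography data cannot be redistributed, so ground truth
is planted synthetically:

* **Gradient.** Seeds get latent positions t evenly spaced in [0, 1];
  expected profiles are convex combinations of fixed "extreme" profiles —
  truncated-Gaussian bumps on disjoint stretches of a 1-D target index
  (cosine similarity depends only on vector values, so no 3-D target
  geometry is needed). For two extremes the convex weights use the angular
  reparametrization s = sin φ/(sin φ + cos φ), φ = tπ/2, which keeps the
  endpoint and midpoint identities while making noiseless similarity
  exactly cos(π/2·|Δt|) — strictly decreasing in latent distance. With
  more than two extremes (Gaussian-kernel weights) the decay is strictly
  monotone along each side of a seed but not an exact global function of
  |Δt|, since far-apart segments decorrelate.
* **Cluster.** Appended seeds share a smooth template on target voxels the
  gradient never uses, except a fraction `overlap` of their support drawn
  from gradient targets; `overlap = 0` gives exact orthogonality and a
  two-component graph.
* **Hubs.** Appended seeds whose expected profile is the equal-weight
  average of all extremes — by construction the seeds most similar on
  average to everyone, the planted convergence-zone truth.
* **Noise.** Additive Gaussian truncated at zero (default sd 0.05 against
  bump peak 1), preserving non-negativity. Truncation gives the noise a
  small positive mean on near-zero entries, so multi-subject averages
  converge to the template plus that small floor rather than the template
  exactly; the variance-reduction property is what is asserted.
* **Coordinates.** A toy cubic seed lattice is attached so volumetric
  output can be exercised.

What passing these tests does *not* show: robustness to registration
error, to subject-varying seed correspondence, to tractography's
distance/gyral biases, or to realistic streamline-count distributions —
none of which the generator emulates.

## Design choices where the design was open

* The pipeline applied to a synthetic generator spec skips
  threshold/binarize by default: the generator emulates already-processed
  continuous group profiles, and binarizing them would collapse the planted
  graded weights into support indicators. Raw subject input gets the full
  chain.
* The group profile is not re-thresholded after averaging.
* No similarity sparsification (k-NN or thresholding) is applied; the
  cosine graph of real profile sets is essentially fully connected and
  dense symmetric solvers handle the few-thousand-seed scale directly.
* Hemispheres (or any independent seed sets) are separate runs sharing a
  config; no cross-set coupling.
* Problem sizes in tests and the acceptance script (n = 200 seeds,
  m = 2000 targets for the study-scale fixtures; n ≤ 50 for oracle
  comparisons) were chosen as the smallest scales at which the planted
  structure is comfortably resolved.

## Known limitations

* Embedding coordinates beyond the first are noise-dominated when the
  planted structure is one-dimensional (their eigenvalues crowd near the
  top of the spectrum), so only coordinate 1 is compared against the
  planted ordering.
* Intrinsic-dimensionality estimation is out of scope; 3 dimensions is a
  visualisation-driven heuristic, not an inference.
* The convergence zone is a descriptive statistic; no null model or
  significance test is attached to it.
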