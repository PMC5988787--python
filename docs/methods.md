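# Methods

This note documents the models implemented in `cemb`, the defaults and why
they are set where they are, the numerical conventions, and what the
synthetic benchmarks do and do not establish.

## Data model

A connectome is a non-negative, symmetric, zero-diagonal weight matrix over
named regions, each tagged `left`/`right`/`midline` and optionally paired
with its homotopic mirror (an involution across hemispheres). Near-symmetric
inputs (relative asymmetry ≤ 1e−6 by default, measured against the largest
entry) are symmetrized as `(A + Aᵀ)/2`; anything worse is rejected rather
than silently repaired, since tractography outputs are symmetric up to I/O
rounding only. The diagonal is forced to zero on load: self-connections are
undefined for fiber-density matrices. Functional matrices are Pearson
correlation matrices over the same node order; their diagonal is recorded
but excluded from every statistic.

Group-consensus weights keep an edge when it is present (weight strictly
> 0) in at least a `presence_fraction` of subjects (default 0.25) and
assign it the mean weight over **all** subjects, zeros included; averaging
over only the carrying subjects is available via `average="present"`. The
all-subject mean is the default because consensus matrices should preserve
the group-level expected density, not inflate edges carried by few subjects.

## Walk + CBOW embedding

Second-order biased walks: from current node *v* with predecessor *t*, the
unnormalized probability of moving to *x* is `w(v,x)·α`, where `α = 1/p`
for backtracking (`x = t`), `α = 1` when *x* neighbors *t*, `α = 1/q`
otherwise. Defaults `p = 0.1`, `q = 1.6` give a localized walk that revisits
its neighborhood often — the regime in which embedding geometry aligns with
community and role structure of brain networks. Each run generates 800
walks of 20 steps; starts cycle round-robin over non-isolated nodes in
label order, so per-node start counts differ by at most one (the per-node
interpretation, 800 walks *per node*, is available via
`WalkConfig(walks_per_node=True)`). The first step is first-order
(weight-proportional); sampling inverts cumulative distributions in a fixed
node order, which makes walks reproducible from the seed alone.

CBOW with negative sampling is implemented in-package (numba-compiled inner
loop): the target node is predicted from the *average* of the input vectors
within ±window (window 3); five noise nodes per position are drawn from the
unigram distribution raised to 3/4; the learning rate decays linearly from
0.025 over all updates; five passes over the corpus; no frequency
subsampling (with a vocabulary of ~100 node types, subsampling would
discard most of the corpus); every node is kept at minimum count 1. Input
vectors are initialized uniformly in `±0.5/D`, output vectors at zero, and
the input layer is returned as the embedding. Training is single-threaded
and bit-deterministic given the seed.

Ensembles: because stochastic training lands each run in a different
rotation/reflection of the embedding space, raw coordinates are not
comparable across runs; cosine similarities and ranks are. Per-run seeds
derive from one master seed through a seed sequence, making whole
ensembles reproducible. The reference analyses use 500 runs; the test
suite and acceptance script use 5–20 runs, which is already enough for
stable medians at the synthetic scale.

The baseline embedder is a Laplacian eigenmap: eigenvectors of the
symmetric normalized Laplacian for the `D` smallest nonzero eigenvalues
(unnormalized variant behind a flag). Isolated nodes receive zero vectors;
column signs are fixed so the largest-magnitude entry is positive.

## Analogies

One task per unordered pair of homotopic pairs, oriented right→left by
default: predict left-A from `vec(R·A) − vec(R·B) + vec(L·B)`; 41 pairs
give C(41,2) = 820 tasks. Candidates are ranked by decreasing cosine
similarity; the three operand nodes are excluded from candidacy (the
word-embedding convention; inclusive mode behind a flag), and the 0-based
rank of the expected node is logged. Across an ensemble the per-task
*median* rank is used; for even run counts the lower central value is
taken so medians stay integral and bin membership (bins of width 5) is
unambiguous. Method comparisons use the Pearson chi-square on the 2×2
top-5 table *without* continuity correction, which reproduces the printed
group statistics (223.0, 68.6) exactly from the printed counts.

Chance level: the homotopic pairing is shuffled (a random bijection between
the hemispheres' pairing slots), tasks are re-enumerated against the
shuffled pairing, and the top-5 proportion recomputed; 1000 shuffles give
an empirical permutation p-value with resolution 1/1001.

## Reconstruction statistics

The embedding reconstruction is the pairwise cosine matrix; for ensembles,
the element-wise mean across runs (cosine structure is stable across runs,
so the mean is a low-variance estimator; single-run mode is available).
Z-scoring of a symmetric matrix uses the upper-triangle off-diagonal
entries, zeros included, with the sample (n−1) standard deviation, mirrored
back to symmetry. Homotopic enrichment is the fraction of mirror pairs
whose z-scored edge exceeds a threshold. Rank correspondence uses Spearman
correlation over upper-triangle entries, optionally restricted to direct
(structural weight > 0) or indirect pairs; Fisher's z (atanh) is applied to
functional matrices before comparison, with clipping at ±(1 − 1e−7).
Nodal metrics are degree (nonzero-edge count), strength (weight sum),
eigenvector centrality (principal eigenvector of the weight matrix, L2
normalized, non-negative), betweenness with edge length 1/weight, and the
Onnela weighted clustering coefficient.

## Structure → function mapping

Each unordered node pair is an observation: features are the Hadamard
product of its two node vectors, the target its (Fisher-z, by default)
functional value. Edges are split 75/25 into train/test (the test set is
the floor of the fraction, e.g. 851-of-3403 at 83 nodes when a quarter is
held out). The deep regressor defaults to the reference protocol — four
fully connected hidden layers of 350 rectified-linear units, minibatch
140, 170 epochs, Adam, squared-error loss, no early stopping. It is backed
by scikit-learn's `MLPRegressor`, which has no dropout layer; the
`dropout` field of `MLPConfig` is retained for the record and the
regularizing role is played by the L2 penalty `alpha` (default 1e−4). The
baseline is ordinary least squares on the same features (minimum-norm
solution when rank-deficient). Evaluation reports held-out Spearman rho
(with MSE) overall and within direct/indirect strata.

The synthetic recovery experiment plants `FC(i,j) =
tanh(γ·ŵᵀ(uᵢ⊙uⱼ)) + ε` on ground-truth latent vectors and regresses on
the *raw* correlation scale: the Fisher transform is the inverse of tanh,
so a Fisher-z target would linearize the planted map exactly (making OLS
optimal by construction) and would amplify noise near |r| = 1. On the raw
scale the MLP must learn the curvature and beats OLS on held-out MSE. The
gain γ scales the pre-noise index to standard deviation 1.5 so the tanh
nonlinearity is material.

## Lesion pipeline

A node lesion zeroes its matrix row and column. Pre- and post-lesion
connectomes are embedded as separate ensembles; a walk started at the
lesioned (now isolated) node emits a length-1 walk, so its vector stays
near initialization. Because each run is rotated differently, comparing
predictions requires a mapping that is invariant to initialization: edges
are split into folds (3 by default) and the ensemble into train/test runs
(90/10, repeated 3 times); for every fold × split combination one
regressor is trained on {training edges × training runs} stacked rows —
forcing it to rely on rotation-stable feature structure — and applied to
held-out edges with held-out runs' features, from the pre-lesion and,
with identical models, the post-lesion ensemble. Training only ever sees
pre-lesion embeddings. Folds and splits are fully crossed.

Per edge, the observed difference `Δ = mean(pre) − mean(post)` is compared
with a permutation null: pooled values are label-permuted (independently
per edge, one seed stream) and the edge is flagged only if Δ exceeds
*every* permuted difference in its direction — an exceedance probability
below 1/n_permutations, uncorrected, per the max-null convention. With
`post := pre` this yields exactly zero flags (Δ = 0 cannot exceed the null
maximum; all-tied edges are never flagged). A node's degree difference
counts its incident flagged edges per direction. Note the test's power
depends on the per-edge prediction-set size: with very few held-out
(run × split) predictions per edge the sampled permutations can recreate
near-observed groupings and the max-null is never exceeded; the defaults
(150 predictions per condition at full scale) avoid this, and the reduced
test configurations keep ≥ 9 per group.

The edge universe is all C(N,2) unordered pairs, matching the functional
matrix (at 83 nodes, 3403 edges — fold sizes of roughly 2269/1134).

## Synthetic generator

One hemisphere is a stochastic block model (4 contiguous modules over 41
nodes; within/between edge probabilities 0.7/0.15) with log-normal(0, 1)
weights, mirrored *exactly* onto the other hemisphere; homotopic pairs get
a direct edge with probability 0.8 at twice the weight scale (callosal
homotopic connections are frequent and strong); non-homotopic
cross-hemisphere edges appear with probability 0.05; an optional midline
node connects anywhere with probability 0.2. Ground-truth latent vectors
for the planted FC map are the SVD-compressed rows of the weight matrix,
so functional structure is a genuine (but hidden) function of structure;
noise is Gaussian on the correlation scale, clipped inside (−1, 1).

What passing synthetic tests shows: the walk model matches its exact
transition distributions; the embedding geometry recovers planted homotopy
(analogies, deleted-edge inference) above baseline and chance; the mapping
machinery recovers a planted structure→function relation and degrades
gracefully with noise; the lesion statistics are correctly calibrated
under the null. What it does not show: performance on real tractography
(distance-dependent wiring, spatial geometry, false-positive edge
structure, biophysical FC dynamics are all absent), nor anything about
specific brain systems.

In the homotopic-link inference benchmark, control deletions are matched
on the hemisphere-crossing property (random *inter-hemispheric*
non-homotopic edges): within-hemisphere edges sit inside modules whose
endpoints share most of their neighbors and are reconstructed trivially,
which would confound the comparison for reasons unrelated to homotopy.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` run at reduced scale chosen to
keep the statistics stable: 20-run ensembles for analogy recovery (1000
pairing shuffles), 5-run ensembles across 10 seeds for homotopic
inference, a 2×128 MLP at 80 epochs for the recovery grid, 8-run
ensembles with 2 folds × 2 splits for the lesion null, and 2000
permutations (resolution 1/2001) for the calibration check. All stages are
bit-deterministic given their seeds under single-threaded execution;
ensemble stores and manifests round-trip through text at `%.17g`
precision, which is exact for float64.

## Known limitations

- `MLPRegressor` provides no dropout; heavy over-parameterized
  architectures rely on L2 and early data abundance instead.
- The CBOW trainer is single-threaded by design (determinism over speed);
  500-run full-scale ensembles take minutes, not seconds.
- Spectral embedding of graphs with fewer than `D` nonzero Laplacian
  eigenvalues (very small or highly disconnected graphs) is rejected
  rather than padded.
- The permutation test draws permutations independently per edge; edge
  statistics are therefore exchangeable but not jointly corrected beyond
  the per-edge max-null rule.
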