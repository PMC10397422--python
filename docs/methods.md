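# Methods

## Model and assumptions

The package treats DTI prediction as supervised link prediction on a
bipartite heterogeneous network: nodes are drugs and protein targets, edges
are experimentally known interactions, and each node carries a biological
feature vector. Three assumptions underpin the design:

1. **Homophily through the interaction graph.** Molecules that share
   interaction neighborhoods are likely to share interaction partners, so
   propagating node features along the graph enriches them with predictive
   context.
2. **Heterogeneous smoothing demand.** The right propagation depth differs
   per node: hubs sit close to the graph's stationary state after a step or
   two, peripheral nodes need many steps. A single global depth either
   starves the periphery or over-smooths the core.
3. **Sequence and structure carry signal.** Protein 3-mer composition over
   chemical categories and molecular substructure fingerprints correlate
   with interaction behavior.

### Propagation operator

The operator is Ā = (D+I)^(r−1)(A+I)(D+I)^(−r). Self-loop augmentation
(A+I, D+I) is load-bearing: on a bipartite graph without self-loops the
powers of the normalized adjacency oscillate between the two node sets and
never converge; with self-loops the walk is aperiodic and Ā^k converges to
the closed form with (d+1)-weights per connected component. The degree
d_i is always the degree in A; the self-loop enters only via the +1 terms.

`r` interpolates between row-stochastic (r = 0) and column-stochastic
(r = 1) normalization; the default r = 0.5 is the symmetric convention,
under which Ā is similar to a symmetric matrix and its spectral analysis
(and the stationary formula for every r) follows from
Ā^k = D̃^(r−1/2) S^k D̃^(1/2−r) with S = D̃^(−1/2)ÃD̃^(−1/2).

### Depth selection and smoothing

For node i the influence distribution at depth k is row i of Ā^k (with
identity weights and activation, the Jacobian of X^(k) with respect to
X^(0) collapses to exactly these entries). The depth
k_i = min{k ≥ k_min : ‖Ā^(∞)_i − (Ā^k)_i‖₂ < ε} is found by one shared
power sweep for all nodes; the embedding is the arithmetic mean of the
propagation trajectory X^(0..k_i) per node, accumulated in the same sweep.

Parameters, defaults, and why:

| parameter | default | meaning |
|---|---|---|
| ε | 1e-4 | distance-to-stationarity tolerance; smaller → deeper smoothing |
| k_min | 1 | floor; depth 0 would return raw features unpropagated |
| k_max | 200 | truncation guard for slow-mixing components; truncation is flagged, not raised |
| r | 0.5 | symmetric normalization |

The stationary row is always the closed form (exact and O(|V|) per node),
never an iterated estimate. On graphs with weakly coupled dense blocks the
spectral gap can be so small that ε = 1e-4 is unreachable within k_max;
depths then truncate at k_max and the NDLS embedding approaches the deep
fixed-depth one. This is a real regime of the method, visible in the
diagnostics below.

### Initial features

- **Drugs**: RDKit Morgan fingerprints (radius 2, 1024 bits), reduced to
  d = 64 by a one-hidden-layer autoencoder (logistic encoder, linear
  decoder, squared-error reconstruction, Adam, 200 epochs, seeded) whose
  hidden activation is the embedding. A deterministic exact-SVD reducer is
  available (`reducer="truncated-svd"`) for bit-reproducible runs; when
  d exceeds the number of molecules the extra SVD dimensions are zero.
- **Targets**: sliding 3-mers over the 4-category conjoint alphabet
  (non-polar G A V L I F P; polar-neutral W S Y C M N Q T; acidic D E;
  basic K R H), counted and normalized to frequencies (counts available
  via `normalize=False`). Non-standard residues (X, B, Z, U, \*) are
  dropped before windowing, with a logged count.
- **Scaling**: the stacked matrix C is L2 row-normalized before
  propagation. Without this the drug block (entries ~0.5) outweighs the
  target block (frequencies ~1/64) by ~30× and propagation lets one
  modality drown the other; this materially degrades prediction and is the
  package's own choice where the literature is silent.

### Classifier

sklearn's `GradientBoostingClassifier` behind `GBDTPairClassifier`
(T = 500 trees, learning rate 0.1, depth 3, seeded — ordinary settings for
a few-thousand-sample binary task; none of these are reproduction targets).
Pair features are `[X_drug, X_target]`, fixed block order. Calls use a
strict `score > cutoff` rule at cutoff 0.5; rankings break score ties by
(drug_id, target_id) to stay deterministic.

## Evaluation protocol

Negatives are sampled uniformly without replacement from non-interacting
pairs (ratio 1:1, or 1:10 for the imbalanced protocol). Folds are
stratified by label (per-fold positive fraction within one pair of
global). By default each fold's positive test edges are **masked out of
the adjacency before smoothing**, so embeddings cannot leak held-out
labels through the graph; `mask_test_edges=False` reproduces the simpler
full-graph protocol common in the literature. AUC/AUPR come from sklearn's
ROC/average-precision implementations, cross-checked in the test suite
against independent enumeration oracles; F1 is computed as
2TP/(2TP+FP+FN) with a 0/0 → 0 convention.

Diagnostics:

- **MAD** — mean over nodes of the mean cosine distance (1 − cos) to all
  other nonzero rows; in [0, 1] for non-negative embeddings, lower = more
  over-smoothed. This is the all-pairs form; the masked-neighborhood
  variant from the GNN literature is not implemented.
- **IQR dispersion** — Q3 − Q1 (linear-interpolation quartiles) of a pair
  vector's elements; for sets of vectors, mean ± SD of per-vector IQRs.
- **Paired Wilcoxon** — two-sided signed-rank p-value for per-round metric
  comparisons; all-zero difference vectors are reported as undefined (NaN).

## Synthetic benchmark

`SyntheticConfig` plants a block structure: drugs and targets belong to g
latent groups; a pair interacts with probability p_in within a group and
p_out across. Target sequences over-sample the residues of one chemical
category per group (weight 4 vs 1), so sequence features correlate with
graph structure; drug molecules come from a fixed 72-entry catalog of
small valid SMILES and carry no group information — the drug side of the
signal must come through the graph.

Defaults (80 drugs, 64 targets, g = 8, p_in = 0.5, p_out = 0.002,
sequence lengths 50–250) give ~350 interactions and an intrinsic
(group-oracle) separability of about 0.95 AUC, a desk-scale stand-in for
benchmarks on which graph-based predictors reach mid-0.9 AUC. What the
generator does **not** emulate: realistic molecular chemistry shared
within a community, degree heavy tails, sequence homology beyond
composition bias, and correlated (non-uniform) negatives. A green
learnability test therefore establishes that the pipeline recovers planted
community structure through the graph + feature channels — not that it
would attain any particular accuracy on curated interaction databases.

## Numerical choices and degenerate inputs

- Stationary rows per connected component (components of A+I); an isolated
  node's row is its own indicator, and its depth is the k_min floor.
- Duplicate interactions deduplicate silently; unknown ids in an edge list
  are errors naming the pair; molecules that fail SMILES parsing and
  sequences with <3 standard residues are errors naming the row.
- A complete bipartite graph has no negatives to sample: empty set with a
  warning. Requests beyond the non-edge universe return the whole universe
  with a warning.
- Single-class label vectors leave AUC/AUPR undefined (NaN + warning)
  rather than raising.
- All randomness flows through explicit integer seeds; the autoencoder is
  seed-deterministic, and the SVD reducer is fully deterministic.

## Known limitations

- The L2 depth criterion compares against the exact stationary row, so on
  slow-mixing graphs most depths saturate at k_max; ε should be loosened
  (or k_max raised) for such inputs.
- Prefix averaging weights every layer equally; no learned or decaying
  layer weighting.
- The GBDT sees concatenated embeddings only; no explicit pair-similarity
  features.
- Cold-start molecules (no parseable SMILES / usable sequence) cannot be
  embedded and are rejected up front.
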