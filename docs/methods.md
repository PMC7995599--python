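# Methods

## Problem and data model

The package predicts unobserved miRNA–disease associations from three
inputs: a binary association matrix `A ∈ {0,1}^{m×n}` (rows miRNAs, columns
diseases, indexed in first-appearance order of the pair list), a collection
of per-disease ancestor DAGs (MeSH-style, parent→child edges pointing
toward the target disease), and a dense miRNA functional-similarity matrix
FS. All files are plain TSV; the DAG dialect is a flat
(disease, parent, child) edge list because only the graph structure is
needed, not MeSH descriptor records.

## Similarity stack

Disease semantic similarity uses two variants over each DAG.

* Variant 1: the target contributes 1 and each ancestor `d` contributes
  `max{Δ·C(d′)}` over its children `d′` within the DAG. Δ (default 0.5,
  unitless, in (0,1)) controls how fast contribution decays with distance
  from the target. The semantic value DV is the sum of contributions.
* Variant 2: every node contributes the information content
  `−log(#DAGs containing d / #diseases)`, shared by all targets. The
  denominator is the size of the supplied collection (the study's own
  disease set, not all of MeSH). The log base is irrelevant: changing base
  rescales numerator and denominator of the similarity identically; a test
  asserts this invariance. Natural log is used. The target disease itself is
  scored by the same formula (no special case), so variant 2 of a disease
  appearing in several DAGs is informative rather than pinned at 1.

Both variants score a pair by summed shared-ancestor contributions over
summed semantic values; SS is their arithmetic mean with unit diagonal. In
the degenerate case where every node of both DAGs appears in every DAG
(all variant-2 contributions zero), the variant-2 similarity is defined as
0 off-diagonal.

The Gaussian interaction-profile kernel is
`K(i,j) = exp(−α‖IV_i − IV_j‖²)` with `α = α₀ / mean‖IV‖²` (α₀ default 1),
applied to rows of A for miRNAs (GM) and columns for diseases (GD). The
integrated networks select the primary source where it is defined — SS
where both diseases have DAGs, FS where both miRNAs appear in FS with a
positive entry — and the kernel elsewhere. Diagonals are forced to 1.

## Heterogeneous network and meta-paths

Kernel similarities are strictly positive everywhere, so a sparsifier is
needed before any graph is meaningful. Default: each node keeps its top-k
most similar neighbours (k configurable; ties broken by name), the edge set
union-symmetrized; a plain threshold rule is also available. MD edges are
exactly the 1-cells of A.

Meta-path instances between a miRNA and a disease are enumerated
exhaustively up to `l_max` edges (default 3) as simple paths; a
bounded-walk mode (`allow_revisits`) exists but is off by default since
node repetition adds no information. All three edge kinds are traversable
by default. Enumeration order is deterministic (length, then node
sequence), and enumeration from one miRNA to all diseases shares a single
DFS for speed.

Two deviations from a naive reading were necessary for the method to work
as a predictor rather than a memorizer:

* **Target-edge masking** (`exclude_direct`, default on): a pair's own
  association edge is excluded from its instance set. Without this, every
  training positive carries a length-1 instance that no held-out pair can
  have, and the node branch collapses to a "has direct edge" detector that
  scores at chance on held-out pairs.
* A per-type **instance cap** (default 20; the desk-scale preset uses 16)
  bounds the tensor sizes fed to the GRU; instances are kept in the
  deterministic enumeration order.

## Neural architecture

Raw features are the corresponding rows of SM / SD. Projections `W^R
(Z×m)` and `W^D (Z×n)` map both to a shared Z-space. The pair branch embeds
`[h_r ; h_d ; h_r∘h_d ; h_r+h_d]` with an MLP (hidden width 100, ReLU,
dropout; affine last layer) and scores validity with a 2-layer head π;
`Loss_N` is standard binary cross-entropy (the likelihood form without
logs would be degenerate to minimise).

The node branch runs a GRU over each instance's projected node features
(zero initial state), with dropout applied to the update candidate:
Bernoulli(1−q) mask during training and (1−q)-scaling at evaluation —
note this is non-inverted dropout, so evaluation activations are scaled
rather than the training ones. Node states are pooled by K attention heads
(default 4) whose outputs are averaged; instances of one meta-path type are
fused by softmax attention over ReLU scores with an elementwise sigmoid on
the weighted sum; types are fused the same way without the sigmoid. The
grouping key is the full node-type string, not just the length. One width
X = Z is used throughout (the full-scale default is 256); the two
can be set independently for ablations. A pair with no instances
contributes a zero node embedding and trains through the pair branch alone.

`Loss_M` is the negative-sampling cross-entropy of a trainable linear
logit on the fused node embedding, mean-normalised per batch. The total
objective is `Loss_N + λ·Loss_M + (1−λ)·Loss_reg` with λ = 0.5 and
`Loss_reg` the weight-decay functional (coefficient × Σ‖θ‖²; setting the
coefficient to 0 removes it exactly). Signs follow the standard
negative-log-likelihood convention.

The final score is `σ(w·[h_node ; g_pair] + b)` with a trainable head.
The head is fitted jointly but as a *stop-gradient probe*: its cross-
entropy is added to the optimised scalar while its inputs are detached, so
the representation is shaped only by the objective above and the probe
merely learns how to weigh the two branches. Disabling the pair branch
(ablation) drops `Loss_N` and feeds the probe zeros in place of `g_pair`.

## Optimisation

Training is full-batch Adam on a purpose-built reverse-mode autodiff
engine over numpy arrays (the operator set is exactly what the model
needs; gradients are validated against central finite differences to
1e−4 relative error). With one optimiser step per epoch a learning rate of
0.02 (package default) replaces the 1e−3 typical of minibatch training.
Negatives are resampled fresh every epoch, uniformly without replacement
from the current zero cells at ratio 1:1 — over a run the model therefore
sees the whole unconfirmed set, which measurably improves held-out ranking
versus a fixed negative sample. Parameters are Glorot-uniform under the
run seed; runs are bitwise reproducible (single-threaded numpy).

Defaults: 100 epochs, λ = 0.5, weight decay 1e−4, dropout 0.5, embedding
width 256. The desk-scale preset (`TrainConfig.desk_scale()`) used by the
package's own studies narrows this to width 16, dropout 0.2, 120 epochs,
instance cap 16 and top-k 8, sized so one fit takes tens of seconds on a
single CPU; it was fixed once after a small grid on a single held-out
split and used unchanged thereafter.

## Evaluation

AUC is the Mann–Whitney statistic with half-credit for ties. Repeated
k-fold CV partitions the confirmed pairs (near-equal random folds),
zeroes each held-out group in A *before* similarity, network and meta-path
construction — kernels GM/GD depend on A, so anything less leaks — and
ranks held-out positives against all unconfirmed pairs. Global LOOCV is
offered in a scaled mode that retrains once per disjoint block of held-out
positives (block size 1 on a subsample reduces to true leave-one-out).
The new-disease protocol zeroes a disease's entire column before training
and ranks all of its miRNAs against the original labels.

## Synthetic benchmark: what it shows and what it cannot

The planted benchmark links all three inputs through matched blocks:
associations are Bernoulli(p_in = 0.35) within matched (miRNA, disease)
blocks and Bernoulli(p_out = 0.02) elsewhere, with 1% of cells flipped as
noise (m = 60, n = 40, 4 blocks); FS is high within miRNA blocks and
undefined on a random 30% of pairs (exercising the kernel fallback);
disease DAGs share block-level ancestors drawn from a common layered term
pool. Everything regenerates bitwise from a seed.

Because within-block cells are i.i.d. given the blocks, they are
statistically exchangeable: no scorer, however good, can rank a held-out
within-block positive above a within-block true negative except by chance.
The Bayes-optimal scorer is the block oracle, which measures ≈ 0.81–0.82
AUC under the package's evaluation protocol at the default densities
(≈ 22% of positives are out-of-block p_out/noise draws and essentially
unrankable). The trained model reaches ≈ 0.75 (5-fold mean) and ≈ 0.71
(new-disease), i.e. most but not all of the oracle gap; the pair-embedding
ablation costs ≈ 0.05 AUC, and restricting meta-paths to length 1 costs a
small margin. Passing benchmark tests therefore demonstrates faithful
mechanics and directional behaviour, not the absolute AUC levels
reported on real association databases, where block structure is only an
approximation and similarity carries finer-grained signal.

## Known limitations

* Exhaustive enumeration scales with degree^l_max; real-scale networks
  need the top-k sparsifier kept modest (the defaults).
* Full-batch training holds every instance tensor in memory; at
  HMDD scale (495×383, thousands of positives) a run is minutes-to-hours
  on one CPU, and the full-scale width of 256 multiplies that further.
* The softmax fusions normalise away meta-path *counts*; only the
  composition of paths informs the node embedding. On data where counts
  themselves are the signal, much of it is inaccessible by design (a raw
  path count scores ≈ 0.79 AUC on the default benchmark by itself).
* Non-inverted dropout means evaluation activations are (1−q)-scaled;
  comparisons across q values should be done at fixed mode.
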