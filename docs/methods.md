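# Methods

## The prediction problem

DNA shape features are per-position geometric descriptors of the B-form
double helix. Intra-base-pair features (Shear, Stretch, Stagger, Buckle,
ProT, Opening) and groove features (MGW, EP) take one value per base pair of
an n-mer; inter-base-pair (step) features (Shift, Slide, Rise, Tilt, Roll,
HelT) take one value per dinucleotide step (n−1 values). Translations are in
Å, rotations in degrees, electrostatic potential in kT/e. Each feature has a
fluctuation ("-FL") companion quantifying its spread across a conformational
ensemble; the package stores fluctuation values as opaque nonnegative reals
because ensemble spreads are reported inconsistently (SD vs. variance) across
data sources, and nothing downstream depends on which convention the
training data used.

The modelling assumption is that the shape at a position is determined by
its local sequence context and that flank influence weakens with distance.
The model makes that assumption structural: flanking context enters one base
pair at a time, layer by layer, so the trade-off between context size and
data support is explicit rather than hidden in a k-mer table's coverage.

## Architecture

Nodes are bases (4 one-hot channels) or steps (16 channels, alphabetical
`AA..TT` order); `N` encodes as the uniform average of its compatible pure
encodings, so every encoding row sums to 1. One uniform `N` cap node is
attached at each end; a cap's missing outer neighbour is the cap itself.
Self-linked caps give terminal bases two neighbours like interior bases and
a boundary fixed point under arbitrarily deep message passing, which is why
one cap per side suffices. For step graphs the caps are "N-step" nodes
(uniform 16-vectors); whether a cap should instead pair with the first real
base was an open interpretive point — the pure-N self-linked step node was
chosen because it keeps cap semantics identical for both node kinds.

The *self layer* is a width-1 convolution (position-wise linear map, no
nonlinearity) from the input channels to `filter_size` (F) channels. Each of
the L *shape layers* then computes, per node i,

    λ = W1·X[i−1] + W2·X[i+1] + b1          (F-vector)
    α = T1·X[i−1] + T2·X[i+1] + b2          (F-vector)
    u = batchnorm(relu(λ ⊙ X[i] + α))
    X̃[i] = GRUCell(input = u, state = X[i])

Conventions fixed here (the mixing recurrence admits several readings of the
same symbols; these are this package's choices, documented so that weights
are interpretable):

* the neighbour-mix weights W1, W2, T1, T2 are F×F matrices, so λ and α are
  F-vectors and `λ ⊙ X[i]` is an elementwise product. The alternative —
  rank-3 tensors making λ itself a matrix — costs F³ parameters per weight
  and was rejected; at equal parameter budgets the two parameterizations did
  not differ in what the tests require of the model.
* GRU: z = σ(W_z u + U_z h + b_z), r = σ(W_r u + U_r h + b_r),
  candidate c = tanh(W_c u + U_c (r⊙h) + b_c), new state
  (1−z)⊙h + z⊙c, with h = X[i].
* batch normalization sits after the ReLU, is per-channel over all nodes of
  a mini-batch during training (momentum 0.9, eps 1e−5), and uses frozen
  running statistics at inference, so prediction is deterministic.
* the per-layer head is tanh **of the channel mean** (not the mean of
  per-channel tanh): this guarantees the single emitted value is strictly
  inside (−1, 1), which is what makes denormalized predictions provably
  bounded by median ± (p99 − p1).
* dropout (inverted scaling) is applied once to each layer's output feature
  vectors during training; both that layer's head and the next layer consume
  the dropped tensor. Inference never drops.

Because layer k's node update reads only neighbours at distance 1, the head
of layer k depends on at most k nodes of context on each side — exactly k bp
for per-bp features. On step graphs a substitution at one bp touches two
adjacent step nodes, so the bp-radius of depth k is k+1; radii are always
reported in bp with this convention. `receptive_radius` measures the radius
empirically by perturbation probing (random sequences, all substitutions at
increasing distance, threshold 1e−10 on the prediction change) rather than
trusting the architecture.

The whole network is plain numpy with hand-derived reverse-mode gradients;
a finite-difference check (central differences, 1e−4 relative, toy input)
runs in the test suite.

## Normalization

Targets are normalized as Ŝ = (S − median) / (p99 − p1) with the median and
the 1st/99th percentiles pooled over all defined training values
(linear-interpolation percentile convention, so stats files reproduce
bit-exactly). Note the denominator: the difference is taken ascending
(p99 − p1) so that normalization is orientation-preserving and invertible —
a formulation with the subtraction written the other way round would flip
the sign. Values outside [−1, 1] can occur for extremes and are left as-is;
the tanh head bounds *predictions*, not targets. Degenerate stats
(p99 = p1) are rejected. Stats serialize to JSON via `repr` (shortest
round-trip decimal, ≥ 17 significant digits).

## Training

Loss: mean over layers of the masked MAE (sum of absolute errors over
defined nodes / count of defined nodes); undefined positions (`NA` in
training files, e.g. groove width at terminal base pairs, margin default 2
for MGW/EP) contribute nothing. Supervising every layer head with equal
weight is what makes depth selectable at prediction time: each layer is
trained to be the best k-bp-context predictor, not an intermediate
representation. Optimizer: SGD with momentum (default 0.95), constant
learning rate, deterministic given (dataset, config, seed) — the seed drives
initialization (Glorot uniform; biases zero), epoch shuffling, and dropout.
Variable-length sequences are grouped by length into mini-batches (default
32) so no padding is needed and cap semantics stay exact. Non-finite loss
aborts with diagnostics.

Published operating point (the `ModelConfig` defaults): 7 shape layers,
filter size 64, dropout 0.5, lr 0.05, momentum 0.95, 1500 epochs. A small
grid search over configs on a fixed train/validation split (default 90/10,
best = lowest deepest-layer validation MAE, first minimum wins ties) is
provided and mirrors how the operating point would be chosen on real data.

## Synthetic ground truth

The generator emulates the structure of simulation-derived training corpora:
~2000 variable-length sequences (default 2121, lengths 15–25), per-position
real values, NA-masked terminal margins, and flank effects that decay with
distance. A ground truth of radius R assigns

    value(i) = center[unit_i] + Σ_{d=1..R} contrib(d, side, base at i∓d)

with contributions drawn uniformly in ±A·γ^(d−1) (defaults A = 0.5,
γ = 0.6, center values spread ±1.5 around 5.0 in arbitrary units, chosen to
give flank effects a realistic fraction — roughly a quarter — of the total
value spread, as groove-width corpora show). Observation noise is Gaussian,
default sd = 5% of the noiseless value range. Fluctuation-style truths pass
the same additive latent through a softplus so emitted values are strictly
positive. Two structural consequences are exploited as oracles: a radius-R
truth is *exactly* a (2R+1)-mer table (so a pentamer table is optimal at
R = 2 and provably biased at R = 4), and edits beyond R provably change
nothing.

What the generator does **not** emulate: bimodal shape distributions,
correlated (non-i.i.d.) noise along a molecule, sequence-composition biases
of real simulation libraries (unless requested via `composition_bias`), or
any physical energetics. Passing the recovery tests therefore demonstrates
that the architecture and trainer can find a flank-decay signal of known
radius under realistic noise — not that predictions on real DNA are
accurate, which depends on the training corpus supplied.

A constrained-context sampling mode plants a chosen k-mer exclusively inside
one fixed context and scrubs accidental bare occurrences, reproducing the
classic failure mode where a query-table entry silently absorbs the flanks
it was always seen with; `flank_bias_report` quantifies this as the total
variation distance of the observed flanking-pair distribution from uniform
(0 balanced, 15/16 point mass).

## Desk-scale experiment sizes

The recovery experiments in the test suite and acceptance script run at a
reduced scale chosen once by validation-MAE grid search on the synthetic
problem: filter size 8, dropout 0, lr 0.08, batch 32, 200 epochs, 2000
training sequences, 300 held-out sequences evaluated against the noiseless
truth. Dropout 0 at this filter size: with 8 channels and ample data the
regularization that the published full-size configuration needs only slows
convergence. A depth-7 model trained this way reaches roughly a third of the
pentamer table's held-out MAE on a radius-4 truth; the per-layer validation
error is non-increasing up to layer R and flat beyond, matching the
selectable-depth design intent.

## Binding-specificity regression

Aligned records (sequence, relative affinity) are encoded as
position-specific k-mer indicators — 4n columns for 1-mers, 16(n−1) for
2-mers, 64(n−2) for 3-mers — plus per-position shape profiles from trained
models (n columns per per-bp feature, n−1 per step feature). Shape columns
are min-max scaled to [0,1] over the dataset by default (z-score available;
the normalization wording in the source literature fixes no single formula,
so both are exposed). Affinities are used as given, with an optional log
transform.

The ridge penalty is selected by nested CV: 10 outer folds (seeded,
shuffled); within each outer training set an inner 10-fold CV picks λ from a
13-point grid log-spaced 10⁻⁶..10⁶ by validation MSE (first minimum wins);
the refit model predicts its outer test fold. R² is the coefficient of
determination 1 − SSE/SST on the *pooled* out-of-fold predictions — not
squared Pearson — because folds are combined before assessment. Downstream
analyses: `aggregate_profiles` (affinity-sorted profile matrices, default
top 25%, optional per-affinity-bin mean curves) and `cap_scan` (all 4^c
cores between fixed caps when ≤ 65,536, else seeded sampling; per-position
quartiles with 1.5·IQR whisker bounds, the usual boxplot convention).

## Conventions and degenerate inputs

* Reverse-complement classes follow the standard helical-parameter
  convention: Shift, Tilt, Shear, Buckle flip sign under strand reversal;
  everything else, and every "-FL" feature (a spread is sign-independent),
  is invariant. The table is overridable in the registry because different
  sign conventions circulate.
* k-mer windows: odd k centred on a base for per-bp features; even k centred
  on the middle step (positions k/2−1, k/2) for step features.
* Missing k-mers predict NaN — no imputation by default (an interpolated
  table is precisely the bias the model exists to avoid); an explicit
  k−2-window fallback is available opt-in.
* Coordinates in emitted files are 1-based inclusive; step features are
  indexed by the 5' base of the step. Floats serialize as shortest
  round-trip decimals.
* Errors are raised for: non-ACGTN characters (position named), sequences
  shorter than the node kind or window allows, degenerate normalization
  stats, all-masked batches, double capping, depth outside 1..L, non-finite
  inputs.

## Limitations

* No encodings for modified or mismatched bases; helical-axis and backbone
  torsion features are not registered by default (the registry accepts
  them if training data is supplied).
* EP is treated as an opaque trainable feature; no electrostatics are
  computed, and no shape values are derived from 3D structures.
* The trainer is CPU-bound numpy; it is sized for corpora of thousands of
  short sequences, not genome-scale training (prediction, by contrast, is
  cheap and batched).
* Model artifacts (.npz) are portable across platforms but training
  bit-reproducibility is guaranteed only for a fixed BLAS/numpy stack.
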