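# Methods

## Candidate sites and window encoding

Every lysine in every input protein is a candidate site; sites listed
in the label TSV are positive, all other lysines are negative. A site
is encoded as the 33-residue window centred on the target lysine
(16 up- and downstream). Windows that overrun a sequence end are padded
with `X`, and `X` shares integer token 20 with every non-canonical
letter (B, J, O, U, Z); the 20 canonical residues map to tokens 0–19 in
alphabetical order (`ACDEFGHIKLMNPQRSTVWY`). The alphabet order is a
free convention — any fixed bijection would do — and alphabetical is the
reproducible choice. Positions are 1-based externally (UniProt
convention); window offsets are 0-based with the target at offset 16.

Class balancing keeps all positives and subsamples negatives without
replacement. The stratified train/validation split preserves the class
ratio within one record per class, and the imbalanced-evaluation-set
constructor keeps all negatives plus an independent random
⌈(1−r)·P⌉ subset of positives per set (default r = 0.9, 10 sets).

## Architectures

All three hybrids share the structure: token window → word-embedding
branch → 32 features; target-site PLM vector → MLP branch → 32
features; concat(64) → dense(32, ReLU) → dropout(0.3) →
dense(1, sigmoid).

Word-branch variants (all convolutions are zero-padded "same", so the
channel-axis concatenation of a residual block's input and output is
well defined; all pooling is max with stride = width 2 and floor length
division, 33 → 16 → 8):

* **conv** — conv(32, k=3) → pool → conv(64, k=3) → pool.
* **inception** — parallel conv(F=32) at k = 1,3,5,7,9,11 plus a
  stride-1 same-padded max-pool followed by a 1×1 conv(F), concatenated
  to 7F channels, then one pool.
* **resnet** — two blocks; a block is conv(F, k=3) → ReLU →
  conv(F, k=3) → ReLU, concatenated with the raw block input along
  channels (no post-concatenation activation). F = 32 then 64, so
  channels run 21 → 53 → 117.

Each branch ends with flatten → dense(32, ReLU) → dropout(0.3).

Several widths are not independent choices but are pinned jointly by
the requirement that the default resnet hybrid contain exactly 93,082
trainable parameters: head dense width 32, pool size 2, kernel 3 inside
residual blocks, the second conv of a block carrying the block's own
filter count, and biases everywhere. The layer-by-layer sum is

    441 + 2,048 + 3,104 + 10,240 + 12,352 + 29,984   (word branch)
  + 32,800                                            (MLP branch)
  + 2,080 + 33                                        (head)
  = 93,082

and the test suite checks this closed form against the runtime count
for all three variants and arbitrary configurations. Choices the
parameter count cannot pin and that remain open conventions: the
activation placement inside a residual block (ReLU after each conv,
none after the concat), kernel size 3 for the plain conv variant, 32
filters per inception branch, and dropout 0.3 on the MLP branch
(matched to the word branch).

## Training

Binary cross-entropy (probabilities clipped to [1e−7, 1−1e−7]) with
Adam at learning rate 1e-4 (β₁ = 0.9, β₂ = 0.999, ε = 1e-8). Defaults:
batch size 256, at most 100 epochs, early stopping on validation loss
with patience 10, best-validation-loss weights retained. Two
strategies:

* **end-to-end** (default): every weight, including the embedding
  table, is updated from the final loss;
* **branched**: each branch is first fitted under a temporary
  dense(1)+sigmoid head, the branches are then frozen (the run records
  the weights at the freeze point so the contract is checkable
  bitwise) and only the combined head is trained; the temporary heads
  are discarded.

Cross-validation uses stratified k-fold (default k = 10); folds train
for a fixed epoch budget with no early stopping, so no held-out
information leaks into model selection. The whole stack runs on
explicit NumPy generators: identical seed, identical run.

## Metrics

The eight reported metrics follow the standard confusion-matrix
definitions with `score ≥ threshold` counted as a positive prediction
(boundary inclusive). Zero-denominator conventions: precision 0 when
there are no positive predictions, MCC 0 when any marginal is empty.
AUROC is the Mann–Whitney statistic with midrank tie handling; AUPRC is
average precision (step interpolation) rather than trapezoidal PR
integration, which is biased when positives are few. Single-class label
vectors make the curve areas undefined; they are reported as missing,
never as a number.

## Feature-group comparison

Groups of unequal width are reduced to 10 columns each by per-group PCA
(centred, unscaled; fitted on training samples). mRMR uses the MID
(difference) scheme: first pick argmax I(f;y), then iteratively add
argmax [I(f;y) − mean_{s∈S} I(f;s)], with plug-in mutual information
after equal-width discretisation into 10 bins and ties broken by pooled
column order. The variant and estimator are package conventions (the
technique itself does not fix them), and the test oracle uses the same
definitions so the greedy path is checked end to end. Group importance
is summed split-gain from a seeded XGBoost classifier (300 trees,
depth 6, learning rate 0.1), normalised to sum to 1 over the pooled
matrix.

## Shapley attribution

Attribution is over the 33 token positions only; the instance's PLM
vector is held fixed inside the prediction function. Masked positions
take their values from background windows (default: 50 windows sampled
from the evaluation set), and a coalition's value is the mean model
output over the background set. The exact estimator enumerates all 2^m
subsets (m ≤ 14) with classical Shapley weights; efficiency holds to
machine precision. The kernel estimator solves the Shapley-kernel
weighted least squares with weight (M−1)/(C(M,|z|)·|z|·(M−|z|)) and the
efficiency constraint eliminated by substitution; when all 2^M − 2
proper coalitions fit in the sample budget it enumerates them and the
solve is exact, otherwise coalitions are sampled from the kernel
distribution (sampling frequency then carries the weighting).

Structural aggregation reads Cα coordinates from PDB ATOM records
(HETATM skipped, first altLoc conformer kept — Cα rather than Cβ or
closest-heavy-atom is the package's convention), computes Euclidean
Cα–Cα distances from each window residue to the target, and averages
|SHAP| in distance bins of 4 Å anchored at 0. The target offset is
excluded from binning (its distance is 0 by construction and its
attribution is structurally zero); empty bins are reported absent, not
zero.

## Synthetic data generator

The generator emulates exactly what the pipeline consumes: FASTA
sequences, a site-label TSV, and a keyed archive of per-residue
embedding matrices. Background residues are i.i.d. uniform over the 20
canonical amino acids; each protein is guaranteed a lysine. A fraction
of lysines (default 9%, matching the positive rate of curated
succinylation training sets, with balance achieved downstream by
undersampling) is marked positive, and each positive site receives, at
each motif offset (±1..±3), a draw from the motif alphabet {E,D,G,A}
with probability p (default 0.5) instead of background. Embedding rows
are Normal(0, σ²I) with σ = 1, except target rows of positive sites,
which are shifted by δ (default 1) along a fixed seeded unit vector u.
The truth JSON records u, δ and p so recovery tests are
self-contained. Defaults: 1,050 proteins of length 150–250 and
embedding width 64 (1024 is used where the full-width architecture is
pinned), which yields ≈2,000 balanced sites.

What the generator does not emulate: real succinylation sequence
statistics (position-specific residue preferences, physicochemical
context), the geometry of actual PLM embedding spaces, sequence
redundancy/homology structure, and label noise. Tests passing on this
fixture therefore demonstrate that the pipeline recovers a planted,
separable signal end to end — not that the model attains any particular
accuracy on biological data.

## Numerical and procedural conventions

* All randomness flows through `numpy` generators; the CLI fans one
  global seed out to per-component seeds via a fixed SHA-256 hash.
* Weight init: Glorot uniform for dense/conv, uniform(−0.05, 0.05) for
  the embedding table; biases zero.
* Flattening is position-major (irrelevant downstream of a dense
  layer).
* Classification threshold 0.5 unless overridden.
* The null-signal check (motif p = 0, δ = 0) is evaluated on an
  independently generated ~2,000-site fixture rather than the
  ~200-sample held-out split, keeping the sampling error of the AUROC
  estimate (~0.011) far below the 0.05 acceptance band.
* Problem sizes in the test suite are scaled to the smallest instances
  that still exercise each property (small proteins and embedding
  width 16 for harness tests; the full default fixture for the
  recovery checks).

## Known limitations

* The NumPy training stack is single-threaded and CPU-bound; it is
  sized for the ~93k-parameter models here, not for large-scale
  sweeps.
* PLM embeddings are consumed as precomputed archives; generating them
  (ProtT5/ESM inference) is out of scope, as are PSSM computation,
  redundancy filtering (CD-HIT) and structure prediction.
* Kernel-SHAP with sampled coalitions inherits the usual
  least-squares approximation error; the exact enumerator is limited
  to 14 positions.
* The imbalanced-validation evaluation and MLP-width sweep are exposed
  as building blocks (`make_imbalanced_validation_sets`, config lists)
  rather than as one-shot reproduction scripts.
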