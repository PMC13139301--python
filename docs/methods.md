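# Methods

## Problem and model

The package regresses a scalar compound–protein affinity (KIBA score or
pEC50) from two complementary views of each partner. The *local* view is
positional: a character-level label encoding of the SMILES (fixed length
100) and a residue-level encoding of the protein sequence (fixed length
1,000, A=1…Y=20 alphabetically, UNKNOWN=21, 0 reserved for padding), read
by embedding + stacked 1-D convolutions + global max pooling. The *global*
view is compositional: an ECFP4 (Morgan radius-2) fingerprint folded to
1,024 bits concatenated with a molecular-descriptor vector for the
compound, and a sequence-descriptor vector (amino-acid composition,
overlapping dipeptide composition, CTD) for the protein, each read by a
fully connected head. The four head outputs concatenate to a
1,216-dimensional joint representation (96 + 96 + 512 + 512 by default)
fused by a dense stack into one prediction.

The rationale encoded in the synthetic benchmark (below) is that affinity
can depend on *conjunctions* the individual views cannot see: a
substructure–motif match is invisible to composition-level descriptors,
while a bulk property interaction (e.g. molecular weight × hydrophobicity)
is invisible to short convolutional windows.

## Architectural choices

Only the 1,216 concatenation width and the two encoding lengths are fixed
constants of the design; per-head widths are configurable and validated at
build time (`ModelConfig` refuses head widths that do not sum to 1,216
unless explicitly marked nonstandard). Defaults: embedding 128; compound
convolutions 32/64/96 filters with kernels 4/6/8; protein kernels 4/8/12;
global heads one dense+ReLU layer of width 512; fusion stack 1024→512→1
with dropout 0.1. The last convolution's filter count must equal the local
head's output width because max-over-time pooling preserves channels.

The network is implemented directly on NumPy (float32) with explicit
backpropagation and Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8). Three numerical
conventions matter:

- **Padding masking.** The padding embedding row is frozen at zero,
  post-ReLU activations at positions beyond a row's last real token are
  zeroed after every convolution, and the max pool ignores those positions.
  Local head outputs are therefore *exactly* invariant to trailing-padding
  length, and batches are internally trimmed to their longest real sequence
  — an exact optimization, not an approximation.
- **Convolution layout.** Each convolution right-pads its input by
  (kernel − 1) zeros and applies a valid convolution, so sequence length is
  preserved through the stack and a sequence shorter than a receptive field
  still yields defined outputs.
- **Inference determinism.** Dropout is inverted dropout applied only
  during training; prediction is deterministic and batch-size invariant (to
  float32 accumulation order, tested at 1e-5).

Checkpoints are a zip of per-parameter `.npy` arrays plus a JSON header
carrying the config and the fitted featurizer (vocabulary, postprocessor
statistics); loading validates every shape and names the offending
parameter on mismatch.

## Feature preparation

SMILES are encoded as written (no canonicalization before label encoding —
canonicalization would change string lengths unpredictably), with
character-level tokens, so two-character element symbols (Cl, Br) split
into two tokens; fingerprints are computed on the parsed molecule and are
therefore spelling-invariant. The vocabulary is built from the characters
of the training-split compounds, sorted, indices from 1; unseen characters
at transform time map to UNKNOWN with a warning.

Descriptor matrices pass through a postprocessor fitted on training rows
only: columns with any non-finite value *or zero variance* (z-scoring a
constant is undefined) are dropped; survivors are z-scored with training
mean/sd; non-finite values appearing later are imputed with the training
mean (0 after scaling). Whether to standardize at all is a genuine open
choice; we standardize because the two global blocks (0/1 fingerprint bits
and unbounded descriptors) otherwise differ in scale by orders of
magnitude.

Descriptor computation is a provider contract (`names` + `compute`). The
built-in compound provider is a ~20-column RDKit panel (counts, MW, logP,
TPSA, etc., first entry the heavy-atom count); the built-in protein
provider emits AAC (20) + dipeptide composition (400) + CTD (147) = 567
columns. CTD uses the standard seven attribute groupings with three classes
each (tables frozen as constants and asserted to partition the alphabet);
distribution descriptors report the fractional position of the first
occurrence and of the 25/50/75/100% occurrence quantiles (ceil convention),
zeros for absent classes. Wider externally computed matrices (e.g. full
autocorrelation/QSO/PseAAC panels) plug in through the same contract — the
model accepts any fixed width.

## Training protocol

Interactions are shuffled once per seed and partitioned into ⌊n/6⌋ test
rows plus five CV folds over the remainder (sizes differing by at most 1).
One shared test set is used across folds. Training uses Adam at 1e-3
(default), batch 256, early stopping on validation MSE with patience 5
(training stops `patience` epochs after the last improvement; the
best-validation weights are restored). Per-fold metrics are aggregated as
mean ± sample (n−1) standard deviation.

Fine-tuning continues training *all* layers of a pretrained model at 1e-4
(default) on the target task, reusing the output head; an optional
`freeze="local"` mode updates only the global heads and fusion stack. The
descriptor postprocessors are refitted on the target training rows while
keeping the column identities fixed by pretraining, so the model's input
width never changes; columns degenerate on the target retain their source
statistics.

Metric edge cases raise explicit errors rather than returning sentinels:
CI with an all-tied observed vector, R²/PCC with a constant vector.

## The synthetic benchmark

The generator emulates a CPI table with a planted signal

y = b + w₁·1[S ⊂ compound]·1[M ⊂ protein] + w₂·z(MW)·z(hydrophobic fraction) + ε

with defaults b = 5 (pEC50-like level), w₁ = 2, w₂ = 1, σ = 0.25, compound
motif S the carboxyl cap `C(=O)O`, protein motif M the 5-mer `HKWYR`
(probability 20⁻⁵ per site by chance). SMILES are assembled from a fragment
grammar (alkyl chains, benzene, amide linkers, optional carboxyl cap)
chosen so every string parses and no fragment junction can spell the motif;
proteins are uniform random sequences of length 50–200 with the motif
substituted in for half of them. z(·) is the z-score over the generated
population; ground-truth signal components are stored with the dataset so
tests can recompute labels exactly at σ = 0.

What the generator does *not* emulate: real KIBA score distributions,
kinase sequence families, chemotype clustering, assay noise structure, or
train/test distribution shift between related targets beyond a simple
re-weighting of the same signal. Passing benchmarks therefore demonstrate
that the implementation can learn the kind of joint local+global structure
the architecture was designed for — not that it attains any particular
accuracy on real bioactivity data.

Benchmark scales were chosen to keep the full pipeline comfortably
CPU-scale: learnability uses 200 compounds × 20 proteins at density 0.5
(2,000 pairs, σ = 0.25) with the default model for ≤ 30 epochs; the
transfer benchmark pretrains once on that source task and compares
fine-tuning against from-scratch training on a 245-pair target task
(shifted b = 6.5, w₁ = 1.2, w₂ = 0.6, same motifs) across five seed
replicates of the target split — the pretrained model is shared across
replicates since the comparison varies the target-side randomness. The
zero-noise cross-validation benchmark uses 400 pairs with a narrow
(nonstandard) model of the same topology.

## Screening cascade

`select_top_fraction` keeps ⌊fraction·n⌋ rows (floor; 31,080 → 3,108 at
10%), breaking score ties at the cut by compound id for determinism.
`apply_candidate_filters` reads "below 5 stars" and "under −7 docking" as
strict inequalities (boundary rows excluded; an inclusive mode is provided
for parity with tools that include the boundary). Rows missing either
property are dropped and counted. Lipinski violations use the standard
inclusive limits (MW ≤ 500, logP ≤ 5, HBD ≤ 5, HBA ≤ 10 are compliant).
Docking scores and #stars are consumed from external tables, never
computed.

## Known limitations

- Single-output regression only; no classification mode, no attention or
  interpretability layers.
- The NumPy implementation targets CPU-scale problems (10³–10⁴ pairs);
  hundred-thousand-pair benchmarks would want a GPU framework.
- First-wins deduplication is the only aggregation policy for replicate
  (compound, protein) measurements.
- Character-level SMILES tokenization splits Cl/Br; the local compound
  head sees them as two tokens.
- CI is computed by exact O(m²) pair enumeration (chunked); adequate for
  test-set sizes here, quadratic for very large m.
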