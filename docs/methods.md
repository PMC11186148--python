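# Methods

## The problem

A SMILES string is a linear spelling of a molecular graph. Unlike a natural
language sentence, most of its symbols are *not* recoverable from their
textual context alone: an atom bonded to a carbon can be almost anything, so
a masked-language model (MLM) trained directly on SMILES plateaus — it learns
the grammar (balanced parentheses, paired ring digits, plausible branch
counts) and the majority symbol, but cannot pin down masked atoms. The
dual-encoder pretraining objective implemented here fixes the information
deficit: a first encoder reads the *unmasked* canonical SMILES and compresses
it into a single molecular embedding (the cls output); a second encoder
receives a *heavily masked* and usually *differently spelled* SMILES of the
same molecule, with the molecular embedding injected as its position-0 input,
and must recover every masked symbol. Because the embedding carries the whole
molecule, masked symbols become (in principle) uniquely determined, so the
mask rate can be pushed to 50% where the plain MLM already fails at 10-20%.
Spelling the second input differently (traversal from a random atom, random
neighbor order) in about 80% of examples prevents the embedding from merely
memorizing the input string: it must encode the molecule, not the spelling.

After pretraining, only the first encoder is kept; a two-layer fully
connected head on the molecular embedding is fine-tuned for property
prediction (binary, regression, or multi-label).

## Architectures

All three models share one transformer encoder design:

* token embeddings over the symbol vocabulary plus learned positional
  embeddings (102 positions: cls + 100 symbols, one spare slot for the
  injected embedding);
* a stack of self-attention blocks (multi-head attention + position-wise
  FFN with ReLU, each sublayer with a residual connection and LayerNorm);
* attention is masked so pad positions are never attended to, which makes
  every output exactly independent of padding length.

The **dual-encoder** shares the token-embedding table between its two
encoders (the symbols mean the same thing on both sides); positional
embeddings and all block weights are independent. The molecular embedding is
injected by replacing the second encoder's position-0 token embedding, so it
participates in self-attention like any other position and every masked
position can read it. Loss is cross-entropy over masked positions only, and
recovery accuracy is the fraction of masked positions whose argmax equals the
original symbol. The **MLM baseline** is the same encoder applied to a single
masked canonical sequence. The **property predictor** is the first encoder
plus `Linear(d→d) → ReLU → Linear(d→k)`, with a sigmoid for classification
heads.

Design points the source architecture leaves open, decided here:

* **Normalization order.** Blocks are pre-LayerNorm with a final LayerNorm on
  the stack output. Pre-LN optimizes stably without a warmup schedule, which
  matters at desk scale where the budget is thousands, not millions, of
  steps; a post-LN variant is retained behind `EncoderConfig(pre_norm=False)`.
* **Dropout placement.** The 0.1 dropout rate applies to the two residual
  branches of each block. Attention probabilities and embeddings are not
  dropped: at these model sizes that extra noise measurably slows masked-
  symbol learning without improving the recovered accuracy.
* **Second-encoder cls.** The injected molecular embedding *replaces* the
  cls slot of the second encoder rather than being appended beside it; the
  second encoder needs no sequence summary of its own.
* **Masking rule.** Exactly `max(1, round(rate·L))` distinct content
  positions are masked (cls and padding never), always with the mask token —
  no 80/10/10 keep/random split, since the objective is exact recovery and
  both architectures use the same rule for comparability. Alternates and
  mask sets are resampled every epoch.
* **Alternate supply.** By default every draw enumerates a fresh uniformly
  random spelling. `PretrainConfig(alternates_per_molecule=K)` instead gives
  each molecule a fixed pool of K precomputed alternates (deterministic in
  the molecule string and a pool seed), mirroring a pipeline that enumerates
  its corpus once up front. The desk-scale experiments use K = 1: with
  unbounded fresh spellings the task of completing an arbitrary 50%-masked
  spelling is out of reach of the tiny 2-layer encoder at the prescribed
  learning rate (its training loss plateaus far from zero), while a fixed
  alternate per molecule keeps the "~80% differently spelled" pressure on
  the embedding and is learnable at this scale. The cost is explicit in the
  matched-rate comparison: accuracy on *fresh* held-out spellings is far
  lower for both architectures, and only the relative ordering is claimed
  there.

## The neural-network engine

No deep-learning framework is used: layers (Dense, LayerNorm, Embedding,
multi-head attention, dropout), the Adam optimizer, and the masked
cross-entropy loss are implemented directly on NumPy arrays with explicit
backward passes. Every backward pass is verified against central finite
differences (at float64) in the test suite; normal operation runs at float32.
Weight tying (the shared token table) works by sharing the Parameter object,
with gradient accumulation across both encoders' backward passes.

## Synthetic molecules

The generator grows a random spanning tree atom by atom with drug-like
statistics: elements drawn C-heavy (C 70%, N 10%, O 12%, S 3%, F 3%,
Cl 1.5%, Br 0.5%), growth extending the most recent atom with probability
0.5 so chains dominate over star-like branching, double bonds at 15% where
valence allows but never sharing an atom (no cumulated systems), and at
most `min(n_atoms/6, 3)` ring-closing bonds between atoms at graph distance
≥ 4 (ring size ≥ 5), each accepted with `ring_prob`. Valence caps
C:4 N:3 O:2 S:2 F:1 Cl:1 Br:1 are never exceeded; hydrogens are implicit.
These bounds matter beyond cosmetics: unconstrained ring proposals yield
fused polycyclic tangles whose alternative spellings are far more ambiguous
under heavy masking than any real screening library, which distorts the
recovery task the corpus exists to exercise. The SMILES writer/parser
covers exactly this subset (atoms, `=`, branches, ring digits 1-9); the
writer can spell a graph from any root with any neighbor order, which is
what the enumeration and the canonical form are built from.

The canonical form uses Weisfeiler-Lehman-style neighborhood refinement to
rank atoms invariantly to input order, roots the DFS at the minimal
(rank, degree, element) atom and orders neighbors the same way; atoms the
refinement cannot distinguish are treated as interchangeable. On this subset
the form agrees with an external cheminformatics toolkit's molecule identity
on thousands of randomized round-trip checks in the test suite.

What the generator deliberately does **not** emulate: aromaticity, charges,
stereochemistry, isotopes, and the long-tailed size distribution of real
screening libraries. Passing the scaled-down pretraining checks therefore
shows that the *mechanism* works (conditioning recovers heavily masked,
re-spelled sequences; pretraining transfers to a structure-determined task);
it does not certify performance on real ADMET or odor data, which need the
external corpora and full-scale training.

Structure-determined labels (`contains_double_bond`, cyclomatic
`ring_count`, `oxygen_count`) make fine-tuning testable: the tasks are
perfectly learnable from structure, so a sound encoder should separate them.

## Tokenization

Symbols, not subwords: one- and two-character elements (`Cl`, `Br`), whole
bracket atoms (`[nH]`, `[C@@H]`), ring digits and `%NN` closures, bond and
branch punctuation, and the stereo marks `/ \ @ @@`. Concatenating the
tokens reproduces the input exactly. Sequences are truncated to the first
100 symbols, cls-prefixed (cls does not count against the 100), and padded
per batch; symbols never seen in the pretraining corpus map to the mask ID
instead of erroring. The vocabulary assigns reserved IDs first
(pad 0, cls 1, mask 2) then observed symbols in sorted order, so the same
corpus always produces the same IDs.

## Training

Pretraining uses Adam at the prescribed 3e-4 with batch size 16 and
length-bucketed batches (examples sorted by length, batch order shuffled —
less padding, identical semantics). When the enc2 source set is fixed (MLM,
or pooled alternates) all tokenization is cached up front and only masks are
resampled per epoch. An exponential moving average of the weights
(decay 0.999) is maintained throughout; periodically (every 10-50 epochs)
the averaged weights' recovery accuracy is measured in evaluation mode on a
rotating mask realization — rotating, because repeatedly maximizing over one
fixed mask set selects checkpoints lucky on that set rather than better
ones. The best-scoring weights are checkpointed; once the accuracy has not
improved for `patience` consecutive evaluations (or the epoch cap is hit),
a cooldown phase decays the learning rate linearly to zero over 200 epochs,
and the final model is whichever of (cooled averaged weights, best
checkpoint) scores higher on a more precise three-realization evaluation.
The logged per-epoch accuracy is computed on the training batches with
dropout active and therefore runs below the evaluation-mode value.

Fine-tuning regimes freeze everything except: the last two encoder layers +
head (lr 1e-3), the last layer + head (7e-4), or the head alone (1e-4); the
non-pretrained baseline trains everything from random initialization.
Freezing is implemented by handing the optimizer only the trainable
parameter group, so frozen weights are bit-identical before and after.
Evaluation is stratified 5-fold cross-validation for classification (plain
k-fold otherwise), reporting the fold mean; a fold whose test split is
single-class skips AUROC with a recorded warning. The bundle returned by
`finetune` is the model trained on the final fold.

Checkpoints embed the encoder configuration and a vocabulary hash;
fine-tuning refuses a checkpoint whose hash does not match the supplied
vocabulary.

## Metrics

Recovery accuracy, AUROC (rank-based with tie correction), AUPRC
(threshold-stepped average precision whose constant-score value is the
positive prevalence), MAE, Spearman (average ranks), and macro/micro F1 at a
0.5 threshold (labels with no true and no predicted positives contribute 0
to the macro mean). All are hand-implemented, order-invariant, and
cross-checked in the tests against scikit-learn/SciPy to 1e-9 alongside
brute-force oracles (pair enumeration, hand confusion counts, explicit rank
formula).

## Problem sizes and numerical choices

The desk-scale experiments use a tiny encoder (2 layers, 4 heads, embedding
dimension 64, FFN 4×) pretrained on fixed-seed synthetic corpora of 50-200
molecules of 4-25 atoms with one precomputed alternate spelling per molecule,
epoch caps of about two thousand with saturation-based early stopping and the
200-epoch cooldown, chosen so the whole pipeline — both architectures
pretrained to convergence plus cross-validated fine-tuning — runs on a single
CPU core. Corpus size trades against attainable recovery: at 50 molecules the
dual-encoder's masked-symbol recovery saturates near complete; at 200
molecules it stops short of full recovery within the same budget, since each
molecule's spellings are visited proportionally less often. Full-scale
settings from the source configuration (8-10 layers, 8-16 heads, dimension
128-256, 100k-molecule corpus) are accepted by the same code paths but are
not exercised by the tests. Numerical details: float32 forward/backward with
float64 loss reduction; attention masking via a -1e9 additive bias; Adam
(β₁ 0.9, β₂ 0.999, ε 1e-8); ties in the canonical-form ranking broken by
atom index.

## Known limitations

* The canonical form relies on refinement ranks; theoretically two
  non-equivalent atoms could share a rank on pathological regular graphs,
  which the supported molecule sizes make vanishingly rare (and the
  enumeration-identity tests would catch).
* The generator's molecules are valence-legal but not chemically curated —
  strained small rings and cumulated double bonds occur.
* The MLM baseline's pooled embedding (mean over symbol outputs) is the
  export path for that architecture only; the dual-encoder exports its cls
  embedding.
* External-data adapters (ADMET benchmark group, odor-descriptor tables) are
  import-guarded; the core package never needs the network.
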