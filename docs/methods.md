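# Methods

## The recognition problem

`emovad` recognizes the emotional state expressed in a single text
utterance as a point in the three-dimensional
valence–arousal–dominance (VAD) cube, each coordinate normalized to
[0, 1]: valence is pleasantness, arousal is activation/intensity,
dominance is the sense of control. The dimensional representation is
aimed at settings — such as chatbot-delivered cognitive behavioural
therapy, where an agent tailors empathic responses to the user's
state — in which discrete labels (joy, fear, …) are too coarse.

Two recognizers are provided and evaluated with the same protocol: a
transparent rule-based lexicon scorer, and a transformer encoder with a
regression head. The surrounding machinery (label transformation,
dataset pooling, splits, metrics, synthetic fixtures) is what makes the
two comparable and testable.

## Categorical → dimensional label transformation

Most emotion corpora are categorically labelled. A VAD lexicon (the
NRC-VAD tab-separated layout: `term  V  A  D`) converts them: each label
word is looked up, and a multi-label example receives the component-wise
mean of its labels' scores. Labels are lowercased and trimmed before
lookup; no synonym mapping is attempted. Examples whose labels all miss
the lexicon are dropped under the default `skip` policy (with a logged
count); an `error` policy aborts naming the offending label.

Natively dimensional corpora annotated on a 1–5 scale are rescaled by
the affine map (x − 1)/4, the only affine map sending {1, 3, 5} to
{0, ½, 1}; rows out of range after rescaling are rejected and counted.

Pooling is plain ordered concatenation with **no deduplication**: the
pooled size is exactly the sum of its parts (three corpora of sizes
10,000 + 58,000 + 7,503 pool to 75,503). Splitting applies a seeded
uniform shuffle and allocates ⌊N·f_train⌋ and ⌊N·f_val⌋ examples, the
test part receiving the remainder, so the three parts always partition
the input; the default fractions are (0.784, 0.196, 0.02). No
stratification is performed.

## Rule-based scorer

The scorer is the classic lexicon heuristic with negation handling:

1. **Tokenize**: lowercase, split on whitespace, strip outer
   punctuation, detach the clitic `n't` (`don't` → `do`, `n't`).
   Interior punctuation is left alone (`happy,happy` is one token);
   there is no stemming or lemmatization — minimality keeps the
   behaviour auditable.
2. **Negation scopes**: a cue token (default
   {not, no, never, n't, cannot, neither, nor, without}) marks the
   following `scope_window` tokens (default 3). Cues themselves are
   never marked and overlapping scopes union, so a token is flipped at
   most once.
3. **Lookup and aggregate**: every token found in the lexicon
   contributes its VAD score; inside a negation scope the valence is
   mirrored, v → 1 − v (arousal/dominance mirroring is configurable but
   off by default — negating "calm" does not necessarily invert
   activation). The utterance score is the unweighted component-wise
   mean of the contributions, which keeps the output inside the unit
   cube; sum or max aggregation would not. An utterance with no lexicon
   hit scores the neutral midpoint (0.5, 0.5, 0.5), keeping the scorer
   total.

These choices (fixed forward window, valence-only flip, mean
aggregation, midpoint fallback) are explicit, configurable defaults for
a procedure whose published description is schematic; they are standard
in lexicon-based sentiment work, not claims about any particular prior
implementation.

## Transformer regressor

The model is preprocessing → encoder → dropout (0.1) → linear head with
three outputs and no activation. The encoder follows the ALBERT layout:
factorized word embeddings (vocabulary → a small embedding dimension,
projected up to the hidden size when the two differ) and a single
post-norm transformer block (multi-head self-attention + residual +
layer norm, GELU feed-forward + residual + layer norm) whose parameters
are **shared across all layer applications**; a tanh pooler reads the
[CLS] position. Two presets:

| preset | blocks | hidden | heads | FFN | emb | vocab | parameters |
|---|---|---|---|---|---|---|---|
| `pretrained-base` | 12 | 768 | 12 | 3072 | 128 | 30,000 | 11,685,891 |
| `tiny-test` | 2 | 32 | 2 | 64 | 32 | 512 | ~20k |

The base parameter count decomposes as 11,683,584 encoder (embeddings
4,005,120 + projection 99,072 + one shared block 7,087,872 + pooler
590,592) plus the 768·3+3 = 2,307 head. No pretrained weights are
bundled; the base preset defines the architecture, and weights are
random unless a checkpoint is loaded.

The network and its gradients are implemented directly in numpy
(exact-erf GELU, masked softmax whose padded-key weights underflow to
exactly zero, analytic layer-norm and attention backward passes,
gradient accumulation across the shared-block applications) together
with an AdamW optimizer (decoupled weight decay 0.01, skipped for
biases and layer-norm parameters). Backward correctness is pinned by a
finite-difference test at relative tolerance 1e−4.

### Training recipe and its parameters

* loss: mean squared error over all outputs (the target is a bounded
  regression; reported losses are example-weighted epoch means);
* optimizer AdamW, β = (0.9, 0.999), ε = 1e−8, weight decay 0.01;
* learning rate 3e−5 (default, appropriate for fine-tuning a pretrained
  base), batch size 32, 20 epochs, dropout 0.1, max sequence length 128
  with truncation;
* no early stopping and no model selection: validation loss is recorded
  per epoch but never acted on;
* optional linear warmup over a leading fraction of steps
  (`warmup_fraction`, default 0 — off) and optional global-norm
  gradient clipping (`clip_norm`, default off).

**The from-scratch tiny recipe.** The defaults above suit fine-tuning a
pretrained base. Training the tiny preset *from scratch* needed two
deliberate departures, both exposed as ordinary estimator parameters:
(i) lr 3e−3 with `warmup_fraction=0.1` — plain AdamW on a post-norm
transformer without warmup intermittently collapses an output dimension
to a near-constant early in training; (ii) `dropout=0.0` — with only 32
pooled units, a 0.1 dropout mask is large multiplicative noise relative
to the model's capacity and can trap optimization in a plateau (we
observed a run stuck at training loss 0.0065 vs 0.0001 for the
dropout-free twin), while the regularization it buys is worthless on a
noise-free synthetic target that the model cannot meaningfully overfit.
With both in place, held-out per-dimension r exceeded 0.98 on every
probed data/initialization seed pairing. The fine-tuning default keeps
dropout 0.1 and no schedule.

Determinism contract: all stochasticity (weight init, batch order,
dropout) derives from `random_state`; the same seed in the same
numerical environment reproduces the loss history bit-for-bit.
Bit-exactness is *not* promised across environments, and predictions
for the same text may differ in the last few ulps between calls whose
batches pad to different widths (floating-point summation order).
Inference is deterministic — dropout is inactive outside training — and
clamped into [0, 1] by default so outputs are valid VAD scores.

The word-level vocabulary (built from the training corpus,
most-frequent-first, capped at the preset's vocabulary size) stands in
for the SentencePiece tokenizer a production deployment would use; for
the synthetic corpora, whose words are drawn from a closed lexicon,
word-level coverage is exact.

## Evaluation

Per-dimension MSE and sample Pearson r, plus one "combined VAD" figure
each. The combined figure is computed on the **scalar average** by
default: each triple collapses to the mean of its components and
MSE / r are taken between the scalar series. This construction can
yield a combined MSE below every per-dimension MSE (opposite-sign
errors cancel in the average) and is the reading consistent with
published result tables of this design; the transparent alternatives —
entrywise MSE over all 3n components (identically the mean of the three
per-dimension MSEs) and the correlation of the concatenated series —
are available as labelled modes. Zero-variance series raise an explicit
error rather than silently returning 0 or 1.

For a categorical reading, predictions and gold scores are both mapped
to the nearest of five anchors in the **valence–arousal plane**
(dominance is ignored; the anchors are VA pairs): *empty* (0.188,
0.183), *threatened* (0.052, 0.928), *tranquil* (0.917, 0.094),
*excited* (0.908, 0.931), *rooted* (0.51, 0.527) — five lexicon words
roughly equidistant numerically and semantically. Distance is
Euclidean; ties break toward the earlier map entry. Per-category
precision/recall/F1 use one-vs-rest counts; macro F1 is the unweighted
mean over the map's categories, micro F1 the pooled-count F1 (equal to
accuracy in this single-label, exhaustive setting), and "average" F1
the support-weighted mean. Categories never predicted get precision 0
with a logged warning.

## Synthetic data: what it emulates, and what it does not

The generators produce a pseudo-word lexicon (uniform VAD on [0,1]³),
dimensional corpora, and categorical corpora, all pure functions of
their seed.

A synthetic dimensional corpus samples each text's words from the
lexicon; its gold score is the negation-aware mean of the in-lexicon
words' scores — the same quantity the rule scorer computes — plus
optional Gaussian noise (sd `noise_sd`) clipped to [0, 1]. Controllable
corruption: `oov_rate` replaces words with out-of-vocabulary
pseudo-words drawn from a disjoint alphabet (so collisions with lexicon
terms are impossible), `negation_rate` inserts cues. Defining gold
negation-aware (rather than as the plain mean) keeps the oracle
identity — rule scorer ≡ gold at zero noise and zero OOV — valid at any
negation rate; at negation rate 0 the two definitions coincide. The
clipping of additive noise introduces a small bias toward the interior
of the cube, which is why the noise-variance test band
([0.0015, 0.0040] for sd 0.05) is quoted for the *clipped* perturbation.

A synthetic categorical corpus assigns each example a category, builds
its text from the 20 lexicon words nearest the category's anchor in VAD
space, and labels it with the category name (flipped to a random other
category with probability `label_noise`). Noise variates are drawn
whether or not they are used, so corpora generated from the same seed
at different noise levels stay example-aligned.

What the synthetic data does **not** emulate: natural-language syntax,
word frequency distributions, subword structure, annotator-disagreement
structure, or label-vocabulary mismatch between corpora and lexicon.
Tests passing on these fixtures therefore demonstrate the correctness
of the pipeline's arithmetic and the model's capacity to learn a
compositional word→score mapping — not performance on real emotion
corpora, which additionally depends on the pretrained encoder and the
real lexicon.

## Problem sizes in the checks

The reproduction script (`scripts/acceptance.py`) and the test-suite
use: pooling at the full 75,503-example scale; the rule-scorer oracle
at n = 200; centroid agreement on 10,000 random VA points; learnability
with the tiny preset on 2,000 training / 400 held-out examples, 20
epochs, averaged over three training seeds (held-out per-dimension
r ≥ 0.8 is the documented bar; observed values are ≈ 0.99). These sizes
exercise every code path at a scale a laptop CPU handles in under a
minute per stage.

## Known limitations

* No pretrained encoder weights ship with the package, so the
  `pretrained-base` preset cannot reproduce published fine-tuned
  results out of the box; it does reproduce the architecture and its
  parameter count exactly.
* The rule scorer's negation handling is window-based, not syntactic;
  intensifiers/downtoners and emoji are out of scope.
* The word-level vocabulary cannot generalize to unseen word forms the
  way subword tokenization does.
* Checkpoints store raw float64 weights (`.npz`); they are a runtime
  artifact, not an interchange format.
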