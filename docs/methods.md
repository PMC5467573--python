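# Methods

## Task and model

`ddicnn` classifies candidate drug pairs in biomedical sentences into five
classes (advice, effect, int, mechanism, other). Every pair of drug mentions
in a sentence is one classification instance. The model is deliberately
minimal: a single convolutional layer over word and position embeddings,
max-over-time pooling, dropout, and a softmax layer. No syntactic parsing, no
hand-engineered features — the premise is that a CNN can learn the relevant
lexical patterns (trigger phrases such as "should not be used in combination
with") and, through position embeddings, the geometry of the entity pair.

## Preprocessing

Entity blinding replaces the two paired mentions with `drug1`/`drug2` and
all other drug mentions with `drug0`, on the raw character spans, *before*
tokenization, so multi-word drug names collapse into single tokens. Candidate
pairs involving a discontinuous mention (multiple character ranges) are
removed and counted rather than modelled; they are a rare annotation
phenomenon, and representing them would complicate the instance geometry for
negligible coverage.

Overlap resolution during blinding (nested or overlapping mentions are legal
in the XML): the paired entities always win over a bystander replacement;
among bystanders, longer spans are replaced first and any span overlapping an
already-claimed region is skipped. A pair whose two mentions overlap each
other has no usable geometry and is dropped (counted separately). Pairs whose
two mentions share a surface form are kept.

Tokenization lower-cases the text and separates — never deletes — special
characters into their own tokens, after splitting the usual English
contractions. The rule list is ordered data (`TokenizerConfig`), auditable
and swappable, and is idempotent on its own output. The same rules serve
training, validation and test.

Padding uses the auxiliary token `"0"` up to the fixed length *n*. The fitted
*n* is the longest training instance, capped by `max_len` (default 128,
comfortably above any synthetic or shared-task sentence). Instances longer
than *n* — possible on new data — are truncated from the tail, except that if
either blinded entity would be lost the window is centered on the two
entities. If the entities are further apart than *n* the instance cannot be
represented and is dropped at training time; at prediction time every input
still receives a label (positions are clamped to the window).

## Embeddings

Word vectors are uniform on (−1, +1), dimension 300 by default, and always
fine-tuned. A pre-trained word2vec file (text or binary dialect) may seed the
table; vocabulary tokens missing from the file — always including the
blinding labels and the padding token, which no external model knows — fall
back to the same uniform initialization, and the coverage fraction is
reported. The padding token's vector is trainable like any other; padded
rows of the input matrix all share that single vector.

Relative positions (i − p₁) and (i − p₂) range over (−n+1, n−1) and are
shifted affinely by +n into [1, 2n−1] to index the two position tables,
which are also initialized uniform on (−1, +1) and trained (they have no
pre-trained source). Position indices of padding rows are computed by the
same formula — the shifted range already accommodates them, and keeping the
formula total avoids a special case. Position dimension m_d defaults to 5;
0 disables position features entirely, 10 is the other studied setting.

## Network and training

For each filter width *w* (defaults (3, 4, 5); the single best combination
found on real data is (2, 4, 6), matching the most common inter-entity
distances), *m* = 200 filters produce score sequences of length n−w+1
through a ReLU; max-over-time pooling keeps one feature per filter. Dropout
on the pooled vector uses the *inverted* convention: kept units are scaled by
1/(1−p) at training time, so evaluation applies the softmax layer to the raw
pooled vector with no rescaling. The loss is the summed negative
log-likelihood (computed via log-sum-exp; minimizing cross-entropy) plus
λ‖W_s‖² with λ = 3 applied to the softmax weights only — not to the biases
or any other tensor. Optimization is Adam (step 1e−3, β₁ 0.9, β₂ 0.999,
ε 1e−8 — conventional defaults, configurable) over mini-batches of 50,
reshuffled every epoch, 25 epochs, all under one seed: two runs with the same
seed produce bit-identical parameters. Filters and softmax weights start
uniform on (−0.1, 0.1); biases at zero. Prediction is the argmax of the
softmax, ties broken toward the lowest class index.

All gradients are derived analytically and implemented in NumPy (float32 by
default for speed; float64 available via `dtype`). The test suite checks
every trainable tensor against central finite differences on a small
double-precision model (n=6, m_e=4, m_d=2, widths {2,3}, m=3) at relative
error < 1e−4, with a fixed dropout mask so the loss is deterministic.

## Experiment harness

The validation split is drawn at the *sentence* level (default 10% of
instances): instances of one sentence are near-duplicates and would leak
across an instance-level split. Sentences are shuffled under a seed and
accumulated until the validation share reaches the target; realized fractions
stay within two percentage points on any non-degenerate corpus. Sweeps train
one model per named configuration on the shared split, fix the epoch count
(25) rather than early-stopping, rank by validation micro-F1, and compare all
configuration pairs with the chi-square protocol below. The test set never
informs any selection. A failed run is recorded with its error and excluded
from ranking and significance, without aborting the sweep.

## Scoring

Per-class and micro-averaged P/R/F1 over the four positive classes; `other`
is never a row of its own and overall counts sum the positive classes only.
A positive-to-positive confusion counts both as a false negative of the gold
class and a false positive of the predicted class — the convention under
which the per-class rows sum exactly to the overall row. P is 0 when
TP+FP = 0, R is 0 when TP+FN = 0, F1 is 0 when P+R = 0. Displayed values are
percentages rounded to two decimals with round-half-even, which reproduces
every printed triple of the published evaluation tables from their counts
(e.g. 27/96 → 28.12).

Model comparison: 2×2 contingency table (model × correct/incorrect over all
candidate instances), 1-df chi-square without continuity correction,
significant iff χ² > 3.84 (strict) and p < 0.05. The contingency construction
is our declared choice; alternatives (positives-only, paired McNemar) exist
and no published table pins one down, so reported χ² values on real data are
protocol-comparable, not value-reproducible.

## Synthetic data

The generator emits corpora in the same unified XML dialect as real DDI data.
Each sentence is built around one focal pair whose class is signalled by a
multi-token trigger phrase, placed between the entities when the sampled
distance allows and after them otherwise. Defaults encode the study
conditions: the positive-class mix follows the published corpus imbalance
(advice 20.9%, effect 41.1%, int 5.6%, mechanism 32.3% of positives) with
half of all pairs non-interacting (the real corpus is ~85% non-interacting,
too sparse to be informative at desk scale); inter-entity distances have
modes at 2, 4 and 6 like the real corpus, with the long tail truncated at
desk scale (default mean ≈ 6, versus 14.6 on real data); provenance mixes
drugbank/medline 77/23, matching the document split of the real corpus.
Bystander mentions (default rate 0.3) exercise the `drug0` path, and their
pairs with the focal entities are emitted as non-interacting, exercising the
multi-instance-per-sentence path. A trigger-swap noise rate (default 0)
controls label noise; a discontinuous-mention rate (default 0) exercises the
preprocessing drop filter. Filler tokens come from a closed ~30-word lexicon
so vocabularies stay small.

What the generator does *not* emulate: real lexical variety, negation scope,
coordination ambiguity, the long-tail sentence lengths of MedLine abstracts,
and annotation disagreement. Passing tests therefore demonstrate that the
pipeline and optimizer are correct and that the architecture can exploit the
signals it was designed for — not that any particular F1 transfers to real
corpora.

The position-only task isolates the position embeddings: the label depends
solely on the inter-entity distance band (defaults: 5–7 vs 11–14), every
non-entity token is a random filler, and every sentence has exactly the same
token count so neither lexical content nor length carries information. The
shortest band starts at distance 5 because a convolution window of width ≤ 5
can only see both entities when they are at most 4 tokens apart — with the
default widths (3, 4, 5) a word-only model is blind to the signal by
construction. On this task the md = 10 model reaches F1 ≥ 0.9 while the
md = 0 ablation sits at the 50% class prior.

## Numerical and design choices

- Character offsets are 0-based inclusive `start-end` ranges, `;`-separated
  for discontinuous mentions (the DDI-corpus convention).
- Pair order is normalized on read so e1 is the leftmost mention.
- Provenance is required (the per-subcorpus breakdown depends on it): an
  `origin` attribute, a drugbank/medline path component, or an explicit
  default.
- Vocabulary construction is order-independent (sorted tokens) with reserved
  indices for padding and unknown tokens; out-of-vocabulary tokens at encode
  time route to the unknown entry.
- Checkpoints are a single zip archive of all tensors (bit-exact), the
  hyper-parameters, and the vocabulary.
- Problem sizes in the test suite and acceptance script (corpora of a few
  hundred instances, 25 epochs, m_e = 300) were chosen as the smallest scale
  at which the studied effects — overfit-to-100%, the ablation gap — are
  stable across seeds.

## Known limitations

- Absolute scores on the real DDI corpus are out of scope: the corpus is an
  external download, and synthetic results do not transfer.
- The CNN runs on CPU via NumPy; it is sized for desk-scale experiments, not
  for training on the full shared-task corpus (though nothing in the design
  prevents it — one epoch over ~28k instances is minutes, not hours).
- Discontinuous mentions are filtered, not modelled.
- The chi-square comparison assumes independent samples; a paired test
  (McNemar) would be more powerful and is a possible extension.
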