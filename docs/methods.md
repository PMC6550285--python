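# Methods

## The tagging problem

A clinical note is a free-text document that should carry a set of
standardized diagnosis codes, but in many settings (veterinary medicine
prominently) it does not. `deeptag` treats automated coding as multilabel
document classification over a fixed space of top-level disease codes — 42
in the standard configuration: 41 disorder categories plus one bucket for
non-disease codes. Each note carries at least one code and several on
average. Fine-grained "subtype" codes from the terminology hierarchy roll up
many-to-one onto the top-level codes; the number of distinct subtypes binned
into a code is used throughout as a proxy for the textual diversity of that
code. The 42 codes are themselves partitioned into 18 expert-defined
meta-diseases, which is the structure the hierarchical losses exploit.

## Model

Tokens are embedded (embeddings trained from scratch on the training split;
no pretrained vectors, so cross-domain vocabulary gaps are visible as
genuinely unseen tokens) and encoded by an LSTM run over the document in both
directions; the document representation h is the concatenation of the two
final states. Each code d has an independent binary logistic head

    p_d = sigmoid(e_d · h + b_d),

and the rows e_d of the final-layer weight matrix are the *code embeddings*.
The joint training loss is the mean binary cross-entropy over documents and
codes, optionally augmented by:

* **cluster penalty** (weight `lambda_cluster`): mean squared distance over
  same-meta code-embedding pairs, plus a hinged repulsion
  `max(0, m - ||e_i - e_j||)^2` averaged over cross-meta pairs. Margin `m`
  defaults to 1.0, the weight to 0.1. The exact functional form is a package
  choice: the attraction/repulsion structure is fixed by the idea ("same-meta
  embeddings closer than cross-meta"), but the equation itself was open.
  See *Known limitations* for what this form does in practice.
* **meta-disease loss** (weight `beta_meta`, default 0.1): the probability of
  meta-disease g is the noisy-OR of its members,
  `q_g = 1 - prod_{d in g} (1 - p_d)`, the meta label is the OR of member
  labels, and the loss is the mean BCE between the two. Noisy-OR was chosen
  over max or mean because meta presence is logically the OR of member
  presences and noisy-OR is smooth and monotone in each member.

Both weights at zero give exactly the plain bidirectional-LSTM baseline;
`bidirectional=False` additionally gives the unidirectional baseline. The
variants are configuration, not separate code.

Training is minibatch Adam (default 1e-3; the synthetic studies use 1e-2,
which converges much faster at their corpus sizes) with gradient-norm
clipping at 5, early stopping on validation weighted F1, and the
best-validation checkpoint returned. Probabilities are clamped at 1e-7
inside every cross-entropy term. Binarization threshold is 0.5, with ties
predicted positive. Unknown tokens share one learned UNK embedding.
Sequences are truncated at `max_len` (default 512) from the tail.

The network and losses run on a small reverse-mode autodiff core
(`deeptag._autodiff`) written on numpy; the LSTM recurrence is a single
fused tape node with hand-written backpropagation through time. All
gradients — the fused node included — are verified against central finite
differences in the test suite (relative error < 1e-4).

## Evaluation protocol

Per code: precision, recall, F1 (all defined as 0 when their denominator is
0) and ROC AUC (midrank ties; NaN and excluded from averages when the code
is single-class in the evaluation set). Per corpus: the exact-match ratio
(a document counts only if its predicted code set equals the true set
exactly) and unweighted (plain mean over codes) and weighted (by per-code
positive counts in the evaluation split) averages of precision/recall/F1.
Performance heterogeneity is analysed by OLS of per-code F1 on log10 of the
per-code training count and the subtype count (log base configurable).

## Abstention

Two document-priority rules for deferring to a human coder; in both, the
highest-priority documents are dropped first and metrics are computed on the
remainder over dropped fractions 0, 0.1, …, 0.9:

* baseline: `1 - mean_d 2|p_d - 0.5|` — a pure confidence-margin rule;
* learned: a one-hidden-layer MLP regressor (width 64, L-BFGS, seeded;
  scikit-learn) from the 42-dim confidence vector to the per-document error
  rate (fraction of codes mispredicted at threshold 0.5), fit on the
  validation split, never on the split being curved.

The learned wrapper's value is precisely where raw margins mislead: if the
tagger is overconfident — wrong at high confidence on some codes — the
baseline keeps the risky documents, while the error signature can still be
learned from the confidence vector.

## Synthetic corpus generator

Real expert-coded corpora of this kind are restricted, so the package ships
a generator that plants the structure the method assumes, making every
claim testable end to end:

* **Ontology**: D codes (default 42) partitioned over G metas (default 18),
  each code owning k subtypes (range default 2–10, or explicit per-code
  counts), each subtype owning a keyword set = its own specific tokens (3)
  + tokens shared across the code (2) + theme tokens shared across the meta
  (2). Theme sharing makes the meta partition learnable from text.
* **Documents**: the per-note code-set size is 1 + Poisson(mean − 1) (mean
  labels default 8); codes are drawn without replacement from a truncated
  power law (exponent default 1), one subtype per code uniformly; each
  keyword is injected twice; background tokens (vocabulary 2000, ~5%
  numeric) fill to a Poisson length (mean 325); all positions shuffled.
  Labels are the rollup of the planted subtypes; optional label-flip noise.
* **Domain shift**: per-occurrence replacement of tokens by forms unseen in
  the source vocabulary with probability `oov_prob` (default 0.154) — half
  consistent per-type "abbreviations", half fresh noise tokens — plus
  uniform thinning to the target length ratio (default 191/325) and
  swapping of a configured fraction of subtypes (default 0.3) for novel
  same-code subtypes whose specific keywords are unique to the new domain
  (shared code/meta tokens are kept). Every transform preserves labels.
  Optional code-frequency re-weighting by note subsampling is off by
  default because it breaks the 1:1 note mapping.

What the generator does **not** emulate: grammar and discourse structure
(documents are keyword bags at random positions — the planted signal is
lexical), section structure of clinical notes, realistic abbreviation
morphology, label-correlation structure beyond co-occurrence induced by
per-note code counts. Passing tests on this corpus therefore demonstrate
that the machinery learns and evaluates lexical multilabel signal correctly;
they do not certify performance on real clinical language.

## Study problem sizes

The packaged studies (`deeptag.studies`, also driven by
`scripts/acceptance.py`) run on one CPU in minutes, at sizes chosen as
density-preserving scale-downs of the full setting: when the label space is
reduced 42 → 10 (4 metas), mean labels per note is reduced 8 → 3 and mean
document length 325 → 80 so that label density and the keyword-to-background
ratio match the full-scale corpus; background vocabulary 500. The
learnability study trains on 2000 such notes; the comparative studies
(cluster geometry, shift benefit, subtype diversity) use 400–800 notes and
5 seeds; models use embedding 32, hidden 24–32 per direction. A note on why
density preservation matters: keeping "8 labels per note" while shrinking to
10 codes makes 80% of labels positive and turns the task into absent-code
detection, and keeping 325-token documents while reducing planted keywords
lets the encoder memorize backgrounds instead of learning keywords — both
regimes defeat the encoder for reasons unrelated to what the studies probe.

## Known limitations

* **Cluster penalty.** With the implemented absolute form, the intra-meta
  attraction drives sibling-code embeddings toward coincidence; since code
  probabilities differ only through `e_d · h + b_d`, coincident rows make
  sibling codes per-document indistinguishable, and measured shifted-domain
  weighted F1 *decreases* relative to the unregularized baseline at every
  tested weight (0.003–0.1) and margin (1–10). The geometric effect itself
  is robust (the intra/inter distance ratio drops sharply). A relative
  ("closer than") triplet-style penalty may be the better reading of the
  idea; only the absolute form is implemented.
* **Meta loss.** Improves shifted-domain F1 on some seeds, but the mean
  effect over 5 seeds is a tie at study scale.
* The LSTM encoder carries the usual long-sequence credit-assignment
  limits; on sparse lexical signal spread over hundreds of tokens it can
  memorize rather than generalize (see the density note above).
* AUC confidence intervals, cross-model significance tests, per-code
  selective prediction, and cost-sensitive deferral are out of scope.
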