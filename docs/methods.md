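# Methods

This note documents the models, the synthetic data, and the numerical and
design choices behind `mednorm`, in the spirit of a model-description
appendix: what is computed, under which assumptions, and what the synthetic
experiments do and do not show.

## Problem setting

Medical entity normalization maps a mention span *m* (with its document
context) to one or more concept identifiers in a terminology knowledge base
(KB). The pipeline is *generate-and-rank*: an unsupervised, annotation-free
retrieval step proposes *k* candidate concepts per mention; a trainable
re-ranker then reorders them using context and may abstain (NIL). This
decomposition matters cross-lingually: retrieval works from whatever
aliases the KB has in any language, and only the (much smaller) re-ranker
needs task- or language-specific supervision — possibly only weak
supervision obtained by annotation projection.

## Knowledge bases

A KB maps concept id → canonical name, language-tagged aliases, semantic
type codes, and source vocabularies. Surfaces are normalized (Unicode NFKC,
casefold, whitespace collapse) for deduplication and indexing; original
surfaces are preserved for display. RRF parsing consumes only the columns
the pipeline needs (CUI, LAT, STR, SAB, SUPPRESS; CUI, TUI) from the
standard pipe-delimited layout; rows with SUPPRESS ∈ {O, E, Y} are dropped
by default and the policy is explicit in the build config. The canonical
name is the first preferred-term row (TS=P, ISPREF=Y) per CUI in file
order — the choice is arbitrary but deterministic, and parsing is otherwise
invariant under row permutation. Fine-grained type codes are stored as-is;
coarse semantic groups come from a configurable type→group table, so
group-level subsetting (as benchmark corpora typically require) is a view,
not a transformation of the stored types.

## Candidate generation

Every (alias, concept) pair is embedded two ways:

* **Sparse**: TF-IDF over character 3-grams with word-boundary padding on
  the normalized surface (scikit-learn `char_wb` analyzer), L2-normalized.
  Character n-grams of size 3 are the established alias-retrieval choice —
  robust to inflection and small typos.
* **Dense**: a pluggable `DenseEncoder` contract (deterministic
  text → unit vector). The reference implementation hashes
  word-boundary-padded character 3-grams into a signed 256-dimensional
  vector (BLAKE2b), then L2-normalizes. It needs no model download and
  gives lexically similar strings high cosine similarity, which is the
  property the pipeline requires of any production embedding model;
  transformer-based encoders plug into the same contract.

Queries embed the mention surface identically; scores are cosines. Alias
hits aggregate to concepts by **max** (a concept ranks by its
best-matching synonym). Search is exact by default — brute force over the
alias matrix is the reference contract, and any approximate backend must
return identical results on small KBs. Two numerical rules make rankings
total and reproducible: scores are quantized to 1e-9 before ranking (so
ordering never depends on floating-point summation order), and exact ties
break by ascending concept id. Ties are not rare: concepts sharing an alias
receive *identical* scores by construction, which is precisely the
ambiguity the re-ranker exists to resolve.

Generator fusion: per mention, each generator's scores are min–max
normalized to [0, 1] (degenerate one-value lists map to 1.0), combined as a
weighted sum (equal weights by default, missing entries contribute 0),
re-ranked with the same tie rule, and truncated to *k* = 64.

## Pre- and post-processing

* **Abbreviation expansion** uses the classic parenthesized-definition
  detector: a candidate short form inside parentheses (2–10 characters,
  ≤ 2 words, at least one letter, alphanumeric start) is matched
  right-to-left against the preceding words (at most min(|SF|+5, 2·|SF|)
  words, not crossing a sentence boundary); each short-form character must
  appear in order, and the first one must start a word. A mention whose
  entire surface equals a detected short form gets the long form as an
  additional *query* surface — mention text and offsets are never
  rewritten, and no statistical disambiguation is attempted.
* **Semantic-group filtering**: when mentions carry class labels and a
  total class → KB-type map is supplied, candidates whose types (or mapped
  groups) have empty intersection with the mention's mapped set are
  removed. Compatibility is defined as non-empty intersection — the
  weakest reading, which never discards a concept that could be right.
  Filtering is a subsequence operation (order and scores preserved) and
  idempotent; an emptied candidate list yields a NIL prediction downstream.

## Re-ranking

Instance construction: per mention, the top `k_train` (default 16)
candidates plus a synthetic NIL appended last. The mention encoding is the
whitespace-normalized context window (default 128 characters per side) with
`<m> … </m>` markers; the candidate encoding is the canonical name plus up
to `max_aliases` aliases (target language first, then English, then others,
alphabetical within groups) joined by `" | "`; NIL encodes as the literal
`[UNK]`. The gold one-hot is set at the first candidate whose id is in the
mention's gold set, else at NIL. The CG score vector *c* keeps the fused
combined scores, with c(NIL) = 0 — the floor of the normalized range, since
retrieval produces no NIL score. *c* is used exactly as produced (range
[0, 1]) against the unconstrained logits *s*; the loss formula compares
them directly and any rescaling would be an undocumented deviation.

Loss: `L = Σᵢ yᵢ(−sᵢ + logsumexp(s)) + λ‖s − c‖²`, computed
log-sum-exp-stably; λ ≥ 0, default 1.0. The analytic gradient w.r.t. *s*
is `softmax(s) − y + 2λ(s − c)` and is verified against central finite
differences in the tests.

### Reference backbone

The scoring contract is `(mention encoding, candidate encoding) → ℝ`;
production implementations may be transformer cross-encoders. The
reference backbone is a linear model over BLAKE2b-hashed features (2²⁰
dimensions) designed so the full train/eval loop runs in seconds on one
CPU while still exhibiting the behaviors the loss is about:

* **Indicator block** (L2-normalized per pair): candidate-encoding
  character 3-grams and tokens, context tokens, and
  context-token × candidate-token pairs. The interaction pairs are
  essential: with purely additive text features the context contribution
  is constant across an instance's candidates and cancels in the softmax,
  making contextual disambiguation unlearnable for a linear scorer.
* **Graded similarity features** (fixed scale, not normalized with the
  block — normalizing them jointly would rescale each candidate's
  similarities by its own feature count and corrupt within-instance
  ordering): n-gram Jaccard, Dice, containment, per-alias-segment set
  cosine (max and mean), the reference dense-encoder cosine (max over
  segments), and an exact-alias indicator. These give the model the
  capacity to approximate the retrieval score, so the regularizer has a
  representable target and λ genuinely controls the trade-off between
  free re-ranking and ranking preservation.

Training: the model is linear, so the mean loss plus an L2 penalty on the
indicator weights is smooth and convex; it is minimized with full-batch
L-BFGS over the active feature subspace (`20 × epochs` iterations, default
epochs 10; zero epochs is a no-op). The similarity features and bias are
exempt from the penalty — they carry consistent signal — while the
indicator penalty (base 1e-3, scaled by (1 + λ) so it keeps pace with the
growing regression term) stops per-candidate indicators from memorizing
residuals that would add noise to held-out score ordering. Training is
deterministic; the config seed exists for stochastic backbones.

Inference re-ranks the `k_train` candidates plus NIL by *s*; ties prefer
any candidate over NIL (abstention only when NIL is strictly best), then
ascending id. The prediction is the top entry, or NIL. The original
candidate set is preserved alongside the re-ranked one. Whether
inference-time k should differ from training-time k is left to the config;
the default uses the same value.

## Weak supervision by marker projection

Indexed marker pairs (`[i … i]`) wrap each mention before translation;
indices keep recovery well-defined when translation reorders entities —
bare brackets cannot distinguish multiple entities per sentence. Nested or
overlapping mentions are routed to separate translation passes (one per
nesting level), since markers cannot nest unambiguously. After translation,
an index is recovered iff exactly one balanced pair survives; its span is
computed on the marker-stripped text (whitespace from the marker templates
trimmed), all marker residue is removed, and gold concept ids transfer
verbatim. Dropped indices are data, not errors: the projection report
tracks projected + dropped = source count per document, and the recovery
rate is the quality signal. The translation model itself is out of scope —
the contract ships an identity translator and a seeded marker-dropping mock
(each closing marker lost with probability p) for tests and calibration.

## Evaluation

Gold mention spans are assumed (normalization-only setting). A top-1
prediction is correct if it hits *any* gold id (multi-id gold sets occur in
real corpora; "any-hit" is the common scorer-compatible reading). NIL
predictions are excluded from the precision denominator and included in the
recall denominator, so P@1 = R@1 exactly when nothing is abstained.
recall@k counts mentions whose top-k candidates intersect the gold set and
is non-decreasing in k by construction. Strata: recall@1 by whitespace
token count (1 / 2 / 3 / ≥4) — long mentions are the known hard case — and
by shared-alias count (0 / 1 / ≥2): the number of retrieved candidates
whose normalized alias set contains the normalized mention surface, which
isolates the same-alias ties retrieval cannot break.

## Synthetic data

The generator emulates the structural challenges of multilingual MEN
without any licensed resource: pseudo-word aliases (consonant-vowel
syllables) over configurable language proportions; lexical ambiguity
injected by giving `round(ambiguity_rate · n_concepts / 2)` disjoint
concept pairs one shared alias each; per-concept cue vocabularies (three
unique tokens) that appear in every sentence mentioning the concept, so
shared-alias mentions are resolvable *only* from context; and surface noise
(single-character word-interior typos, case flips). Mentions of a concept
with a shared alias use it with probability 0.5, keeping the ambiguous
subset large enough to measure. All sampling is integer-based from a
seeded `random.Random`, so outputs are byte-identical across platforms.
Train/test splits are disjoint by document.

Default study conditions: the ambiguity benchmark uses 200 concepts,
ambiguity rate 0.2, 500 train / 500 test mentions; the λ-sweep uses 100
concepts and 150/150 mentions with λ ∈ {0, 0.5, 1, 2, 10} — sizes chosen so
the full suite runs in minutes on one CPU while the measured effects
(retrieval ties at ~50% top-1 on the ambiguous subset, double-digit
re-ranker gains, Spearman ρ(s, c) rising toward ~0.95 with λ) are far from
their decision thresholds.

What passing these tests shows — and does not show. The synthetic corpora
demonstrate the *mechanisms*: retrieval recall, tie resolution from
context, NIL abstention, the λ trade-off, projection conservation. They do
not emulate real clinical text (no discourse structure, no real
morphology, no annotation noise beyond the typo model), real UMLS scale or
alias statistics, or real translation; absolute numbers on them say
nothing about benchmark performance with licensed terminologies and
pretrained encoders.

## Known limitations

* The reference backbone's interaction features memorize
  (context token, concept) associations seen in training; unseen concepts
  benefit only from the similarity features. This is intrinsic to the
  desk-scale linear design; transformer backbones generalize lexically.
* Score fusion uses per-mention min–max normalization with equal weights;
  no calibration across generators is attempted.
* Abbreviation expansion applies only on exact whole-mention matches;
  context windows are not rewritten.
* Discontinuous mention spans are joined with a single space for retrieval
  and projection treats only their convex hull per pass.
* The evaluation offers no relaxed-span or document-level modes; spans are
  taken as given.
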