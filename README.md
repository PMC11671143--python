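# mednorm

Cross-lingual **medical entity normalization** (MEN): linking entity
mentions in clinical and biomedical text — in any language — to concept
identifiers in a terminology knowledge base (UMLS-style CUIs, SNOMED CT,
ICD-10, ATC, …).

The package implements a **generate-and-rank** pipeline for researchers and
practitioners building concept-linking systems for languages where
annotated corpora and target-language synonyms are scarce:

1. **Knowledge bases** — build task-specific terminologies from UMLS RRF
   files (`MRCONSO.RRF`/`MRSTY.RRF`) or custom dictionaries, subset them by
   language, source vocabulary and semantic group, and extend them with
   extra alias lists.
2. **Candidate generation (CG)** — every KB alias is indexed both as a
   TF-IDF vector over character n-grams and as a dense embedding (pluggable
   encoder); a cosine nearest-neighbour search over the union, fused by
   weighted score combination, yields the top *k* = 64 candidate concepts
   per mention with scores *c(m, e)*.
3. **Re-ranking** — a trainable cross-encoder-style scorer *s(m, e)* reads
   the mention in context (`… <m> mention </m> …`) together with each
   candidate's name and aliases, plus a synthetic **NIL** candidate
   (encoded `[UNK]`) that lets the model abstain. Training minimizes the
   **rank-regularized softmax loss**

   L(m, e, y) = Σᵢ yᵢ · L_sm(m, eᵢ) + λ‖s(m,e) − c(m,e)‖²,&emsp;
   L_sm(m, eᵢ) = −s(m, eᵢ) + log Σⱼ exp(s(m, eⱼ))

   where **y** is the one-hot gold vector and λ (default 1.0) trades top-1
   accuracy against preservation of the retrieval ranking.
4. **Weak supervision** — when no gold training data exists in the target
   language, a labeled source corpus is projected through a translation
   backend: indexed markers (`[1 … 1]`) are inserted around mentions,
   the marked text is translated, and spans are recovered from surviving
   marker pairs with gold concept ids transferred verbatim.
5. **Evaluation** — recall@k, P@1 / R@1 / F1@1 with NIL-aware denominators,
   and error stratifications by mention token length and by shared-alias
   ambiguity.

Everything is testable offline: the `testkit` module generates
deterministic synthetic terminologies, RRF fixtures, and corpora with
controlled lexical ambiguity and contextual cue words.

## Worked example

```python
import logging; logging.disable(logging.INFO)
import numpy as np
from mednorm import (SynthSpec, synth_kb, synth_corpus, build_sparse_index,
                     build_dense_index, HashedNgramEncoder, generate_candidates,
                     recall_at_k, TrainConfig, build_instances,
                     LinearHashedBackbone, train_reranker, apply_reranker)
from mednorm.testkit import shared_aliases

spec = SynthSpec(n_concepts=200, ambiguity_rate=0.2, seed=7)
kb = synth_kb(spec)                                  # 200 concepts, ~640 aliases
train, test = synth_corpus(kb, spec, 1000, split=0.5)  # 500 / 500 mentions

indices = {"sparse": build_sparse_index(kb, 3),
           "dense": build_dense_index(kb, HashedNgramEncoder(256, 3))}
generate_candidates(train, indices, k=64)
generate_candidates(test, indices, k=64)
print("recall@64:", recall_at_k(test, [64])[64])

amb = [m for m in test.mentions if test.mention_info[m.mention_id]["ambiguous"]]
for m in test.mentions:
    m.prediction = m.candidates.entries[0][0]        # CG top-1 baseline
print("CG top-1 on ambiguous mentions:",
      round(float(np.mean([m.prediction in m.gold_ids for m in amb])), 3))

cfg = TrainConfig(lambda_reg=1.0, k_train=16, epochs=10, seed=7)
backbone = train_reranker(build_instances(train, kb, cfg),
                          LinearHashedBackbone(), cfg)
apply_reranker(test, backbone, kb, cfg)
print("re-ranked top-1 on ambiguous mentions:",
      round(float(np.mean([m.prediction in m.gold_ids for m in amb])), 3))
```

Output:

```
recall@64: 1.0
CG top-1 on ambiguous mentions: 0.479
re-ranked top-1 on ambiguous mentions: 0.648
```

Retrieval always finds the gold concept among 64 candidates, but mentions
whose surface is an alias shared by two concepts tie in CG (top-1 ≈ chance
plus the deterministic tie-break). The context-aware re-ranker resolves a
large share of those ties from the surrounding cue words — here +17 points
on the ambiguous subset — while λ = 1 keeps its scores anchored to the
retrieval ranking.

A command-line interface mirrors the library
(`mednorm dict / index / synth / project / train-rerank / predict /
evaluate`), configured by a YAML file; see `mednorm --help`.

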