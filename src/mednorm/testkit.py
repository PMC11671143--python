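"""Deterministic synthetic terminologies and corpora.

Every component of the pipeline can be exercised without downloads: this
module generates pseudo-word knowledge bases with controlled lexical
ambiguity, matching UMLS-style RRF fixture files, and annotated corpora in
which each mention is a (possibly noised) alias of its gold concept embedded
in a sentence carrying that concept's cue words.  Ambiguous mentions — those
using an alias shared between two concepts — are resolvable only through the
cues, so the value of a context-aware re-ranker over pure surface matching
is directly measurable.

All sampling is integer-based from ``random.Random(seed)``: the same spec
yields byte-identical outputs on every platform.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .corpus import Corpus, Document, EntityMention
from .kb import BuildConfig, Concept, KnowledgeBase

_CONSONANTS = "bcdfgklmnprstvz"
_VOWELS = "aeiou"

# per-concept semantic type codes cycle through these, with an identity
# class -> {type} map serving as the corpus TypeMap in typed fixtures
TYPE_CODES = ["DISO", "PROC", "ANAT", "CHEM"]

FILLER_WORDS = [
    "the", "patient", "with", "shows", "of", "finding", "noted", "during",
    "exam", "and", "for", "after", "chronic", "acute",
]

# ISO-ish -> RRF language codes used when writing fixture files
RRF_LANG = {"ENG": "ENG", "GER": "GER", "FRE": "FRE", "SPA": "SPA"}


@dataclass
class SynthSpec:
    n_concepts: int = 100
    aliases_per_concept: tuple[int, int] = (2, 4)
    languages: dict[str, float] = field(default_factory=lambda: {"ENG": 0.6, "GER": 0.4})
    ambiguity_rate: float = 0.2
    # probability that a mention of an ambiguous concept uses its shared alias
    shared_alias_use_rate: float = 0.5
    typo_rate: float = 0.1
    case_flip_rate: float = 0.1
    mentions_per_document: int = 5
    seed: int = 0

    def __post_init__(self):
        for name in ("ambiguity_rate", "shared_alias_use_rate", "typo_rate", "case_flip_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    @property
    def n_shared_aliases(self) -> int:
        """Documented ambiguity rule: one shared alias per disjoint concept
        pair, ``round(ambiguity_rate * n_concepts / 2)`` pairs in total."""
        return int(round(self.ambiguity_rate * self.n_concepts / 2))


def _word(rng: random.Random, n_syllables: int) -> str:
    return "".join(
        rng.choice(_CONSONANTS) + rng.choice(_VOWELS) for _ in range(n_syllables)
    )


def _unique_words(rng: random.Random, n: int, taken: set[str]) -> list[str]:
    out = []
    while len(out) < n:
        w = _word(rng, rng.randint(2, 4))
        if w not in taken:
            taken.add(w)
            out.append(w)
    return out


def _pick_language(rng: random.Random, proportions: dict[str, float]) -> str:
    r = rng.random()
    acc = 0.0
    for lang, p in sorted(proportions.items()):
        acc += p
        if r < acc:
            return lang
    return sorted(proportions)[-1]


def synth_kb(spec: SynthSpec) -> KnowledgeBase:
    """Generate a KB of pseudo-word concepts with injected shared aliases.

    Concept ids are SYN0001...; concept ``i`` gets semantic type
    ``TYPE_CODES[i % 4]``; the first ``2 * n_shared_aliases`` concepts are
    grouped into disjoint pairs, each pair receiving one extra shared alias.
    """
    rng = random.Random(spec.seed)
    taken: set[str] = set(FILLER_WORDS)
    kb = KnowledgeBase(build_config=BuildConfig())
    lo, hi = spec.aliases_per_concept
    for i in range(spec.n_concepts):
        cid = f"SYN{i + 1:04d}"
        n_aliases = rng.randint(lo, hi)
        words = _unique_words(rng, n_aliases, taken)
        aliases = {(w, _pick_language(rng, spec.languages)) for w in words}
        kb.concepts[cid] = Concept(
            id=cid,
            canonical_name=words[0],
            aliases=aliases,
            semantic_types={TYPE_CODES[i % len(TYPE_CODES)]},
            source_vocabularies={"SYNVOC"},
        )
    ids = sorted(kb.concepts)
    for j in range(spec.n_shared_aliases):
        shared = _unique_words(rng, 1, taken)[0]
        for cid in (ids[2 * j], ids[2 * j + 1]):
            kb.concepts[cid].aliases.add((shared, "ENG"))
    return kb


def shared_aliases(kb: KnowledgeBase) -> dict[str, set[str]]:
    """Map normalized alias -> ids of the concepts holding it (>= 2 only)."""
    holders: dict[str, set[str]] = {}
    for cid, c in kb.concepts.items():
        for surf in c.normalized_aliases():
            holders.setdefault(surf, set()).add(cid)
    return {a: cids for a, cids in holders.items() if len(cids) >= 2}


def synth_rrf(spec: SynthSpec, directory, n_suppressed: int = 2) -> tuple[str, str]:
    """Write MRCONSO.RRF / MRSTY.RRF fixture files mirroring ``synth_kb``.

    One MRCONSO row per alias (the canonical alias flagged TS=P/ISPREF=Y),
    one MRSTY row per (concept, type), plus ``n_suppressed`` SUPPRESS=O rows
    that the default parsing filter drops, so parsing the fixture recovers
    the generated KB up to canonical-name choice.
    """
    import os

    kb = synth_kb(spec)
    rng = random.Random(spec.seed + 1)
    conso_path = os.path.join(directory, "MRCONSO.RRF")
    sty_path = os.path.join(directory, "MRSTY.RRF")
    suppressed_targets = {
        f"SYN{rng.randint(1, spec.n_concepts):04d}" for _ in range(n_suppressed)
    }
    with open(conso_path, "w", encoding="utf-8") as fh:
        for cid in sorted(kb.concepts):
            c = kb.concepts[cid]
            for surface, lang in sorted(c.aliases):
                is_canon = surface == c.canonical_name
                cols = [""] * 18
                cols[0] = cid
                cols[1] = RRF_LANG.get(lang, "ENG")
                cols[2] = "P" if is_canon else "S"
                cols[6] = "Y" if is_canon else "N"
                cols[11] = "SYNVOC"
                cols[14] = surface
                cols[16] = "N"
                fh.write("|".join(cols) + "|\n")
        for cid in sorted(suppressed_targets):
            cols = [""] * 18
            cols[0] = cid
            cols[1] = "ENG"
            cols[2] = "S"
            cols[6] = "N"
            cols[11] = "SYNVOC"
            cols[14] = f"suppressed alias {cid}"
            cols[16] = "O"
            fh.write("|".join(cols) + "|\n")
    with open(sty_path, "w", encoding="utf-8") as fh:
        for cid in sorted(kb.concepts):
            for tui in sorted(kb.concepts[cid].semantic_types):
                cols = [""] * 6
                cols[0] = cid
                cols[1] = tui
                fh.write("|".join(cols) + "|\n")
    return conso_path, sty_path


def concept_cues(kb: KnowledgeBase, spec: SynthSpec) -> dict[str, list[str]]:
    """Three unique cue words per concept, derived deterministically from the spec.

    Cue vocabularies are disjoint from aliases and fillers; a sentence
    mentioning a concept carries its cues, which is the only signal that
    separates concepts sharing an alias.
    """
    rng = random.Random(spec.seed + 2)
    taken = set(FILLER_WORDS)
    for c in kb.concepts.values():
        taken.update(s for s, _l in c.aliases)
    return {cid: _unique_words(rng, 3, taken) for cid in sorted(kb.concepts)}


def _noise_surface(rng: random.Random, surface: str, spec: SynthSpec) -> str:
    if spec.case_flip_rate and rng.random() < spec.case_flip_rate:
        surface = surface.capitalize()
    if spec.typo_rate and len(surface) > 3 and rng.random() < spec.typo_rate:
        # single-character substitution at a word-interior position
        pos = rng.randint(1, len(surface) - 2)
        repl = rng.choice(_CONSONANTS + _VOWELS)
        surface = surface[:pos] + repl + surface[pos + 1 :]
    return surface


def synth_corpus(
    kb: KnowledgeBase, spec: SynthSpec, n_mentions: int, split: float = 0.5
) -> tuple[Corpus, Corpus]:
    """Generate train/test corpora of cue-bearing sentences (disjoint by document).

    Each mention: a concept drawn uniformly; its surface is the concept's
    shared alias with probability ``shared_alias_use_rate`` when one exists,
    else a uniform own alias; noise per the spec's typo/case model.  The
    sentence interleaves the concept's three cue words with fillers.  The
    first ``split`` fraction of documents forms the train corpus.

    Each corpus carries ``mention_info``: mention_id -> dict with the chosen
    concept, the un-noised alias, and whether that alias is shared
    (``ambiguous``).
    """
    rng = random.Random(spec.seed + 3)
    cues = concept_cues(kb, spec)
    shared = shared_aliases(kb)
    ids = sorted(kb.concepts)
    shared_of: dict[str, list[str]] = {cid: [] for cid in ids}
    for alias, holders in shared.items():
        for cid in holders:
            shared_of[cid].append(alias)
    for cid in shared_of:
        shared_of[cid].sort()

    n_docs = max(1, (n_mentions + spec.mentions_per_document - 1) // spec.mentions_per_document)
    docs: list[Document] = []
    mentions: list[EntityMention] = []
    info: dict[str, dict] = {}
    m_count = 0
    for d in range(n_docs):
        doc_id = f"synth-doc-{d:04d}"
        parts: list[str] = []
        offset = 0
        for s in range(spec.mentions_per_document):
            if m_count >= n_mentions:
                break
            cid = ids[rng.randrange(len(ids))]
            own = sorted({surf for surf, _l in kb.concepts[cid].aliases})
            if shared_of[cid] and rng.random() < spec.shared_alias_use_rate:
                alias = shared_of[cid][rng.randrange(len(shared_of[cid]))]
            else:
                alias = own[rng.randrange(len(own))]
            surface = _noise_surface(rng, alias, spec)
            cue_words = list(cues[cid])
            rng.shuffle(cue_words)
            prefix_tokens = [rng.choice(FILLER_WORDS), cue_words[0], cue_words[1]]
            suffix_tokens = [cue_words[2], rng.choice(FILLER_WORDS)]
            prefix = " ".join(prefix_tokens) + " "
            suffix = " " + " ".join(suffix_tokens) + ". "
            start = offset + len(prefix)
            end = start + len(surface)
            sentence = prefix + surface + suffix
            parts.append(sentence)
            offset += len(sentence)
            mid = f"{doc_id}-m{s}"
            mentions.append(
                EntityMention(
                    mention_id=mid,
                    doc_id=doc_id,
                    spans=[(start, end)],
                    text=surface,
                    semantic_class=sorted(kb.concepts[cid].semantic_types)[0],
                    gold_ids={cid},
                )
            )
            info[mid] = {
                "concept": cid,
                "alias": alias,
                "ambiguous": alias in shared,
            }
            m_count += 1
        docs.append(Document(doc_id=doc_id, passages=[("".join(parts).rstrip(), 0)]))

    n_train_docs = int(round(n_docs * split))
    train_ids = {d.doc_id for d in docs[:n_train_docs]}

    def build(doc_subset: list[Document]) -> Corpus:
        keep = {d.doc_id for d in doc_subset}
        c = Corpus(
            documents=doc_subset,
            mentions=[m for m in mentions if m.doc_id in keep],
            language="ENG",
        )
        c.mention_info = {m.mention_id: info[m.mention_id] for m in c.mentions}
        return c

    train = build([d for d in docs if d.doc_id in train_ids])
    test = build([d for d in docs if d.doc_id not in train_ids])
    return train, test


def identity_type_map(kb: KnowledgeBase) -> dict[str, set[str]]:
    """TypeMap for synthetic corpora: each class maps to itself."""
    return {t: {t} for t in TYPE_CODES}
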