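"""Annotated corpora in a BigBIO-style JSON schema.

Documents are lists of passages with absolute character offsets; entity
mentions are character-offset spans (0-based, half-open) into the
concatenated document text, optionally carrying a semantic class, gold
concept ids, generated candidates, and a prediction.  The reserved
prediction string ``"NIL"`` denotes abstention and never collides with a KB
concept id.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

NIL = "NIL"


@dataclass
class Document:
    doc_id: str
    passages: list[tuple[str, int]]  # (text, absolute start offset)

    @property
    def text(self) -> str:
        """Full document text with passage offsets honoured; gaps are spaces."""
        if not self.passages:
            return ""
        end = max(off + len(t) for t, off in self.passages)
        buf = [" "] * end
        for t, off in self.passages:
            buf[off : off + len(t)] = t
        return "".join(buf)


@dataclass
class EntityMention:
    mention_id: str
    doc_id: str
    spans: list[tuple[int, int]]
    text: str
    semantic_class: str | None = None
    gold_ids: set[str] = field(default_factory=set)
    candidates: object | None = None  # CandidateSet, set by candidate generation
    prediction: str | None = None
    expanded_text: str | None = None  # abbreviation-expanded query surface
    reranked: object | None = None  # CandidateSet after re-ranking

    @property
    def query_surface(self) -> str:
        """Surface used for candidate generation (expansion wins if present)."""
        return self.expanded_text if self.expanded_text is not None else self.text

    def surface_from(self, doc_text: str) -> str:
        """Re-derive the surface from spans: substrings joined by one space."""
        return " ".join(doc_text[s:e] for s, e in self.spans)


@dataclass
class Corpus:
    documents: list[Document] = field(default_factory=list)
    mentions: list[EntityMention] = field(default_factory=list)
    language: str = ""

    def document(self, doc_id: str) -> Document:
        try:
            return self._doc_index[doc_id]
        except AttributeError:
            self._doc_index = {d.doc_id: d for d in self.documents}
            return self._doc_index[doc_id]

    def mentions_of(self, doc_id: str) -> list[EntityMention]:
        return [m for m in self.mentions if m.doc_id == doc_id]


class CorpusFormatError(ValueError):
    pass


def _validate_mention(m: EntityMention, doc: Document) -> None:
    if not m.spans:
        raise CorpusFormatError(f"mention {m.mention_id}: empty span list")
    prev_end = -1
    text = doc.text
    for s, e in m.spans:
        if not (0 <= s < e <= len(text)):
            raise CorpusFormatError(
                f"mention {m.mention_id}: span ({s},{e}) out of bounds for "
                f"document {doc.doc_id} of length {len(text)}"
            )
        if s < prev_end:
            raise CorpusFormatError(
                f"mention {m.mention_id}: spans overlap or are unsorted"
            )
        prev_end = e
    derived = m.surface_from(text)
    if m.text != derived:
        logger.warning(
            "mention %s: stored text %r != text derived from offsets %r; using derived",
            m.mention_id, m.text, derived,
        )
        m.text = derived


def validate_corpus(corpus: Corpus) -> Corpus:
    docs = {d.doc_id: d for d in corpus.documents}
    for m in corpus.mentions:
        if m.doc_id not in docs:
            raise CorpusFormatError(f"mention {m.mention_id}: unknown doc_id {m.doc_id!r}")
        _validate_mention(m, docs[m.doc_id])
    return corpus


def load_corpus(path) -> Corpus:
    """Load a BigBIO-style JSON corpus and enforce offset invariants.

    Mention text is re-derived from the offsets; on mismatch the re-derived
    text wins (with a logged warning).  Out-of-bounds spans are a hard error.
    """
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    corpus = Corpus(language=data.get("language", ""))
    for doc in data["documents"]:
        passages = [(p["text"], int(p["offset"])) for p in doc["passages"]]
        corpus.documents.append(Document(doc_id=doc["id"], passages=passages))
        for ent in doc.get("entities", ()):
            spans = [(int(s), int(e)) for s, e in ent["offsets"]]
            gold = {n["db_id"] for n in ent.get("normalized", ())}
            m = EntityMention(
                mention_id=ent["id"],
                doc_id=doc["id"],
                spans=spans,
                text=ent.get("text", ""),
                semantic_class=ent.get("type"),
                gold_ids=gold,
                prediction=ent.get("prediction"),
            )
            cand = ent.get("candidates")
            if cand is not None:
                from .candgen import CandidateSet  # deferred: avoid import cycle

                m.candidates = CandidateSet.from_records(cand)
            corpus.mentions.append(m)
    return validate_corpus(corpus)


def from_ner_output(
    docs: list[tuple[str, str]],
    spans: list[tuple[str, int, int, str | None]],
) -> Corpus:
    """Build a corpus from raw texts plus NER-tagger spans (no gold ids)."""
    corpus = Corpus(documents=[Document(doc_id=d, passages=[(t, 0)]) for d, t in docs])
    for i, (doc_id, start, end, cls) in enumerate(spans):
        doc = corpus.document(doc_id)
        m = EntityMention(
            mention_id=f"{doc_id}-m{i}",
            doc_id=doc_id,
            spans=[(start, end)],
            text=doc.text[start:end],
            semantic_class=cls,
        )
        corpus.mentions.append(m)
    return validate_corpus(corpus)


def write_corpus(corpus: Corpus, path) -> None:
    """Write the corpus (with predictions/candidates) back to the JSON schema."""
    by_doc: dict[str, list[EntityMention]] = {}
    for m in corpus.mentions:
        by_doc.setdefault(m.doc_id, []).append(m)
    out = {"language": corpus.language, "documents": []}
    for doc in corpus.documents:
        ents = []
        for m in by_doc.get(doc.doc_id, ()):
            ent = {
                "id": m.mention_id,
                "offsets": [[s, e] for s, e in m.spans],
                "text": m.text,
                "type": m.semantic_class,
                "normalized": [{"db_id": g} for g in sorted(m.gold_ids)],
            }
            if m.prediction is not None:
                ent["prediction"] = m.prediction  # NIL serialized verbatim
            if m.candidates is not None:
                ent["candidates"] = m.candidates.to_records()
            ents.append(ent)
        out["documents"].append(
            {
                "id": doc.doc_id,
                "passages": [{"text": t, "offset": off} for t, off in doc.passages],
                "entities": ents,
            }
        )
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(out, fh, ensure_ascii=False, indent=1)


# Spec name for the round-trippable prediction writer.
write_predictions = write_corpus
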