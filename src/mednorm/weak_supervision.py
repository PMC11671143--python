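"""Weak supervision by marker-based annotation projection through translation.

To train a re-ranker for a language without gold-annotated corpora, entity
annotations are transferred from a labeled source corpus: indexed markers
are inserted around each mention span, the marked text is run through a
translation backend, and spans are recovered from the surviving marker pairs
in the translated text.  The source mentions' gold concept ids transfer
verbatim to the recovered spans — these labels are weak because translation
may drop or garble markers, so the projection report tracks per-document
recovery.

The translation model itself is a pluggable text -> text contract; an
identity translator and a seeded marker-dropping translator are provided for
testing and calibration.
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass, field

from .corpus import Corpus, Document, EntityMention, validate_corpus


@dataclass
class MarkerScheme:
    """Indexed marker pair templates, e.g. ``[1 ... 1]``.

    Indexed pairs (rather than bare brackets) keep recovery well-defined when
    translation reorders multiple entities in one sentence.
    """

    open_template: str = "[{i} "
    close_template: str = " {i}]"

    def open(self, i: int) -> str:
        return self.open_template.format(i=i)

    def close(self, i: int) -> str:
        return self.close_template.format(i=i)

    def check_text(self, text: str, indices: list[int]) -> None:
        for i in indices:
            for marker in (self.open(i), self.close(i)):
                if marker in text:
                    raise ValueError(
                        f"marker {marker!r} already occurs in the source text"
                    )


@dataclass
class ProjectionReport:
    per_document: dict[str, dict[str, int]] = field(default_factory=dict)
    skipped_documents: list[str] = field(default_factory=list)

    def record(self, doc_id: str, projected: int, dropped: int) -> None:
        self.per_document[doc_id] = {"projected": projected, "dropped": dropped}

    @property
    def projected(self) -> int:
        return sum(d["projected"] for d in self.per_document.values())

    @property
    def dropped(self) -> int:
        return sum(d["dropped"] for d in self.per_document.values())

    @property
    def recovery_rate(self) -> float:
        total = self.projected + self.dropped
        return self.projected / total if total else 1.0

    def to_dict(self) -> dict:
        return {
            "projected": self.projected,
            "dropped": self.dropped,
            "recovery_rate": self.recovery_rate,
            "skipped_documents": list(self.skipped_documents),
            "per_document": self.per_document,
        }


def insert_markers(
    doc_text: str, spans: list[tuple[int, int]], scheme: MarkerScheme
) -> str:
    """Wrap each span with its indexed marker pair (1-based indices).

    Spans must be contiguous and mutually non-overlapping within one pass;
    stripping the markers from the result restores the source text exactly.
    """
    ordered = sorted(range(len(spans)), key=lambda i: spans[i])
    prev_end = -1
    for i in ordered:
        s, e = spans[i]
        if s < prev_end:
            raise ValueError(f"overlapping spans at ({s},{e}); route to separate passes")
        prev_end = e
    scheme.check_text(doc_text, [i + 1 for i in range(len(spans))])
    out = []
    cursor = 0
    for i in ordered:
        s, e = spans[i]
        out.append(doc_text[cursor:s])
        out.append(scheme.open(i + 1))
        out.append(doc_text[s:e])
        out.append(scheme.close(i + 1))
        cursor = e
    out.append(doc_text[cursor:])
    return "".join(out)


def recover_spans(
    marked_text: str, scheme: MarkerScheme, expected_indices: list[int]
) -> tuple[str, dict[int, tuple[int, int]], list[int]]:
    """Recover entity spans from (possibly mangled) marked text.

    For each expected index with exactly one balanced marker pair, the span
    is computed on the marker-stripped text; indices with missing or
    unbalanced markers are dropped (data, not errors).  All marker residue —
    including unbalanced leftovers — is removed from the clean text.
    """
    # locate marker occurrences for every expected index
    occurrences: list[tuple[int, int, int, str]] = []  # (pos, len, index, kind)
    balanced: dict[int, tuple[int, int]] = {}  # index -> (open pos, close pos)
    for i in expected_indices:
        om, cm = scheme.open(i), scheme.close(i)
        opens = [m.start() for m in re.finditer(re.escape(om), marked_text)]
        closes = [m.start() for m in re.finditer(re.escape(cm), marked_text)]
        for p in opens:
            occurrences.append((p, len(om), i, "open"))
        for p in closes:
            occurrences.append((p, len(cm), i, "close"))
        if len(opens) == 1 and len(closes) == 1 and opens[0] < closes[0]:
            balanced[i] = (opens[0], closes[0])

    occurrences.sort()
    # strip all marker residue (kept occurrences must not overlap)
    kept: list[tuple[int, int]] = []  # (pos, length)
    cursor = 0
    clean_parts = []
    for pos, length, _i, _k in occurrences:
        if pos < cursor:  # overlapping residue (pathological); skip
            continue
        clean_parts.append(marked_text[cursor:pos])
        kept.append((pos, length))
        cursor = pos + length
    clean_parts.append(marked_text[cursor:])
    clean = "".join(clean_parts)

    def shift(orig_pos: int) -> int:
        """Map a position in the marked text to the marker-stripped text."""
        return orig_pos - sum(l for p, l in kept if p < orig_pos)

    spans: dict[int, tuple[int, int]] = {}
    dropped: list[int] = []
    for i in expected_indices:
        if i not in balanced:
            dropped.append(i)
            continue
        open_pos, close_pos = balanced[i]
        start = shift(open_pos)
        end = shift(close_pos)
        # trim whitespace the marker templates carried
        while start < end and clean[start].isspace():
            start += 1
        while end > start and clean[end - 1].isspace():
            end -= 1
        spans[i] = (start, end)
    return clean, spans, dropped


class Translator:
    """Contract: deterministic (or seeded) text -> text translation."""

    def translate(self, text: str) -> str:  # pragma: no cover - interface
        raise NotImplementedError


class IdentityTranslator(Translator):
    def translate(self, text: str) -> str:
        return text


class MarkerDroppingTranslator(Translator):
    """Mock translator that drops each closing marker with probability p.

    Emulates the dominant failure mode of marker projection through real
    NMT models; seeded for reproducibility.
    """

    def __init__(self, scheme: MarkerScheme, p: float = 0.2, seed: int = 0):
        self.scheme = scheme
        self.p = p
        self.rng = random.Random(seed)

    def translate(self, text: str) -> str:
        for i in range(1, 1000):
            cm = self.scheme.close(i)
            if cm not in text:
                continue
            if self.rng.random() < self.p:
                text = text.replace(cm, "", 1)
        return text


def _nesting_passes(mentions: list[EntityMention]) -> list[list[EntityMention]]:
    """Partition mentions into passes of mutually non-overlapping spans.

    Nested or overlapping entities go to later passes (one pass per nesting
    level), since markers cannot nest unambiguously.
    """
    remaining = sorted(mentions, key=lambda m: (m.spans[0][0], -m.spans[-1][1]))
    passes: list[list[EntityMention]] = []
    while remaining:
        current: list[EntityMention] = []
        leftover: list[EntityMention] = []
        prev_end = -1
        for m in remaining:
            s, e = m.spans[0][0], m.spans[-1][1]
            if s >= prev_end:
                current.append(m)
                prev_end = e
            else:
                leftover.append(m)
        passes.append(current)
        remaining = leftover
    return passes


def project_corpus(
    corpus: Corpus, translator: Translator, scheme: MarkerScheme | None = None
) -> tuple[Corpus, ProjectionReport]:
    """Project entity annotations into the translator's target language.

    Overlapping/nested source entities are handled in separate translation
    passes; each pass yields its own output document (suffix ``#p<n>`` for
    passes beyond the first).  Gold concept ids transfer verbatim.  A
    translator failure skips the document and is reported.
    """
    scheme = scheme or MarkerScheme()
    report = ProjectionReport()
    out = Corpus(language="")
    for doc in corpus.documents:
        mentions = [m for m in corpus.mentions if m.doc_id == doc.doc_id]
        projected = dropped = 0
        try:
            passes = _nesting_passes(mentions)
            if not passes:
                passes = [[]]
            for p_idx, batch in enumerate(passes):
                out_doc_id = doc.doc_id if p_idx == 0 else f"{doc.doc_id}#p{p_idx}"
                spans = [(m.spans[0][0], m.spans[-1][1]) for m in batch]
                marked = insert_markers(doc.text, spans, scheme)
                translated = translator.translate(marked)
                clean, recovered, dropped_idx = recover_spans(
                    translated, scheme, list(range(1, len(batch) + 1))
                )
                out.documents.append(Document(doc_id=out_doc_id, passages=[(clean, 0)]))
                # marker order follows span order, so re-sort the batch
                ordered = sorted(batch, key=lambda m: (m.spans[0][0], m.spans[-1][1]))
                for j, m in enumerate(ordered, start=1):
                    if j in recovered:
                        s, e = recovered[j]
                        out.mentions.append(
                            EntityMention(
                                mention_id=m.mention_id,
                                doc_id=out_doc_id,
                                spans=[(s, e)],
                                text=clean[s:e],
                                semantic_class=m.semantic_class,
                                gold_ids=set(m.gold_ids),
                            )
                        )
                        projected += 1
                    else:
                        dropped += 1
        except Exception:  # translator failure: skip document
            report.skipped_documents.append(doc.doc_id)
            dropped = len(mentions)
            projected = 0
        report.record(doc.doc_id, projected, dropped)
    return validate_corpus(out), report
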