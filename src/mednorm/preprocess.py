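"""Abbreviation expansion and semantic-group candidate filtering.

Abbreviation detection follows the Schwartz–Hearst algorithm: a
parenthesized short-form candidate next to a preceding long form, validated
by the right-to-left character matching rule.  A mention whose full surface
equals a detected short form gets an additional expanded query surface for
candidate generation; the original text is never rewritten.

Semantic-group filtering restricts a mention's candidate list to concepts
whose types are compatible with the mention's annotated class under a
corpus-specific class -> KB-type map; compatibility is non-empty
intersection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .candgen import CandidateSet
from .corpus import Corpus
from .kb import KnowledgeBase

MAX_SHORT_FORM = 10
MIN_SHORT_FORM = 2


@dataclass
class AbbreviationTable:
    """Per-document short form -> (long form, definition span)."""

    pairs: dict[str, str] = field(default_factory=dict)
    definition_spans: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __contains__(self, short: str) -> bool:
        return short in self.pairs

    def __getitem__(self, short: str) -> str:
        return self.pairs[short]

    def __len__(self) -> int:
        return len(self.pairs)


def _valid_short_form(sf: str) -> bool:
    if not (MIN_SHORT_FORM <= len(sf) <= MAX_SHORT_FORM):
        return False
    if len(sf.split()) > 2:
        return False
    if not any(ch.isalpha() for ch in sf):
        return False
    return sf[0].isalnum()


def _find_best_long_form(sf: str, candidate: str) -> str | None:
    """Right-to-left matching of short-form characters inside the candidate.

    Every alphanumeric character of the short form must occur, in order, in
    the long form; the match of the first character must start a word.
    """
    s_idx = len(sf) - 1
    l_idx = len(candidate) - 1
    while s_idx >= 0:
        ch = sf[s_idx].lower()
        if not ch.isalnum():
            s_idx -= 1
            continue
        while (l_idx >= 0 and candidate[l_idx].lower() != ch) or (
            s_idx == 0 and l_idx > 0 and candidate[l_idx - 1].isalnum()
        ):
            l_idx -= 1
        if l_idx < 0:
            return None
        s_idx -= 1
        l_idx -= 1
    start = candidate.rfind(" ", 0, l_idx + 1) + 1
    return candidate[start:]


def _accept_pair(sf: str, lf: str) -> bool:
    if len(lf) < len(sf):
        return False
    if lf.lower() == sf.lower():
        return False
    if f" {sf.lower()} " in f" {lf.lower()} ":  # long form must not contain the short form
        return False
    max_words = min(len(sf) + 5, len(sf) * 2)
    return len(lf.split()) <= max_words


def extract_abbreviations(doc_text: str) -> AbbreviationTable:
    """Detect (long form, parenthesized short form) definition pairs.

    Only the definition site is extracted; later free-standing uses of the
    short form are not re-extracted.  The first definition of a short form
    wins.
    """
    table = AbbreviationTable()
    pos = 0
    while True:
        open_idx = doc_text.find("(", pos)
        if open_idx < 0:
            break
        close_idx = doc_text.find(")", open_idx + 1)
        if close_idx < 0:
            break
        pos = close_idx + 1
        sf = doc_text[open_idx + 1 : close_idx].strip()
        if not _valid_short_form(sf):
            continue
        # long-form candidate: up to min(|sf|+5, 2|sf|) words immediately
        # before the open parenthesis, not crossing a sentence boundary
        prefix = doc_text[:open_idx].rstrip()
        for stop in ".;!?\n":
            cut = prefix.rfind(stop)
            if cut >= 0:
                prefix = prefix[cut + 1 :]
        words = prefix.split()
        max_words = min(len(sf) + 5, len(sf) * 2)
        candidate = " ".join(words[-max_words:])
        if not candidate:
            continue
        lf = _find_best_long_form(sf, candidate)
        if lf is None or not _accept_pair(sf, lf):
            continue
        if sf not in table.pairs:
            table.pairs[sf] = lf
            lf_start = doc_text.rfind(lf, 0, open_idx)
            table.definition_spans[sf] = (lf_start, close_idx + 1)
    return table


def extract_abbreviation_tables(corpus: Corpus) -> dict[str, AbbreviationTable]:
    return {d.doc_id: extract_abbreviations(d.text) for d in corpus.documents}


def expand_mentions(corpus: Corpus, tables: dict[str, AbbreviationTable]) -> Corpus:
    """Attach expanded query surfaces to mentions that equal a short form.

    Exact whole-mention match only; mention text and offsets are untouched,
    only the surface used for candidate generation changes.
    """
    for m in corpus.mentions:
        table = tables.get(m.doc_id)
        if table and m.text in table:
            m.expanded_text = table[m.text]
    return corpus


class TypeMapError(KeyError):
    pass


def filter_by_semantic_group(
    cands: CandidateSet,
    mention_class: str,
    type_map: dict[str, set[str]],
    kb: KnowledgeBase,
) -> CandidateSet:
    """Keep candidates whose concept types intersect the mapped type set.

    The map must be total over the classes being filtered (unknown class is
    a hard error).  The output is a subsequence of the input: relative order
    and scores are preserved, and the result may be empty (in which case the
    downstream prediction is NIL).
    """
    if mention_class not in type_map:
        raise TypeMapError(f"semantic class {mention_class!r} missing from type map")
    allowed = set(type_map[mention_class])
    keep = set()
    for cid in cands.ids:
        concept = kb.concepts.get(cid)
        if concept is None:
            continue
        if (concept.semantic_types | kb.groups_of(concept)) & allowed:
            keep.add(cid)
    return cands.subset(keep)


def filter_corpus_candidates(
    corpus: Corpus, type_map: dict[str, set[str]], kb: KnowledgeBase
) -> Corpus:
    for m in corpus.mentions:
        if m.candidates is not None and m.semantic_class is not None:
            m.candidates = filter_by_semantic_group(m.candidates, m.semantic_class, type_map, kb)
    return corpus
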