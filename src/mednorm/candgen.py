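"""Candidate generation: alias indices and ranked concept candidates.

Every alias in the target KB is embedded — sparsely as TF-IDF over character
n-grams (surface-form matching) and/or densely through a pluggable text
encoder — to build an index.  At inference the mention surface is embedded
the same way and a nearest-neighbour search over the alias vectors yields a
ranked list of k candidate concepts per mention; multiple generators are
fused by weighted score combination.

Scores are cosine similarities.  Alias hits are aggregated to concepts by
maximum (a concept ranks by its best-matching synonym), and equal scores are
broken by ascending concept id so that ranking is total and deterministic:
concepts sharing an alias receive identical scores and only a defined
tie-break (or a downstream re-ranker) separates them.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from sklearn.feature_extraction.text import TfidfVectorizer

from .corpus import Corpus
from .kb import KnowledgeBase, normalize_surface

DEFAULT_K = 64
DEFAULT_NGRAM = 3

# Cosine scores are quantized to this resolution before ranking so ordering
# (and the exact-tie rule) is independent of floating-point summation order.
SCORE_DECIMALS = 9


@dataclass
class CandidateSet:
    """Ranked candidate concepts for one mention.

    Entries are sorted by combined score descending, ties by ascending
    concept id; no duplicate ids; length capped at ``k``.
    """

    mention_id: str
    entries: list[tuple[str, float]]  # (concept id, combined score in [0, 1])
    k: int
    per_generator: dict[str, list[tuple[str, float]]] = field(default_factory=dict)

    @property
    def ids(self) -> list[str]:
        return [cid for cid, _ in self.entries]

    def top_ids(self, k: int) -> list[str]:
        return [cid for cid, _ in self.entries[:k]]

    def subset(self, keep_ids: set[str]) -> "CandidateSet":
        """Subsequence restriction: order and scores preserved."""
        return CandidateSet(
            mention_id=self.mention_id,
            entries=[(c, s) for c, s in self.entries if c in keep_ids],
            k=self.k,
            per_generator=self.per_generator,
        )

    def to_records(self) -> list[dict]:
        return [{"id": c, "score": s} for c, s in self.entries]

    @classmethod
    def from_records(cls, records: list[dict], mention_id: str = "", k: int | None = None):
        entries = [(r["id"], float(r["score"])) for r in records]
        return cls(mention_id=mention_id, entries=entries, k=k or max(len(entries), 1))


class DenseEncoder:
    """Contract for dense text encoders: deterministic text -> unit vector."""

    dimension: int

    def encode(self, text: str) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def encode_batch(self, texts: list[str]) -> np.ndarray:
        return np.stack([self.encode(t) for t in texts]) if texts else np.zeros((0, self.dimension))


class HashedNgramEncoder(DenseEncoder):
    """Deterministic reference encoder: signed hashed character n-grams.

    Each word-boundary-padded character n-gram of the NFKC-casefolded text is
    hashed (BLAKE2b) to a coordinate and a sign; the accumulated vector is
    L2-normalized.  Runs anywhere, needs no model download, and preserves the
    property that lexically similar strings are close in cosine space, which
    is what the pipeline requires of a production embedding model.
    """

    def __init__(self, dimension: int = 256, n: int = DEFAULT_NGRAM):
        self.dimension = dimension
        self.n = n

    def _ngrams(self, text: str) -> list[str]:
        out = []
        for word in normalize_surface(text).split():
            padded = f" {word} "
            if len(padded) <= self.n:
                out.append(padded)
            else:
                out.extend(padded[i : i + self.n] for i in range(len(padded) - self.n + 1))
        return out

    def encode(self, text: str) -> np.ndarray:
        vec = np.zeros(self.dimension)
        for g in self._ngrams(text):
            h = hashlib.blake2b(g.encode("utf-8"), digest_size=8).digest()
            val = int.from_bytes(h, "big")
            idx = val % self.dimension
            sign = 1.0 if (val >> 32) & 1 else -1.0
            vec[idx] += sign
        norm = np.linalg.norm(vec)
        return vec / norm if norm > 0 else vec


@dataclass
class AliasIndex:
    """Vector index over (alias surface, concept id) pairs of one KB."""

    kind: str  # "sparse" | "dense"
    entries: list[tuple[str, str]]  # (normalized alias surface, concept id)
    matrix: object  # unit-row-norm matrix, scipy CSR (sparse) or ndarray (dense)
    vectorizer: object = None  # TfidfVectorizer for kind == "sparse"
    encoder: DenseEncoder | None = None

    def embed_query(self, surface: str):
        if self.kind == "sparse":
            return self.vectorizer.transform([normalize_surface(surface)])
        return self.encoder.encode(surface)[None, :]


def build_sparse_index(kb: KnowledgeBase, n: int = DEFAULT_NGRAM) -> AliasIndex:
    """TF-IDF over word-boundary-padded character n-grams of all KB aliases."""
    entries = _alias_entries(kb)
    if not entries:
        raise ValueError("cannot index a KB with zero aliases")
    surfaces = [s for s, _c in entries]
    vectorizer = TfidfVectorizer(
        analyzer="char_wb", ngram_range=(n, n), lowercase=False, norm="l2"
    )
    matrix = vectorizer.fit_transform(surfaces)
    return AliasIndex(kind="sparse", entries=entries, matrix=matrix.tocsr(), vectorizer=vectorizer)


def build_dense_index(kb: KnowledgeBase, encoder: DenseEncoder) -> AliasIndex:
    entries = _alias_entries(kb)
    if not entries:
        raise ValueError("cannot index a KB with zero aliases")
    matrix = encoder.encode_batch([s for s, _c in entries])
    return AliasIndex(kind="dense", entries=entries, matrix=matrix, encoder=encoder)


def _alias_entries(kb: KnowledgeBase) -> list[tuple[str, str]]:
    entries = []
    for cid in sorted(kb.concepts):
        for surface, _lang in sorted(kb.concepts[cid].aliases):
            entries.append((normalize_surface(surface), cid))
    return entries


def query_index(index: AliasIndex, surface: str, k: int) -> list[tuple[str, float]]:
    """Top-k concepts by cosine score, max-aggregated over each concept's aliases.

    Exact search; scores quantized to ``SCORE_DECIMALS`` and ties broken by
    ascending concept id.  Empty surfaces yield an empty result.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not surface or not normalize_surface(surface):
        return []
    q = index.embed_query(surface)
    if index.kind == "sparse":
        scores = np.asarray((index.matrix @ q.T).todense()).ravel()
    else:
        scores = index.matrix @ q.ravel()
    scores = np.round(scores, SCORE_DECIMALS)
    best: dict[str, float] = {}
    for (alias, cid), score in zip(index.entries, scores):
        if score > best.get(cid, -np.inf):
            best[cid] = float(score)
    ranked = sorted(best.items(), key=lambda t: (-t[1], t[0]))
    return ranked[:k]


def ensemble_merge(
    lists: dict[str, list[tuple[str, float]]],
    weights: dict[str, float],
    k: int,
    mention_id: str = "",
) -> CandidateSet:
    """Fuse per-generator ranked lists by weighted min–max-normalized scores.

    Per list, scores are min–max normalized to [0, 1] for this mention
    (degenerate single-valued lists map to 1.0); the combined score is the
    weighted sum with missing entries contributing 0; ranking uses the
    standard tie rule and the list is truncated to ``k``.
    """
    if not lists:
        raise ValueError("ensemble_merge requires at least one candidate list")
    if set(lists) != set(weights):
        raise ValueError("generator names of lists and weights differ")
    total_w = sum(weights.values())
    if not np.isclose(total_w, 1.0):
        raise ValueError(f"weights must sum to 1, got {total_w}")
    combined: dict[str, float] = {}
    for name, ranked in lists.items():
        if not ranked:
            continue
        vals = [s for _c, s in ranked]
        lo, hi = min(vals), max(vals)
        for cid, s in ranked:
            norm = 1.0 if hi == lo else (s - lo) / (hi - lo)
            combined[cid] = combined.get(cid, 0.0) + weights[name] * norm
    entries = sorted(combined.items(), key=lambda t: (-round(t[1], SCORE_DECIMALS), t[0]))
    return CandidateSet(
        mention_id=mention_id, entries=entries[:k], k=k, per_generator=dict(lists)
    )


def generate_candidates(
    corpus: Corpus,
    indices: dict[str, AliasIndex],
    weights: dict[str, float] | None = None,
    k: int = DEFAULT_K,
) -> Corpus:
    """Attach a CandidateSet to every mention of the corpus (in place).

    The abbreviation-expanded surface is used as the query when present.
    With a single generator the merge is the identity on its ranking.
    """
    if weights is None:
        weights = {name: 1.0 / len(indices) for name in indices}
    for m in corpus.mentions:
        per_gen = {
            name: query_index(index, m.query_surface, k)
            for name, index in indices.items()
        }
        m.candidates = ensemble_merge(per_gen, weights, k, mention_id=m.mention_id)
    return corpus
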