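"""Knowledge bases: terminology concepts with multilingual aliases.

A :class:`KnowledgeBase` is the normalization target: a map from opaque
concept identifiers (e.g., UMLS CUIs) to :class:`Concept` records carrying a
canonical name, language-tagged aliases, semantic type codes, and source
vocabularies.  KBs are built either from UMLS-style RRF distribution files
(``MRCONSO.RRF`` / ``MRSTY.RRF``) or from custom concept dictionaries, and
can be subset by language, source vocabulary and semantic group to obtain
task-specific target terminologies.
"""

from __future__ import annotations

import json
import logging
import re
import unicodedata
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

KB_FORMAT_VERSION = "mednorm-kb-1"

# Column indices in the standard UMLS RRF layouts (pipe-delimited, no
# quoting, trailing empty field).  Only these columns are consumed.
_MRCONSO_NCOLS = 18
_MRCONSO_CUI = 0
_MRCONSO_LAT = 1
_MRCONSO_TS = 2
_MRCONSO_ISPREF = 6
_MRCONSO_SAB = 11
_MRCONSO_STR = 14
_MRCONSO_SUPPRESS = 16
_MRSTY_NCOLS = 6
_MRSTY_CUI = 0
_MRSTY_TUI = 1

_WS_RE = re.compile(r"\s+")


def normalize_surface(text: str) -> str:
    """Normalize a surface string for deduplication and indexing.

    Unicode NFKC, casefold, and collapse of internal whitespace.  The
    original surface is preserved on the concept for display; this form is
    the key under which aliases are deduplicated and retrieved.
    """
    return _WS_RE.sub(" ", unicodedata.normalize("NFKC", text).casefold()).strip()


@dataclass
class Concept:
    """One terminology entry: identifier, names, and semantic metadata."""

    id: str
    canonical_name: str
    aliases: set[tuple[str, str]] = field(default_factory=set)  # (surface, lang)
    semantic_types: set[str] = field(default_factory=set)
    source_vocabularies: set[str] = field(default_factory=set)

    def normalized_aliases(self) -> set[str]:
        return {normalize_surface(s) for s, _lang in self.aliases}


@dataclass
class BuildConfig:
    """Filter settings a KB was built (or subset) with."""

    languages: set[str] = field(default_factory=set)
    source_vocabularies: set[str] = field(default_factory=set)
    semantic_groups: set[str] = field(default_factory=set)
    drop_suppressed: bool = True
    # Optional fine-grained-type -> coarse-group table used when
    # ``semantic_groups`` is non-empty (e.g., TUI -> UMLS semantic group).
    type_to_group: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "languages": sorted(self.languages),
            "source_vocabularies": sorted(self.source_vocabularies),
            "semantic_groups": sorted(self.semantic_groups),
            "drop_suppressed": self.drop_suppressed,
            "type_to_group": dict(sorted(self.type_to_group.items())),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BuildConfig":
        return cls(
            languages=set(d.get("languages", ())),
            source_vocabularies=set(d.get("source_vocabularies", ())),
            semantic_groups=set(d.get("semantic_groups", ())),
            drop_suppressed=bool(d.get("drop_suppressed", True)),
            type_to_group=dict(d.get("type_to_group", {})),
        )


@dataclass
class KnowledgeBase:
    concepts: dict[str, Concept] = field(default_factory=dict)
    build_config: BuildConfig = field(default_factory=BuildConfig)

    @property
    def alias_count(self) -> int:
        return sum(len(c.aliases) for c in self.concepts.values())

    def groups_of(self, concept: Concept) -> set[str]:
        """Coarse semantic groups of a concept under the configured map.

        Types without a mapping pass through unchanged, so a KB without a
        group table can still be filtered directly by type code.
        """
        tmap = self.build_config.type_to_group
        return {tmap.get(t, t) for t in concept.semantic_types}


class KBFormatError(ValueError):
    """Raised for malformed terminology inputs or serialized KBs."""


def _dedup_aliases(aliases) -> set[tuple[str, str]]:
    """Keep one surface per (normalized form, language); first wins."""
    seen: dict[tuple[str, str], tuple[str, str]] = {}
    for surface, lang in aliases:
        key = (normalize_surface(surface), lang)
        if key not in seen:
            seen[key] = (surface, lang)
    return set(seen.values())


def parse_umls_rrf(conso_path, sty_path, filters: BuildConfig | None = None) -> KnowledgeBase:
    """Build a KB from MRCONSO.RRF / MRSTY.RRF files.

    Rows failing any filter (language, source vocabulary, suppression) are
    skipped; a concept is kept only if at least one alias row survives and,
    when ``filters.semantic_groups`` is non-empty, its mapped groups
    intersect the requested set.  The result is independent of row order
    except for the canonical-name choice, which is the first preferred-term
    row (TS=P, ISPREF=Y) per CUI in file order, falling back to the first
    retained row.
    """
    filters = filters or BuildConfig()
    # alias rows per CUI, in file order: (surface, lang, sab, is_pref)
    rows: dict[str, list[tuple[str, str, str, bool]]] = {}
    with open(conso_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("|")
            if cols and cols[-1] == "":  # trailing delimiter
                cols = cols[:-1]
            if len(cols) != _MRCONSO_NCOLS:
                raise KBFormatError(
                    f"{conso_path}:{lineno}: expected {_MRCONSO_NCOLS} columns, got {len(cols)}"
                )
            cui, lat = cols[_MRCONSO_CUI], cols[_MRCONSO_LAT]
            sab, surface = cols[_MRCONSO_SAB], cols[_MRCONSO_STR]
            suppress = cols[_MRCONSO_SUPPRESS]
            if filters.drop_suppressed and suppress in ("O", "E", "Y"):
                continue
            if filters.languages and lat not in filters.languages:
                continue
            if filters.source_vocabularies and sab not in filters.source_vocabularies:
                continue
            is_pref = cols[_MRCONSO_TS] == "P" and cols[_MRCONSO_ISPREF] == "Y"
            rows.setdefault(cui, []).append((surface, lat, sab, is_pref))

    types: dict[str, set[str]] = {}
    with open(sty_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("|")
            if cols and cols[-1] == "":
                cols = cols[:-1]
            if len(cols) != _MRSTY_NCOLS:
                raise KBFormatError(
                    f"{sty_path}:{lineno}: expected {_MRSTY_NCOLS} columns, got {len(cols)}"
                )
            cui, tui = cols[_MRSTY_CUI], cols[_MRSTY_TUI]
            if cui not in rows:
                logger.warning("MRSTY row %d: CUI %s has no retained aliases; ignored", lineno, cui)
                continue
            types.setdefault(cui, set()).add(tui)

    kb = KnowledgeBase(build_config=filters)
    for cui in sorted(rows):
        alias_rows = rows[cui]
        canonical = next((s for s, _l, _v, pref in alias_rows if pref), alias_rows[0][0])
        concept = Concept(
            id=cui,
            canonical_name=canonical,
            aliases=_dedup_aliases((s, lang) for s, lang, _v, _p in alias_rows),
            semantic_types=types.get(cui, set()),
            source_vocabularies={v for _s, _l, v, _p in alias_rows},
        )
        if filters.semantic_groups:
            if not (kb.groups_of(concept) & filters.semantic_groups):
                continue
        kb.concepts[cui] = concept
    return kb


def parse_custom_dict(path) -> KnowledgeBase:
    """Load a custom concept dictionary (JSON lines, one record per line).

    Each record: ``{"id": ..., "name": ..., "aliases": [[surface, lang],
    ...], "types": [...], "sources": [...]}``.  The canonical name is added
    to the alias set if missing (language code ``""`` = unspecified).
    """
    kb = KnowledgeBase()
    with open(path, encoding="utf-8") as fh:
        for idx, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            cid, name = rec.get("id"), rec.get("name")
            if not cid or not name:
                raise KBFormatError(f"record {idx}: missing id or name")
            if cid in kb.concepts:
                raise KBFormatError(f"duplicate concept id {cid!r}")
            aliases = [(s, lang or "") for s, lang in (tuple(a) for a in rec.get("aliases", ()))]
            norms = {(normalize_surface(s), lang) for s, lang in aliases}
            if not any(n == normalize_surface(name) for n, _l in norms):
                aliases.append((name, rec.get("language", "")))
            kb.concepts[cid] = Concept(
                id=cid,
                canonical_name=name,
                aliases=_dedup_aliases(aliases),
                semantic_types=set(rec.get("types", ())),
                source_vocabularies=set(rec.get("sources", ())),
            )
    return kb


def subset_kb(
    kb: KnowledgeBase,
    languages: set[str] | None = None,
    sabs: set[str] | None = None,
    groups: set[str] | None = None,
) -> KnowledgeBase:
    """Restrict a KB by language, source vocabulary, and semantic group.

    Empty/None filter sets mean no restriction.  A concept survives iff it
    retains at least one alias after language filtering, its source
    vocabularies intersect ``sabs`` (when given), and its mapped semantic
    groups intersect ``groups`` (when given).  Idempotent and monotone.
    """
    languages = set(languages or ())
    sabs = set(sabs or ())
    groups = set(groups or ())
    cfg = BuildConfig(
        languages=languages or set(kb.build_config.languages),
        source_vocabularies=sabs or set(kb.build_config.source_vocabularies),
        semantic_groups=groups or set(kb.build_config.semantic_groups),
        drop_suppressed=kb.build_config.drop_suppressed,
        type_to_group=dict(kb.build_config.type_to_group),
    )
    out = KnowledgeBase(build_config=cfg)
    for cid, c in kb.concepts.items():
        if sabs and not (c.source_vocabularies & sabs):
            continue
        if groups and not (kb.groups_of(c) & groups):
            continue
        aliases = {(s, l) for s, l in c.aliases if not languages or l in languages}
        if not aliases:
            continue
        canonical = c.canonical_name
        if normalize_surface(canonical) not in {normalize_surface(s) for s, _l in aliases}:
            # canonical surface was filtered out; fall back to the first
            # surviving alias (sorted for determinism)
            canonical = min(aliases)[0]
        out.concepts[cid] = Concept(
            id=cid,
            canonical_name=canonical,
            aliases=aliases,
            semantic_types=set(c.semantic_types),
            source_vocabularies=set(c.source_vocabularies),
        )
    return out


def add_aliases(
    kb: KnowledgeBase, extra: dict[str, set[tuple[str, str]]]
) -> tuple[KnowledgeBase, list[str]]:
    """Union extra aliases into a KB with normalization-aware dedup.

    Unknown concept ids are collected into the returned report rather than
    raising: supplementary alias lists (e.g., drug synonym gazetteers)
    routinely cover more ids than a task-specific KB subset.
    """
    unknown: list[str] = []
    out = KnowledgeBase(build_config=kb.build_config)
    out.concepts = {
        cid: Concept(
            id=c.id,
            canonical_name=c.canonical_name,
            aliases=set(c.aliases),
            semantic_types=set(c.semantic_types),
            source_vocabularies=set(c.source_vocabularies),
        )
        for cid, c in kb.concepts.items()
    }
    for cid, aliases in extra.items():
        concept = out.concepts.get(cid)
        if concept is None:
            unknown.append(cid)
            continue
        existing = {(normalize_surface(s), l) for s, l in concept.aliases}
        for surface, lang in sorted(aliases):
            key = (normalize_surface(surface), lang)
            if key not in existing:
                concept.aliases.add((surface, lang))
                existing.add(key)
    return out, sorted(unknown)


def save_kb(kb: KnowledgeBase, path) -> None:
    """Serialize as versioned JSON lines: header record, then one concept per line."""
    with open(path, "w", encoding="utf-8") as fh:
        header = {"format": KB_FORMAT_VERSION, "build_config": kb.build_config.to_dict(),
                  "n_concepts": len(kb.concepts)}
        fh.write(json.dumps(header, ensure_ascii=False) + "\n")
        for cid in sorted(kb.concepts):
            c = kb.concepts[cid]
            rec = {
                "id": c.id,
                "name": c.canonical_name,
                "aliases": sorted([s, l] for s, l in c.aliases),
                "types": sorted(c.semantic_types),
                "sources": sorted(c.source_vocabularies),
            }
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")


def load_kb(path) -> KnowledgeBase:
    with open(path, encoding="utf-8") as fh:
        header_line = fh.readline()
        if not header_line:
            raise KBFormatError(f"{path}: empty KB file")
        header = json.loads(header_line)
        if header.get("format") != KB_FORMAT_VERSION:
            raise KBFormatError(
                f"{path}: unsupported KB format tag {header.get('format')!r}"
            )
        kb = KnowledgeBase(build_config=BuildConfig.from_dict(header.get("build_config", {})))
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            kb.concepts[rec["id"]] = Concept(
                id=rec["id"],
                canonical_name=rec["name"],
                aliases={(s, l) for s, l in rec["aliases"]},
                semantic_types=set(rec["types"]),
                source_vocabularies=set(rec["sources"]),
            )
        if len(kb.concepts) != header.get("n_concepts", len(kb.concepts)):
            raise KBFormatError(
                f"{path}: truncated KB file: header promises {header['n_concepts']} "
                f"concepts, found {len(kb.concepts)}"
            )
    return kb
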