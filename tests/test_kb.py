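"""Knowledge-base construction, subsetting, and serialization."""

import random

import pytest

from mednorm.kb import (
    BuildConfig,
    KBFormatError,
    add_aliases,
    load_kb,
    normalize_surface,
    parse_custom_dict,
    parse_umls_rrf,
    save_kb,
    subset_kb,
)
from mednorm.testkit import SynthSpec, synth_kb


def _conso_row(cui, lat, surface, sab="SNOMED", suppress="N", ts="P", ispref="Y"):
    cols = [""] * 18
    cols[0], cols[1], cols[2], cols[6] = cui, lat, ts, ispref
    cols[11], cols[14], cols[16] = sab, surface, suppress
    return "|".join(cols) + "|"


def _sty_row(cui, tui):
    cols = [""] * 6
    cols[0], cols[1] = cui, tui
    return "|".join(cols) + "|"


def _write(path, lines):
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


class TestParseRRF:
    def test_single_concept_row_maps_columns(self, tmp_path):
        _write(tmp_path / "c.rrf", [_conso_row("C0000001", "ENG", "Myocardial biopsy")])
        _write(tmp_path / "s.rrf", [_sty_row("C0000001", "T060")])
        kb = parse_umls_rrf(tmp_path / "c.rrf", tmp_path / "s.rrf")
        assert len(kb.concepts) == 1
        assert kb.alias_count == 1
        concept = kb.concepts["C0000001"]
        assert concept.semantic_types == {"T060"}
        assert concept.canonical_name == "Myocardial biopsy"

    def test_language_filter_excludes_all_rows(self, tmp_path):
        _write(tmp_path / "c.rrf", [_conso_row("C0000001", "ENG", "Myocardial biopsy")])
        _write(tmp_path / "s.rrf", [_sty_row("C0000001", "T060")])
        kb = parse_umls_rrf(
            tmp_path / "c.rrf", tmp_path / "s.rrf", BuildConfig(languages={"GER"})
        )
        assert len(kb.concepts) == 0

    def test_mixed_language_fixture_hand_counted(self, tmp_path):
        # 3 concepts, 5 rows: C1 has ENG+GER aliases, C2 one GER alias,
        # C3 one ENG alias plus one suppressed row.  Dropping suppressed
        # leaves 4 alias rows over 3 concepts (hand count).
        rows = [
            _conso_row("C1", "ENG", "heart failure"),
            _conso_row("C1", "GER", "Herzinsuffizienz", ts="S", ispref="N"),
            _conso_row("C2", "GER", "Lungenentzündung"),
            _conso_row("C3", "ENG", "asthma"),
            _conso_row("C3", "ENG", "suppressed synonym", suppress="O", ts="S", ispref="N"),
        ]
        _write(tmp_path / "c.rrf", rows)
        _write(tmp_path / "s.rrf", [_sty_row("C1", "T047"), _sty_row("C2", "T047"), _sty_row("C3", "T047")])
        kb = parse_umls_rrf(tmp_path / "c.rrf", tmp_path / "s.rrf")
        assert len(kb.concepts) == 3
        assert kb.alias_count == 4
        kb_ger = parse_umls_rrf(
            tmp_path / "c.rrf", tmp_path / "s.rrf", BuildConfig(languages={"GER"})
        )
        assert set(kb_ger.concepts) == {"C1", "C2"}
        assert kb_ger.alias_count == 2

    def test_malformed_line_raises_with_line_number(self, tmp_path):
        _write(tmp_path / "c.rrf", [_conso_row("C1", "ENG", "x"), "too|few|columns"])
        _write(tmp_path / "s.rrf", [_sty_row("C1", "T047")])
        with pytest.raises(KBFormatError, match=":2"):
            parse_umls_rrf(tmp_path / "c.rrf", tmp_path / "s.rrf")

    def test_sty_for_absent_cui_is_ignored(self, tmp_path, caplog):
        _write(tmp_path / "c.rrf", [_conso_row("C1", "ENG", "x")])
        _write(tmp_path / "s.rrf", [_sty_row("C1", "T047"), _sty_row("C9", "T047")])
        kb = parse_umls_rrf(tmp_path / "c.rrf", tmp_path / "s.rrf")
        assert set(kb.concepts) == {"C1"}

    def test_row_permutation_invariance(self, tmp_path):
        rows = [
            _conso_row("C1", "ENG", "alpha"),
            _conso_row("C1", "ENG", "beta", ts="S", ispref="N"),
            _conso_row("C2", "ENG", "gamma"),
        ]
        sty = [_sty_row("C1", "T047"), _sty_row("C2", "T061")]
        _write(tmp_path / "c1.rrf", rows)
        _write(tmp_path / "s1.rrf", sty)
        kb_a = parse_umls_rrf(tmp_path / "c1.rrf", tmp_path / "s1.rrf")
        rng = random.Random(3)
        for trial in range(5):
            shuffled = rows[:]
            rng.shuffle(shuffled)
            _write(tmp_path / "c2.rrf", shuffled)
            kb_b = parse_umls_rrf(tmp_path / "c2.rrf", tmp_path / "s1.rrf")
            assert {c: kb_a.concepts[c].aliases for c in kb_a.concepts} == {
                c: kb_b.concepts[c].aliases for c in kb_b.concepts
            }
            # canonical name comes from the preferred-term row wherever it moves
            assert kb_b.concepts["C1"].canonical_name == "alpha"


class TestCustomDict:
    def test_name_added_to_aliases(self, tmp_path):
        p = tmp_path / "d.jsonl"
        p.write_text(
            '{"id": "I21", "name": "Myokardinfarkt", "aliases": [["Herzinfarkt", "de"]], "types": ["DISO"]}\n'
        )
        kb = parse_custom_dict(p)
        assert len(kb.concepts["I21"].aliases) == 2

    def test_duplicate_id_raises(self, tmp_path):
        p = tmp_path / "d.jsonl"
        p.write_text(
            '{"id": "I21", "name": "a"}\n{"id": "I21", "name": "b"}\n'
        )
        with pytest.raises(KBFormatError, match="I21"):
            parse_custom_dict(p)

    def test_missing_name_raises_with_index(self, tmp_path):
        p = tmp_path / "d.jsonl"
        p.write_text('{"id": "X"}\n')
        with pytest.raises(KBFormatError, match="record 0"):
            parse_custom_dict(p)

    def test_alias_count_matches_hand_count(self, tmp_path):
        # 50 records, record i has i % 3 aliases; names never among them,
        # so every record contributes (i % 3) + 1 aliases
        lines = []
        expected = 0
        for i in range(50):
            aliases = [[f"alias-{i}-{j}", "en"] for j in range(i % 3)]
            expected += len(aliases) + 1
            lines.append(
                '{"id": "R%d", "name": "name-%d", "aliases": %s}'
                % (i, i, str(aliases).replace("'", '"'))
            )
        p = tmp_path / "d.jsonl"
        p.write_text("\n".join(lines) + "\n")
        kb = parse_custom_dict(p)
        assert kb.alias_count == expected


class TestSubset:
    def test_group_filter_can_empty_the_kb(self, tiny_kb):
        assert subset_kb(tiny_kb, groups={"ANAT"}).concepts == {}

    def test_empty_filters_are_identity(self, tiny_kb):
        out = subset_kb(tiny_kb)
        assert set(out.concepts) == set(tiny_kb.concepts)
        assert out.alias_count == tiny_kb.alias_count

    def test_language_filter_hand_counted(self, tiny_kb):
        out = subset_kb(tiny_kb, languages={"de"})
        # only C2 has a German alias
        assert set(out.concepts) == {"C2"}
        assert out.alias_count == 1
        assert out.concepts["C2"].canonical_name == "Herzinfarkt"

    def test_idempotent_and_monotone(self, small_kb):
        once = subset_kb(small_kb, languages={"ENG"}, groups={"DISO"})
        twice = subset_kb(once, languages={"ENG"}, groups={"DISO"})
        assert {c: once.concepts[c].aliases for c in once.concepts} == {
            c: twice.concepts[c].aliases for c in twice.concepts
        }
        assert len(once.concepts) <= len(small_kb.concepts)
        assert once.alias_count <= small_kb.alias_count
        # adding a filter never increases counts
        narrower = subset_kb(small_kb, languages={"ENG"}, groups={"DISO"}, sabs={"NOPE"})
        assert len(narrower.concepts) <= len(once.concepts)


class TestAddAliases:
    def test_new_alias_increments_count(self, tiny_kb):
        out, unknown = add_aliases(tiny_kb, {"C1": {("acetylsalicylic acid", "en")}})
        assert out.alias_count == tiny_kb.alias_count + 1
        assert unknown == []

    def test_case_duplicate_is_not_added(self, tiny_kb):
        out, _ = add_aliases(tiny_kb, {"C1": {("MYOCARDIAL BIOPSY", "en")}})
        assert out.alias_count == tiny_kb.alias_count

    def test_unknown_id_reported_not_raised(self, tiny_kb):
        out, unknown = add_aliases(
            tiny_kb, {"C1": {("new synonym", "en")}, "C99": {("ghost", "en")}}
        )
        assert out.alias_count == tiny_kb.alias_count + 1
        assert unknown == ["C99"]


class TestRoundTrip:
    def test_save_load_identity(self, tiny_kb, tmp_path):
        path = tmp_path / "kb.jsonl"
        save_kb(tiny_kb, path)
        loaded = load_kb(path)
        assert set(loaded.concepts) == set(tiny_kb.concepts)
        for cid in tiny_kb.concepts:
            a, b = tiny_kb.concepts[cid], loaded.concepts[cid]
            assert (a.canonical_name, a.aliases, a.semantic_types, a.source_vocabularies) == (
                b.canonical_name, b.aliases, b.semantic_types, b.source_vocabularies
            )

    def test_build_config_preserved(self, tmp_path):
        spec = SynthSpec(n_concepts=5, seed=1)
        kb = synth_kb(spec)
        kb.build_config = BuildConfig(languages={"ENG"}, semantic_groups={"DISO"})
        path = tmp_path / "kb.jsonl"
        save_kb(kb, path)
        loaded = load_kb(path)
        assert loaded.build_config.languages == {"ENG"}
        assert loaded.build_config.semantic_groups == {"DISO"}

    def test_truncated_file_raises(self, tiny_kb, tmp_path):
        path = tmp_path / "kb.jsonl"
        save_kb(tiny_kb, path)
        lines = path.read_text().splitlines()
        path.write_text("\n".join(lines[:-1]) + "\n")
        with pytest.raises(KBFormatError, match="truncated"):
            load_kb(path)

    def test_wrong_version_tag_raises(self, tmp_path):
        path = tmp_path / "kb.jsonl"
        path.write_text('{"format": "something-else", "n_concepts": 0}\n')
        with pytest.raises(KBFormatError, match="format"):
            load_kb(path)


def test_normalize_surface_nfkc_casefold_whitespace():
    assert normalize_surface("  Héart  Failure ") == normalize_surface("héart failure")
    assert normalize_surface("ÄRZTIN") == normalize_surface("ärztin")
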