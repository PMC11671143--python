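import pytest

from mednorm.kb import BuildConfig, Concept, KnowledgeBase
from mednorm.testkit import SynthSpec, synth_corpus, synth_kb


@pytest.fixture
def tiny_kb() -> KnowledgeBase:
    """Two cardiology concepts plus one sharing an alias with another."""
    kb = KnowledgeBase(build_config=BuildConfig())
    kb.concepts["C1"] = Concept(
        id="C1",
        canonical_name="myocardial biopsy",
        aliases={("myocardial biopsy", "en"), ("biopsy of myocardium", "en")},
        semantic_types={"PROC"},
        source_vocabularies={"V1"},
    )
    kb.concepts["C2"] = Concept(
        id="C2",
        canonical_name="myocardial infarction",
        aliases={("myocardial infarction", "en"), ("Herzinfarkt", "de")},
        semantic_types={"DISO"},
        source_vocabularies={"V1"},
    )
    kb.concepts["C3"] = Concept(
        id="C3",
        canonical_name="lupus vulgaris",
        aliases={("lupus vulgaris", "en"), ("lupus", "en")},
        semantic_types={"DISO"},
        source_vocabularies={"V2"},
    )
    kb.concepts["C4"] = Concept(
        id="C4",
        canonical_name="lupus erythematosus",
        aliases={("lupus erythematosus", "en"), ("lupus", "en")},
        semantic_types={"DISO"},
        source_vocabularies={"V2"},
    )
    return kb


@pytest.fixture(scope="session")
def small_spec() -> SynthSpec:
    return SynthSpec(n_concepts=30, ambiguity_rate=0.2, seed=5)


@pytest.fixture(scope="session")
def small_kb(small_spec):
    return synth_kb(small_spec)


@pytest.fixture(scope="session")
def small_corpora(small_kb, small_spec):
    return synth_corpus(small_kb, small_spec, 120, split=0.5)
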