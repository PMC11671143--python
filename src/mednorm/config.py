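"""YAML pipeline configuration and the staged generate-and-rank driver.

The pipeline runs fixed stages in order: abbreviation expansion → candidate
generation → optional semantic-group filtering → optional re-ranking →
evaluation (when gold annotations are present).  All stage parameters come
from one validated config object; unknown keys are rejected by name, and all
randomness flows from the single configured seed.
"""

from __future__ import annotations

import logging

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import candgen, evaluation, preprocess, rerank
from .corpus import NIL, Corpus
from .kb import KnowledgeBase

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class KBSection(_Section):
    source: str | None = None  # path to a saved KB or custom dict (JSONL)
    rrf_conso: str | None = None
    rrf_sty: str | None = None
    languages: list[str] = Field(default_factory=list)
    sabs: list[str] = Field(default_factory=list)
    groups: list[str] = Field(default_factory=list)
    drop_suppressed: bool = True
    type_to_group: dict[str, str] = Field(default_factory=dict)


class CandgenSection(_Section):
    k: int = 64
    ngram_size: int = 3
    generators: list[str] = Field(default_factory=lambda: ["sparse", "dense"])
    weights: dict[str, float] = Field(default_factory=dict)
    encoder: str = "hashed-ngram"
    encoder_dim: int = 256


class RerankSection(_Section):
    enabled: bool = True
    lambda_reg: float = 1.0
    k_train: int = 16
    epochs: int = 10
    learning_rate: float = 0.5
    window: int = 128
    max_aliases: int = 3


class EvalSection(_Section):
    ks: list[int] = Field(default_factory=lambda: [1, 2, 4, 8, 16, 32, 64])
    type_map: dict[str, list[str]] = Field(default_factory=dict)
    expand_abbreviations: bool = True


class PipelineConfig(_Section):
    kb: KBSection = Field(default_factory=KBSection)
    candgen: CandgenSection = Field(default_factory=CandgenSection)
    rerank: RerankSection = Field(default_factory=RerankSection)
    eval: EvalSection = Field(default_factory=EvalSection)
    seed: int = 0

    def train_config(self) -> rerank.TrainConfig:
        return rerank.TrainConfig(
            lambda_reg=self.rerank.lambda_reg,
            k_train=self.rerank.k_train,
            epochs=self.rerank.epochs,
            learning_rate=self.rerank.learning_rate,
            seed=self.seed,
            window=self.rerank.window,
            max_aliases=self.rerank.max_aliases,
        )


def parse_config(path) -> PipelineConfig:
    """Load and validate a YAML pipeline config; defaults fill missing keys."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    try:
        return PipelineConfig.model_validate(data)
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc


def dump_config(config: PipelineConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.model_dump(), fh, sort_keys=True)


def build_indices(config: PipelineConfig, kb: KnowledgeBase) -> dict[str, candgen.AliasIndex]:
    indices: dict[str, candgen.AliasIndex] = {}
    for name in config.candgen.generators:
        if name == "sparse":
            indices[name] = candgen.build_sparse_index(kb, n=config.candgen.ngram_size)
        elif name == "dense":
            encoder = candgen.HashedNgramEncoder(
                dimension=config.candgen.encoder_dim, n=config.candgen.ngram_size
            )
            indices[name] = candgen.build_dense_index(kb, encoder)
        else:
            raise ConfigError(f"unknown candidate generator {name!r}")
    return indices


def run_pipeline(
    config: PipelineConfig,
    corpus: Corpus,
    kb: KnowledgeBase,
    train_corpus: Corpus | None = None,
    indices: dict[str, candgen.AliasIndex] | None = None,
    backbone: rerank.ScoringBackbone | None = None,
) -> tuple[Corpus, evaluation.EvalReport]:
    """Run the staged pipeline on a corpus and evaluate when gold ids exist.

    When re-ranking is enabled and no trained backbone is supplied, a
    reference backbone is trained on ``train_corpus`` (which must then be
    provided).  Stage progress is logged with counts.
    """
    weights = config.candgen.weights or {
        g: 1.0 / len(config.candgen.generators) for g in config.candgen.generators
    }
    if set(weights) != set(config.candgen.generators):
        raise ConfigError("candgen.weights keys must match candgen.generators")

    if config.eval.expand_abbreviations:
        tables = preprocess.extract_abbreviation_tables(corpus)
        preprocess.expand_mentions(corpus, tables)
        n_exp = sum(1 for m in corpus.mentions if m.expanded_text is not None)
        logger.info("stage abbreviation-expansion: %d mentions expanded", n_exp)

    if indices is None:
        indices = build_indices(config, kb)
    candgen.generate_candidates(corpus, indices, weights, k=config.candgen.k)
    logger.info("stage candidate-generation: %d mentions", len(corpus.mentions))

    if config.eval.type_map:
        type_map = {cls: set(codes) for cls, codes in config.eval.type_map.items()}
        preprocess.filter_corpus_candidates(corpus, type_map, kb)
        logger.info("stage semantic-filter: applied to %d mentions", len(corpus.mentions))

    if config.rerank.enabled:
        tcfg = config.train_config()
        if backbone is None:
            if train_corpus is None:
                raise ConfigError("re-ranking enabled but no trained backbone or train corpus")
            candgen.generate_candidates(train_corpus, indices, weights, k=config.candgen.k)
            if config.eval.type_map:
                preprocess.filter_corpus_candidates(
                    train_corpus, {c: set(v) for c, v in config.eval.type_map.items()}, kb
                )
            instances = rerank.build_instances(train_corpus, kb, tcfg)
            backbone = rerank.LinearHashedBackbone()
            rerank.train_reranker(instances, backbone, tcfg)
            logger.info("stage train-rerank: %d instances", len(instances))
        rerank.apply_reranker(corpus, backbone, kb, tcfg)
        logger.info("stage rerank: predictions set for %d mentions", len(corpus.mentions))
    else:
        for m in corpus.mentions:
            if m.candidates is not None and m.candidates.entries:
                m.prediction = m.candidates.entries[0][0]
            else:
                m.prediction = NIL
        logger.info("stage predict-top1: CG top-1 predictions set")

    has_gold = any(m.gold_ids for m in corpus.mentions)
    report = (
        evaluation.full_report(corpus, kb, ks=config.eval.ks)
        if has_gold
        else evaluation.EvalReport(n_mentions=len(corpus.mentions))
    )
    logger.info("stage evaluate: %s", "gold present" if has_gold else "no gold ids")
    return corpus, report
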