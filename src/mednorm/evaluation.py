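"""Linking metrics: recall@k, P@1/R@1/F1@1, and error stratifications.

Evaluation assumes gold mention spans (normalization-only setting).  A top-1
prediction is correct if it hits any of the mention's gold concept ids.
NIL predictions are abstentions: they are excluded from the precision
denominator but count against recall, so

    P@1 = n_correct / n_predicted        (non-NIL predictions)
    R@1 = n_correct / n_mentions
    F1@1 = 2 P R / (P + R)               (0 when both are 0)

Stratified reports bucket recall@1 by mention token length (long spans are
the hard cases) and by alias-sharing ambiguity (concepts sharing the
mention's surface as an alias tie in candidate generation and can only be
separated by re-ranking).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .corpus import NIL, Corpus
from .kb import KnowledgeBase, normalize_surface


@dataclass
class EvalReport:
    recall_at_k: dict[int, float] = field(default_factory=dict)
    p1: float = 0.0
    r1: float = 0.0
    f1: float = 0.0
    n_mentions: int = 0
    n_predicted: int = 0
    n_correct: int = 0
    strata: dict[str, dict[str, dict[str, float]]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "recall_at_k": {str(k): v for k, v in sorted(self.recall_at_k.items())},
            "p1": self.p1,
            "r1": self.r1,
            "f1": self.f1,
            "n_mentions": self.n_mentions,
            "n_predicted": self.n_predicted,
            "n_correct": self.n_correct,
            "strata": self.strata,
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    def to_table(self) -> str:
        lines = [
            f"mentions: {self.n_mentions}  predicted: {self.n_predicted}  correct: {self.n_correct}",
            f"P@1 {self.p1:.4f}  R@1 {self.r1:.4f}  F1@1 {self.f1:.4f}",
        ]
        if self.recall_at_k:
            lines.append(
                "recall@k  " + "  ".join(f"{k}:{v:.4f}" for k, v in sorted(self.recall_at_k.items()))
            )
        for name, table in self.strata.items():
            lines.append(f"[{name}]")
            for bucket, row in table.items():
                lines.append(
                    f"  {bucket:>4}  n={int(row['n']):5d}  recall@1={row['recall_at_1']:.4f}"
                )
        return "\n".join(lines)


def _is_correct(prediction: str | None, gold_ids: set[str]) -> bool:
    return prediction is not None and prediction != NIL and prediction in gold_ids


def recall_at_k(corpus: Corpus, ks: list[int]) -> dict[int, float]:
    """Fraction of mentions whose top-k candidates intersect the gold set.

    Mentions without candidates count as misses at every k.
    """
    n = len(corpus.mentions)
    out = {}
    for k in ks:
        hits = 0
        for m in corpus.mentions:
            if m.candidates is None:
                continue
            if set(m.candidates.top_ids(k)) & m.gold_ids:
                hits += 1
        out[k] = hits / n if n else 0.0
    return out


def top1_metrics(corpus: Corpus, ks: list[int] | None = None) -> EvalReport:
    """P@1/R@1/F1@1 over predictions, plus recall@k when candidates exist."""
    n_mentions = len(corpus.mentions)
    n_predicted = sum(1 for m in corpus.mentions if m.prediction not in (None, NIL))
    n_correct = sum(1 for m in corpus.mentions if _is_correct(m.prediction, m.gold_ids))
    p1 = n_correct / n_predicted if n_predicted else 0.0
    r1 = n_correct / n_mentions if n_mentions else 0.0
    f1 = 2 * p1 * r1 / (p1 + r1) if (p1 + r1) else 0.0
    report = EvalReport(
        p1=p1, r1=r1, f1=f1,
        n_mentions=n_mentions, n_predicted=n_predicted, n_correct=n_correct,
    )
    if ks and any(m.candidates is not None for m in corpus.mentions):
        report.recall_at_k = recall_at_k(corpus, ks)
    return report


def _bucket_table(assignments: list[tuple[str, bool]], order: list[str]) -> dict[str, dict[str, float]]:
    table = {b: {"n": 0, "correct": 0} for b in order}
    for bucket, correct in assignments:
        table[bucket]["n"] += 1
        table[bucket]["correct"] += int(correct)
    return {
        b: {
            "n": float(row["n"]),
            "recall_at_1": row["correct"] / row["n"] if row["n"] else 0.0,
        }
        for b, row in table.items()
    }


def stratified_report(corpus: Corpus, tokenizer=None) -> dict[str, dict[str, float]]:
    """Recall@1 by mention token length: buckets 1, 2, 3, >=4."""
    tokenize = tokenizer or (lambda text: text.split())
    rows = []
    for m in corpus.mentions:
        n_tok = len(tokenize(m.text))
        bucket = str(n_tok) if n_tok <= 3 else ">=4"
        rows.append((bucket, _is_correct(m.prediction, m.gold_ids)))
    return _bucket_table(rows, ["1", "2", "3", ">=4"])


def ambiguity_report(corpus: Corpus, kb: KnowledgeBase) -> dict[str, dict[str, float]]:
    """Recall@1 by the number of candidate concepts sharing the mention surface.

    For each mention, count retrieved candidate concepts whose normalized
    alias set contains the normalized mention surface; bucket by 0 / 1 / >=2.
    The >=2 bucket isolates same-alias ties, which candidate generation alone
    cannot break.
    """
    rows = []
    for m in corpus.mentions:
        surface = normalize_surface(m.text)
        count = 0
        if m.candidates is not None:
            for cid in m.candidates.ids:
                concept = kb.concepts.get(cid)
                if concept is not None and surface in concept.normalized_aliases():
                    count += 1
        bucket = str(count) if count <= 1 else ">=2"
        rows.append((bucket, _is_correct(m.prediction, m.gold_ids)))
    return _bucket_table(rows, ["0", "1", ">=2"])


def full_report(corpus: Corpus, kb: KnowledgeBase | None = None,
                ks: list[int] | None = None) -> EvalReport:
    report = top1_metrics(corpus, ks=ks)
    report.strata["mention_length"] = stratified_report(corpus)
    if kb is not None:
        report.strata["alias_ambiguity"] = ambiguity_report(corpus, kb)
    return report


def export_decisions_tsv(corpus: Corpus, path) -> None:
    """Per-mention decisions in a tab-separated format for external scorers."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("mention_id\tdoc_id\ttext\tgold_ids\tprediction\tcorrect\n")
        for m in corpus.mentions:
            fh.write(
                "\t".join(
                    [
                        m.mention_id,
                        m.doc_id,
                        m.text.replace("\t", " "),
                        "|".join(sorted(m.gold_ids)),
                        m.prediction or "",
                        str(int(_is_correct(m.prediction, m.gold_ids))),
                    ]
                )
                + "\n"
            )
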