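"""Context-aware candidate re-ranking with rank regularization.

Candidate generation ranks concepts by surface similarity alone, so concepts
sharing an alias receive identical scores and contextual disambiguation is
impossible.  This module trains a scoring model s(m, e) over pairs of a
mention-in-context encoding and a candidate-concept encoding.  Per mention,
the top k candidates plus a synthetic NIL (not-in-list) concept — encoded as
the literal string ``[UNK]`` — form one training instance; NIL lets the
model abstain when the correct concept was not retrieved.

The training objective combines a softmax loss over the instance with a
rank-regularization term tying the learned scores to the candidate
generator's scores c(m, e):

    L(m, e, y) = sum_i y_i * L_sm(m, e_i) + lambda * ||s(m,e) - c(m,e)||^2
    L_sm(m, e_i) = -s(m, e_i) + log sum_j exp(s(m, e_j))

with one-hot gold vector y.  lambda trades top-1 accuracy against
preservation of the retrieval ranking; the default is 1.0.  c(NIL) is 0, the
floor of the normalized candidate-score range.

The reference scoring backbone is a linear model over hashed character-n-gram
and token features of the (mention context, candidate) pair, including
context-token x candidate-token interaction features — a purely additive text
featurization would contribute the same context term to every candidate of an
instance and cancel in the softmax, making contextual disambiguation
unlearnable.  It trains in seconds on one CPU; transformer cross-encoders
plug into the same contract.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp, softmax
from scipy.stats import spearmanr

from .candgen import CandidateSet
from .corpus import NIL, Corpus
from .kb import Concept, KnowledgeBase, normalize_surface

logger = logging.getLogger(__name__)

NIL_ENCODING = "[UNK]"
MENTION_OPEN = "<m>"
MENTION_CLOSE = "</m>"
ALIAS_SEPARATOR = " | "

MODEL_FORMAT_VERSION = "mednorm-reranker-1"


@dataclass
class TrainConfig:
    lambda_reg: float = 1.0
    k_train: int = 16
    epochs: int = 10  # iteration budget scale; see train_reranker
    learning_rate: float = 0.5  # step size for stochastic backbones; the
    # reference linear backbone is fit by a convex solver and ignores it
    seed: int = 0
    window: int = 128  # context characters per side
    max_aliases: int = 3
    target_language: str = ""

    def __post_init__(self):
        if self.lambda_reg < 0:
            raise ValueError("lambda_reg must be >= 0")
        if self.k_train < 2:
            raise ValueError("k_train must be >= 2")


@dataclass
class RerankInstance:
    """One mention with its k candidates + NIL, gold one-hot, and CG scores."""

    mention_id: str
    mention_encoding: str
    candidate_encodings: list[str]  # last entry is the NIL encoding
    candidate_ids: list[str]  # last entry is NIL
    gold_index: int
    cg_scores: np.ndarray  # c(m, e), NIL entry = 0

    @property
    def gold_onehot(self) -> np.ndarray:
        y = np.zeros(len(self.candidate_ids))
        y[self.gold_index] = 1.0
        return y


# ---------------------------------------------------------------------------
# Encodings


def encode_mention_context(mention, document, window: int = 128) -> str:
    """Mention with marked boundaries and up to ``window`` chars of context per side.

    Whitespace in each part is collapsed; parts are joined by single spaces.
    """
    text = document.text
    start = mention.spans[0][0]
    end = mention.spans[-1][1]
    left = " ".join(text[max(0, start - window) : start].split())
    right = " ".join(text[end : end + window].split())
    core = " ".join(mention.text.split())
    parts = [p for p in (left, MENTION_OPEN, core, MENTION_CLOSE, right) if p]
    return " ".join(parts)


def encode_concept(
    concept: Concept | None, max_aliases: int = 3, target_language: str = ""
) -> str:
    """Canonical name plus up to ``max_aliases`` aliases, priority-ordered.

    Alias priority: target language first, then English, then all others;
    alphabetical within each group.  ``None`` encodes the NIL concept.
    """
    if concept is None:
        return NIL_ENCODING
    canon_norm = normalize_surface(concept.canonical_name)
    tgt = target_language.casefold()
    english = {"en", "eng"}

    def bucket(lang: str) -> int:
        lf = lang.casefold()
        if tgt and lf == tgt:
            return 0
        if lf in english:
            return 1
        return 2

    ranked = sorted(
        (a for a in concept.aliases if normalize_surface(a[0]) != canon_norm),
        key=lambda a: (bucket(a[1]), a[0]),
    )
    parts = [concept.canonical_name] + [s for s, _l in ranked[:max_aliases]]
    return ALIAS_SEPARATOR.join(parts)


def build_instances(
    corpus: Corpus, kb: KnowledgeBase, config: TrainConfig
) -> list[RerankInstance]:
    """Turn mentions-with-candidates into training/inference instances.

    Per mention: top ``k_train`` candidates plus NIL appended last; the gold
    one-hot is set at the first candidate whose id is in the mention's gold
    set, else at NIL; c(NIL) = 0.  Mentions without candidates are skipped
    with a logged warning.
    """
    instances = []
    for m in corpus.mentions:
        cands: CandidateSet | None = m.candidates
        if cands is None or not cands.entries:
            logger.warning("mention %s has no candidates; skipped", m.mention_id)
            continue
        top = cands.entries[: config.k_train]
        ids = [cid for cid, _s in top] + [NIL]
        encodings = [
            encode_concept(kb.concepts.get(cid), config.max_aliases, config.target_language)
            for cid, _s in top
        ] + [NIL_ENCODING]
        c = np.array([s for _cid, s in top] + [0.0])
        gold_index = len(ids) - 1  # NIL unless a gold candidate is present
        for i, cid in enumerate(ids[:-1]):
            if cid in m.gold_ids:
                gold_index = i
                break
        doc = corpus.document(m.doc_id)
        instances.append(
            RerankInstance(
                mention_id=m.mention_id,
                mention_encoding=encode_mention_context(m, doc, config.window),
                candidate_encodings=encodings,
                candidate_ids=ids,
                gold_index=gold_index,
                cg_scores=c,
            )
        )
    return instances


# ---------------------------------------------------------------------------
# Loss


def softmax_loss(s: np.ndarray, i: int) -> float:
    """-s_i + log sum_j exp(s_j), computed log-sum-exp-stably."""
    s = np.asarray(s, dtype=float)
    return float(-s[i] + logsumexp(s))


def rank_regularized_loss(s, c, y, lam: float) -> float:
    """Softmax loss at the gold index plus lam * ||s - c||^2."""
    s = np.asarray(s, dtype=float)
    c = np.asarray(c, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (len(s) == len(c) == len(y)):
        raise ValueError(f"length mismatch: |s|={len(s)} |c|={len(c)} |y|={len(y)}")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    gold = int(np.argmax(y))
    return softmax_loss(s, gold) + lam * float(np.sum((s - c) ** 2))


def rank_regularized_loss_grad(s, c, y, lam: float) -> np.ndarray:
    """Analytic gradient of the loss with respect to the score vector s."""
    s = np.asarray(s, dtype=float)
    return softmax(s) - np.asarray(y, dtype=float) + 2.0 * lam * (s - np.asarray(c, dtype=float))


# ---------------------------------------------------------------------------
# Reference scoring backbone


class ScoringBackbone:
    """Contract: trainable map (mention encoding, candidate encoding) -> score."""

    def score(self, mention_encoding: str, candidate_encoding: str) -> float:
        raise NotImplementedError

    def score_instance(self, instance: RerankInstance) -> np.ndarray:
        return np.array(
            [self.score(instance.mention_encoding, e) for e in instance.candidate_encodings]
        )


class LinearHashedBackbone(ScoringBackbone):
    """Linear scorer over hashed features of the (context, candidate) pair.

    Active features per pair: character n-grams and tokens of the candidate
    encoding, tokens of the mention context, context-token x candidate-token
    interaction pairs (these let the model associate context cues with
    specific concepts), graded surface-similarity values (n-gram
    Jaccard/Dice/containment/cosine, the reference dense-encoder cosine, and
    an exact-alias indicator — enough capacity to approximate the retrieval
    score the regularizer pulls toward), and a bias.  The indicator block is
    L2-normalized per pair; similarity features keep a fixed scale.  Feature
    keys are hashed with BLAKE2b so featurization is stable across
    processes.
    """

    _SIM_KEYS = (
        "sim_jaccard", "sim_dice", "sim_contain", "sim_maxcos",
        "sim_meancos", "sim_densecos", "sim_exact", "bias",
    )

    def __init__(self, dim: int = 2**20, n: int = 3):
        self.dim = dim
        self.n = n
        self.weights = np.zeros(dim)
        from .candgen import HashedNgramEncoder  # deferred: avoid import cycle

        self._dense_encoder = HashedNgramEncoder(dimension=256, n=n)
        self._dense_cache: dict[str, np.ndarray] = {}
        # similarity features and the bias are exempt from the L2 penalty at
        # fit time: they carry consistent signal, while the sparse
        # indicators are the ones that memorize noise
        self._no_decay = np.array(sorted(self._hash(k) for k in self._SIM_KEYS))

    # -- featurization -----------------------------------------------------

    def _dense(self, text: str) -> np.ndarray:
        vec = self._dense_cache.get(text)
        if vec is None:
            vec = self._dense_encoder.encode(text)
            self._dense_cache[text] = vec
        return vec

    def _hash(self, key: str) -> int:
        h = hashlib.blake2b(key.encode("utf-8"), digest_size=8).digest()
        return int.from_bytes(h, "big") % self.dim

    @staticmethod
    def _char_ngrams(text: str, n: int) -> set[str]:
        grams = set()
        for word in normalize_surface(text).split():
            padded = f" {word} "
            if len(padded) <= n:
                grams.add(padded)
            else:
                grams.update(padded[i : i + n] for i in range(len(padded) - n + 1))
        return grams

    @staticmethod
    def _mention_surface(mention_encoding: str) -> str:
        try:
            start = mention_encoding.index(MENTION_OPEN) + len(MENTION_OPEN)
            end = mention_encoding.index(MENTION_CLOSE)
            return mention_encoding[start:end].strip()
        except ValueError:
            return mention_encoding

    # Graded similarity features carry this weight before normalization so
    # they are not drowned out by the many binary indicator features.
    SIM_SCALE = 2.0
    WEIGHT_DECAY = 0.001

    def featurize(self, mention_encoding: str, candidate_encoding: str):
        """Sparse feature vector as (indices, values).

        The block of binary indicator features is L2-normalized per pair; the
        graded similarity features keep a fixed scale so the similarity ->
        score mapping is identical across the candidates of an instance
        (normalizing them jointly with the indicators would rescale each
        candidate's similarities by its own feature count).
        """
        raw: dict[int, float] = {}

        def add(key: str, value: float = 1.0):
            idx = self._hash(key)
            raw[idx] = raw.get(idx, 0.0) + value

        cand_tokens = set(normalize_surface(candidate_encoding).replace("|", " ").split())
        ctx_tokens = set(normalize_surface(mention_encoding).split())
        for g in self._char_ngrams(candidate_encoding, self.n):
            add("c|" + g)
        for t in cand_tokens:
            add("ct|" + t)
        for t in ctx_tokens:
            add("m|" + t)
        for tm in ctx_tokens:
            for te in cand_tokens:
                add("x|" + tm + "\t" + te)
        binary_norm = float(np.sqrt(len(raw))) or 1.0
        for k in raw:
            raw[k] /= binary_norm

        surface = normalize_surface(self._mention_surface(mention_encoding))
        sg = self._char_ngrams(surface, self.n)
        cg = self._char_ngrams(candidate_encoding, self.n)
        inter = len(sg & cg)
        union = len(sg | cg)
        add("sim_jaccard", self.SIM_SCALE * (inter / union if union else 0.0))
        add("sim_dice", self.SIM_SCALE * (2 * inter / (len(sg) + len(cg)) if sg or cg else 0.0))
        add("sim_contain", self.SIM_SCALE * (inter / len(sg) if sg else 0.0))
        # per-alias-segment similarities: the candidate encoding concatenates
        # canonical name and aliases, and retrieval aggregates alias scores by
        # max, so segment-level max/mean cosine gives the model the capacity
        # to approximate the retrieval score it is regularized toward
        segments = [
            normalize_surface(seg) for seg in candidate_encoding.split(ALIAS_SEPARATOR.strip())
        ]
        seg_cos = []
        for seg in segments:
            gg = self._char_ngrams(seg, self.n)
            denom = (len(sg) * len(gg)) ** 0.5
            seg_cos.append(len(sg & gg) / denom if denom else 0.0)
        add("sim_maxcos", self.SIM_SCALE * (max(seg_cos) if seg_cos else 0.0))
        add("sim_meancos", self.SIM_SCALE * (sum(seg_cos) / len(seg_cos) if seg_cos else 0.0))
        dvec = self._dense(surface)
        dense_cos = max((float(dvec @ self._dense(seg)) for seg in segments), default=0.0)
        add("sim_densecos", self.SIM_SCALE * dense_cos)
        add("sim_exact", self.SIM_SCALE * (1.0 if surface in segments else 0.0))
        add("bias")

        idx = np.fromiter(raw.keys(), dtype=np.int64, count=len(raw))
        val = np.fromiter(raw.values(), dtype=np.float64, count=len(raw))
        return idx, val

    # -- scoring / updates -------------------------------------------------

    def score_features(self, feats) -> float:
        idx, val = feats
        return float(self.weights[idx] @ val)

    def score(self, mention_encoding: str, candidate_encoding: str) -> float:
        return self.score_features(self.featurize(mention_encoding, candidate_encoding))

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        nz = np.nonzero(self.weights)[0]
        payload = {
            "format": MODEL_FORMAT_VERSION,
            "dim": self.dim,
            "n": self.n,
            "indices": nz.tolist(),
            "values": self.weights[nz].tolist(),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "LinearHashedBackbone":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        if payload.get("format") != MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model format tag {payload.get('format')!r}")
        model = cls(dim=payload["dim"], n=payload["n"])
        model.weights[np.array(payload["indices"], dtype=int)] = payload["values"]
        return model


# ---------------------------------------------------------------------------
# Training / inference


def train_reranker(
    instances: list[RerankInstance],
    backbone: LinearHashedBackbone,
    config: TrainConfig,
) -> LinearHashedBackbone:
    """Fit the backbone by minimizing the mean rank-regularized loss.

    The reference backbone is linear, so the objective (mean loss plus an L2
    penalty on the indicator weights) is smooth and convex and is minimized
    to convergence with full-batch L-BFGS over the active feature subspace;
    ``config.epochs`` scales the iteration budget (``20 x epochs``
    iterations) and zero epochs leave the backbone unchanged.  The result is
    deterministic; the config seed only matters for stochastic backbones.
    """
    if not instances:
        raise ValueError("no training instances")
    if config.epochs == 0:
        return backbone
    from scipy import optimize, sparse

    feats_cache = [
        [backbone.featurize(inst.mention_encoding, e) for e in inst.candidate_encodings]
        for inst in instances
    ]
    # remap active features to a compact column space
    active = np.unique(np.concatenate([idx for row in feats_cache for idx, _v in row]))
    col_of = {int(f): j for j, f in enumerate(active)}
    rows, cols, vals = [], [], []
    slices = []
    golds = []
    c_all = []
    r = 0
    for inst, row_feats in zip(instances, feats_cache):
        start = r
        for idx, val in row_feats:
            rows.extend([r] * len(idx))
            cols.extend(col_of[int(f)] for f in idx)
            vals.extend(val)
            r += 1
        slices.append((start, r))
        golds.append(start + inst.gold_index)
        c_all.append(inst.cg_scores)
    phi = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(r, len(active)), dtype=np.float64
    )
    c_vec = np.concatenate(c_all)
    gold_rows = np.array(golds)
    n_inst = len(instances)
    lam = config.lambda_reg
    # indicator weights are L2-penalized; similarity features and bias are not
    penalized = np.ones(len(active), dtype=bool)
    for j, f in enumerate(active):
        if int(f) in set(int(h) for h in backbone._no_decay):
            penalized[j] = False
    # scale the penalty with the magnitude of the data-fit term: the squared
    # regression term grows with lambda, and a fixed penalty would let the
    # indicator weights overfit its residuals at high lambda
    wd = backbone.WEIGHT_DECAY * (1.0 + lam)

    bounds = np.array(slices)

    def objective(w):
        s = phi @ w
        total = 0.0
        g_pairs = np.empty_like(s)
        for (a, b), grow in zip(bounds, gold_rows):
            seg = s[a:b]
            p = softmax(seg)
            total += -seg[grow - a] + logsumexp(seg)
            g = p.copy()
            g[grow - a] -= 1.0
            g_pairs[a:b] = g
        if lam:
            diff = s - c_vec
            total += lam * float(diff @ diff)
            g_pairs += 2.0 * lam * diff
        total /= n_inst
        grad = (phi.T @ g_pairs) / n_inst
        if wd:
            total += wd * float(w[penalized] @ w[penalized])
            grad[penalized] += 2.0 * wd * w[penalized]
        if not np.isfinite(total):
            raise FloatingPointError("non-finite training loss")
        return total, grad

    w0 = backbone.weights[active]
    result = optimize.minimize(
        objective,
        w0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 20 * config.epochs, "ftol": 1e-12, "gtol": 1e-9},
    )
    logger.info(
        "training converged=%s iterations=%d final loss %.6f",
        result.success, result.nit, result.fun,
    )
    backbone.weights[active] = result.x
    return backbone


def apply_reranker(
    corpus: Corpus,
    backbone: ScoringBackbone,
    kb: KnowledgeBase,
    config: TrainConfig,
) -> Corpus:
    """Re-rank every mention's candidates by s(m, e) and set predictions.

    The top-scoring entry becomes the prediction; if that entry is the NIL
    concept the model abstains.  The original CandidateSet is preserved;
    the re-ranked list is stored separately on the mention.
    """
    instances = build_instances(corpus, kb, config)
    by_mention = {inst.mention_id: inst for inst in instances}
    for m in corpus.mentions:
        inst = by_mention.get(m.mention_id)
        if inst is None:
            m.prediction = NIL
            continue
        s = backbone.score_instance(inst)
        # ties: NIL loses to any equally scored candidate (abstention only
        # when NIL is strictly best), then ascending concept id
        order = sorted(
            range(len(s)),
            key=lambda i: (-s[i], inst.candidate_ids[i] == NIL, inst.candidate_ids[i]),
        )
        m.reranked = CandidateSet(
            mention_id=m.mention_id,
            entries=[(inst.candidate_ids[i], float(s[i])) for i in order],
            k=len(order),
        )
        top = inst.candidate_ids[order[0]]
        m.prediction = NIL if top == NIL else top
    return corpus


# ---------------------------------------------------------------------------
# Rank-regularization analysis helper


def spearman_s_vs_c(
    instances: list[RerankInstance], backbone: ScoringBackbone
) -> float:
    """Median per-instance Spearman correlation between s(m, e) and c(m, e)."""
    rhos = []
    for inst in instances:
        s = backbone.score_instance(inst)
        if np.allclose(s, s[0]) or np.allclose(inst.cg_scores, inst.cg_scores[0]):
            continue
        rho = spearmanr(s, inst.cg_scores).statistic
        if np.isfinite(rho):
            rhos.append(rho)
    return float(np.median(rhos)) if rhos else float("nan")


def lambda_sweep(
    train_instances: list[RerankInstance],
    heldout_instances: list[RerankInstance],
    lambdas: list[float],
    seeds: list[int],
    config: TrainConfig,
    dim: int = 2**20,
) -> dict[float, float]:
    """Train at each lambda (x seeds) and report median held-out Spearman rho(s, c).

    A small synthetic analogue of studying how the regularization weight
    trades learned-ranking freedom against preservation of the retrieval
    ranking.
    """
    results: dict[float, float] = {}
    for lam in lambdas:
        rhos = []
        for seed in seeds:
            cfg = TrainConfig(
                lambda_reg=lam,
                k_train=config.k_train,
                epochs=config.epochs,
                learning_rate=config.learning_rate,
                seed=seed,
                window=config.window,
                max_aliases=config.max_aliases,
                target_language=config.target_language,
            )
            backbone = LinearHashedBackbone(dim=dim)
            train_reranker(train_instances, backbone, cfg)
            rhos.append(spearman_s_vs_c(heldout_instances, backbone))
        results[lam] = float(np.median(rhos))
    return results
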