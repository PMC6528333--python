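"""Knowledge-base triples and translation-based embeddings.

Chemical--disease pairs found in the corpus are annotated with their KB
relation (``marker/mechanism``, ``therapeutic`` or ``inferred-association``;
pairs absent from the KB get the synthetic ``null`` relation).  The combined
triple set is embedded with the classic translation model: a relation vector
translates the chemical to the disease, e_c + r ≈ e_d for true triples,
trained with a margin-ranking hinge against corrupted triples

    L = Σ max(0, γ + ||e_c + r − e_d|| − ||e_c' + r − e_d'||)

where each corrupted triple replaces the chemical or the disease (chosen
with probability 1/2) by a random same-typed entity not forming a true
triple.  Entity vectors are initialized from the average of their mention
word vectors and re-normalized to unit L2 norm after every epoch; relation
vectors start uniform in [−0.25, 0.25].
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from .corpus_io import (
    ALL_RELATIONS,
    KB_RELATIONS,
    NULL_RELATION,
    TripleFile,
    read_word_vectors,
    write_word_vectors,
)

logger = logging.getLogger(__name__)

Triple = tuple[str, str, str]  # (chemical mesh_id, relation, disease mesh_id)

#: When a pair holds several KB relations, the one carried over to the
#: annotated triple set (most CID-specific first).
RELATION_PRECEDENCE = ("marker/mechanism", "therapeutic", "inferred-association")


def annotate_pairs(
    candidate_pairs: list[tuple[str, str]], kb: TripleFile
) -> list[Triple]:
    """Annotate corpus entity-ID pairs with their KB relation.

    Pairs absent from the KB get the ``null`` relation; pairs holding several
    KB relations resolve by :data:`RELATION_PRECEDENCE`.
    """
    by_pair: dict[tuple[str, str], set[str]] = {}
    for c, r, d in kb:
        by_pair.setdefault((c, d), set()).add(r)
    out: list[Triple] = []
    seen = set()
    for c, d in candidate_pairs:
        if (c, d) in seen:
            continue
        seen.add((c, d))
        rels = by_pair.get((c, d))
        if not rels:
            out.append((c, NULL_RELATION, d))
        else:
            rel = next(r for r in RELATION_PRECEDENCE if r in rels)
            out.append((c, rel, d))
    return out


def build_training_triples(
    annotated: list[Triple], kb: TripleFile
) -> list[Triple]:
    """Merge annotated corpus pairs with the raw KB rows (deduplicated)."""
    seen = set()
    out = []
    for t in list(annotated) + list(kb):
        if t not in seen:
            seen.add(t)
            out.append(t)
    return out


# ---------------------------------------------------------------------------
# embedding space
# ---------------------------------------------------------------------------


class EmbeddingSpace:
    """Word, entity and relation vectors sharing one k-dimensional space.

    Tracks how often trained entity/relation vectors are read so variant
    configurations that must not consult the KB can be audited.
    """

    def __init__(
        self,
        words: dict[str, np.ndarray],
        entities: dict[str, np.ndarray],
        relations: dict[str, np.ndarray],
        entity_words: dict[str, list[str]] | None = None,
        seed: int = 0,
    ):
        self.words = words
        self.entities = entities
        self.relations = relations
        self.entity_words = entity_words or {}
        self.seed = seed
        self.k = len(next(iter(relations.values()))) if relations else 0
        self.entity_lookups = 0
        self.relation_lookups = 0
        self._fallback_cache: dict[str, np.ndarray] = {}
        self._oov_rng = np.random.default_rng(seed + 104729)
        self._oov_cache: dict[str, np.ndarray] = {}

    # --- lookups ----------------------------------------------------------

    def word(self, token: str) -> np.ndarray | None:
        return self.words.get(token)

    def entity(self, mesh_id: str) -> np.ndarray:
        """Trained entity vector; counts as a knowledge lookup."""
        self.entity_lookups += 1
        return self.entities[mesh_id]

    def relation(self, label: str) -> np.ndarray:
        """Trained relation vector; counts as a knowledge lookup."""
        self.relation_lookups += 1
        return self.relations[label]

    def has_entity(self, mesh_id: str) -> bool:
        return mesh_id in self.entities

    def average_entity_vector(self, mesh_id: str) -> np.ndarray:
        """Mention-word-average vector (no trained knowledge consulted).

        Used both as the averaged-entity variant's entity source and as the
        fallback for entities unseen during embedding training.
        """
        if mesh_id in self._fallback_cache:
            return self._fallback_cache[mesh_id]
        vecs = [
            self.words[w]
            for w in self.entity_words.get(mesh_id, [])
            if w in self.words
        ]
        if vecs:
            v = np.mean(vecs, axis=0)
        else:
            logger.warning("entity %s has no in-vocabulary mention words", mesh_id)
            if mesh_id not in self._oov_cache:
                self._oov_cache[mesh_id] = self._oov_rng.uniform(
                    -0.25, 0.25, self.k
                )
            v = self._oov_cache[mesh_id]
        self._fallback_cache[mesh_id] = v
        return v

    def reset_counters(self) -> None:
        self.entity_lookups = 0
        self.relation_lookups = 0

    # --- persistence ------------------------------------------------------

    def save(self, directory, extra_meta: dict | None = None) -> None:
        os.makedirs(directory, exist_ok=True)
        write_word_vectors(self.words, os.path.join(directory, "words.vec"))
        write_word_vectors(self.entities, os.path.join(directory, "entities.vec"))
        write_word_vectors(self.relations, os.path.join(directory, "relations.vec"))
        meta = {
            "k": self.k,
            "seed": self.seed,
            "entity_words": self.entity_words,
        }
        meta.update(extra_meta or {})
        with open(os.path.join(directory, "space.json"), "w", encoding="utf-8") as fh:
            json.dump(meta, fh, ensure_ascii=False, indent=1)

    @classmethod
    def load(cls, directory) -> "EmbeddingSpace":
        with open(os.path.join(directory, "space.json"), encoding="utf-8") as fh:
            meta = json.load(fh)
        return cls(
            words=read_word_vectors(os.path.join(directory, "words.vec")),
            entities=read_word_vectors(os.path.join(directory, "entities.vec")),
            relations=read_word_vectors(os.path.join(directory, "relations.vec")),
            entity_words=meta.get("entity_words", {}),
            seed=meta.get("seed", 0),
        )


def init_embeddings(
    entity_words: dict[str, list[str]],
    word_vectors: dict[str, np.ndarray],
    k: int | None = None,
    relations: tuple[str, ...] = ALL_RELATIONS,
    seed: int = 0,
) -> EmbeddingSpace:
    """Initial embedding space.

    Entity vectors are the arithmetic mean of their mention-word vectors
    (mention words missing from the vector file are drawn uniform
    [−0.25, 0.25], seeded); relation vectors are uniform [−0.25, 0.25].
    Deterministic given ``seed``.
    """
    if k is None:
        k = len(next(iter(word_vectors.values())))
    rng = np.random.default_rng(seed)
    words = dict(word_vectors)
    entities: dict[str, np.ndarray] = {}
    for mesh_id in sorted(entity_words):
        vecs = []
        for w in entity_words[mesh_id]:
            if w not in words:
                words[w] = rng.uniform(-0.25, 0.25, k)
            vecs.append(words[w])
        if vecs:
            entities[mesh_id] = np.mean(vecs, axis=0)
        else:
            logger.debug("entity %s has no mention words; random vector", mesh_id)
            entities[mesh_id] = rng.uniform(-0.25, 0.25, k)
    rel_vectors = {r: rng.uniform(-0.25, 0.25, k) for r in relations}
    return EmbeddingSpace(words, entities, rel_vectors, entity_words, seed=seed)


# ---------------------------------------------------------------------------
# translation-model training
# ---------------------------------------------------------------------------


@dataclass
class TransEConfig:
    k: int = 100
    gamma: float = 1.0
    epochs: int = 500
    learning_rate: float = 0.01
    norm: int = 2
    batch_size: int = 128
    seed: int = 0

    def __post_init__(self):
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.norm not in (1, 2):
            raise ValueError("norm must be 1 or 2")


def corrupt_triple(
    t: Triple,
    chemical_pool: list[str],
    disease_pool: list[str],
    triple_set: set[Triple],
    rng: np.random.Generator,
    max_tries: int = 100,
) -> Triple:
    """Corrupt one entity slot of a true triple.

    With probability 1/2 the chemical is replaced by a random chemical,
    otherwise the disease by a random disease; resampled until the corrupted
    triple leaves the true set.  A side whose pool offers no alternative
    falls back to the other side.
    """
    c, r, d = t

    def try_side(head: bool) -> Triple | None:
        pool = chemical_pool if head else disease_pool
        current = c if head else d
        candidates = [x for x in pool if x != current]
        if not candidates:
            return None
        for _ in range(max_tries):
            x = candidates[rng.integers(len(candidates))]
            cand = (x, r, d) if head else (c, r, x)
            if cand not in triple_set:
                return cand
        return None

    head_first = bool(rng.random() < 0.5)
    for head in (head_first, not head_first):
        cand = try_side(head)
        if cand is not None:
            return cand
    raise ValueError(f"triple {t} cannot be corrupted within its pools")


def _residual_norms(
    ec: np.ndarray, r: np.ndarray, ed: np.ndarray, norm: int
) -> np.ndarray:
    res = ec + r - ed
    if norm == 1:
        return np.abs(res).sum(axis=-1)
    return np.sqrt((res ** 2).sum(axis=-1))


def transe_loss(
    correct: list[Triple],
    corrupted: list[Triple],
    space: EmbeddingSpace,
    config: TransEConfig,
) -> float:
    """Margin-ranking hinge loss of a batch of (correct, corrupted) pairs."""
    if len(correct) != len(corrupted):
        raise ValueError("correct and corrupted batches differ in length")
    total = 0.0
    for (c, r, d), (c2, r2, d2) in zip(correct, corrupted):
        ec, ed = space.entities[c], space.entities[d]
        ec2, ed2 = space.entities[c2], space.entities[d2]
        rv, rv2 = space.relations[r], space.relations[r2]
        if not (len(ec) == len(rv) == len(ed)):
            raise ValueError("embedding dimension mismatch")
        pos = _residual_norms(ec, rv, ed, config.norm)
        neg = _residual_norms(ec2, rv2, ed2, config.norm)
        total += max(0.0, config.gamma + float(pos) - float(neg))
    return total


class TransE:
    """Translation-embedding model over a chemical-disease triple set.

    Parameters
    ----------
    triples : list of (chemical, relation, disease)
        The true triple set S (corpus-annotated pairs merged with KB rows).
    entity_words : dict, optional
        Lowercased mention words per entity, used to initialize entity
        vectors from word-vector averages.
    word_vectors : dict, optional
        Pre-trained word vectors; mention words outside this vocabulary are
        drawn uniform [−0.25, 0.25].
    config : TransEConfig
    """

    def __init__(
        self,
        triples: list[Triple],
        entity_words: dict[str, list[str]] | None = None,
        word_vectors: dict[str, np.ndarray] | None = None,
        config: TransEConfig | None = None,
        initial_space: EmbeddingSpace | None = None,
        extra_chemicals: tuple[str, ...] = (),
        extra_diseases: tuple[str, ...] = (),
    ):
        if not triples:
            raise ValueError("empty triple set")
        self.triples = list(triples)
        self.extra_chemicals = tuple(extra_chemicals)
        self.extra_diseases = tuple(extra_diseases)
        self.config = config or TransEConfig()
        if initial_space is not None:
            self.space = initial_space
        else:
            self.space = init_embeddings(
                entity_words or {c: [] for c, _, _ in triples}
                | {d: [] for _, _, d in triples},
                word_vectors or {},
                k=self.config.k,
                seed=self.config.seed,
            )
        # make sure every triple / pool entity has a vector
        rng = np.random.default_rng(self.config.seed + 7)
        pool_entities = [e for c, _, d in self.triples for e in (c, d)]
        pool_entities += list(extra_chemicals) + list(extra_diseases)
        for e in pool_entities:
            if e not in self.space.entities:
                self.space.entities[e] = rng.uniform(-0.25, 0.25, self.config.k)
        for _, r, _ in self.triples:
            if r not in self.space.relations:
                raise ValueError(f"relation {r!r} outside {ALL_RELATIONS}")

    def fit(self) -> "TransEResults":
        """Minimize the margin-ranking loss by minibatch SGD.

        One corrupted counterpart is drawn per triple per epoch; entity
        vectors are re-normalized to unit L2 norm after every epoch.
        """
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        chem_pool = sorted({c for c, _, _ in self.triples}
                           | set(self.extra_chemicals))
        dis_pool = sorted({d for _, _, d in self.triples}
                          | set(self.extra_diseases))
        ent_ids = sorted({e for c, _, d in self.triples for e in (c, d)}
                         | set(chem_pool) | set(dis_pool))
        ent_index = {e: i for i, e in enumerate(ent_ids)}
        rel_ids = sorted({r for _, r, _ in self.triples})
        rel_index = {r: i for i, r in enumerate(rel_ids)}
        E = np.stack([self.space.entities[e] for e in ent_ids]).astype(np.float64)
        R = np.stack([self.space.relations[r] for r in rel_ids]).astype(np.float64)
        triple_set = set(self.triples)
        idx_triples = np.array(
            [(ent_index[c], rel_index[r], ent_index[d]) for c, r, d in self.triples]
        )

        loss_trace: list[float] = []
        order = np.arange(len(self.triples))
        for _epoch in range(cfg.epochs):
            rng.shuffle(order)
            epoch_loss = 0.0
            for start in range(0, len(order), cfg.batch_size):
                batch = order[start : start + cfg.batch_size]
                pos = idx_triples[batch]
                neg = np.empty_like(pos)
                for row, ti in enumerate(batch):
                    c2, r2, d2 = corrupt_triple(
                        self.triples[ti], chem_pool, dis_pool, triple_set, rng
                    )
                    neg[row] = (ent_index[c2], rel_index[r2], ent_index[d2])

                res_p = E[pos[:, 0]] + R[pos[:, 1]] - E[pos[:, 2]]
                res_n = E[neg[:, 0]] + R[neg[:, 1]] - E[neg[:, 2]]
                if cfg.norm == 1:
                    dp = np.abs(res_p).sum(1)
                    dn = np.abs(res_n).sum(1)
                    gp = np.sign(res_p)
                    gn = np.sign(res_n)
                else:
                    dp = np.sqrt((res_p ** 2).sum(1))
                    dn = np.sqrt((res_n ** 2).sum(1))
                    gp = res_p / np.maximum(dp, 1e-12)[:, None]
                    gn = res_n / np.maximum(dn, 1e-12)[:, None]
                margins = cfg.gamma + dp - dn
                active = margins > 0
                epoch_loss += float(margins[active].sum())
                if not active.any():
                    continue
                lr = cfg.learning_rate
                gp = gp[active] * lr
                gn = gn[active] * lr
                pa, na = pos[active], neg[active]
                # d loss = +d||pos|| - d||neg|| on active terms
                np.add.at(E, pa[:, 0], -gp)
                np.add.at(E, pa[:, 2], gp)
                np.add.at(R, pa[:, 1], -gp)
                np.add.at(E, na[:, 0], gn)
                np.add.at(E, na[:, 2], -gn)
                np.add.at(R, na[:, 1], gn)
            E /= np.maximum(np.linalg.norm(E, axis=1, keepdims=True), 1e-12)
            loss_trace.append(epoch_loss / len(self.triples))

        self.space.entities = {e: E[i].copy() for e, i in ent_index.items()}
        for r, i in rel_index.items():
            self.space.relations[r] = R[i].copy()
        return TransEResults(self, self.space, loss_trace)


@dataclass
class TransEResults:
    """Fitted translation embeddings with their training trace."""

    model: TransE
    space: EmbeddingSpace
    loss_trace: list[float] = field(default_factory=list)

    def residual(self, triple: Triple) -> float:
        c, r, d = triple
        return float(
            _residual_norms(
                self.space.entities[c],
                self.space.relations[r],
                self.space.entities[d],
                self.model.config.norm,
            )
        )

    def rank_tails(self, c: str, r: str, candidates: list[str]) -> list[str]:
        """Candidate diseases sorted by translational plausibility of
        (c, r, ·), best first."""
        scored = [
            (self.residual((c, r, d)), d) for d in candidates
        ]
        scored.sort(key=lambda t: (t[0], t[1]))
        return [d for _, d in scored]

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Translation embedding fit",
            "=" * 34,
            f"triples:        {len(self.model.triples)}",
            f"entities:       {len(self.space.entities)}",
            f"relations:      {len(self.space.relations)}",
            f"k:              {cfg.k}",
            f"gamma:          {cfg.gamma}",
            f"norm:           L{cfg.norm}",
            f"epochs:         {cfg.epochs}",
            f"final loss:     {self.loss_trace[-1]:.4f}" if self.loss_trace else "",
        ]
        return "\n".join(line for line in lines if line)

    def save(self, directory) -> None:
        self.space.save(
            directory,
            extra_meta={
                "config": asdict(self.model.config),
                "loss_trace": self.loss_trace,
            },
        )


def train_transe(
    triples: list[Triple],
    config: TransEConfig | None = None,
    entity_words: dict[str, list[str]] | None = None,
    word_vectors: dict[str, np.ndarray] | None = None,
) -> TransEResults:
    """Functional wrapper: build a :class:`TransE` model and fit it."""
    return TransE(triples, entity_words, word_vectors, config).fit()


# ---------------------------------------------------------------------------
# guidance lookup
# ---------------------------------------------------------------------------


def lookup_guidance(instance, space: EmbeddingSpace):
    """Guidance vectors (e_c, e_d, r) for a candidate instance.

    This is where prior knowledge enters the classifier: the trained entity
    vectors gate the convolutions and the relation vector of the instance's
    annotated KB relation drives the attention pooling.  An entity unseen in
    embedding training falls back to its mention-word-average vector.
    """
    if instance.kb_relation is None:
        raise ValueError("instance has no kb_relation; run annotate_pairs first")
    vecs = []
    for mesh_id in instance.pair:
        if space.has_entity(mesh_id):
            vecs.append(space.entity(mesh_id))
        else:
            logger.warning("entity %s unseen in training; word-average fallback", mesh_id)
            vecs.append(space.average_entity_vector(mesh_id))
    r = space.relation(instance.kb_relation)
    return vecs[0], vecs[1], r
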