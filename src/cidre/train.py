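"""Training, prediction, document-level merging, and evaluation.

The classifier is trained separately per candidate level (intra- and
inter-sentence) with Adam on minibatches of 20, learning rate 1e-4 for
intra and 2e-4 for inter instances, early-stopped on validation F1 over a
document-granular 80/20 split.  Instance predictions are OR-merged to
document-level (doc, chemical-ID, disease-ID) pairs — an entity pair is
positive as soon as any of its instances is — and scored with
precision/recall/F1 against the gold pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .corpus_io import TripleFile
from .instances import CandidateInstance, LABEL_CID
from .kb import EmbeddingSpace
from .model import KcnConfig, KcnParams, Vocabulary, batch_loss, batch_loss_and_grads, forward

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    batch_size: int = 20
    lr_intra: float = 1e-4
    lr_inter: float = 2e-4
    split_fraction: float = 0.8
    max_epochs: int = 50
    patience: int = 5
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.split_fraction < 1:
            raise ValueError("split fraction must be in (0, 1)")
        if self.lr_intra <= 0 or self.lr_inter <= 0:
            raise ValueError("learning rates must be positive")

    def learning_rate(self, level: str) -> float:
        return self.lr_intra if level == "intra" else self.lr_inter


@dataclass
class PRF:
    """Precision/recall/F1 (percent) with the underlying counts."""

    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r > 0 else 0.0

    def as_dict(self) -> dict:
        return {
            "precision": self.precision, "recall": self.recall, "f1": self.f1,
            "tp": self.tp, "fp": self.fp, "fn": self.fn,
        }

    def __str__(self) -> str:
        return f"P={self.precision:.2f} R={self.recall:.2f} F={self.f1:.2f}"


def split_train_validation(
    instances: list[CandidateInstance], config: TrainConfig
) -> tuple[list[CandidateInstance], list[CandidateInstance]]:
    """Seeded 80/20 split at document granularity.

    All instances of one document land on the same side, so near-duplicate
    instances cannot leak across the split.
    """
    doc_ids = sorted({inst.doc_id for inst in instances})
    if len(doc_ids) < 2:
        raise ValueError("need at least 2 documents to split")
    rng = np.random.default_rng(config.seed)
    rng.shuffle(doc_ids)
    n_train = max(1, min(len(doc_ids) - 1, round(len(doc_ids) * config.split_fraction)))
    train_docs = set(doc_ids[:n_train])
    train = [i for i in instances if i.doc_id in train_docs]
    val = [i for i in instances if i.doc_id not in train_docs]
    return train, val


# ---------------------------------------------------------------------------
# the model / results pair
# ---------------------------------------------------------------------------


class _Adam:
    def __init__(self, arrays: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.arrays = arrays
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(a) for a in arrays]
        self.v = [np.zeros_like(a) for a in arrays]
        self.t = 0

    def step(self, grads: dict[int, np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for i, arr in enumerate(self.arrays):
            g = grads[id(arr)]
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            arr -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)


class KCN:
    """Knowledge-guided convolutional classifier for one candidate level.

    Built from labeled candidate instances and a fitted embedding space;
    ``fit`` trains with Adam and early stopping on validation F1 and
    returns a :class:`KCNResults`.
    """

    def __init__(
        self,
        instances: list[CandidateInstance],
        space: EmbeddingSpace,
        config: KcnConfig | None = None,
        level: str | None = None,
    ):
        if not instances:
            raise ValueError("empty training set")
        self.instances = list(instances)
        self.space = space
        self.config = config or KcnConfig()
        levels = {i.level for i in self.instances}
        if level is None:
            if len(levels) != 1:
                raise ValueError(
                    "instances mix levels; train one classifier per level"
                )
            level = levels.pop()
        self.level = level

    def fit(
        self,
        train_config: TrainConfig | None = None,
        validation: list[CandidateInstance] | None = None,
    ) -> "KCNResults":
        tc = train_config or TrainConfig()
        if validation is None:
            train, validation = split_train_validation(self.instances, tc)
        else:
            train = self.instances
        if not train:
            raise ValueError("empty training split")

        vocab = Vocabulary.from_instances(train)
        params = KcnParams(self.config, vocab, word_vectors=self.space.words)
        arrays = [arr for _, arr in params.param_items()]
        opt = _Adam(arrays, lr=tc.learning_rate(self.level))
        rng = np.random.default_rng(tc.seed)

        history: list[dict] = []
        best_f1, best_params, best_epoch = -1.0, params.copy(), -1
        since_best = 0
        order = np.arange(len(train))
        for epoch in range(tc.max_epochs):
            rng.shuffle(order)
            losses = []
            for start in range(0, len(order), tc.batch_size):
                batch = [train[i] for i in order[start : start + tc.batch_size]]
                loss, grads = batch_loss_and_grads(
                    batch, self.space, params, self.config
                )
                opt.step(grads)
                losses.append(loss)
            val_prf = _instance_prf(validation, self.space, params, self.config)
            history.append(
                {"epoch": epoch, "train_loss": float(np.mean(losses)),
                 "val_f1": val_prf.f1}
            )
            logger.info("epoch %d: loss %.4f val F1 %.2f", epoch,
                        history[-1]["train_loss"], val_prf.f1)
            if val_prf.f1 > best_f1:
                best_f1, best_epoch, since_best = val_prf.f1, epoch, 0
                best_params = params.copy()
            else:
                since_best += 1
                if since_best > tc.patience:
                    break
        return KCNResults(self, best_params, history, best_epoch, best_f1)


@dataclass
class KCNResults:
    """Fitted classifier: best-validation parameters plus training history."""

    model: KCN
    params: KcnParams
    history: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_val_f1: float = float("nan")

    def predict_proba(self, instances) -> np.ndarray:
        return np.array(
            [forward(i, self.model.space, self.params, self.model.config)[0]
             for i in instances]
        )

    def predict(self, instances) -> list[bool]:
        return predict_level(instances, self)

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            f"Gated convolutional relation classifier ({self.model.level}-sentence level)",
            "=" * 60,
            f"instances:        {len(self.model.instances)}",
            f"gate / attention: {cfg.gate} / {cfg.attention}",
            f"entity source:    {cfg.entity_source}   sharing: {cfg.sharing}",
            f"filters:          {cfg.filters_per_window} x windows {cfg.window_sizes}"
            f" (l={cfg.l})",
            f"dims d=k:         {cfg.d}/{cfg.k}   hidden: {cfg.hidden}",
            f"epochs run:       {len(self.history)}"
            f" (best epoch {self.best_epoch}, val F1 {self.best_val_f1:.2f})",
        ]
        return "\n".join(lines)


def train_level(
    instances: list[CandidateInstance],
    space: EmbeddingSpace,
    kcn_config: KcnConfig | None = None,
    train_config: TrainConfig | None = None,
    validation: list[CandidateInstance] | None = None,
) -> KCNResults:
    """Train one level's classifier (functional wrapper over :class:`KCN`)."""
    return KCN(instances, space, kcn_config).fit(train_config, validation)


def predict_level(instances, results: KCNResults) -> list[bool]:
    """Instance labels: positive iff p(CID) > p(null); ties are negative."""
    out = []
    for inst in instances:
        p, _ = forward(inst, results.model.space, results.params,
                       results.model.config)
        out.append(bool(p[LABEL_CID] > p[1 - LABEL_CID]))
    return out


def _instance_prf(instances, space, params, config) -> PRF:
    tp = fp = fn = 0
    for inst in instances:
        p, _ = forward(inst, space, params, config)
        pred = p[LABEL_CID] > p[1 - LABEL_CID]
        gold = inst.label == LABEL_CID
        tp += pred and gold
        fp += pred and not gold
        fn += gold and not pred
    return PRF(tp, fp, fn)


# ---------------------------------------------------------------------------
# merging and scoring
# ---------------------------------------------------------------------------


def merge_document_level(
    intra_preds: list[tuple[CandidateInstance, bool]],
    inter_preds: list[tuple[CandidateInstance, bool]] = (),
) -> set[tuple[str, str, str]]:
    """OR-merge instance predictions into document-level ID pairs.

    An entity pair holds a CID relation as soon as at least one of its
    instances, at either level, is predicted positive.
    """
    return {
        inst.doc_pair
        for inst, positive in list(intra_preds) + list(inter_preds)
        if positive
    }


def evaluate_prf(
    predicted_pairs: set[tuple[str, str, str]],
    gold_pairs: set[tuple[str, str, str]],
) -> PRF:
    """Precision/recall/F1 over (doc, chemical-ID, disease-ID) sets."""
    if not gold_pairs:
        raise ValueError("empty gold set")
    tp = len(predicted_pairs & gold_pairs)
    return PRF(tp, len(predicted_pairs) - tp, len(gold_pairs) - tp)


def gold_pair_set(docs) -> set[tuple[str, str, str]]:
    return {(d.doc_id, c, dis) for d in docs for c, dis in d.gold_cid}


def only_kb_baseline(
    candidate_pairs: set[tuple[str, str, str]], kb: TripleFile
) -> set[tuple[str, str, str]]:
    """Predict positive iff the pair is curated as marker/mechanism — the one
    KB relation that denotes a true chemical-induced disease."""
    cid_pairs = {(c, d) for c, r, d in kb if r == "marker/mechanism"}
    return {
        (doc_id, c, d)
        for doc_id, c, d in candidate_pairs
        if (c, d) in cid_pairs
    }


# ---------------------------------------------------------------------------
# end-to-end evaluation and the ablation grid
# ---------------------------------------------------------------------------


@dataclass
class PipelineScores:
    intra: PRF
    inter: PRF
    document: PRF


def train_and_evaluate(
    train_instances: list[CandidateInstance],
    test_instances: list[CandidateInstance],
    test_gold: set[tuple[str, str, str]],
    space: EmbeddingSpace,
    kcn_config: KcnConfig | None = None,
    train_config: TrainConfig | None = None,
) -> tuple[PipelineScores, dict[str, KCNResults]]:
    """Train per-level classifiers and score merged predictions.

    Each level's merged predictions, and their union, are evaluated against
    the full document-level gold set (which is what makes inter-sentence
    recall intrinsically low: most gold pairs co-occur in a sentence).
    """
    kcn_config = kcn_config or KcnConfig()
    train_config = train_config or TrainConfig()
    level_preds: dict[str, list[tuple[CandidateInstance, bool]]] = {}
    results: dict[str, KCNResults] = {}
    for level in ("intra", "inter"):
        tr = [i for i in train_instances if i.level == level]
        te = [i for i in test_instances if i.level == level]
        if not tr or not te:
            level_preds[level] = []
            continue
        res = KCN(tr, space, kcn_config, level=level).fit(train_config)
        results[level] = res
        level_preds[level] = list(zip(te, predict_level(te, res)))
    scores = PipelineScores(
        intra=evaluate_prf(merge_document_level(level_preds["intra"]), test_gold),
        inter=evaluate_prf(merge_document_level(level_preds["inter"]), test_gold)
        if level_preds["inter"]
        else PRF(0, 0, len(test_gold)),
        document=evaluate_prf(
            merge_document_level(level_preds["intra"], level_preds["inter"]),
            test_gold,
        ),
    )
    return scores, results


#: Named variant configurations mirroring the ablation grid: the full model,
#: averaged-entity (AE), self-attention (SA), and both replacements (AE-SA).
VARIANTS: dict[str, dict] = {
    "KCN": {},
    "AE": {"entity_source": "averaged-words"},
    "SA": {"attention": "self"},
    "AE-SA": {"entity_source": "averaged-words", "attention": "self"},
}


def variant_config(base: KcnConfig, name: str) -> KcnConfig:
    if name in VARIANTS:
        return replace(base, **VARIANTS[name])
    if name in ("GTU", "GLU", "GTRU"):
        return replace(base, gate=name)
    if name in ("DGate-SAtt", "SGate-SAtt", "DGate-DAtt", "SGate-DAtt"):
        return replace(base, sharing=name)
    raise ValueError(f"unknown variant {name!r}")


def run_ablation(
    grid: list[str],
    train_instances: list[CandidateInstance],
    test_instances: list[CandidateInstance],
    test_gold: set[tuple[str, str, str]],
    space: EmbeddingSpace,
    base_config: KcnConfig | None = None,
    train_config: TrainConfig | None = None,
    seeds: tuple[int, ...] = (0,),
) -> pd.DataFrame:
    """Train and score every named variant for every seed.

    Returns a tidy frame with one row per (variant, seed, level) holding
    P/R/F; means over seeds can be taken with a groupby.
    """
    base_config = base_config or KcnConfig()
    train_config = train_config or TrainConfig()
    rows = []
    for name in grid:
        for seed in seeds:
            cfg = replace(variant_config(base_config, name), seed=seed)
            tc = replace(train_config, seed=seed)
            space.reset_counters()
            scores, _ = train_and_evaluate(
                train_instances, test_instances, test_gold, space, cfg, tc
            )
            for level, prf in (
                ("intra", scores.intra),
                ("inter", scores.inter),
                ("document", scores.document),
            ):
                rows.append(
                    {"config": name, "seed": seed, "level": level,
                     "P": prf.precision, "R": prf.recall, "F": prf.f1}
                )
    return pd.DataFrame(rows)


def ablation_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Mean P/R/F per (config, level) over seeds."""
    return (
        table.groupby(["config", "level"])[["P", "R", "F"]]
        .mean()
        .reset_index()
    )
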