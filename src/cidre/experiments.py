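"""Canonical synthetic experiments at fixed study conditions.

These drivers pin the problem sizes the package uses to characterize
itself: a templated corpus large enough for a 400-train / 100-test split of
intra-sentence instances, classifiers with 50 filters over five window
widths in a 16-dimensional embedding space, 30 training epochs, and a
planted-structure knowledge base for link-prediction ranking.  The sizes
are deliberately small: they are chosen so the planted signal is learnable
to saturation, which is what makes the qualitative claims (knowledge helps;
gates and attention localize on triggers) checkable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .instances import CandidateInstance, build_instances
from .kb import TransE, TransEConfig, TransEResults, init_embeddings
from .model import KcnConfig, forward
from .pipeline import fit_embedding_space
from .synthetic import SyntheticConfig, generate_dataset
from .train import (
    KCN,
    PRF,
    TrainConfig,
    _instance_prf,
    ablation_summary,
    gold_pair_set,
    only_kb_baseline,
    run_ablation,
)


@dataclass
class StudyConditions:
    """Problem sizes for the synthetic characterization runs."""

    n_documents: int = 760
    n_train_instances: int = 400
    n_test_instances: int = 100
    embedding_dim: int = 16
    filters_per_window: int = 10     # x 5 windows = 50 total
    hidden: int = 32
    max_epochs: int = 30
    transe_epochs: int = 50
    noise: float = 0.0
    informative_fraction: float = 1.0

    def kcn_config(self, seed: int = 0, **overrides) -> KcnConfig:
        base = dict(
            filters_per_window=self.filters_per_window,
            d=self.embedding_dim, k=self.embedding_dim,
            hidden=self.hidden, seed=seed,
        )
        base.update(overrides)
        return KcnConfig(**base)

    def train_config(self, seed: int = 0) -> TrainConfig:
        # the budget is the epoch count itself; no early stop inside it
        return TrainConfig(max_epochs=self.max_epochs,
                           patience=self.max_epochs, seed=seed)


@dataclass
class PreparedCorpus:
    docs: list
    parses: dict
    kb: object
    hierarchy: object
    space: object
    train_instances: list[CandidateInstance]
    test_instances: list[CandidateInstance]
    test_docs: list
    transe: TransEResults = None


def prepare_synthetic(
    conditions: StudyConditions, corpus_seed: int, by_documents: bool = False
) -> PreparedCorpus:
    """Generate a corpus, fit embeddings, and split train/test.

    ``by_documents=False`` takes exactly ``n_train/n_test`` intra-sentence
    instances (document-granular); ``by_documents=True`` holds out 100
    documents with all their instances, for document-level scoring.
    """
    cfg = SyntheticConfig(
        n_documents=conditions.n_documents,
        noise=conditions.noise,
        informative_fraction=conditions.informative_fraction,
        embedding_dim=conditions.embedding_dim,
        seed=corpus_seed,
    )
    docs, parses, kb, hierarchy, vectors = generate_dataset(cfg)
    instances = build_instances(docs, parses, hierarchy)
    transe = fit_embedding_space(
        instances, docs, kb, vectors,
        TransEConfig(k=conditions.embedding_dim,
                     epochs=conditions.transe_epochs, seed=corpus_seed),
    )
    rng = np.random.default_rng(corpus_seed + 977)

    if by_documents:
        doc_ids = sorted({d.doc_id for d in docs})
        rng.shuffle(doc_ids)
        test_set = set(doc_ids[:100])
        train = [i for i in instances if i.doc_id not in test_set]
        test = [i for i in instances if i.doc_id in test_set]
        test_docs = [d for d in docs if d.doc_id in test_set]
    else:
        intra = [i for i in instances if i.level == "intra"]
        doc_ids = sorted({i.doc_id for i in intra})
        rng.shuffle(doc_ids)
        per_doc = {d: sum(1 for i in intra if i.doc_id == d) for d in doc_ids}
        test_set, count = set(), 0
        for d in doc_ids:
            if count + per_doc[d] <= conditions.n_test_instances:
                test_set.add(d)
                count += per_doc[d]
            if count == conditions.n_test_instances:
                break
        test = [i for i in intra if i.doc_id in test_set]
        train = [i for i in intra if i.doc_id not in test_set][
            : conditions.n_train_instances
        ]
        test_docs = [d for d in docs if d.doc_id in test_set]

    return PreparedCorpus(docs, parses, kb, hierarchy, transe.space,
                          train, test, test_docs, transe)


def learnability_run(
    prepared: PreparedCorpus, conditions: StudyConditions,
    seeds: tuple[int, ...],
) -> list[float]:
    """Held-out instance-level F1 of the full model, one value per seed."""
    f1s = []
    for seed in seeds:
        cfg = conditions.kcn_config(seed)
        results = KCN(prepared.train_instances, prepared.space, cfg).fit(
            conditions.train_config(seed)
        )
        prf = _instance_prf(prepared.test_instances, prepared.space,
                            results.params, cfg)
        f1s.append(float(prf.f1))
    return f1s


def ablation_run(
    prepared: PreparedCorpus, conditions: StudyConditions,
    grid: tuple[str, ...] = ("KCN", "SA", "AE-SA"),
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4),
) -> pd.DataFrame:
    """Variant grid at document level; returns the per-seed tidy table."""
    return run_ablation(
        list(grid),
        prepared.train_instances,
        prepared.test_instances,
        gold_pair_set(prepared.test_docs),
        prepared.space,
        conditions.kcn_config(),
        conditions.train_config(),
        seeds=seeds,
    )


def mean_document_f1(table: pd.DataFrame) -> dict[str, float]:
    summary = ablation_summary(table)
    doc = summary[summary["level"] == "document"]
    return dict(zip(doc["config"], doc["F"]))


def only_kb_run(prepared: PreparedCorpus) -> PRF:
    """The knowledge-matching baseline on the held-out documents."""
    pairs = {i.doc_pair for i in prepared.test_instances}
    pred = only_kb_baseline(pairs, prepared.kb)
    from .train import evaluate_prf

    return evaluate_prf(pred, gold_pair_set(prepared.test_docs))


def attention_trigger_rate(
    prepared: PreparedCorpus, conditions: StudyConditions,
    triggers: tuple[str, ...] = ("induced", "caused"), seed: int = 0,
) -> float:
    """Share of correctly classified positive test instances whose maximum
    attention weight (either branch) falls on the trigger token."""
    cfg = conditions.kcn_config(seed)
    results = KCN(prepared.train_instances, prepared.space, cfg).fit(
        conditions.train_config(seed)
    )
    hits = total = 0
    for inst in prepared.test_instances:
        if inst.label != 1:
            continue
        p, diag = forward(inst, prepared.space, results.params, cfg)
        if p[1] <= p[0]:
            continue
        total += 1
        trigger_pos = [i for i, t in enumerate(inst.sdp) if t in triggers]
        best = {int(np.argmax(diag["alpha_c"])), int(np.argmax(diag["alpha_d"]))}
        if best & set(trigger_pos):
            hits += 1
    return hits / total if total else float("nan")


# ---------------------------------------------------------------------------
# planted-structure knowledge base
# ---------------------------------------------------------------------------


@dataclass
class PlantedKb:
    """A triple set with exact group-wise translational structure.

    Chemicals fall into groups sharing one latent position; every (group,
    relation) combination owns one disease, so (c, r, d) is a true triple
    iff d is the disease of (group(c), r).  The set is generated by a
    translation rule, so a correctly implemented trainer should rank
    held-out tails at the top.
    """

    triples: list = field(default_factory=list)
    heldout: list = field(default_factory=list)
    chem_group: dict = field(default_factory=dict)
    dis_of: dict = field(default_factory=dict)   # (group, relation) -> disease


def make_planted_kb(
    seed: int, n_groups: int = 10, chems_per_group: int = 4,
    n_heldout: int = 30,
) -> PlantedKb:
    rng = np.random.default_rng(seed)
    relations = ("marker/mechanism", "therapeutic", "inferred-association",
                 "null")
    chem_group = {
        f"C{g:02d}x{j}": g
        for g in range(n_groups) for j in range(chems_per_group)
    }
    dis_of = {
        (g, r): f"D{g:02d}r{ri}"
        for g in range(n_groups) for ri, r in enumerate(relations)
    }
    triples = [
        (c, r, dis_of[(g, r)])
        for c, g in chem_group.items()
        for r in relations
    ]
    rng.shuffle(triples)
    # hold out triples whose entities all still occur in the training rest
    heldout, train = [], list(triples)
    for t in list(train):
        if len(heldout) == n_heldout:
            break
        rest = [x for x in train if x != t]
        ents = {e for x in rest for e in (x[0], x[2])}
        if t[0] in ents and t[2] in ents:
            heldout.append(t)
            train = rest
    return PlantedKb(train, heldout, chem_group, dis_of)


def planted_recovery_run(
    seed: int, epochs: int = 500, k: int = 16, n_candidates: int = 10
) -> tuple[float, list[float]]:
    """Train on the planted KB; return (held-out top-1 rate, loss trace).

    Each held-out query ranks the true disease against ``n_candidates - 1``
    distractor diseases belonging to other (group, relation) combinations.
    """
    kb = make_planted_kb(seed)
    cfg = TransEConfig(k=k, epochs=epochs, seed=seed, learning_rate=0.02)
    result = TransE(kb.triples, config=cfg).fit()
    rng = np.random.default_rng(seed + 13)
    top1 = 0
    for c, r, d in kb.heldout:
        distractors = [x for x in set(kb.dis_of.values())
                       if x != d and x in result.space.entities]
        rng.shuffle(distractors)
        cands = [d] + distractors[: n_candidates - 1]
        ranked = result.rank_tails(c, r, cands)
        top1 += ranked[0] == d
    return top1 / len(kb.heldout), result.loss_trace
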