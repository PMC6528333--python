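"""End-to-end glue: corpus -> instances -> knowledge -> classifier -> scores.

Convenience functions chaining the pipeline stages the way the command-line
interface and the reproduction script run them.
"""

from __future__ import annotations

from dataclasses import replace

from .corpus_io import Document, MeshHierarchy, TripleFile
from .instances import CandidateInstance, build_instances
from .kb import (
    EmbeddingSpace,
    TransE,
    TransEConfig,
    TransEResults,
    annotate_pairs,
    build_training_triples,
)
from .model import KcnConfig
from .synthetic import entity_mention_words
from .train import (
    PipelineScores,
    TrainConfig,
    gold_pair_set,
    train_and_evaluate,
)


def annotate_instances(
    instances: list[CandidateInstance], kb: TripleFile
) -> list[tuple[str, str, str]]:
    """Fill each instance's ``kb_relation`` from the KB; returns the
    annotated (chemical, relation, disease) triples of the corpus pairs."""
    pairs = [inst.pair for inst in instances]
    annotated = annotate_pairs(pairs, kb)
    rel_of = {(c, d): r for c, r, d in annotated}
    for inst in instances:
        inst.kb_relation = rel_of[inst.pair]
    return annotated


def fit_embedding_space(
    instances: list[CandidateInstance],
    docs: list[Document],
    kb: TripleFile,
    word_vectors: dict,
    transe_config: TransEConfig | None = None,
) -> TransEResults:
    """Annotate instances against the KB and fit translation embeddings on
    the merged corpus+KB triple set."""
    annotated = annotate_instances(instances, kb)
    triples = build_training_triples(annotated, kb)
    model = TransE(
        triples,
        entity_words=entity_mention_words(docs),
        word_vectors=word_vectors,
        config=transe_config or TransEConfig(),
    )
    return model.fit()


def prepare_corpus(
    docs: list[Document],
    parses,
    hierarchy: MeshHierarchy | None,
    kb: TripleFile,
) -> list[CandidateInstance]:
    """Instance construction plus KB annotation for one corpus."""
    instances = build_instances(docs, parses, hierarchy)
    annotate_instances(instances, kb)
    return instances


def run_endtoend(
    train_docs,
    train_parses,
    test_docs,
    test_parses,
    hierarchy: MeshHierarchy | None,
    kb: TripleFile,
    word_vectors: dict,
    kcn_config: KcnConfig | None = None,
    train_config: TrainConfig | None = None,
    transe_config: TransEConfig | None = None,
    space: EmbeddingSpace | None = None,
) -> tuple[PipelineScores, EmbeddingSpace]:
    """Full run on a train corpus / test corpus split.

    Embeddings are fitted on the training corpus pairs merged with the KB;
    the per-level classifiers are trained on the training instances and
    scored on the test corpus at intra, inter and merged document level.
    """
    kcn_config = kcn_config or KcnConfig()
    train_instances = build_instances(train_docs, train_parses, hierarchy)
    test_instances = build_instances(test_docs, test_parses, hierarchy)
    if space is None:
        seed = (transe_config or TransEConfig()).seed
        transe_config = replace(
            transe_config or TransEConfig(), k=kcn_config.k, seed=seed
        )
        result = fit_embedding_space(
            train_instances, list(train_docs) + list(test_docs), kb,
            word_vectors, transe_config,
        )
        space = result.space
    else:
        annotate_instances(train_instances, kb)
    annotate_instances(test_instances, kb)
    scores, _ = train_and_evaluate(
        train_instances,
        test_instances,
        gold_pair_set(test_docs),
        space,
        kcn_config,
        train_config,
    )
    return scores, space
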