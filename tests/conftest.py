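import numpy as np
import pytest

from cidre.instances import CandidateInstance, build_instances
from cidre.corpus_io import Mention
from cidre.kb import EmbeddingSpace, TransEConfig
from cidre.model import KcnConfig
from cidre.pipeline import fit_embedding_space
from cidre.synthetic import SyntheticConfig, generate_dataset, sentence1_fixture


@pytest.fixture(scope="session")
def s1():
    """The worked single-sentence document and its parse."""
    return sentence1_fixture()


@pytest.fixture(scope="session")
def small_dataset():
    """A small synthetic corpus with KB, hierarchy and word vectors."""
    return generate_dataset(SyntheticConfig(n_documents=60, seed=42))


@pytest.fixture(scope="session")
def small_instances(small_dataset):
    docs, parses, kb, hierarchy, vectors = small_dataset
    return build_instances(docs, parses, hierarchy)


@pytest.fixture(scope="session")
def fitted_space(small_dataset, small_instances):
    docs, parses, kb, hierarchy, vectors = small_dataset
    result = fit_embedding_space(
        small_instances, docs, kb, vectors,
        TransEConfig(k=16, epochs=20, seed=0),
    )
    return result.space


def make_instance(sdp, label=0, kb_relation="null", level="intra",
                  chem_id="MESH:C000", dis_id="MESH:D000", doc_id="T1"):
    """A candidate instance with an explicit SDP, for model-level tests."""
    chem = Mention(doc_id, 0, 1, "c", "Chemical", chem_id, 0)
    dis = Mention(doc_id, 2, 3, "d", "Disease", dis_id, 0)
    return CandidateInstance(doc_id, chem, dis, level, sdp=list(sdp),
                             label=label, kb_relation=kb_relation)


def tiny_space(k=4, tokens=("a", "b", "c"), seed=0):
    """A minimal embedding space for forward-pass tests."""
    rng = np.random.default_rng(seed)
    words = {t: rng.normal(0, 0.3, k) for t in tokens}
    entities = {"MESH:C000": rng.normal(0, 0.3, k),
                "MESH:D000": rng.normal(0, 0.3, k)}
    relations = {r: rng.normal(0, 0.3, k)
                 for r in ("marker/mechanism", "therapeutic",
                           "inferred-association", "null")}
    return EmbeddingSpace(words, entities, relations,
                          entity_words={"MESH:C000": ["c"], "MESH:D000": ["d"]})


@pytest.fixture
def tiny_cfg():
    return KcnConfig(window_sizes=(1, 2, 3), filters_per_window=2,
                     d=4, k=4, hidden=5, seed=0)
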