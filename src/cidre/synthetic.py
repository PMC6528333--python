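"""Synthetic corpora with planted statistical structure.

The generator emits the exact file formats the readers consume (PubTator
corpus, CoNLL-style parses, KB triple TSV, MeSH hierarchy TSV, word2vec
text vectors), so the synthetic path is byte-compatible with the real-data
path and every stage of the pipeline is testable without any download.

Each document realizes one chemical--disease pair in a templated sentence
frame whose dependency tree is constructed alongside, so parses are valid
by construction and the shortest dependency path of every candidate pair is
known exactly.  The planted label rule is

    positive  ⟺  (the frame verb is a trigger, e.g. "induced")
              AND (the pair's KB relation is marker/mechanism)

optionally flipped with probability ``noise``.  The KB covers each pair
with probability ``informative_fraction``; covered pairs are
marker/mechanism half the time and a distractor relation (therapeutic or
inferred-association) otherwise, uncovered pairs annotate as *null*
downstream.  A controllable share of documents realizes the pair across
sentences (exercising the inter-sentence distance rule), repeats mentions
(exercising the nearest-pair rule and the intra/inter exclusion), or plants
a hypernym disease (exercising the MeSH-ancestor filter).

What this emulates — and what it does not: the verb-frame contrast mirrors
trigger/negation cues of real abstracts and the KB coverage mirrors curated
prior knowledge, but the language is templated, entity surface forms are
single tokens, and parse trees are noise-free.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .corpus_io import (
    DependencyTree,
    Document,
    Mention,
    MeshHierarchy,
    TripleFile,
    assign_sentence_indices,
    write_ctd_triples,
    write_mesh_hierarchy,
    write_parses,
    write_pubtator,
    write_word_vectors,
)

MARKER = "marker/mechanism"
DISTRACTORS = ("therapeutic", "inferred-association")


@dataclass
class SyntheticConfig:
    n_documents: int = 60
    n_chemicals: int = 12
    n_diseases: int = 12
    triggers: tuple[str, ...] = ("induced", "caused")
    anti_triggers: tuple[str, ...] = ("reversed", "prevented")
    informative_fraction: float = 1.0
    noise: float = 0.0
    p_inter: float = 0.25
    p_far_inter: float = 0.05
    p_repeat_mention: float = 0.1
    p_hypernym: float = 0.1
    embedding_dim: int = 16
    n_extra_kb_triples: int = 20
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.noise < 0.5:
            raise ValueError("noise must be in [0, 0.5)")
        if set(self.triggers) & set(self.anti_triggers):
            raise ValueError("trigger and anti-trigger sets must be disjoint")
        if not 0 <= self.informative_fraction <= 1:
            raise ValueError("informative_fraction must be in [0, 1]")


# entity naming ------------------------------------------------------------


def chem_id(i: int) -> str:
    return f"MESH:C{i:03d}"


def dis_id(i: int) -> str:
    return f"MESH:D{i:03d}"


def ancestor_id(i: int) -> str:
    return f"MESH:A{i:03d}"


def chem_word(i: int) -> str:
    return f"compound{i}"


def dis_word(i: int) -> str:
    return f"disorder{i}"


def ancestor_word(i: int) -> str:
    return f"syndrome{i}"


_TEMPLATE_WORDS = [
    "clinical", "observations", "were", "by", "injections", "in", "control",
    "groups", "observed", "also", "the", "study", "continued", "for", "days",
]


# ---------------------------------------------------------------------------
# sentence frames: (text, tokens, heads, tags) built together
# ---------------------------------------------------------------------------


def _title_sentence():
    return ("Clinical observations .",
            ["clinical", "observations"], [1, -1], ["nmod", "root"])


def _intra_sentence(dis: str, verb: str, chem: str):
    text = f"{dis.capitalize()} were {verb} by {chem} injections in control groups ."
    tokens = [dis, "were", verb, "by", chem, "injections", "in", "control", "groups"]
    heads = [2, 2, -1, 2, 5, 3, 2, 8, 6]
    tags = ["vmod", "vmod", "root", "vmod", "nmod", "pmod", "vmod", "nmod", "pmod"]
    return text, tokens, heads, tags


def _chem_sentence(chem: str, verb: str):
    text = f"{chem.capitalize()} injections were {verb} ."
    tokens = [chem, "injections", "were", verb]
    heads = [1, 3, 3, -1]
    tags = ["nmod", "sub", "vmod", "root"]
    return text, tokens, heads, tags


def _dis_sentence(dis: str, also: bool = False):
    if also:
        text = f"{dis.capitalize()} were also observed ."
        tokens = [dis, "were", "also", "observed"]
        heads = [3, 3, 3, -1]
        tags = ["sub", "vmod", "vmod", "root"]
    else:
        text = f"{dis.capitalize()} were observed ."
        tokens = [dis, "were", "observed"]
        heads = [2, 2, -1]
        tags = ["sub", "vmod", "root"]
    return text, tokens, heads, tags


def _filler_sentence():
    return ("The study continued for days .",
            ["the", "study", "continued", "for", "days"],
            [1, 2, -1, 2, 3],
            ["nmod", "sub", "root", "vmod", "pmod"])


class _DocBuilder:
    """Assemble a document and its parses sentence by sentence."""

    def __init__(self, doc_id: str):
        self.doc_id = doc_id
        self.sentences: list[tuple] = [_title_sentence()]
        self.mention_specs: list[tuple[int, str, str, str]] = []

    def add(self, frame, mentions: list[tuple[str, str, str]] = ()) -> int:
        """Add a sentence frame; ``mentions`` are (surface, etype, mesh_id)."""
        idx = len(self.sentences)
        self.sentences.append(frame)
        for surface, etype, mesh in mentions:
            self.mention_specs.append((idx, surface, etype, mesh))
        return idx

    def build(self, gold: set[tuple[str, str]]):
        texts = [s[0] for s in self.sentences]
        title = texts[0]
        abstract = " ".join(texts[1:])
        doc = Document(self.doc_id, title, abstract, gold_cid=set(gold))
        # sentence character offsets within the full text
        offsets = []
        pos = 0
        for i, t in enumerate(texts):
            offsets.append(pos)
            pos += len(t) + 1  # single joining space
        full = doc.text
        for sidx, surface, etype, mesh in self.mention_specs:
            shown = surface.capitalize() if self._starts(sidx, surface) else surface
            start = full.index(shown, offsets[sidx])
            doc.mentions.append(
                Mention(self.doc_id, start, start + len(shown), shown, etype, mesh)
            )
        assign_sentence_indices(doc)
        trees = {
            (self.doc_id, i): DependencyTree(self.doc_id, i, list(toks),
                                             list(heads), list(tags))
            for i, (_, toks, heads, tags) in enumerate(self.sentences)
        }
        for tree in trees.values():
            tree.validate()
        return doc, trees

    def _starts(self, sidx: int, surface: str) -> bool:
        return self.sentences[sidx][0].lower().startswith(surface.lower())


# ---------------------------------------------------------------------------
# corpus generation
# ---------------------------------------------------------------------------


def _pair_relation(pair, pair_relations, rng, config):
    """Assign (once, globally) the KB relation of an entity pair."""
    if pair not in pair_relations:
        if rng.random() < config.informative_fraction:
            pair_relations[pair] = (
                MARKER if rng.random() < 0.5
                else DISTRACTORS[int(rng.integers(len(DISTRACTORS)))]
            )
        else:
            pair_relations[pair] = None  # absent from the KB
    return pair_relations[pair]


def generate_corpus(config: SyntheticConfig, rng: np.random.Generator | None = None):
    """Generate documents, parses, and the pair-level KB relation map.

    Returns ``(docs, parses, pair_relations)`` where ``pair_relations`` maps
    (chem_id, dis_id) to its global KB relation (None = uncovered).
    """
    rng = rng or np.random.default_rng(config.seed)
    docs: list[Document] = []
    parses: dict[tuple[str, int], DependencyTree] = {}
    pair_relations: dict[tuple[str, str], str | None] = {}

    for n in range(config.n_documents):
        doc_id = f"SYN{n:04d}"
        ci = int(rng.integers(config.n_chemicals))
        di = int(rng.integers(config.n_diseases))
        c_id, d_id = chem_id(ci), dis_id(di)
        c_w, d_w = chem_word(ci), dis_word(di)
        relation = _pair_relation((c_id, d_id), pair_relations, rng, config)

        u = rng.random()
        far = u < config.p_far_inter
        inter = u < config.p_far_inter + config.p_inter
        # far cross-sentence realizations never contribute positives: their
        # candidate is pruned by the distance rule, so a gold pair there
        # would be unrecoverable by construction.
        trigger = (not far) and bool(rng.random() < 0.5)
        verb = (
            config.triggers[int(rng.integers(len(config.triggers)))]
            if trigger
            else config.anti_triggers[int(rng.integers(len(config.anti_triggers)))]
        )

        b = _DocBuilder(doc_id)
        if inter:
            b.add(_chem_sentence(c_w, verb), [(c_w, "Chemical", c_id)])
            gap = 3 if far else int(rng.integers(0, 3))  # sentences between
            for _ in range(gap):
                b.add(_filler_sentence())
            b.add(_dis_sentence(d_w), [(d_w, "Disease", d_id)])
            if far:
                for _ in range(2):
                    b.add(_filler_sentence())
            elif rng.random() < config.p_repeat_mention:
                # a second, farther disease mention: nearest-pair rule keeps
                # the first
                b.add(_filler_sentence())
                b.add(_dis_sentence(d_w, also=True), [(d_w, "Disease", d_id)])
        else:
            b.add(_intra_sentence(d_w, verb, c_w),
                  [(d_w, "Disease", d_id), (c_w, "Chemical", c_id)])
            if rng.random() < config.p_repeat_mention:
                # extra cross-sentence mention of the same pair: excluded
                # from inter level because the pair co-occurs in a sentence
                b.add(_dis_sentence(d_w, also=True), [(d_w, "Disease", d_id)])

        if not far and rng.random() < config.p_hypernym:
            a_id, a_w = ancestor_id(di), ancestor_word(di)
            b.add(_dis_sentence(a_w, also=True), [(a_w, "Disease", a_id)])

        label = trigger and relation == MARKER
        # the flip draw is taken unconditionally so corpora generated with
        # different noise levels (same seed) differ only in labels
        if rng.random() < config.noise:
            label = not label
        gold = {(c_id, d_id)} if label else set()

        doc, trees = b.build(gold)
        docs.append(doc)
        parses.update(trees)

    return docs, parses, pair_relations


def generate_kb(
    config: SyntheticConfig,
    pair_relations: dict[tuple[str, str], str | None],
    rng: np.random.Generator | None = None,
):
    """KB triples, MeSH hierarchy and word vectors for a generated corpus.

    The triple file holds every covered corpus pair plus a few extra
    KB-only rows; the hierarchy gives every disease a tree number whose
    proper prefix belongs to its planted ancestor; word vectors are
    spherical Gaussian, seeded.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    rows = [
        (c, rel, d) for (c, d), rel in sorted(pair_relations.items())
        if rel is not None
    ]
    used = set(pair_relations)
    extra = 0
    tries = 0
    while extra < config.n_extra_kb_triples and tries < 10 * config.n_extra_kb_triples:
        tries += 1
        pair = (chem_id(int(rng.integers(config.n_chemicals))),
                dis_id(int(rng.integers(config.n_diseases))))
        if pair in used:
            continue
        used.add(pair)
        rel = (MARKER, *DISTRACTORS)[int(rng.integers(3))]
        rows.append((pair[0], rel, pair[1]))
        extra += 1
    kb = TripleFile(rows)

    trees: dict[str, set[str]] = {}
    for i in range(config.n_diseases):
        trees[dis_id(i)] = {f"C01.{i:03d}.100"}
        trees[ancestor_id(i)] = {f"C01.{i:03d}"}
    for i in range(config.n_chemicals):
        trees[chem_id(i)] = {f"D02.{i:03d}.200"}
    hierarchy = MeshHierarchy(trees)

    vocab = list(_TEMPLATE_WORDS)
    vocab += list(config.triggers) + list(config.anti_triggers)
    vocab += [chem_word(i) for i in range(config.n_chemicals)]
    vocab += [dis_word(i) for i in range(config.n_diseases)]
    vocab += [ancestor_word(i) for i in range(config.n_diseases)]
    vectors = {
        w: rng.normal(0.0, 0.3, config.embedding_dim) for w in sorted(set(vocab))
    }
    return kb, hierarchy, vectors


def entity_mention_words(docs) -> dict[str, list[str]]:
    """Lowercased mention words per entity ID, for embedding initialization."""
    out: dict[str, list[str]] = {}
    for doc in docs:
        for m in doc.mentions:
            if m.mesh_id == "-1":
                continue
            out.setdefault(m.mesh_id, [])
            for w in m.text.lower().split():
                out[m.mesh_id].append(w)
    return {k: sorted(set(v)) for k, v in out.items()}


def generate_dataset(config: SyntheticConfig):
    """One-call generation: (docs, parses, kb, hierarchy, word_vectors)."""
    rng = np.random.default_rng(config.seed)
    docs, parses, pair_relations = generate_corpus(config, rng)
    kb, hierarchy, vectors = generate_kb(config, pair_relations, rng)
    return docs, parses, kb, hierarchy, vectors


def write_dataset(config: SyntheticConfig, directory) -> dict[str, str]:
    """Generate and write all five artifact files; returns their paths."""
    import os

    os.makedirs(directory, exist_ok=True)
    docs, parses, kb, hierarchy, vectors = generate_dataset(config)
    paths = {
        "corpus": os.path.join(directory, "corpus.pubtator"),
        "parses": os.path.join(directory, "parses.conll"),
        "kb": os.path.join(directory, "kb_triples.tsv"),
        "hierarchy": os.path.join(directory, "mesh_hierarchy.tsv"),
        "vectors": os.path.join(directory, "word_vectors.vec"),
    }
    write_pubtator(docs, paths["corpus"])
    write_parses(parses, paths["parses"])
    write_ctd_triples(kb, paths["kb"])
    write_mesh_hierarchy(hierarchy, paths["hierarchy"])
    write_word_vectors(vectors, paths["vectors"])
    return paths


# ---------------------------------------------------------------------------
# the worked single-sentence fixture
# ---------------------------------------------------------------------------


def sentence1_fixture():
    """A one-document corpus whose single abstract sentence is the classic
    pilocarpine-induced-seizures example, with a dependency tree whose
    shortest path between the pair serializes to the 17-token sequence

        pilocarpine ↑ nmod ↑ injections ↑ pmod ↑ by ↑ vmod ↑ induced
        ↓ vmod ↓ seizures

    Returns ``(doc, parses)``.
    """
    doc_id = "S1"
    title = "A case report ."
    abstract = ("Seizures were induced by pilocarpine injections in "
                "trained and non-trained control groups.")
    doc = Document(doc_id, title, abstract)
    text = doc.text
    for surface, etype, mesh in (
        ("pilocarpine", "Chemical", "MESH:D010862"),
        ("Seizures", "Disease", "MESH:D012640"),
    ):
        start = text.index(surface)
        doc.mentions.append(
            Mention(doc_id, start, start + len(surface), surface, etype, mesh)
        )
    doc.gold_cid = {("MESH:D010862", "MESH:D012640")}
    assign_sentence_indices(doc)

    title_tree = DependencyTree(
        doc_id, 0, ["a", "case", "report"], [2, 2, -1], ["nmod", "nmod", "root"]
    )
    tokens = ["seizures", "were", "induced", "by", "pilocarpine", "injections",
              "in", "trained", "and", "non-trained", "control", "groups"]
    heads = [2, 2, -1, 2, 5, 3, 2, 11, 7, 7, 11, 6]
    tags = ["vmod", "vmod", "root", "vmod", "nmod", "pmod", "vmod",
            "nmod", "coord", "conj", "nmod", "pmod"]
    sent_tree = DependencyTree(doc_id, 1, tokens, heads, tags)
    for t in (title_tree, sent_tree):
        t.validate()
    return doc, {(doc_id, 0): title_tree, (doc_id, 1): sent_tree}
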