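"""Candidate-instance construction and shortest-dependency-path generation.

A candidate instance pairs one chemical mention with one disease mention,
either inside a single sentence (*intra*) or across two sentences (*inter*).
Intra pairs are taken exhaustively.  Inter pairs go through three pruning
rules applied in order:

1. an entity-ID pair that co-occurs in some sentence of the document is
   never also an inter pair;
2. mention pairs farther than 3 sentences apart are dropped;
3. of the surviving mention pairs for one entity-ID pair, only the nearest
   is kept (sentence distance, then token distance between mention starts,
   then earliest chemical offset, then earliest disease offset).

A hypernym filter then removes instances whose chemical (disease) is a MeSH
ancestor of a chemical (disease) participating in any other candidate
instance of the same document, so only the most specific entities remain.

The classifier input for an instance is the shortest dependency path (SDP)
between the two mention head tokens, serialized as words interleaved with
(direction, dependency-tag, direction) segments, ``"↑"`` marking a
child-to-parent step and ``"↓"`` the reverse.  Inter-sentence paths run
through a synthetic root joining the two sentence trees.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

from .corpus_io import (
    DependencyTree,
    Document,
    Mention,
    MeshHierarchy,
    normalize_tokens,
)

UP = "↑"    # ↑ child -> parent
DOWN = "↓"  # ↓ parent -> child

LABEL_CID = 1
LABEL_NULL = 0


@dataclass
class CandidateInstance:
    doc_id: str
    chemical: Mention
    disease: Mention
    level: str  # "intra" | "inter"
    sdp: list[str] | None = None
    label: int | None = None
    kb_relation: str | None = None

    @property
    def pair(self) -> tuple[str, str]:
        return (self.chemical.mesh_id, self.disease.mesh_id)

    @property
    def doc_pair(self) -> tuple[str, str, str]:
        return (self.doc_id, self.chemical.mesh_id, self.disease.mesh_id)


def _pairable(doc: Document):
    """Mention pairs eligible for candidates: normalized IDs, no overlap."""
    chems = [m for m in doc.chemicals() if m.mesh_id != "-1"]
    diss = [m for m in doc.diseases() if m.mesh_id != "-1"]
    for c in chems:
        for d in diss:
            if not c.overlaps(d):
                yield c, d


def build_intra(doc: Document) -> list[CandidateInstance]:
    """All chemical-disease mention pairs sharing a sentence, no limitation."""
    return [
        CandidateInstance(doc.doc_id, c, d, "intra")
        for c, d in _pairable(doc)
        if c.sentence_index == d.sentence_index
    ]


def _token_distance(doc: Document, a: int, b: int) -> int:
    lo, hi = min(a, b), max(a, b)
    return len(doc.text[lo:hi].split())


def build_inter(
    doc: Document, intra: list[CandidateInstance] | None = None
) -> list[CandidateInstance]:
    """Inter-sentence candidates after the three pruning rules."""
    if intra is None:
        intra = build_intra(doc)
    intra_pairs = {inst.pair for inst in intra}
    best: dict[tuple[str, str], tuple[tuple, CandidateInstance]] = {}
    for c, d in _pairable(doc):
        if c.sentence_index == d.sentence_index:
            continue
        pair = (c.mesh_id, d.mesh_id)
        if pair in intra_pairs:  # rule 1
            continue
        sdist = abs(c.sentence_index - d.sentence_index)
        if sdist > 3:  # rule 2
            continue
        key = (sdist, _token_distance(doc, c.start, d.start), c.start, d.start)
        if pair not in best or key < best[pair][0]:  # rule 3
            best[pair] = (key, CandidateInstance(doc.doc_id, c, d, "inter"))
    return [inst for _, inst in best.values()]


def hypernym_filter(
    instances: list[CandidateInstance], hierarchy: MeshHierarchy
) -> list[CandidateInstance]:
    """Drop instances containing an entity more general than a same-typed
    entity in any *other* pre-filter instance of the same document.

    Removal is decided against the pre-filter instance set: a chain of
    ancestors is pruned in one pass, with no cascading re-evaluation.
    """
    kept = []
    for i, inst in enumerate(instances):
        c_id, d_id = inst.pair
        others = [o for j, o in enumerate(instances) if j != i]
        general = any(
            hierarchy.is_hypernym(c_id, o.chemical.mesh_id) for o in others
        ) or any(hierarchy.is_hypernym(d_id, o.disease.mesh_id) for o in others)
        if not general:
            kept.append(inst)
    return kept


def label_instances(
    instances: list[CandidateInstance], doc: Document
) -> list[CandidateInstance]:
    """Label each instance positive iff its ID pair is a gold CID pair."""
    for inst in instances:
        inst.label = LABEL_CID if inst.pair in doc.gold_cid else LABEL_NULL
    return instances


# ---------------------------------------------------------------------------
# shortest dependency paths
# ---------------------------------------------------------------------------


class SdpError(ValueError):
    pass


def mention_head_index(doc: Document, tree: DependencyTree, mention: Mention) -> int:
    """Index (in the tree's token list) of the mention head token.

    Head-final heuristic: the last normalized token overlapping the mention
    span.  The sentence's normalized tokens must line up with the tree.
    """
    s, e = doc.sentences[mention.sentence_index]
    toks = normalize_tokens(doc.text[s:e], offset=s)
    if len(toks) != len(tree.tokens):
        raise SdpError(
            f"{doc.doc_id}/s{mention.sentence_index}: sentence has {len(toks)} "
            f"normalized tokens but parse has {len(tree.tokens)}"
        )
    hits = [
        i for i, (_, ts, te) in enumerate(toks)
        if ts < mention.end and mention.start < te
    ]
    if not hits:
        raise SdpError(
            f"{doc.doc_id}: mention {mention.text!r} matches no parse token"
        )
    return hits[-1]


def _path_to_root(tree: DependencyTree, i: int) -> list[int]:
    path = [i]
    while tree.heads[path[-1]] != -1:
        path.append(tree.heads[path[-1]])
    return path


def _tree_path(tree: DependencyTree, a: int, b: int) -> list[int]:
    """Unique undirected path between two tokens of a tree, via ancestors."""
    pa, pb = _path_to_root(tree, a), _path_to_root(tree, b)
    in_pb = {n: i for i, n in enumerate(pb)}
    for i, n in enumerate(pa):
        if n in in_pb:
            return pa[: i + 1] + pb[: in_pb[n]][::-1]
    raise SdpError("tokens are not connected")  # unreachable on valid trees


def _emit(tree: DependencyTree, path: list[int]) -> list[str]:
    """Serialize a within-tree token path as word / (dir, tag, dir) tokens."""
    out = [tree.tokens[path[0]].lower()]
    for u, v in zip(path, path[1:]):
        if tree.heads[u] == v:  # child -> parent
            out.extend([UP, tree.tags[u], UP])
        elif tree.heads[v] == u:  # parent -> child
            out.extend([DOWN, tree.tags[v], DOWN])
        else:
            raise SdpError("non-adjacent step in tree path")
        out.append(tree.tokens[v].lower())
    return out


def extract_sdp(
    trees: dict[tuple[str, int], DependencyTree],
    doc: Document,
    chem: Mention,
    dis: Mention,
) -> list[str]:
    """SDP token sequence from the chemical head to the disease head.

    Intra-sentence: the unique tree path, of length ``4w - 3`` for ``w`` word
    nodes.  Inter-sentence: the chemical's path to its sentence root, a
    ``(↑, root, ↑)`` ascent to the synthetic joining root, a
    ``(↓, tag, ↓)`` descent onto the other sentence's root, then the path
    down to the disease head — one extra 3-token segment, total ``4w``.
    """
    key_c = (doc.doc_id, chem.sentence_index)
    key_d = (doc.doc_id, dis.sentence_index)
    if key_c not in trees or key_d not in trees:
        missing = key_c if key_c not in trees else key_d
        raise KeyError(f"no parse for sentence {missing}")
    tc, td = trees[key_c], trees[key_d]
    hc = mention_head_index(doc, tc, chem)
    hd = mention_head_index(doc, td, dis)
    if chem.sentence_index == dis.sentence_index:
        return _emit(tc, _tree_path(tc, hc, hd))
    up = _emit(tc, _path_to_root(tc, hc))
    down_path = _path_to_root(td, hd)[::-1]  # root .. head
    down = _emit(td, down_path)
    root_tag = td.tags[td.root] or "root"
    return up + [UP, "root", UP, DOWN, root_tag, DOWN] + down


def sdp_word_count(sdp: list[str]) -> int:
    """Number of word nodes on a serialized path."""
    n = len(sdp)
    # intra: n = 4w-3; inter: n = 4w
    return (n + 3) // 4 if n % 4 != 0 else n // 4


# ---------------------------------------------------------------------------
# pipeline glue + serialization
# ---------------------------------------------------------------------------


def build_instances(
    docs: list[Document],
    parses: dict[tuple[str, int], DependencyTree],
    hierarchy: MeshHierarchy | None = None,
    label: bool = True,
) -> list[CandidateInstance]:
    """Full per-document construction: intra + inter, hypernym filter,
    SDP extraction, gold labeling."""
    out: list[CandidateInstance] = []
    for doc in docs:
        intra = build_intra(doc)
        inter = build_inter(doc, intra)
        instances = intra + inter
        if hierarchy is not None:
            instances = hypernym_filter(instances, hierarchy)
        for inst in instances:
            inst.sdp = extract_sdp(parses, doc, inst.chemical, inst.disease)
        if label:
            label_instances(instances, doc)
        out.extend(instances)
    return out


def save_instances(instances: list[CandidateInstance], path) -> None:
    """JSON-lines serialization for inspection and CLI hand-off."""
    with open(path, "w", encoding="utf-8") as fh:
        for inst in instances:
            row = {
                "doc_id": inst.doc_id,
                "chemical": asdict(inst.chemical),
                "disease": asdict(inst.disease),
                "level": inst.level,
                "sdp": inst.sdp,
                "label": inst.label,
                "kb_relation": inst.kb_relation,
            }
            fh.write(json.dumps(row, ensure_ascii=False) + "\n")


def load_instances(path) -> list[CandidateInstance]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            row = json.loads(line)
            out.append(
                CandidateInstance(
                    doc_id=row["doc_id"],
                    chemical=Mention(**row["chemical"]),
                    disease=Mention(**row["disease"]),
                    level=row["level"],
                    sdp=row["sdp"],
                    label=row["label"],
                    kb_relation=row["kb_relation"],
                )
            )
    return out
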