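"""Readers and writers for every external format the pipeline touches.

Formats handled here:

* PubTator corpora — ``pmid|t|``/``pmid|a|`` text lines, tab-separated mention
  rows with character offsets and MeSH IDs, and ``CID`` relation rows;
* CoNLL-style dependency parses, one block per sentence;
* CTD-style chemical--disease triple TSVs;
* MeSH hierarchy TSVs (ID to pipe-separated tree numbers);
* word2vec text-format vector files.

Character offsets follow the PubTator convention: 0-based, half-open, over
``title + " " + abstract``.  Sentence boundaries are recovered with a small
deterministic rule-based splitter; a mention whose span crosses a boundary
forces the two sentences to be merged, so every mention lies inside exactly
one sentence span.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

ENTITY_TYPES = ("Chemical", "Disease")

#: The three relation labels curated in CTD.  The *null* relation used for
#: corpus pairs absent from the knowledge base is synthesized downstream and
#: never stored in a triple file.
KB_RELATIONS = ("marker/mechanism", "therapeutic", "inferred-association")
NULL_RELATION = "null"
ALL_RELATIONS = KB_RELATIONS + (NULL_RELATION,)


class ParseError(ValueError):
    """A line of an input file could not be parsed."""


class ValidationError(ValueError):
    """Parsed content violates a structural invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class Mention:
    """A typed, MeSH-normalized entity mention in a document."""

    doc_id: str
    start: int
    end: int
    text: str
    etype: str
    mesh_id: str
    sentence_index: int = -1

    def overlaps(self, other: "Mention") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass
class Document:
    """A title+abstract with mentions and gold chemical-induced-disease pairs."""

    doc_id: str
    title: str
    abstract: str
    sentences: list[tuple[int, int]] = field(default_factory=list)
    mentions: list[Mention] = field(default_factory=list)
    gold_cid: set[tuple[str, str]] = field(default_factory=set)

    @property
    def text(self) -> str:
        return self.title + " " + self.abstract if self.abstract else self.title

    def chemicals(self) -> list[Mention]:
        return [m for m in self.mentions if m.etype == "Chemical"]

    def diseases(self) -> list[Mention]:
        return [m for m in self.mentions if m.etype == "Disease"]


@dataclass
class DependencyTree:
    """A single-sentence dependency tree over normalized tokens.

    ``heads`` are 0-based token indices with sentinel ``-1`` for the root;
    ``tags`` hold the dependency relation of each token to its head (the
    root's tag is conventionally ``"root"``).
    """

    doc_id: str
    sentence_index: int
    tokens: list[str]
    heads: list[int]
    tags: list[str]

    def validate(self) -> None:
        n = len(self.tokens)
        if not (len(self.heads) == len(self.tags) == n) or n == 0:
            raise ValidationError(
                f"tree {self.doc_id}/{self.sentence_index}: inconsistent lengths"
            )
        roots = [i for i, h in enumerate(self.heads) if h == -1]
        if len(roots) != 1:
            raise ValidationError(
                f"tree {self.doc_id}/{self.sentence_index}: {len(roots)} roots"
            )
        for i, h in enumerate(self.heads):
            if h != -1 and not (0 <= h < n):
                raise ValidationError(
                    f"tree {self.doc_id}/{self.sentence_index}: head {h} of token {i} "
                    "out of range"
                )
        # acyclicity + connectivity: every token must reach the root
        for i in range(n):
            seen = set()
            j = i
            while j != -1:
                if j in seen:
                    raise ValidationError(
                        f"tree {self.doc_id}/{self.sentence_index}: cycle through token {j}"
                    )
                seen.add(j)
                j = self.heads[j]

    @property
    def root(self) -> int:
        return self.heads.index(-1)


class MeshHierarchy:
    """MeSH ID -> tree-number lookup with a hypernym (proper-ancestor) test."""

    def __init__(self, trees: dict[str, set[str]] | None = None):
        self.trees: dict[str, set[str]] = {k: set(v) for k, v in (trees or {}).items()}
        self._warned: set[str] = set()

    def is_hypernym(self, h: str, e: str) -> bool:
        """True iff some tree number of ``h`` is a proper prefix of some tree
        number of ``e`` at a ``.`` boundary.  Irreflexive on IDs."""
        if h == e:
            return False
        for mesh_id in (h, e):
            if mesh_id not in self.trees and mesh_id not in self._warned:
                logger.warning("MeSH ID %s absent from hierarchy", mesh_id)
                self._warned.add(mesh_id)
        for th in self.trees.get(h, ()):
            for te in self.trees.get(e, ()):
                if te.startswith(th + "."):
                    return True
        return False


@dataclass
class TripleFile:
    """Deduplicated (chemical, relation, disease) rows from a KB TSV."""

    triples: list[tuple[str, str, str]]

    def __post_init__(self) -> None:
        seen = set()
        unique = []
        for t in self.triples:
            if t[1] not in KB_RELATIONS:
                raise ValidationError(f"unknown relation label {t[1]!r}")
            if t not in seen:
                seen.add(t)
                unique.append(t)
        self.triples = unique

    def counts(self) -> dict[str, int]:
        out = {r: 0 for r in KB_RELATIONS}
        for _, r, _ in self.triples:
            out[r] += 1
        return out

    def __len__(self) -> int:
        return len(self.triples)

    def __iter__(self):
        return iter(self.triples)


# ---------------------------------------------------------------------------
# sentence splitting and token normalization
# ---------------------------------------------------------------------------

# words whose trailing period does not end a sentence
_ABBREVIATIONS = {
    "e.g", "i.e", "al", "fig", "figs", "dr", "vs", "cf", "ca", "approx",
    "resp", "no", "mr", "mrs", "st",
}

_BOUNDARY = re.compile(r"[.?!]+(?=(\s+)[A-Z0-9])")


def split_sentences(text: str) -> list[tuple[int, int]]:
    """Deterministic rule-based sentence spans over ``text``.

    A boundary is a run of ``.?!`` followed by whitespace and an uppercase
    letter or digit, unless the preceding word is on the abbreviation guard
    list.  Spans are half-open, ordered, non-overlapping and jointly cover
    every non-space character.
    """
    if not text:
        return []
    starts = [0]
    for m in _BOUNDARY.finditer(text):
        word = text[: m.start()].rsplit(None, 1)
        prev = word[-1].lstrip("([\"'") if word else ""
        if prev.lower().rstrip(".") in _ABBREVIATIONS:
            continue
        starts.append(m.end() + len(m.group(1)))
    spans = []
    for i, s in enumerate(starts):
        e = starts[i + 1] if i + 1 < len(starts) else len(text)
        # trim trailing whitespace from the span
        while e > s and text[e - 1].isspace():
            e -= 1
        if e > s:
            spans.append((s, e))
    return spans


def _merge_spans_for_mentions(
    spans: list[tuple[int, int]], mentions: list[Mention]
) -> list[tuple[int, int]]:
    """Merge adjacent sentence spans until no mention crosses a boundary."""
    spans = list(spans)
    changed = True
    while changed:
        changed = False
        for m in mentions:
            hit = [i for i, (s, e) in enumerate(spans) if m.start < e and s < m.end]
            if len(hit) > 1:
                lo, hi = hit[0], hit[-1]
                spans[lo : hi + 1] = [(spans[lo][0], spans[hi][1])]
                changed = True
                break
    return spans


def assign_sentence_indices(doc: Document) -> None:
    """Compute ``doc.sentences`` and each mention's ``sentence_index``."""
    spans = split_sentences(doc.text)
    spans = _merge_spans_for_mentions(spans, doc.mentions)
    doc.sentences = spans
    for m in doc.mentions:
        idx = [i for i, (s, e) in enumerate(spans) if m.start >= s and m.end <= e]
        if len(idx) != 1:
            raise ValidationError(
                f"{doc.doc_id}: mention {m.text!r} [{m.start},{m.end}) not inside "
                "exactly one sentence"
            )
        m.sentence_index = idx[0]


_PUNCT_EDGE = re.compile(r"^\W+|\W+$", re.UNICODE)


def normalize_tokens(text: str, offset: int = 0) -> list[tuple[str, int, int]]:
    """Whitespace-tokenize ``text``, lowercase, strip punctuation from token
    edges, and drop punctuation-only tokens.

    Returns (token, start, end) triples with offsets into the original string
    (shifted by ``offset``).  This is the tokenization contract a dependency
    parse is expected to match.
    """
    out = []
    for m in re.finditer(r"\S+", text):
        tok = _PUNCT_EDGE.sub("", m.group())
        if tok:
            out.append((tok.lower(), m.start() + offset, m.end() + offset))
    return out


# ---------------------------------------------------------------------------
# PubTator
# ---------------------------------------------------------------------------


def read_pubtator(path) -> list[Document]:
    """Parse a PubTator file into :class:`Document` objects.

    Blocks are separated by blank lines.  Each block carries a ``|t|`` and a
    ``|a|`` line, then tab-separated mention rows
    ``pmid<TAB>start<TAB>end<TAB>text<TAB>type<TAB>mesh``, then optional
    ``pmid<TAB>CID<TAB>chem<TAB>dis`` relation rows.
    """
    docs: list[Document] = []
    cur: Document | None = None

    def flush():
        nonlocal cur
        if cur is not None:
            assign_sentence_indices(cur)
            docs.append(cur)
            cur = None

    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip():
                flush()
                continue
            tparts = line.split("|", 2)
            if len(tparts) == 3 and tparts[1] in ("t", "a"):
                doc_id, kind, content = tparts
                if cur is None or cur.doc_id != doc_id:
                    flush()
                    cur = Document(doc_id=doc_id, title="", abstract="")
                if kind == "t":
                    cur.title = content
                else:
                    cur.abstract = content
                continue
            cols = line.split("\t")
            if cur is None:
                raise ParseError(f"line {lineno}: annotation before any |t| line")
            if len(cols) == 4 and cols[1] == "CID":
                cur.gold_cid.add((cols[2], cols[3]))
                continue
            if len(cols) < 6:
                raise ParseError(f"line {lineno}: malformed mention line: {line!r}")
            doc_id, start_s, end_s, mtext, etype, mesh_id = cols[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"line {lineno}: non-integer offsets") from exc
            if etype not in ENTITY_TYPES:
                raise ParseError(f"line {lineno}: unknown entity type {etype!r}")
            text = cur.text
            if not (0 <= start < end <= len(text)):
                raise ValidationError(
                    f"line {lineno}: offsets [{start},{end}) outside document text"
                )
            if text[start:end] != mtext:
                raise ValidationError(
                    f"line {lineno}: span text {text[start:end]!r} != {mtext!r}"
                )
            cur.mentions.append(
                Mention(doc_id, start, end, mtext, etype, mesh_id)
            )
        flush()
    return docs


def write_pubtator(docs: list[Document], path, predictions=None) -> None:
    """Write documents in PubTator format.

    ``predictions``, if given, replaces each document's gold ``CID`` lines
    with the predicted (doc_id, chem_id, dis_id) positives.
    """
    by_doc: dict[str, set[tuple[str, str]]] = {}
    if predictions is not None:
        known = {d.doc_id for d in docs}
        for doc_id, c, d in predictions:
            if doc_id not in known:
                raise ValidationError(f"prediction for unknown doc_id {doc_id}")
            by_doc.setdefault(doc_id, set()).add((c, d))
    with open(path, "w", encoding="utf-8") as fh:
        for doc in docs:
            fh.write(f"{doc.doc_id}|t|{doc.title}\n")
            fh.write(f"{doc.doc_id}|a|{doc.abstract}\n")
            for m in doc.mentions:
                fh.write(
                    f"{doc.doc_id}\t{m.start}\t{m.end}\t{m.text}\t{m.etype}\t{m.mesh_id}\n"
                )
            pairs = by_doc.get(doc.doc_id, set()) if predictions is not None else doc.gold_cid
            for c, d in sorted(pairs):
                fh.write(f"{doc.doc_id}\tCID\t{c}\t{d}\n")
            fh.write("\n")


def write_predictions(docs: list[Document], predictions, path) -> None:
    """Write documents with predicted CID lines, sorted by doc then IDs."""
    write_pubtator(sorted(docs, key=lambda d: d.doc_id), path, predictions=predictions)


def read_predictions(path) -> set[tuple[str, str, str]]:
    """Recover the (doc_id, chem_id, dis_id) set from a prediction file."""
    return {
        (d.doc_id, c, dis)
        for d in read_pubtator(path)
        for c, dis in d.gold_cid
    }


# ---------------------------------------------------------------------------
# dependency parses
# ---------------------------------------------------------------------------


def read_parses(path) -> dict[tuple[str, int], DependencyTree]:
    """Read CoNLL-style parse blocks.

    Each block starts with a header line ``#<doc_id>\\t<sentence_index>``
    followed by one token row per line: ``index<TAB>form<TAB>head<TAB>deprel``
    (0-based indices, head ``-1`` for the root).  Blocks are separated by
    blank lines.
    """
    trees: dict[tuple[str, int], DependencyTree] = {}
    key = None
    rows: list[tuple[int, str, int, str]] = []

    def flush():
        nonlocal key, rows
        if key is None:
            return
        rows.sort(key=lambda r: r[0])
        tree = DependencyTree(
            doc_id=key[0],
            sentence_index=key[1],
            tokens=[r[1] for r in rows],
            heads=[r[2] for r in rows],
            tags=[r[3] for r in rows],
        )
        tree.validate()
        trees[key] = tree
        key, rows = None, []

    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip():
                flush()
                continue
            if line.startswith("#"):
                flush()
                parts = line[1:].split("\t")
                if len(parts) != 2:
                    raise ParseError(f"line {lineno}: malformed block header")
                key = (parts[0], int(parts[1]))
                continue
            cols = line.split("\t")
            if len(cols) != 4 or key is None:
                raise ParseError(f"line {lineno}: malformed token row: {line!r}")
            rows.append((int(cols[0]), cols[1], int(cols[2]), cols[3]))
        flush()
    return trees


def write_parses(trees: dict[tuple[str, int], DependencyTree], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for (doc_id, sidx), tree in trees.items():
            fh.write(f"#{doc_id}\t{sidx}\n")
            for i, (tok, head, tag) in enumerate(
                zip(tree.tokens, tree.heads, tree.tags)
            ):
                fh.write(f"{i}\t{tok}\t{head}\t{tag}\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# CTD triples, MeSH hierarchy, word vectors
# ---------------------------------------------------------------------------


def read_ctd_triples(path) -> TripleFile:
    """Read a three-column TSV of (chemical, relation, disease) rows."""
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) != 3:
                raise ParseError(f"line {lineno}: expected 3 columns")
            rows.append((cols[0], cols[1], cols[2]))
    return TripleFile(rows)


def write_ctd_triples(tf: TripleFile, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for c, r, d in tf:
            fh.write(f"{c}\t{r}\t{d}\n")


def read_mesh_hierarchy(path) -> MeshHierarchy:
    """Read a TSV mapping MeSH ID to pipe-separated tree numbers."""
    trees: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) != 2 or not cols[1]:
                raise ParseError(f"line {lineno}: expected 'id<TAB>tree|tree'")
            numbers = {t for t in cols[1].split("|") if t}
            if not numbers:
                raise ValidationError(f"line {lineno}: empty tree numbers")
            trees.setdefault(cols[0], set()).update(numbers)
    return MeshHierarchy(trees)


def write_mesh_hierarchy(h: MeshHierarchy, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for mesh_id in sorted(h.trees):
            fh.write(f"{mesh_id}\t{'|'.join(sorted(h.trees[mesh_id]))}\n")


def read_word_vectors(path) -> dict[str, np.ndarray]:
    """Read word2vec text format: header ``count dim``, then one vector/line."""
    vectors: dict[str, np.ndarray] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ParseError("word2vec text file must start with 'count dim'")
        count, dim = int(header[0]), int(header[1])
        for lineno, raw in enumerate(fh, 2):
            parts = raw.rstrip("\n").split(" ")
            if not parts[0]:
                continue
            vec = np.array([float(x) for x in parts[1:] if x], dtype=np.float64)
            if vec.shape[0] != dim:
                raise ValidationError(
                    f"line {lineno}: vector of length {vec.shape[0]}, expected {dim}"
                )
            vectors[parts[0]] = vec
    if len(vectors) != count:
        logger.warning(
            "word2vec header declared %d vectors, read %d", count, len(vectors)
        )
    return vectors


def write_word_vectors(vectors: dict[str, np.ndarray], path) -> None:
    items = list(vectors.items())
    dim = len(next(iter(vectors.values()))) if vectors else 0
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(items)} {dim}\n")
        for tok, vec in items:
            fh.write(tok + " " + " ".join(f"{x:.8g}" for x in vec) + "\n")
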