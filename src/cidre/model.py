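"""The knowledge-guided convolutional classifier.

Two parallel convolutional branches read the same embedded shortest
dependency path X ∈ R^{d×n}.  Each branch gates its convolutional features
with one of the two focused entities:

    s_i = tanh(X_{i:i+h-1} * W_s + b_s)
    a_i = relu(X_{i:i+h-1} * W_a + V_a·e + b_a)        (tanh-ReLU gating)
    c_i = s_i × a_i

the chemical branch receiving e_c and the disease branch e_d.  Sigmoid-gated
(GTU) and linear (GLU) variants replace relu by a sigmoid and, for GLU, drop
the tanh on the feature path.  Feature maps from all window sizes stack into
M ∈ R^{l×n} (zero same-padding keeps every map at length n).

Pooling is attention against the pair's KB-relation vector r:

    g_i = tanh(W_g M[:,i] + b_g) · r,   α = softmax(g),   m = Σ α_i M[:,i]

with a scalar self-attention variant g_i = tanh(w_g^T M[:,i] + b_g) for
configurations that must not consult the KB.  The pooled branch features are
concatenated and classified by a relu hidden layer and a binary softmax;
training minimizes mean cross-entropy.

Everything is plain numpy with analytic gradients (verified against finite
differences in the test suite).  Entity and relation vectors are knowledge
inputs and receive no gradient; token embeddings (words, dependency tags,
direction symbols) are trainable parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .kb import EmbeddingSpace, lookup_guidance

UNK = "<unk>"

GATE_KINDS = ("GTRU", "GTU", "GLU")
ATTENTION_KINDS = ("relation", "self")
ENTITY_SOURCES = ("transe", "averaged-words")
SHARING_MODES = ("DGate-SAtt", "SGate-SAtt", "DGate-DAtt", "SGate-DAtt")


@dataclass
class KcnConfig:
    """Hyper-parameters of the two-branch gated convolutional network."""

    window_sizes: tuple[int, ...] = (1, 2, 3, 4, 5)
    filters_per_window: int = 100
    d: int = 100          # token embedding dimension
    k: int = 100          # entity/relation embedding dimension
    hidden: int = 100     # h0, width of the pre-softmax relu layer
    gate: str = "GTRU"
    attention: str = "relation"
    entity_source: str = "transe"
    sharing: str = "DGate-SAtt"
    seed: int = 0

    def __post_init__(self):
        if self.gate not in GATE_KINDS:
            raise ValueError(f"gate must be one of {GATE_KINDS}")
        if self.attention not in ATTENTION_KINDS:
            raise ValueError(f"attention must be one of {ATTENTION_KINDS}")
        if self.entity_source not in ENTITY_SOURCES:
            raise ValueError(f"entity_source must be one of {ENTITY_SOURCES}")
        if self.sharing not in SHARING_MODES:
            raise ValueError(f"sharing must be one of {SHARING_MODES}")
        if self.filters_per_window < 1 or self.hidden < 1:
            raise ValueError("filters_per_window and hidden must be positive")

    @property
    def l(self) -> int:  # noqa: E743 - the field's symbol for total filters
        return self.filters_per_window * len(self.window_sizes)

    @property
    def share_gate(self) -> bool:
        return self.sharing.startswith("SGate")

    @property
    def share_attention(self) -> bool:
        return self.sharing.endswith("SAtt")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(x: np.ndarray) -> np.ndarray:
    z = x - np.max(x)
    e = np.exp(z)
    return e / e.sum()


class Vocabulary:
    """Token index over SDP vocabulary: words, tags, direction symbols, UNK."""

    def __init__(self, tokens):
        uniq = sorted(set(tokens))
        self.tokens = [UNK] + uniq
        self.index = {t: i for i, t in enumerate(self.tokens)}

    def __len__(self):
        return len(self.tokens)

    def encode(self, sdp: list[str]) -> np.ndarray:
        return np.array([self.index.get(t, 0) for t in sdp], dtype=np.int64)

    @classmethod
    def from_instances(cls, instances) -> "Vocabulary":
        return cls(t for inst in instances for t in inst.sdp)


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in = int(np.prod(shape[1:])) or shape[0]
    fan_out = shape[0]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, shape)


class KcnParams:
    """Full parameter bundle, honoring the configured branch sharing.

    Convolution weights for window width h are stored flattened as
    ``(filters, h*d)``; segment ``j*d:(j+1)*d`` of a row holds the weights
    applied to the token at window offset j.
    """

    def __init__(self, config: KcnConfig, vocab: Vocabulary,
                 word_vectors: dict[str, np.ndarray] | None = None):
        self.config = config
        self.vocab = vocab
        rng = np.random.default_rng(config.seed)
        d, k, lh = config.d, config.k, config.filters_per_window
        l = config.l

        self.E = np.empty((len(vocab), d))
        for i, tok in enumerate(vocab.tokens):
            vec = (word_vectors or {}).get(tok)
            self.E[i] = vec if vec is not None else rng.uniform(-0.25, 0.25, d)

        def make_conv():
            return {
                h: {
                    "Ws": _glorot(rng, (lh, h * d)),
                    "bs": np.zeros(lh),
                    "Wa": _glorot(rng, (lh, h * d)),
                    "Va": rng.uniform(-0.25, 0.25, (lh, k)),
                    # gates start open (cf. forget-gate bias init in LSTMs):
                    # a zero-centered relu/sigmoid pre-activation would close
                    # half the gates and starve early gradients
                    "ba": np.ones(lh),
                }
                for h in config.window_sizes
            }

        def make_attn():
            if config.attention == "relation":
                return {"Wg": _glorot(rng, (k, l)), "bg": np.zeros(k)}
            return {"wg": _glorot(rng, (1, l))[0], "bg": np.zeros(1)}

        chem_conv = make_conv()
        self.conv = {
            "chem": chem_conv,
            "dis": chem_conv if config.share_gate else make_conv(),
        }
        chem_attn = make_attn()
        self.attn = {
            "chem": chem_attn,
            "dis": chem_attn if config.share_attention else make_attn(),
        }
        self.clf = {
            "Wh": _glorot(rng, (config.hidden, 2 * l)),
            "bh": np.zeros(config.hidden),
            "Wo": _glorot(rng, (2, config.hidden)),
            "bo": np.zeros(2),
        }

    def param_items(self) -> list[tuple[str, np.ndarray]]:
        """Unique (name, array) pairs; shared storage appears once."""
        items: list[tuple[str, np.ndarray]] = [("embed/E", self.E)]
        seen: set[int] = {id(self.E)}
        for branch in ("chem", "dis"):
            conv = self.conv[branch]
            if id(conv[self.config.window_sizes[0]]["Ws"]) in seen:
                continue
            for h, p in conv.items():
                for name, arr in p.items():
                    items.append((f"conv/{branch}/h{h}/{name}", arr))
                    seen.add(id(arr))
        for branch in ("chem", "dis"):
            ap = self.attn[branch]
            first = next(iter(ap.values()))
            if id(first) in seen:
                continue
            for name, arr in ap.items():
                items.append((f"attn/{branch}/{name}", arr))
                seen.add(id(arr))
        for name, arr in self.clf.items():
            items.append((f"clf/{name}", arr))
        return items

    def copy(self) -> "KcnParams":
        new = object.__new__(KcnParams)
        new.config = self.config
        new.vocab = self.vocab
        new.E = self.E.copy()

        def copy_conv(conv):
            return {h: {n: a.copy() for n, a in p.items()} for h, p in conv.items()}

        chem_conv = copy_conv(self.conv["chem"])
        new.conv = {
            "chem": chem_conv,
            "dis": chem_conv
            if self.conv["dis"] is self.conv["chem"]
            else copy_conv(self.conv["dis"]),
        }
        chem_attn = {n: a.copy() for n, a in self.attn["chem"].items()}
        new.attn = {
            "chem": chem_attn,
            "dis": chem_attn
            if self.attn["dis"] is self.attn["chem"]
            else {n: a.copy() for n, a in self.attn["dis"].items()},
        }
        new.clf = {n: a.copy() for n, a in self.clf.items()}
        return new

    def set_from(self, other: "KcnParams") -> None:
        for (_, a), (_, b) in zip(self.param_items(), other.param_items()):
            a[...] = b

    def save(self, path) -> None:
        arrays = {name.replace("/", "__"): arr for name, arr in self.param_items()}
        np.savez(path, **arrays)
        with open(str(path) + ".json", "w", encoding="utf-8") as fh:
            json.dump(
                {"config": asdict(self.config), "vocab": self.vocab.tokens},
                fh,
                ensure_ascii=False,
            )

    @classmethod
    def load(cls, path) -> "KcnParams":
        with open(str(path) + ".json", encoding="utf-8") as fh:
            meta = json.load(fh)
        cfg = KcnConfig(**{**meta["config"],
                           "window_sizes": tuple(meta["config"]["window_sizes"])})
        vocab = Vocabulary.__new__(Vocabulary)
        vocab.tokens = meta["vocab"]
        vocab.index = {t: i for i, t in enumerate(vocab.tokens)}
        params = cls(cfg, vocab)
        data = np.load(path)
        for name, arr in params.param_items():
            arr[...] = data[name.replace("/", "__")]
        return params


# ---------------------------------------------------------------------------
# forward operations
# ---------------------------------------------------------------------------


def embed_sequence(sdp: list[str], params: KcnParams) -> np.ndarray:
    """Token embedding matrix X ∈ R^{d×n}; OOV words map to the UNK vector."""
    if not sdp:
        raise ValueError("empty SDP sequence")
    idx = params.vocab.encode(sdp)
    return params.E[idx].T, idx


def _pad_patches(X: np.ndarray, h: int) -> tuple[np.ndarray, int]:
    """Same-padded sliding-window patch matrix: (h*d, n)."""
    d, n = X.shape
    pl = (h - 1) // 2
    Xp = np.zeros((d, n + h - 1))
    Xp[:, pl : pl + n] = X
    P = np.vstack([Xp[:, j : j + n] for j in range(h)])
    return P, pl


def gated_conv(
    X: np.ndarray,
    e: np.ndarray,
    branch_params: dict,
    gate_kind: str,
    window_sizes: tuple[int, ...],
):
    """Entity-gated convolutional feature map M ∈ R^{l×n} plus caches."""
    if X.shape[1] < 1:
        raise ValueError("input sequence must have at least one token")
    maps, caches = [], []
    for h in window_sizes:
        p = branch_params[h]
        P, pl = _pad_patches(X, h)
        zs = p["Ws"] @ P + p["bs"][:, None]
        s = zs if gate_kind == "GLU" else np.tanh(zs)
        za = p["Wa"] @ P + (p["Va"] @ e + p["ba"])[:, None]
        a = np.maximum(za, 0.0) if gate_kind == "GTRU" else _sigmoid(za)
        maps.append(s * a)
        caches.append({"P": P, "pl": pl, "s": s, "za": za, "a": a})
    return np.vstack(maps), caches


def attention_pool(M: np.ndarray, r: np.ndarray, attn_params: dict):
    """Relation-guided attention pooling: m = Σ α_i M[:,i]."""
    if M.shape[1] < 1:
        raise ValueError("feature map must have at least one column")
    Zg = attn_params["Wg"] @ M + attn_params["bg"][:, None]
    G = np.tanh(Zg)
    g = r @ G
    if not np.all(np.isfinite(g)):
        raise FloatingPointError("non-finite attention scores")
    alpha = softmax(g)
    m = M @ alpha
    return m, alpha, {"G": G}


def self_attention_pool(M: np.ndarray, attn_params: dict):
    """Scalar self-attention pooling (no relation vector)."""
    if M.shape[1] < 1:
        raise ValueError("feature map must have at least one column")
    zg = attn_params["wg"] @ M + attn_params["bg"][0]
    g = np.tanh(zg)
    if not np.all(np.isfinite(g)):
        raise FloatingPointError("non-finite attention scores")
    alpha = softmax(g)
    m = M @ alpha
    return m, alpha, {"g": g}


def classify(m_c: np.ndarray, m_d: np.ndarray, clf_params: dict):
    """Relu hidden layer and binary softmax over concatenated features."""
    m = np.concatenate([m_c, m_d])
    if clf_params["Wh"].shape[1] != m.shape[0]:
        raise ValueError("classifier/feature shape mismatch")
    zh = clf_params["Wh"] @ m + clf_params["bh"]
    o = np.maximum(zh, 0.0)
    p = softmax(clf_params["Wo"] @ o + clf_params["bo"])
    return p, {"m": m, "zh": zh, "o": o}


def guidance_vectors(instance, space: EmbeddingSpace, config: KcnConfig):
    """Entity and relation guidance per the configured variant.

    The averaged-words entity source and the self-attention pooling never
    read trained KB vectors (auditable through the space's lookup counters).
    """
    if config.entity_source == "transe":
        e_c, e_d, r = lookup_guidance(instance, space)
        if config.attention == "self":
            r = None
    else:
        e_c = space.average_entity_vector(instance.chemical.mesh_id)
        e_d = space.average_entity_vector(instance.disease.mesh_id)
        r = (
            space.relation(instance.kb_relation)
            if config.attention == "relation"
            else None
        )
    return e_c, e_d, r


def forward(instance, space: EmbeddingSpace, params: KcnParams,
            config: KcnConfig | None = None, cache: bool = False):
    """Full forward pass: probability pair plus per-branch diagnostics.

    Diagnostics carry the attention weights and the per-token mean gate
    activation of each branch (the quantities one would inspect as heat
    maps over the SDP tokens).
    """
    config = config or params.config
    X, idx = embed_sequence(instance.sdp, params)
    e_c, e_d, r = guidance_vectors(instance, space, config)

    branch_out = {}
    for branch, e in (("chem", e_c), ("dis", e_d)):
        M, conv_cache = gated_conv(
            X, e, params.conv[branch], config.gate, config.window_sizes
        )
        if config.attention == "relation":
            m, alpha, att_cache = attention_pool(M, r, params.attn[branch])
        else:
            m, alpha, att_cache = self_attention_pool(M, params.attn[branch])
        branch_out[branch] = {
            "e": e, "M": M, "m": m, "alpha": alpha,
            "conv_cache": conv_cache, "att_cache": att_cache,
        }

    p, clf_cache = classify(branch_out["chem"]["m"], branch_out["dis"]["m"],
                            params.clf)
    diagnostics = {
        "alpha_c": branch_out["chem"]["alpha"],
        "alpha_d": branch_out["dis"]["alpha"],
        "gate_mean_c": _mean_gate(branch_out["chem"]["conv_cache"]),
        "gate_mean_d": _mean_gate(branch_out["dis"]["conv_cache"]),
        "tokens": list(instance.sdp),
    }
    if cache:
        return p, diagnostics, {
            "X": X, "idx": idx, "r": r, "branches": branch_out, "clf": clf_cache,
        }
    return p, diagnostics


def _mean_gate(conv_caches) -> np.ndarray:
    return np.mean(np.vstack([c["a"] for c in conv_caches]), axis=0)


# ---------------------------------------------------------------------------
# loss and gradients
# ---------------------------------------------------------------------------


def batch_loss(instances, space, params, config: KcnConfig | None = None) -> float:
    """Mean cross-entropy −(1/N) Σ log p(y|instance)."""
    if not instances:
        raise ValueError("empty instance batch")
    config = config or params.config
    total = 0.0
    for inst in instances:
        p, _ = forward(inst, space, params, config)
        total -= np.log(max(p[inst.label], 1e-300))
    return total / len(instances)


def batch_loss_and_grads(instances, space, params,
                         config: KcnConfig | None = None):
    """Mean cross-entropy and its gradient for every trainable array.

    Returns ``(loss, grads)`` where ``grads`` maps ``id(array) -> gradient``
    for each unique array of ``params.param_items()``; shared branch storage
    accumulates contributions from both branches.
    """
    if not instances:
        raise ValueError("empty instance batch")
    config = config or params.config
    grads: dict[int, np.ndarray] = {
        id(arr): np.zeros_like(arr) for _, arr in params.param_items()
    }

    def add(arr, g):
        key = id(arr)
        if key in grads:
            grads[key] += g

    total = 0.0
    N = len(instances)
    for inst in instances:
        p, _, cache = forward(inst, space, params, config, cache=True)
        total -= np.log(max(p[inst.label], 1e-300))

        dlogits = p.copy()
        dlogits[inst.label] -= 1.0
        dlogits /= N

        clf = params.clf
        cc = cache["clf"]
        add(clf["Wo"], np.outer(dlogits, cc["o"]))
        add(clf["bo"], dlogits)
        do = clf["Wo"].T @ dlogits
        dzh = do * (cc["zh"] > 0)
        add(clf["Wh"], np.outer(dzh, cc["m"]))
        add(clf["bh"], dzh)
        dm = clf["Wh"].T @ dzh
        l = params.config.l
        dm_branch = {"chem": dm[:l], "dis": dm[l:]}

        X = cache["X"]
        dX = np.zeros_like(X)
        for branch in ("chem", "dis"):
            bo = cache["branches"][branch]
            M, alpha = bo["M"], bo["alpha"]
            dm_b = dm_branch[branch]
            ap = params.attn[branch]
            dM = np.outer(dm_b, alpha)
            dalpha = M.T @ dm_b
            dg = alpha * (dalpha - float(alpha @ dalpha))
            if config.attention == "relation":
                G = bo["att_cache"]["G"]
                dG = np.outer(cache["r"], dg)
                dZg = dG * (1.0 - G ** 2)
                add(ap["Wg"], dZg @ M.T)
                add(ap["bg"], dZg.sum(axis=1))
                dM += ap["Wg"].T @ dZg
            else:
                g = bo["att_cache"]["g"]
                dzg = dg * (1.0 - g ** 2)
                add(ap["wg"], M @ dzg)
                add(ap["bg"], np.array([dzg.sum()]))
                dM += np.outer(ap["wg"], dzg)

            dX += _gated_conv_backward(
                dM, X, bo["e"], params.conv[branch], config.gate,
                config.window_sizes, bo["conv_cache"], add,
            )

        dE_local = dX.T  # (n, d) rows per token occurrence
        np.add.at(grads[id(params.E)], cache["idx"], dE_local)

    return total / N, grads


def _gated_conv_backward(dM, X, e, branch_params, gate_kind, window_sizes,
                         caches, add):
    d, n = X.shape
    dX = np.zeros_like(X)
    row = 0
    for h, c in zip(window_sizes, caches):
        p = branch_params[h]
        lh = p["Ws"].shape[0]
        dc = dM[row : row + lh]
        row += lh
        s, a, za, P, pl = c["s"], c["a"], c["za"], c["P"], c["pl"]
        ds = dc * a
        da = dc * s
        dzs = ds if gate_kind == "GLU" else ds * (1.0 - s ** 2)
        if gate_kind == "GTRU":
            dza = da * (za > 0)
        else:
            dza = da * a * (1.0 - a)
        add(p["Ws"], dzs @ P.T)
        add(p["bs"], dzs.sum(axis=1))
        add(p["Wa"], dza @ P.T)
        rowsum = dza.sum(axis=1)
        add(p["Va"], np.outer(rowsum, e))
        add(p["ba"], rowsum)
        dP = p["Ws"].T @ dzs + p["Wa"].T @ dza
        dXp = np.zeros((d, n + h - 1))
        for j in range(h):
            dXp[:, j : j + n] += dP[j * d : (j + 1) * d]
        dX += dXp[:, pl : pl + n]
    return dX


def export_diagnostics(instances, space, params, path,
                       config: KcnConfig | None = None) -> None:
    """Per-token attention/gate diagnostics as TSV, one block per instance."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("doc_id\tchemical\tdisease\ttoken\talpha_c\talpha_d\tgate_c\tgate_d\n")
        for inst in instances:
            _, diag = forward(inst, space, params, config)
            for i, tok in enumerate(diag["tokens"]):
                fh.write(
                    f"{inst.doc_id}\t{inst.chemical.mesh_id}\t{inst.disease.mesh_id}"
                    f"\t{tok}\t{diag['alpha_c'][i]:.6f}\t{diag['alpha_d'][i]:.6f}"
                    f"\t{diag['gate_mean_c'][i]:.6f}\t{diag['gate_mean_d'][i]:.6f}\n"
                )
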