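"""The gated convolutional classifier: forward oracle, gradients, invariants.

The reference oracle here is a deliberately naive scalar re-implementation
of the whole forward pass (explicit loops, one multiply at a time), kept
independent of the vectorized implementation it checks.
"""

import math

import numpy as np
import pytest

from cidre.model import (
    KcnConfig,
    KcnParams,
    Vocabulary,
    attention_pool,
    batch_loss,
    batch_loss_and_grads,
    classify,
    embed_sequence,
    forward,
    gated_conv,
    self_attention_pool,
)
from conftest import make_instance, tiny_space


def make_params(cfg, tokens=("a", "b", "c"), seed=None):
    vocab = Vocabulary(tokens)
    if seed is not None:
        cfg = KcnConfig(**{**cfg.__dict__, "seed": seed})
    return KcnParams(cfg, vocab)


# ---------------------------------------------------------------------------
# straight-line scalar oracle
# ---------------------------------------------------------------------------


def oracle_forward(sdp_tokens, params, e_c, e_d, r, cfg):
    """Scalar re-implementation of embedding -> gates -> pooling -> softmax."""

    def token_vec(t):
        i = params.vocab.index.get(t, 0)
        return [float(x) for x in params.E[i]]

    X = [token_vec(t) for t in sdp_tokens]  # n rows of d floats
    n, d = len(X), cfg.d

    def conv_map(branch, e):
        rows = []
        for h in cfg.window_sizes:
            p = params.conv[branch][h]
            pl = (h - 1) // 2
            for f in range(cfg.filters_per_window):
                ws = p["Ws"][f]
                wa = p["Wa"][f]
                va = sum(float(p["Va"][f][j]) * float(e[j]) for j in range(cfg.k))
                for_row = []
                for i in range(n):
                    zs = float(p["bs"][f])
                    za = va + float(p["ba"][f])
                    for j in range(h):
                        src = i - pl + j
                        if 0 <= src < n:
                            for dd in range(d):
                                zs += float(ws[j * d + dd]) * X[src][dd]
                                za += float(wa[j * d + dd]) * X[src][dd]
                    if cfg.gate == "GLU":
                        s = zs
                    else:
                        s = math.tanh(zs)
                    if cfg.gate == "GTRU":
                        a = max(za, 0.0)
                    else:
                        a = 1.0 / (1.0 + math.exp(-za))
                    for_row.append(s * a)
                rows.append(for_row)
        return rows  # l rows of n floats

    def pool(M, branch):
        ap = params.attn[branch]
        g = []
        for i in range(n):
            if cfg.attention == "relation":
                gi = 0.0
                for kk in range(cfg.k):
                    z = float(ap["bg"][kk])
                    for j in range(cfg.l):
                        z += float(ap["Wg"][kk][j]) * M[j][i]
                    gi += math.tanh(z) * float(r[kk])
            else:
                z = float(ap["bg"][0])
                for j in range(cfg.l):
                    z += float(ap["wg"][j]) * M[j][i]
                gi = math.tanh(z)
            g.append(gi)
        mx = max(g)
        ex = [math.exp(x - mx) for x in g]
        tot = sum(ex)
        alpha = [x / tot for x in ex]
        return [sum(alpha[i] * M[j][i] for i in range(n)) for j in range(cfg.l)]

    mc = pool(conv_map("chem", e_c), "chem")
    md = pool(conv_map("dis", e_d), "dis")
    m = mc + md
    clf = params.clf
    o = []
    for i in range(cfg.hidden):
        z = float(clf["bh"][i])
        for j in range(2 * cfg.l):
            z += float(clf["Wh"][i][j]) * m[j]
        o.append(max(z, 0.0))
    logits = []
    for i in range(2):
        z = float(clf["bo"][i])
        for j in range(cfg.hidden):
            z += float(clf["Wo"][i][j]) * o[j]
        logits.append(z)
    mx = max(logits)
    ex = [math.exp(x - mx) for x in logits]
    return [x / sum(ex) for x in ex]


class TestForwardOracle:
    @pytest.mark.parametrize("gate", ["GTRU", "GTU", "GLU"])
    @pytest.mark.parametrize("attention", ["relation", "self"])
    def test_forward_matches_scalar_oracle(self, gate, attention):
        rng = np.random.default_rng(hash((gate, attention)) % 2**31)
        space = tiny_space()
        for trial in range(8):
            cfg = KcnConfig(
                window_sizes=tuple(range(1, int(rng.integers(2, 4)) + 1)),
                filters_per_window=int(rng.integers(1, 3)),
                d=4, k=4, hidden=int(rng.integers(2, 5)),
                gate=gate, attention=attention, seed=int(rng.integers(1000)),
            )
            n = int(rng.integers(1, 7))
            sdp = [["a", "b", "c", "zz"][int(j)]
                   for j in rng.integers(0, 4, size=n)]
            inst = make_instance(sdp, kb_relation="null")
            params = make_params(cfg, seed=cfg.seed)
            p, _ = forward(inst, space, params, cfg)
            e_c = space.average_entity_vector("MESH:C000")
            e_d = space.average_entity_vector("MESH:D000")
            r = space.relations["null"]
            # the implementation reads trained entity vectors; mirror it
            e_c = space.entities["MESH:C000"]
            e_d = space.entities["MESH:D000"]
            expected = oracle_forward(sdp, params, e_c, e_d, r, cfg)
            np.testing.assert_allclose(p, expected, atol=1e-8)


class TestEmbedding:
    def test_column_count(self, tiny_cfg):
        params = make_params(tiny_cfg)
        X, _ = embed_sequence(["a", "b", "a"], params)
        assert X.shape == (4, 3)

    def test_same_token_identical_columns(self, tiny_cfg):
        params = make_params(tiny_cfg)
        X, _ = embed_sequence(["a", "a"], params)
        np.testing.assert_array_equal(X[:, 0], X[:, 1])

    def test_oov_maps_to_unk(self, tiny_cfg):
        params = make_params(tiny_cfg)
        X, idx = embed_sequence(["never-seen"], params)
        assert idx[0] == 0
        np.testing.assert_array_equal(X[:, 0], params.E[0])

    def test_empty_rejected(self, tiny_cfg):
        with pytest.raises(ValueError):
            embed_sequence([], make_params(tiny_cfg))


class TestGatedConv:
    def test_closed_gate_zero_map(self):
        cfg = KcnConfig(window_sizes=(1,), filters_per_window=1, d=2, k=2,
                        hidden=2, gate="GTRU", seed=0)
        params = make_params(cfg)
        h1 = params.conv["chem"][1]
        h1["Wa"][...] = 0.0
        h1["Va"][...] = 0.0
        h1["ba"][...] = -1.0
        X = np.ones((2, 3))
        M, _ = gated_conv(X, np.zeros(2), params.conv["chem"], "GTRU", (1,))
        np.testing.assert_array_equal(M, np.zeros((1, 3)))

    def test_gtu_gate_strictly_in_unit_interval(self, tiny_cfg):
        cfg = KcnConfig(**{**tiny_cfg.__dict__, "gate": "GTU"})
        params = make_params(cfg)
        rng = np.random.default_rng(0)
        X = rng.normal(size=(cfg.d, 5))
        _, caches = gated_conv(X, rng.normal(size=cfg.k),
                               params.conv["chem"], "GTU", cfg.window_sizes)
        for c in caches:
            assert np.all(c["a"] > 0) and np.all(c["a"] < 1)

    def test_gtru_nonnegative_and_unbounded_witness(self, tiny_cfg):
        params = make_params(tiny_cfg)
        rng = np.random.default_rng(1)
        X = 5.0 * rng.normal(size=(tiny_cfg.d, 8))
        _, caches = gated_conv(X, 5.0 * rng.normal(size=tiny_cfg.k),
                               params.conv["chem"], "GTRU",
                               tiny_cfg.window_sizes)
        gates = np.concatenate([c["a"].ravel() for c in caches])
        assert np.all(gates >= 0)
        assert np.any(gates > 1), "relu gates should exceed 1 for some input"

    def test_scalar_example(self):
        # h=1, l=1, d=2: s=tanh(0.5), a=relu(1.5), c = tanh(0.5)*1.5
        cfg = KcnConfig(window_sizes=(1,), filters_per_window=1, d=2, k=2,
                        hidden=2, seed=0)
        params = make_params(cfg)
        p1 = params.conv["chem"][1]
        p1["Ws"][...] = np.array([[1.0, 0.0]])
        p1["Wa"][...] = np.array([[0.0, 1.0]])
        p1["bs"][...] = 0.0
        p1["ba"][...] = 0.0
        p1["Va"][...] = np.array([[0.5, 0.0]])
        X = np.array([[0.5], [1.0]])
        e = np.array([1.0, 0.0])  # Va.e = 0.5
        M, _ = gated_conv(X, e, params.conv["chem"], "GTRU", (1,))
        assert M[0, 0] == pytest.approx(math.tanh(0.5) * 1.5)


class TestAttentionPooling:
    def test_single_column_degenerate(self, tiny_cfg):
        params = make_params(tiny_cfg)
        M = np.arange(float(tiny_cfg.l)).reshape(-1, 1)
        r = np.ones(tiny_cfg.k)
        m, alpha, _ = attention_pool(M, r, params.attn["chem"])
        np.testing.assert_allclose(alpha, [1.0])
        np.testing.assert_allclose(m, M[:, 0])

    def test_zero_relation_uniform(self, tiny_cfg):
        params = make_params(tiny_cfg)
        rng = np.random.default_rng(0)
        M = rng.normal(size=(tiny_cfg.l, 4))
        _, alpha, _ = attention_pool(M, np.zeros(tiny_cfg.k),
                                     params.attn["chem"])
        np.testing.assert_allclose(alpha, 0.25)

    def test_self_attention_zero_params_uniform(self):
        cfg = KcnConfig(window_sizes=(1, 2), filters_per_window=2, d=3, k=3,
                        hidden=2, attention="self", seed=0)
        params = make_params(cfg)
        params.attn["chem"]["wg"][...] = 0.0
        params.attn["chem"]["bg"][...] = 0.0
        M = np.random.default_rng(1).normal(size=(cfg.l, 5))
        _, alpha, _ = self_attention_pool(M, params.attn["chem"])
        np.testing.assert_allclose(alpha, 0.2)

    def test_weights_normalized_and_nonnegative(self, tiny_cfg, fitted_space,
                                                small_instances):
        params = KcnParams(tiny_cfg,
                           Vocabulary.from_instances(small_instances))
        cfg16 = KcnConfig(**{**tiny_cfg.__dict__, "d": 16, "k": 16})
        params = KcnParams(cfg16, Vocabulary.from_instances(small_instances))
        for inst in small_instances[:40]:
            _, diag = forward(inst, fitted_space, params, cfg16)
            for alpha in (diag["alpha_c"], diag["alpha_d"]):
                assert np.all(alpha >= 0)
                assert np.sum(alpha) == pytest.approx(1.0, abs=1e-6)
                assert len(alpha) == len(inst.sdp)


class TestClassify:
    def test_zero_output_weights_give_uniform(self, tiny_cfg):
        params = make_params(tiny_cfg)
        params.clf["Wo"][...] = 0.0
        params.clf["bo"][...] = 0.0
        rng = np.random.default_rng(0)
        p, _ = classify(rng.normal(size=tiny_cfg.l),
                        rng.normal(size=tiny_cfg.l), params.clf)
        np.testing.assert_allclose(p, [0.5, 0.5])

    def test_probabilities_sum_to_one(self, tiny_cfg):
        params = make_params(tiny_cfg)
        rng = np.random.default_rng(1)
        for _ in range(10):
            p, _ = classify(rng.normal(size=tiny_cfg.l),
                            rng.normal(size=tiny_cfg.l), params.clf)
            assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_toy_softmax(self):
        cfg = KcnConfig(window_sizes=(1,), filters_per_window=1, d=2, k=2,
                        hidden=2, seed=0)
        params = make_params(cfg)
        params.clf["Wh"][...] = np.eye(2)
        params.clf["bh"][...] = 0.0
        params.clf["Wo"][...] = np.array([[1.0, 0.0], [0.0, 1.0]])
        params.clf["bo"][...] = 0.0
        p, _ = classify(np.array([1.0]), np.array([2.0]), params.clf)
        expected = np.exp([1.0, 2.0]) / np.exp([1.0, 2.0]).sum()
        np.testing.assert_allclose(p, expected)

    def test_shape_mismatch_rejected(self, tiny_cfg):
        params = make_params(tiny_cfg)
        with pytest.raises(ValueError):
            classify(np.zeros(1), np.zeros(1), params.clf)


class TestForward:
    FIG_SDP = ["atp", "↑", "pmod", "↑", "by", "↑", "vmod", "↑", "induced",
               "↑", "nmod", "↑", "hypotension"]

    def test_published_positive_instance_runs(self, tiny_cfg):
        """The published positive example runs end-to-end: a probability
        pair plus one attention weight per SDP token and branch."""
        space = tiny_space(tokens=tuple(self.FIG_SDP))
        inst = make_instance(self.FIG_SDP, kb_relation="marker/mechanism")
        params = KcnParams(tiny_cfg, Vocabulary(self.FIG_SDP))
        p, diag = forward(inst, space, params, tiny_cfg)
        assert p.shape == (2,) and p.sum() == pytest.approx(1.0)
        assert len(diag["alpha_c"]) == len(self.FIG_SDP)
        assert len(diag["alpha_d"]) == len(self.FIG_SDP)
        assert len(diag["gate_mean_c"]) == len(self.FIG_SDP)

    def test_ae_sa_reads_no_trained_knowledge(self, tiny_cfg):
        cfg = KcnConfig(**{**tiny_cfg.__dict__,
                           "entity_source": "averaged-words",
                           "attention": "self"})
        space = tiny_space()
        space.reset_counters()
        inst = make_instance(["a", "b"], kb_relation="marker/mechanism")
        params = make_params(cfg)
        forward(inst, space, params, cfg)
        assert space.entity_lookups == 0
        assert space.relation_lookups == 0

    def test_kcn_reads_trained_knowledge(self, tiny_cfg):
        space = tiny_space()
        space.reset_counters()
        inst = make_instance(["a"], kb_relation="null")
        params = make_params(tiny_cfg)
        forward(inst, space, params, tiny_cfg)
        assert space.entity_lookups == 2
        assert space.relation_lookups == 1

    def test_filter_permutation_invariance(self, tiny_cfg):
        """Permuting filters (with their attention/classifier columns)
        leaves the output probabilities unchanged."""
        space = tiny_space()
        inst = make_instance(["a", "b", "c"], kb_relation="null")
        params = make_params(tiny_cfg)
        p0, _ = forward(inst, space, params, tiny_cfg)

        lh = tiny_cfg.filters_per_window
        perm_local = np.random.default_rng(0).permutation(lh)
        perm_full = np.concatenate([
            w * lh + perm_local for w in range(len(tiny_cfg.window_sizes))
        ])
        for branch in ("chem",):  # shared gate storage would double-permute
            for h in tiny_cfg.window_sizes:
                for name in ("Ws", "bs", "Wa", "Va", "ba"):
                    arr = params.conv[branch][h][name]
                    arr[...] = arr[perm_local]
            params.attn[branch]["Wg"][...] = params.attn[branch]["Wg"][:, perm_full]
        # disease branch untouched (DGate); but attention is shared (SAtt),
        # so permute the disease conv too to stay consistent
        for h in tiny_cfg.window_sizes:
            for name in ("Ws", "bs", "Wa", "Va", "ba"):
                arr = params.conv["dis"][h][name]
                arr[...] = arr[perm_local]
        W = params.clf["Wh"]
        l = tiny_cfg.l
        W[:, :l] = W[:, :l][:, perm_full]
        W[:, l:] = W[:, l:][:, perm_full]
        p1, _ = forward(inst, space, params, tiny_cfg)
        np.testing.assert_allclose(p0, p1, atol=1e-10)


class TestSharingContracts:
    @pytest.mark.parametrize("sharing,gate_shared,attn_shared", [
        ("DGate-SAtt", False, True),
        ("SGate-SAtt", True, True),
        ("DGate-DAtt", False, False),
        ("SGate-DAtt", True, False),
    ])
    def test_storage_identity(self, tiny_cfg, sharing, gate_shared, attn_shared):
        cfg = KcnConfig(**{**tiny_cfg.__dict__, "sharing": sharing})
        params = make_params(cfg)
        conv_same = params.conv["chem"][1]["Ws"] is params.conv["dis"][1]["Ws"]
        first = next(iter(params.attn["chem"]))
        attn_same = params.attn["chem"][first] is params.attn["dis"][first]
        assert conv_same == gate_shared
        assert attn_same == attn_shared
        # mutation visibility across branches iff shared
        params.conv["chem"][1]["Ws"][0, 0] = 123.0
        assert (params.conv["dis"][1]["Ws"][0, 0] == 123.0) == gate_shared

    def test_copy_preserves_sharing(self, tiny_cfg):
        cfg = KcnConfig(**{**tiny_cfg.__dict__, "sharing": "SGate-SAtt"})
        params = make_params(cfg).copy()
        assert params.conv["chem"][1]["Ws"] is params.conv["dis"][1]["Ws"]
        cfg2 = KcnConfig(**{**tiny_cfg.__dict__, "sharing": "DGate-DAtt"})
        params2 = make_params(cfg2).copy()
        assert params2.conv["chem"][1]["Ws"] is not params2.conv["dis"][1]["Ws"]


class TestLossAndGradients:
    def test_uniform_predictor_loss_is_ln2(self, tiny_cfg):
        space = tiny_space()
        params = make_params(tiny_cfg)
        params.clf["Wo"][...] = 0.0
        params.clf["bo"][...] = 0.0
        batch = [make_instance(["a", "b"], label=i % 2, kb_relation="null")
                 for i in range(4)]
        assert batch_loss(batch, space, params, tiny_cfg) == pytest.approx(
            math.log(2), abs=1e-9
        )

    def test_hand_set_probabilities(self, tiny_cfg):
        # force logits so p(correct) is known, batch of 3
        space = tiny_space()
        params = make_params(tiny_cfg)
        params.clf["Wh"][...] = 0.0
        params.clf["bh"][...] = 0.0
        params.clf["Wo"][...] = 0.0
        params.clf["bo"][...] = np.array([2.0, 0.0])
        p0 = math.exp(2) / (math.exp(2) + 1)
        batch = [make_instance(["a"], label=0, kb_relation="null"),
                 make_instance(["b"], label=0, kb_relation="null"),
                 make_instance(["c"], label=1, kb_relation="null")]
        expected = -(2 * math.log(p0) + math.log(1 - p0)) / 3
        assert batch_loss(batch, space, params, tiny_cfg) == pytest.approx(
            expected, abs=1e-9
        )

    def test_empty_batch_rejected(self, tiny_cfg):
        with pytest.raises(ValueError):
            batch_loss([], tiny_space(), make_params(tiny_cfg), tiny_cfg)

    @pytest.mark.parametrize("gate", ["GTRU", "GTU", "GLU"])
    @pytest.mark.parametrize("attention", ["relation", "self"])
    def test_finite_difference_gradients(self, gate, attention):
        """Analytic gradients of the cross-entropy match central finite
        differences for every parameter group."""
        cfg = KcnConfig(window_sizes=(1, 2), filters_per_window=2, d=3, k=3,
                        hidden=4, gate=gate, attention=attention, seed=5)
        space = tiny_space(k=3)
        batch = [
            make_instance(["a", "b", "c"], label=1, kb_relation="null"),
            make_instance(["b", "a"], label=0,
                          kb_relation="marker/mechanism"),
        ]
        params = make_params(cfg, seed=5)
        loss, grads = batch_loss_and_grads(batch, space, params, cfg)
        eps = 1e-6
        rng = np.random.default_rng(0)
        for name, arr in params.param_items():
            flat = arr.reshape(-1)
            g = grads[id(arr)].reshape(-1)
            idx = rng.choice(flat.size, size=min(4, flat.size), replace=False)
            for j in idx:
                old = flat[j]
                flat[j] = old + eps
                lp = batch_loss(batch, space, params, cfg)
                flat[j] = old - eps
                lm = batch_loss(batch, space, params, cfg)
                flat[j] = old
                fd = (lp - lm) / (2 * eps)
                # relative 1e-4 with an absolute floor below the FD noise
                tol = 1e-4 * max(abs(fd), abs(g[j])) + 1e-9
                assert abs(fd - g[j]) < tol, (name, j, fd, g[j])

    def test_shared_params_accumulate_both_branches(self):
        """Under shared gates the gradient of the shared array equals the
        sum of the two branch gradients computed separately."""
        base = dict(window_sizes=(1, 2), filters_per_window=2, d=3, k=3,
                    hidden=4, seed=9)
        space = tiny_space(k=3)
        batch = [make_instance(["a", "c"], label=1, kb_relation="null")]
        shared = KcnConfig(**base, sharing="SGate-SAtt")
        params_s = make_params(shared, seed=9)
        _, grads_s = batch_loss_and_grads(batch, space, params_s, shared)

        unshared = KcnConfig(**base, sharing="DGate-SAtt")
        params_u = make_params(unshared, seed=9)
        # make both branches hold the shared initial values
        for h in unshared.window_sizes:
            for nm in ("Ws", "bs", "Wa", "Va", "ba"):
                params_u.conv["chem"][h][nm][...] = params_s.conv["chem"][h][nm]
                params_u.conv["dis"][h][nm][...] = params_s.conv["chem"][h][nm]
        for nm in params_s.attn["chem"]:
            params_u.attn["chem"][nm][...] = params_s.attn["chem"][nm]
        for nm in params_s.clf:
            params_u.clf[nm][...] = params_s.clf[nm]
        params_u.E[...] = params_s.E
        _, grads_u = batch_loss_and_grads(batch, space, params_u, unshared)
        for h in unshared.window_sizes:
            for nm in ("Ws", "bs", "Wa", "Va", "ba"):
                combined = (grads_u[id(params_u.conv["chem"][h][nm])]
                            + grads_u[id(params_u.conv["dis"][h][nm])])
                np.testing.assert_allclose(
                    grads_s[id(params_s.conv["chem"][h][nm])], combined,
                    atol=1e-12,
                )
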