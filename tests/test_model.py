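"""Fusion network: LSTM gate oracle, attention, training, determinism."""

import dataclasses
import math

import numpy as np
import pytest

from tcmspred.model import (ModelConfig, FusionNetwork, TrainedModel, bce_loss,
                            cross_attend, encode_targets, forward, load_model,
                            predict, save_model, train)
from tcmspred.network import PairFeatures

TINY = ModelConfig(gene_dim=3, hidden=2, proc_hidden=(4,), cls_hidden=(3,),
                   dropout=0.0, batch_size=4, max_epochs=3, patience=2, seed=0)


def make_features(herb="H1", symptom="S1", n_genes=6, L=4, valid_h=2,
                  valid_s=3, sem_dim=5, seed=0, digest="t") -> PairFeatures:
    rng = np.random.default_rng(seed)
    h_seq = np.full(L, -1)
    h_seq[:valid_h] = rng.integers(0, n_genes, valid_h)
    s_seq = np.full(L, -1)
    s_seq[:valid_s] = rng.integers(0, n_genes, valid_s)
    h_mask = np.arange(L) < valid_h
    s_mask = np.arange(L) < valid_s
    return PairFeatures(
        herb=herb, symptom=symptom,
        semantic_herb=rng.normal(size=sem_dim),
        semantic_symptom=rng.normal(size=sem_dim),
        proximity=tuple(rng.normal(size=4)),
        herb_token_seq=h_seq, herb_mask=h_mask,
        symptom_token_seq=s_seq, symptom_mask=s_mask,
        config_digest=digest)


def make_dataset(n=24, seed=3):
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        label = i % 2
        f = make_features(herb=f"H{i}", symptom=f"S{i}", seed=100 + i)
        # plant a separable signal in the proximity scalars
        f.proximity = tuple(np.array(f.proximity) + (3.0 if label else -3.0))
        out.append((f, label))
    return out


def scalar_lstm_oracle(x_seq, W, U, b, h0, c0):
    """Independent gate-by-gate LSTM using explicit loops."""
    H = h0.shape[0]
    h, c = h0.copy(), c0.copy()
    outs = []
    sig = lambda v: 1.0 / (1.0 + math.exp(-v))
    for x in x_seq:
        gates = x @ W + h @ U + b
        i = np.array([sig(v) for v in gates[0:H]])
        f = np.array([sig(v) for v in gates[H:2 * H]])
        g = np.array([math.tanh(v) for v in gates[2 * H:3 * H]])
        o = np.array([sig(v) for v in gates[3 * H:4 * H]])
        c = f * c + i * g
        h = o * np.tanh(c)
        outs.append(h.copy())
    return outs


class TestEncoder:
    def _net(self):
        return FusionNetwork(TINY, n_genes=6, semantic_dim=5,
                             rng=np.random.default_rng(1))

    def test_output_width_is_twice_hidden(self):
        net = self._net()
        seq = np.array([2, -1, -1, -1])
        mask = np.array([True, False, False, False])
        state = encode_targets(net, seq, mask)
        assert state.hidden.shape == (1, 4, 2 * TINY.hidden)

    def test_two_token_sequence_matches_gate_oracle(self):
        """Forward-direction states equal an independently coded LSTM."""
        net = self._net()
        seq = np.array([1, 4, -1, -1])
        mask = np.array([True, True, False, False])
        state = encode_targets(net, seq, mask)
        E = net.params["gene_emb"].data
        H = TINY.hidden
        x_seq = [E[1], E[4]]
        expect = scalar_lstm_oracle(
            x_seq, net.params["lstm_herb_f_W"].data,
            net.params["lstm_herb_f_U"].data, net.params["lstm_herb_f_b"].data,
            np.zeros(H), np.zeros(H))
        for t in range(2):
            np.testing.assert_allclose(state.hidden.data[0, t, :H],
                                       expect[t], atol=1e-6)
        # backward block runs over the reversed sequence
        expect_b = scalar_lstm_oracle(
            list(reversed(x_seq)), net.params["lstm_herb_b_W"].data,
            net.params["lstm_herb_b_U"].data, net.params["lstm_herb_b_b"].data,
            np.zeros(H), np.zeros(H))
        np.testing.assert_allclose(state.hidden.data[0, 0, H:],
                                   expect_b[1], atol=1e-6)
        np.testing.assert_allclose(state.hidden.data[0, 1, H:],
                                   expect_b[0], atol=1e-6)

    def test_reversal_swaps_directional_blocks_with_shared_weights(self):
        net = self._net()
        # share weights across the two directions
        for kind in ("W", "U", "b"):
            net.params[f"lstm_herb_b_{kind}"].data = \
                net.params[f"lstm_herb_f_{kind}"].data.copy()
        H = TINY.hidden
        seq = np.array([0, 3, 5])
        mask = np.ones(3, dtype=bool)
        fwd = encode_targets(net, seq, mask).hidden.data[0]
        rev = encode_targets(net, seq[::-1].copy(), mask).hidden.data[0]
        for t in range(3):
            np.testing.assert_allclose(fwd[t, :H], rev[2 - t, H:], atol=1e-12)
            np.testing.assert_allclose(fwd[t, H:], rev[2 - t, :H], atol=1e-12)

    def test_all_pad_sequence_rejected(self):
        net = self._net()
        with pytest.raises(ValueError, match="pad"):
            encode_targets(net, np.full(4, -1), np.zeros(4, dtype=bool))


class TestAttention:
    def _states(self, net, n_q=2, n_k=5, valid_k=5, seed=2):
        rng = np.random.default_rng(seed)
        from tcmspred.autograd import Tensor
        from tcmspred.model import EncoderState
        d = TINY.attn_dim
        q = EncoderState(Tensor(rng.normal(size=(1, n_q, d))),
                         np.ones((1, n_q), dtype=bool))
        k_mask = np.zeros((1, n_k), dtype=bool)
        k_mask[0, :valid_k] = True
        k = EncoderState(Tensor(rng.normal(size=(1, n_k, d))), k_mask)
        return q, k

    def test_rows_match_exhaustive_softmax_oracle(self):
        net = FusionNetwork(TINY, 6, 5, np.random.default_rng(1))
        q, k = self._states(net, n_q=3, n_k=5)
        A = cross_attend(net, q, k).weights.data[0]
        logits = (q.hidden.data[0] @ k.hidden.data[0].T) / np.sqrt(TINY.attn_dim)
        for row, lrow in zip(A, logits):
            e = np.exp(lrow - lrow.max())
            np.testing.assert_allclose(row, e / e.sum(), atol=1e-9)
        np.testing.assert_allclose(A.sum(axis=1), 1.0, atol=1e-6)

    def test_equal_logits_give_uniform_weights(self):
        from tcmspred.autograd import Tensor
        from tcmspred.model import EncoderState
        net = FusionNetwork(TINY, 6, 5, np.random.default_rng(1))
        d = TINY.attn_dim
        q = EncoderState(Tensor(np.zeros((1, 1, d))), np.ones((1, 1), bool))
        k = EncoderState(Tensor(np.tile(np.arange(d, dtype=float),
                                        (1, 4, 1))), np.ones((1, 4), bool))
        A = cross_attend(net, q, k).weights.data
        np.testing.assert_allclose(A, 0.25)

    def test_masked_keys_get_exactly_zero(self):
        net = FusionNetwork(TINY, 6, 5, np.random.default_rng(1))
        q, k = self._states(net, n_q=2, n_k=5, valid_k=3)
        A = cross_attend(net, q, k).weights.data[0]
        assert (A[:, 3:] == 0).all()
        np.testing.assert_allclose(A.sum(axis=1), 1.0, atol=1e-6)

    def test_single_valid_key_takes_all_weight(self):
        net = FusionNetwork(TINY, 6, 5, np.random.default_rng(1))
        q, k = self._states(net, n_q=2, n_k=4, valid_k=1)
        A = cross_attend(net, q, k).weights.data[0]
        np.testing.assert_allclose(A[:, 0], 1.0)


class TestForward:
    def _trained_stub(self, zero_final=False):
        net = FusionNetwork(TINY, 6, 5, np.random.default_rng(4))
        params = {k: v.data.copy() for k, v in net.params.items()}
        if zero_final:
            last = len(TINY.cls_hidden)
            params[f"cls_{last}_W"][:] = 0.0
            params[f"cls_{last}_b"][:] = 0.0
        return TrainedModel(params=params, config=TINY, n_genes=6,
                            semantic_dim=5, prox_mean=np.zeros(4),
                            prox_std=np.ones(4), feature_digest="t")

    def test_zero_final_layer_gives_half(self):
        model = self._trained_stub(zero_final=True)
        score = forward(make_features(), model)
        assert score.probability == pytest.approx(0.5)

    def test_probability_strictly_inside_unit_interval(self):
        model = self._trained_stub()
        for seed in range(5):
            p = forward(make_features(seed=seed), model).probability
            assert 0.0 < p < 1.0

    def test_digest_mismatch_rejected(self):
        model = self._trained_stub()
        bad = make_features(digest="other")
        with pytest.raises(ValueError, match="digest"):
            predict(model, [bad])

    def test_predict_empty_is_empty(self):
        assert predict(self._trained_stub(), []) == []

    def test_predict_matches_forward_and_batch_invariance(self):
        model = self._trained_stub()
        feats = [make_features(herb=f"H{i}", seed=i) for i in range(7)]
        singles = [forward(f, model).probability for f in feats]
        small = dataclasses.replace(TINY, batch_size=1)
        big = dataclasses.replace(TINY, batch_size=32)
        p_small = [s.probability for s in predict(
            TrainedModel(**{**model.__dict__, "config": small}), feats)]
        p_big = [s.probability for s in predict(
            TrainedModel(**{**model.__dict__, "config": big}), feats)]
        np.testing.assert_allclose(p_small, p_big, atol=1e-6)
        np.testing.assert_allclose(singles, p_big, atol=1e-6)


def test_bce_at_half_is_log_two():
    from tcmspred.autograd import Tensor
    probs = Tensor(np.full(4, 0.5))
    loss = bce_loss(probs, np.array([0, 1, 1, 0]))
    assert float(loss.data) == pytest.approx(math.log(2), abs=1e-9)


def test_bce_forward_gradient_matches_finite_differences():
    """d(BCE o forward)/d(probe param), rel. err <= 1e-4 on a tiny config."""
    net = FusionNetwork(TINY, 6, 5, np.random.default_rng(5))
    feats = [make_features(seed=11), make_features(seed=12)]
    labels = np.array([1, 0])
    from tcmspred.model import _batch_arrays

    arrays = _batch_arrays(feats, np.zeros(4), np.ones(4))

    def loss_value():
        return float(bce_loss(net.forward_batch(*arrays), labels).data)

    for p in net.params.values():
        p.grad = None
    loss = bce_loss(net.forward_batch(*arrays), labels)
    loss.backward()
    for name in ("cls_0_W", "proc_0_W", "lstm_herb_f_W", "gene_emb"):
        par = net.params[name]
        idx = (0, 0)
        eps = 1e-6
        par.data[idx] += eps
        lp = loss_value()
        par.data[idx] -= 2 * eps
        lm = loss_value()
        par.data[idx] += eps
        num = (lp - lm) / (2 * eps)
        ana = par.grad[idx]
        assert abs(num - ana) / max(abs(num), 1e-8) < 1e-4, name


def test_training_overfits_separable_pairs():
    """Training drives loss below 0.1 on a tiny separable problem."""
    pos = make_features(herb="HP", seed=1)
    pos.proximity = (3.0, 3.0, 3.0, 3.0)
    neg = make_features(herb="HN", seed=2)
    neg.proximity = (-3.0, -3.0, -3.0, -3.0)
    dataset = [(pos, 1), (neg, 0)] * 20
    cfg = dataclasses.replace(TINY, max_epochs=50, patience=50, lr=5e-3,
                              val_fraction=0.1)
    model = train(dataset, cfg)
    assert min(model.history["train_loss"]) < 0.1


def test_single_class_dataset_rejected():
    dataset = [(make_features(seed=i), 1) for i in range(8)]
    with pytest.raises(ValueError, match="both classes"):
        train(dataset, TINY)


def test_training_is_deterministic_and_checkpoint_round_trips(tmp_path):
    dataset = make_dataset()
    cfg = dataclasses.replace(TINY, max_epochs=3)
    m1 = train(dataset, cfg)
    m2 = train(dataset, cfg)
    for k in m1.params:
        np.testing.assert_array_equal(m1.params[k], m2.params[k])

    save_model(m1, tmp_path / "ckpt")
    loaded = load_model(tmp_path / "ckpt")
    feats = [f for f, _ in dataset[:6]]
    p_orig = [s.probability for s in predict(m1, feats)]
    p_load = [s.probability for s in predict(loaded, feats)]
    np.testing.assert_array_equal(p_orig, p_load)
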