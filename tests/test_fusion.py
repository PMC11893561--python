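"""Cross-attention fusion, weighted cross-entropy, training and prediction."""

import dataclasses
import math

import numpy as np
import pytest

from aamm import (ADTrainConfig, BagDataset, CrossAttentionBlock, FusionModel,
                  GMVAEModel, SelectionConfig, TrainConfig, class_weights,
                  concat_modalities, cross_attention_block, fuse,
                  max_pool_baseline, mean_pool_baseline,
                  perceiver_fuse_unimodal, predict_bag, scaled_dot_attention,
                  train_classifier, weighted_ce)
from aamm.autodiff import Tensor
from conftest import SMALL_DIMS


# -- attention primitive ---------------------------------------------------------

def test_identical_keys_give_uniform_average(rng):
    K = np.tile(rng.normal(size=(1, 3)), (4, 1))
    V = rng.normal(size=(4, 2))
    Q = rng.normal(size=(2, 3))
    out = scaled_dot_attention(Q, K, V)
    assert np.allclose(out, np.tile(V.mean(axis=0), (2, 1)), atol=1e-12)


def test_single_key_returns_value_row(rng):
    Q = rng.normal(size=(3, 2))
    K = rng.normal(size=(1, 2))
    V = rng.normal(size=(1, 4))
    out = scaled_dot_attention(Q, K, V)
    assert np.allclose(out, np.tile(V[0], (3, 1)), atol=1e-12)


def test_two_key_softmax_hand_case():
    # d_k = 1, logit gap ln 4 -> weights (0.2, 0.8)
    out = scaled_dot_attention(np.array([[1.0]]),
                               np.array([[0.0], [math.log(4)]]),
                               np.array([[0.0], [1.0]]))
    assert abs(out[0, 0] - 0.8) < 1e-10


def test_attention_rows_are_convex_combinations(rng):
    Q, K = rng.normal(size=(5, 3)), rng.normal(size=(7, 3))
    V = rng.normal(size=(7, 1))
    out = scaled_dot_attention(Q, K, V)
    assert np.all(out >= V.min() - 1e-12) and np.all(out <= V.max() + 1e-12)
    # row-stochastic weights
    scores = Q @ K.T / math.sqrt(3)
    w = np.exp(scores - scores.max(axis=1, keepdims=True))
    w /= w.sum(axis=1, keepdims=True)
    assert np.allclose(w.sum(axis=1), 1.0, atol=1e-6)


def test_attention_rejects_empty_context():
    with pytest.raises(ValueError):
        scaled_dot_attention(np.ones((1, 2)), np.ones((0, 2)), np.ones((0, 2)))


# -- cross-attention block --------------------------------------------------------

def test_identity_block_reduces_to_bare_attention(rng):
    block = CrossAttentionBlock.identity(3)
    Q, C = rng.normal(size=(2, 3)), rng.normal(size=(5, 3))
    assert np.allclose(cross_attention_block(Q, C, block),
                       scaled_dot_attention(Q, C, C), atol=1e-12)


def test_zero_query_projection_gives_uniform_attention(rng):
    block = CrossAttentionBlock.identity(3)
    block.q_proj.W.data[:] = 0.0
    C = rng.normal(size=(6, 3))
    out = cross_attention_block(rng.normal(size=(2, 3)), C, block)
    assert np.allclose(out, np.tile(C.mean(axis=0), (2, 1)), atol=1e-10)


def test_block_equals_project_attend_project_composition(rng):
    block = CrossAttentionBlock(4, 6, 5, np.random.default_rng(3))
    Q, C = rng.normal(size=(2, 4)), rng.normal(size=(7, 6))
    out = cross_attention_block(Q, C, block)
    q = Q @ block.q_proj.W.data + block.q_proj.b.data
    k = C @ block.k_proj.W.data + block.k_proj.b.data
    v = C @ block.v_proj.W.data + block.v_proj.b.data
    oracle = scaled_dot_attention(q, k, v) @ block.out_proj.W.data \
        + block.out_proj.b.data
    assert np.allclose(out, oracle, atol=1e-10)


# -- fuse cascade -----------------------------------------------------------------

def _small_fusion(modalities=("p", "c", "t", "r"), mode="multimodal", seed=0):
    return FusionModel(modalities=modalities, mode=mode, d_model=16,
                       n_classes=2, n_latents=4, seed=seed, dims=SMALL_DIMS)


def _feats(rng, m):
    return {k: rng.normal(size=(m, d)) for k, d in SMALL_DIMS.items()}


def test_fuse_single_instance_pools_to_itself(rng):
    model = _small_fusion()
    f = _feats(rng, 1)
    H, pooled = fuse(f["p"], f["c"], f["t"], f["r"], model)
    assert H.shape == (1, 16)
    assert np.allclose(pooled, H[0], atol=1e-12)


def test_fuse_invariant_to_consistent_row_permutation(rng):
    model = _small_fusion()
    f = _feats(rng, 6)
    _, pooled = fuse(f["p"], f["c"], f["t"], f["r"], model)
    perm = rng.permutation(6)
    _, pooled_p = fuse(f["p"][perm], f["c"][perm], f["t"][perm], f["r"][perm],
                       model)
    assert np.allclose(pooled, pooled_p, atol=1e-8)


def test_full_cascade_matches_step_by_step_oracle(rng):
    """With identity projections and equal dims, the cascade is exactly the
    three-stage attention chain H1 <- (t,c), H2 <- (H1,p), H3 <- (r,H2)."""
    d = 3
    model = FusionModel(modalities=("p", "c", "t", "r"), d_model=d,
                        n_classes=2, seed=0,
                        dims={"p": d, "c": d, "t": d, "r": d})
    model.input_proj.W.data = np.eye(d, dtype=np.float32)
    model.input_proj.b.data[:] = 0.0
    for name in model._ctx_names:
        model.blocks[name] = CrossAttentionBlock.identity(d)
    model.r_block = CrossAttentionBlock.identity(d)
    f = {k: rng.normal(size=(3, d)) for k in "pctr"}
    H1 = scaled_dot_attention(f["t"], f["c"], f["c"])
    H2 = scaled_dot_attention(H1, f["p"], f["p"])
    H3 = scaled_dot_attention(f["r"], H2, H2)
    got_H, got_pool = fuse(f["p"], f["c"], f["t"], f["r"], model)
    assert np.allclose(got_H, H3, atol=1e-10)
    assert np.allclose(got_pool, H3.mean(axis=0), atol=1e-10)


def test_cascade_skips_absent_modalities(rng):
    model = _small_fusion(modalities=("p", "c"))
    f = _feats(rng, 4)
    H, _ = model.fuse({"p": f["p"], "c": f["c"]})
    assert H.shape == (4, 16)
    with pytest.raises(ValueError, match="missing"):
        model.fuse({"p": f["p"]})


# -- perceiver unimodal -----------------------------------------------------------

def test_perceiver_single_latent_equals_its_readout(rng):
    model = _small_fusion(modalities=("p", "r"), mode="unimodal")
    model.latents = Tensor(rng.normal(size=(1, 16)).astype(np.float32),
                           requires_grad=True)
    f = _feats(rng, 5)
    pooled = perceiver_fuse_unimodal(f["p"], f["r"], model)
    Hq = model.input_proj(f["r"])
    H = model.p_block(Hq, f["p"])
    readout = model.latent_block(model.latents.data, H)
    assert np.allclose(pooled, readout[0], atol=1e-10)


def test_perceiver_invariant_to_instance_duplication(rng):
    model = _small_fusion(modalities=("p", "r"), mode="unimodal")
    f = _feats(rng, 5)
    pooled = perceiver_fuse_unimodal(f["p"], f["r"], model)
    dup = perceiver_fuse_unimodal(np.vstack([f["p"], f["p"]]),
                                  np.vstack([f["r"], f["r"]]), model)
    assert np.allclose(pooled, dup, atol=1e-6)


# -- pooling baselines and losses ---------------------------------------------------

def test_pooling_baselines(rng):
    H = np.array([[1.0, 2.0], [3.0, 4.0]])
    assert np.array_equal(mean_pool_baseline(H), [2.0, 3.0])
    assert np.array_equal(max_pool_baseline(H), [3.0, 4.0])
    row = rng.normal(size=(1, 4))
    assert np.array_equal(mean_pool_baseline(row), row[0])
    assert np.array_equal(max_pool_baseline(row), row[0])
    H6 = rng.normal(size=(6, 4))
    oracle_mean = [sum(H6[i, j] for i in range(6)) / 6 for j in range(4)]
    oracle_max = [max(H6[i, j] for i in range(6)) for j in range(4)]
    assert np.allclose(mean_pool_baseline(H6), oracle_mean)
    assert np.allclose(max_pool_baseline(H6), oracle_max)
    with pytest.raises(ValueError):
        mean_pool_baseline(np.zeros((0, 3)))


def test_concat_modalities(rng):
    f = {"c": rng.normal(size=(3, 2)), "p": rng.normal(size=(3, 4))}
    out = concat_modalities(f)
    assert out.shape == (3, 6)
    assert np.array_equal(out[:, :2], f["c"])


def test_class_weights_formula_and_conservation(rng):
    assert np.allclose(class_weights([0] * 50 + [1] * 50, 2), [1.0, 1.0])
    assert np.allclose(class_weights([0] * 90 + [1] * 10, 2), [5 / 9, 5.0])
    w = class_weights([0] * 60 + [1] * 30 + [2] * 10, 3)
    assert np.allclose(w, [100 / 180, 100 / 90, 100 / 30])
    assert math.isclose(60 * w[0] + 30 * w[1] + 10 * w[2], 100.0)
    with pytest.raises(ValueError):
        class_weights([0, 0, 0], 2)


def test_weighted_ce_uniform_logits_is_log2():
    logits = np.zeros((4, 2))
    assert math.isclose(weighted_ce(logits, [0, 1, 1, 0], [1.0, 1.0]),
                        math.log(2), rel_tol=1e-12)


def test_weighted_ce_matches_hand_oracle():
    # two bags with true-class probabilities 0.8 and 0.5, weights (5/9, 5)
    logits = np.array([[math.log(0.8), math.log(0.2)],
                       [math.log(0.5), math.log(0.5)]])
    got = weighted_ce(logits, [0, 1], [5 / 9, 5.0])
    expected = -0.5 * (5 / 9 * math.log(0.8) + 5.0 * math.log(0.5))
    assert math.isclose(got, expected, rel_tol=1e-12)


def test_unit_weights_reduce_to_unweighted_ce(rng):
    logits = rng.normal(size=(6, 3))
    labels = rng.integers(0, 3, size=6)
    logp = logits - np.log(np.exp(logits).sum(axis=1, keepdims=True))
    unweighted = -np.mean(logp[np.arange(6), labels])
    assert math.isclose(weighted_ce(logits, labels, np.ones(3)), unweighted,
                        rel_tol=1e-12)


def test_weighted_ce_approaches_zero_for_confident_correct():
    logits = np.array([[30.0, 0.0]])
    assert weighted_ce(logits, [0], [1.0, 1.0]) < 1e-10


# -- training and prediction ---------------------------------------------------------

def _tiny_selected_dataset(rng, n=10):
    from aamm import EmbeddingBag
    bags = []
    for i in range(n):
        m = int(rng.integers(3, 6))
        label = i % 2
        shift = 2.0 * label
        bags.append(EmbeddingBag(
            bag_id=f"b{i}", label=label,
            F_p=rng.normal(size=(m, SMALL_DIMS["p"])) + shift,
            F_c=rng.normal(size=(m, SMALL_DIMS["c"])) + shift,
            F_t=rng.normal(size=(m, SMALL_DIMS["t"])) + shift,
            F_r=rng.normal(size=(m, SMALL_DIMS["r"]))))
    return BagDataset(bags)


def test_zero_learning_rate_leaves_weights_unchanged(rng):
    ds = _tiny_selected_dataset(rng)
    model = _small_fusion()
    before = [p.data.copy() for p in model.parameters()]
    train_classifier(ds, model, TrainConfig(learning_rate=0.0, epochs=1,
                                            d_model=16, n_latents=4))
    for b, p in zip(before, model.parameters()):
        assert np.array_equal(b, p.data)


def test_training_loss_decreases_and_is_seeded(rng):
    ds = _tiny_selected_dataset(rng)
    cfg = TrainConfig(epochs=8, d_model=16, n_latents=4, seed=1)
    m1 = _small_fusion(seed=1)
    train_classifier(ds, m1, cfg)
    assert m1.loss_history[-1] < m1.loss_history[0]
    m2 = _small_fusion(seed=1)
    train_classifier(ds, m2, cfg)
    for p1, p2 in zip(m1.parameters(), m2.parameters()):
        assert np.array_equal(p1.data, p2.data)


def test_train_rejects_missing_modality(rng):
    ds = _tiny_selected_dataset(rng)
    stripped = BagDataset([b.with_(F_t=None) for b in ds])
    model = _small_fusion()
    with pytest.raises(ValueError, match="missing"):
        train_classifier(stripped, model, TrainConfig(epochs=1, d_model=16))


def _frozen_ad(dim=SMALL_DIMS["p"]):
    return GMVAEModel(dim, latent_dim=4, n_components=2, hidden_dims=(8,),
                      seed=0).freeze()


def test_predict_none_equals_k1_max(rng, small_dataset):
    ad = _frozen_ad()
    fusion = _small_fusion().freeze()
    bag = small_dataset[0]
    p_none = predict_bag(bag, ad, fusion, SelectionConfig(k=1.0, strategy="none"))
    p_all = predict_bag(bag, ad, fusion, SelectionConfig(k=1.0, strategy="max"))
    assert np.allclose(p_none.probabilities, p_all.probabilities, atol=1e-6)


def test_predict_permutation_invariance(rng, small_dataset):
    ad = _frozen_ad()
    fusion = _small_fusion().freeze()
    bag = small_dataset[1]
    perm = rng.permutation(bag.n_instances)
    bag_p = bag.with_(F_p=bag.F_p[perm], F_c=bag.F_c[perm], F_t=bag.F_t[perm],
                      instance_labels=bag.instance_labels[perm])
    p1 = predict_bag(bag, ad, fusion, SelectionConfig(k=0.5, strategy="max"))
    p2 = predict_bag(bag_p, ad, fusion, SelectionConfig(k=0.5, strategy="max"))
    assert np.allclose(p1.probabilities, p2.probabilities, atol=1e-5)


def test_predict_probabilities_on_simplex(rng, small_dataset):
    ad = _frozen_ad()
    fusion = _small_fusion().freeze()
    pred = predict_bag(small_dataset[2], ad, fusion, SelectionConfig())
    assert math.isclose(pred.probabilities.sum(), 1.0, rel_tol=1e-9)
    assert pred.label == int(np.argmax(pred.probabilities))


def test_predict_end_to_end_hand_oracle(rng, small_dataset):
    """Prediction equals the explicit chain reconstruct -> select -> fuse
    -> head -> softmax computed outside the pipeline."""
    from aamm import reconstruct, select_max, apply_selection
    ad = _frozen_ad()
    fusion = _small_fusion().freeze()
    bag = small_dataset[3]
    sel_cfg = SelectionConfig(k=0.5, strategy="max")
    pred = predict_bag(bag, ad, fusion, sel_cfg)
    rec = reconstruct(ad, bag.F_p)
    res = select_max(rec.errors, 0.5)
    kept = apply_selection(bag.with_(F_r=rec.F_r, errors=rec.errors), res)
    feats = {k: kept.modalities()[k].astype(np.float32)
             for k in fusion.modalities}
    _, pooled = fusion.fuse(feats)
    logits = fusion.head(pooled)
    logits = np.asarray(logits, dtype=float)[0]
    p = np.exp(logits - logits.max())
    p /= p.sum()
    assert np.allclose(pred.probabilities, p, atol=1e-10)


def test_fusion_checkpoint_round_trip(tmp_path, rng):
    ds = _tiny_selected_dataset(rng)
    model = _small_fusion()
    train_classifier(ds, model, TrainConfig(epochs=1, d_model=16, n_latents=4))
    path = tmp_path / "fusion.ckpt"
    model.save(path)
    loaded = FusionModel.load(path)
    feats = {k: v.astype(np.float32) for k, v in ds[0].modalities().items()}
    out1 = model.logits(feats)
    out2 = loaded.logits(feats)
    assert np.array_equal(np.asarray(out1), np.asarray(out2))
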