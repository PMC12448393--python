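import copy
import math

import numpy as np
import pytest

from ecfuse._autodiff import Tensor
from ecfuse.features import ModelConfig, init_extractor_params, iter_parameters
from ecfuse.ontology import build_label_spaces, encode_targets, parse_ec
from ecfuse.prediction import autoregressive_forward_t, init_head_params
from ecfuse.training import (
    PhaseSchedule,
    TrainConfig,
    bce_multilevel_loss,
    bce_multilevel_loss_t,
    compute_pooled_features,
    load_checkpoint,
    sample_triplets,
    save_checkpoint,
    total_loss,
    train_phase1,
    train_phase2,
    triplet_loss,
    triplet_loss_t,
)


# ------------------------------------------------------------------- closed forms
def test_triplet_loss_closed_forms():
    a = np.zeros((1, 3))
    # d(a,p)=0, d(a,n)=2, margin=1 -> hinge inactive
    assert triplet_loss(a, a, np.array([[2.0, 0, 0]]), margin=1.0) == pytest.approx(0.0)
    # d(a,p)=1, d(a,n)=0.5, margin=0.2 -> 0.7
    loss = triplet_loss(a, np.array([[1.0, 0, 0]]), np.array([[0.5, 0, 0]]), margin=0.2)
    assert loss == pytest.approx(0.7, abs=1e-9)
    # additivity over a batch of two identical triplets
    a2 = np.zeros((2, 3))
    p2 = np.array([[1.0, 0, 0]] * 2)
    n2 = np.array([[0.5, 0, 0]] * 2)
    assert triplet_loss(a2, p2, n2, margin=0.2) == pytest.approx(1.4, abs=1e-9)


def test_triplet_loss_zero_iff_margin_satisfied():
    rng = np.random.default_rng(0)
    for _ in range(50):
        a, p, n = rng.normal(size=(3, 4))
        margin = rng.uniform(0.1, 1.0)
        loss = triplet_loss(a[None], p[None], n[None], margin)
        d_ap = np.linalg.norm(a - p)
        d_an = np.linalg.norm(a - n)
        assert loss >= 0.0
        assert (loss == 0.0) == (d_ap + margin <= d_an)


def test_triplet_loss_tensor_matches_array_version():
    rng = np.random.default_rng(1)
    a, p, n = rng.normal(size=(3, 6, 4))
    t = triplet_loss_t([Tensor(x) for x in a], [Tensor(x) for x in p],
                       [Tensor(x) for x in n], margin=0.5)
    assert t.item() == pytest.approx(triplet_loss(a, p, n, 0.5), rel=1e-9)


def test_bce_closed_forms():
    # y=1, p=0.5 -> ln 2; two entries y=(1,0), p=(0.5,0.5) -> 2 ln 2
    assert bce_multilevel_loss([np.array([0.5])], [np.array([1.0])]) == pytest.approx(
        math.log(2), abs=1e-9
    )
    assert bce_multilevel_loss(
        [np.array([0.5, 0.5])], [np.array([1.0, 0.0])]
    ) == pytest.approx(2 * math.log(2), abs=1e-9)
    # perfect 0/1 predictions: only the clamping epsilon remains
    perfect = bce_multilevel_loss(
        [np.array([1.0, 0.0])] * 4, [np.array([1.0, 0.0])] * 4
    )
    assert 0 <= perfect < 8 * 1e-6


def test_bce_matches_scalar_loop_oracle():
    rng = np.random.default_rng(2)
    for _ in range(20):
        preds = [rng.uniform(0.01, 0.99, size=rng.integers(1, 6)) for _ in range(4)]
        ys = [rng.integers(0, 2, size=p.shape).astype(float) for p in preds]
        expected = 0.0
        for p, y in zip(preds, ys):
            for pi, yi in zip(p, y):
                pi = min(max(pi, 1e-7), 1 - 1e-7)
                expected += -(yi * math.log(pi) + (1 - yi) * math.log(1 - pi))
        assert bce_multilevel_loss(preds, ys) == pytest.approx(expected, abs=1e-8)
        t = bce_multilevel_loss_t([Tensor(p) for p in preds], ys)
        assert t.item() == pytest.approx(expected, abs=1e-8)


def test_total_loss_phase_weightings():
    assert total_loss(3.0, 7.0, 1.0, 0.0) == 3.0  # phase 1: lambda2 = 0
    assert total_loss(3.0, 7.0, 0.0, 1.0) == 7.0  # phase 2: lambda1 = 0, lambda2 = 1
    assert total_loss(3.0, 7.0, 0.0, 0.0) == 0.0


# ---------------------------------------------------------------- triplet mining
def test_sample_triplets_share_and_not_share_predicate():
    ec_sets = [{"1.1.1.1"}, {"1.1.1.1"}, {"2.2.2.2"}, {"2.2.2.2", "1.1.1.1"}, {"3.3.3.3"}]
    triples = sample_triplets(ec_sets, 100, np.random.default_rng(3))
    assert len(triples) == 100
    for a, p, n in triples:
        assert ec_sets[a] & ec_sets[p] and a != p
        assert not (ec_sets[a] & ec_sets[n])


def test_sample_triplets_deterministic_and_skips_singletons():
    ec_sets = [{"1.1.1.1"}, {"1.1.1.1"}, {"2.2.2.2"}]
    t1 = sample_triplets(ec_sets, 20, np.random.default_rng(7))
    t2 = sample_triplets(ec_sets, 20, np.random.default_rng(7))
    assert t1 == t2
    # the singleton class never anchors
    assert all(a != 2 for a, _, _ in t1)


def test_sample_triplets_errors():
    with pytest.raises(ValueError):  # no class has two members
        sample_triplets([{"1.1.1.1"}, {"2.2.2.2"}], 5, np.random.default_rng(0))
    with pytest.raises(ValueError):  # no negative exists
        sample_triplets([{"1.1.1.1"}, {"1.1.1.1"}], 5, np.random.default_rng(0))


# -------------------------------------------------------------- training loops
@pytest.fixture(scope="module")
def toy_training(tiny_split_module):
    return tiny_split_module


@pytest.fixture(scope="module")
def tiny_split_module():
    from ecfuse.synthetic import SynthConfig, generate_dataset, split_dataset

    cfg = SynthConfig(branching=(2, 2, 2, 2), proteins_per_leaf=3,
                      length_range=(14, 18), motif_len=7, seed=5)
    return split_dataset(generate_dataset(cfg), 0.34, np.random.default_rng(0))


def _snapshot(tree):
    return [p.data.copy() for p in iter_parameters(tree)]


def _bit_identical(tree, snap):
    return all(np.array_equal(p.data, s) for p, s in zip(iter_parameters(tree), snap))


def _small_cfgs():
    model_cfg = ModelConfig(n_features=16, n_heads=2)
    train_cfg = TrainConfig(
        phase1=PhaseSchedule(3, 20, 5e-4),
        phase2=PhaseSchedule(60, 48, 1e-3, cosine_annealing=True),
        triplets_per_epoch=20,
    )
    return model_cfg, train_cfg


def test_phase1_trains_extractor_and_freezes_head(toy_training):
    train, _ = toy_training
    model_cfg, train_cfg = _small_cfgs()
    rng = np.random.default_rng(0)
    extractor = init_extractor_params(model_cfg, rng)
    head = init_head_params(model_cfg.fused_width, train.label_spaces, rng)
    head_snap = _snapshot(head["mlps"])
    ext_snap = _snapshot(extractor)
    trace = train_phase1(train, extractor, model_cfg, train_cfg, rng)
    assert len(trace) == 3 and all(np.isfinite(r["loss"]) for r in trace)
    assert _bit_identical(head["mlps"], head_snap)  # freeze contract
    assert not _bit_identical(extractor, ext_snap)  # extractor actually moved


def test_phase1_same_seed_gives_identical_trace(toy_training):
    train, _ = toy_training
    model_cfg, train_cfg = _small_cfgs()
    traces = []
    for _ in range(2):
        rng = np.random.default_rng(123)
        extractor = init_extractor_params(model_cfg, rng)
        traces.append(train_phase1(train, extractor, model_cfg, train_cfg, rng))
    assert traces[0] == traces[1]


def test_phase2_freezes_extractor_and_reduces_bce(toy_training):
    train, _ = toy_training
    model_cfg, train_cfg = _small_cfgs()
    rng = np.random.default_rng(1)
    extractor = init_extractor_params(model_cfg, rng)
    head = init_head_params(model_cfg.fused_width, train.label_spaces, rng)
    ext_snap = _snapshot(extractor)
    trace = train_phase2(train, extractor, head, model_cfg, train_cfg, rng)
    assert _bit_identical(extractor, ext_snap)  # freeze contract
    assert trace[-1]["loss"] < trace[0]["loss"]


def test_phase2_cache_equivalence(toy_training):
    """Training on precomputed pooled features equals computing them inline."""
    train, _ = toy_training
    model_cfg, train_cfg = _small_cfgs()
    outs = []
    for use_cache in (False, True):
        rng = np.random.default_rng(2)
        extractor = init_extractor_params(model_cfg, rng)
        head = init_head_params(model_cfg.fused_width, train.label_spaces, rng)
        cache = (
            compute_pooled_features(train, extractor, model_cfg) if use_cache else None
        )
        train_phase2(train, extractor, head, model_cfg, train_cfg, rng, pooled_cache=cache)
        outs.append(_snapshot(head["mlps"]))
    assert all(np.array_equal(a, b) for a, b in zip(*outs))


def test_total_loss_gradient_matches_finite_differences(toy_training):
    """Analytic gradients of the combined objective at 10 random parameters."""
    train, _ = toy_training
    model_cfg, _ = _small_cfgs()
    rng = np.random.default_rng(3)
    extractor = init_extractor_params(model_cfg, rng)
    head = init_head_params(model_cfg.fused_width, train.label_spaces, rng)
    pairs = [train.records[i][0] for i in range(3)]
    targets = encode_targets(train.records[0][1], train.label_spaces)

    def forward():
        from ecfuse.features import forward_features_t

        pooled = []
        for pair in pairs:
            _, pool_t, _ = forward_features_t(
                Tensor(pair.seq_embedding), Tensor(pair.tdi_embedding), extractor, model_cfg
            )
            pooled.append(pool_t)
        lt = triplet_loss_t([pooled[0]], [pooled[1]], [pooled[2]], margin=1.0)
        preds = autoregressive_forward_t(
            pooled[0].reshape(1, -1), head,
            prev_override=[t[None, :] for t in targets.levels[:3]],
        )
        lb = bce_multilevel_loss_t(preds, [t[None, :] for t in targets.levels])
        return lt * 0.7 + lb * 0.3

    loss = forward()
    loss.backward()
    all_params = iter_parameters(extractor) + iter_parameters(head["mlps"])
    prng = np.random.default_rng(4)
    checked = 0
    eps = 1e-6
    for _ in range(10):
        p = all_params[int(prng.integers(len(all_params)))]
        if p.grad is None:
            continue
        idx = tuple(int(prng.integers(s)) for s in p.data.shape)
        orig = p.data[idx]
        p.data[idx] = orig + eps
        up = forward().item()
        p.data[idx] = orig - eps
        down = forward().item()
        p.data[idx] = orig
        numeric = (up - down) / (2 * eps)
        analytic = p.grad[idx]
        assert analytic == pytest.approx(numeric, rel=1e-4, abs=1e-7)
        checked += 1
    assert checked >= 8


def test_scheduled_sampling_changes_head_trajectory_but_still_learns(toy_training):
    train, _ = toy_training
    model_cfg, train_cfg = _small_cfgs()
    outs = []
    for ss in (0.0, 1.0):
        rng = np.random.default_rng(9)
        extractor = init_extractor_params(model_cfg, rng)
        head = init_head_params(model_cfg.fused_width, train.label_spaces, rng)
        cfg = copy.deepcopy(train_cfg)
        cfg.scheduled_sampling = ss
        trace = train_phase2(train, extractor, head, model_cfg, cfg, rng)
        assert trace[-1]["loss"] < trace[0]["loss"]
        outs.append(_snapshot(head["mlps"]))
    assert not all(np.array_equal(a, b) for a, b in zip(*outs))


def test_phase1_divergence_aborts(toy_training):
    train, _ = toy_training
    model_cfg, train_cfg = _small_cfgs()
    rng = np.random.default_rng(5)
    extractor = init_extractor_params(model_cfg, rng)
    # poison one parameter to force a non-finite forward
    iter_parameters(extractor)[0].data[:] = np.inf
    with pytest.raises(RuntimeError, match="diverged"):
        train_phase1(train, extractor, model_cfg, train_cfg, rng)


def test_checkpoint_round_trip(tmp_path, toy_training):
    train, _ = toy_training
    model_cfg, train_cfg = _small_cfgs()
    rng = np.random.default_rng(6)
    extractor = init_extractor_params(model_cfg, rng)
    head = init_head_params(model_cfg.fused_width, train.label_spaces, rng)
    path = tmp_path / "ckpt.npz"
    save_checkpoint(path, model_cfg, extractor, head, train.label_spaces, train_cfg)
    cfg2, ext2, head2, spaces2 = load_checkpoint(path)
    assert cfg2.to_dict() == model_cfg.to_dict()
    assert spaces2.vocab == train.label_spaces.vocab
    for a, b in zip(iter_parameters(extractor), iter_parameters(ext2)):
        np.testing.assert_array_equal(a.data, b.data)
    for a, b in zip(iter_parameters(head["mlps"]), iter_parameters(head2["mlps"])):
        np.testing.assert_array_equal(a.data, b.data)
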