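"""Network forward/backward correctness, training behavior, checkpoints."""

import numpy as np
import pytest

from ddicnn.cnn import (
    Adam,
    CNNDDIClassifier,
    convolve,
    forward,
    loss_and_grads,
    pool_max,
    relu,
    softmax,
)
from ddicnn.corpus import ClassLabel
from ddicnn.preprocess import BlindedInstance
from ddicnn.simulate import GeneratorConfig, generate_corpus
from ddicnn.preprocess import corpus_to_instances


def _tiny_setup(seed=0, B=2, n=6, me=4, md=2, m=3, V=11, widths=(2, 3), dtype=float):
    rng = np.random.default_rng(seed)
    D = me + 2 * md
    k = 5
    params = {
        "We": rng.normal(size=(V, me)).astype(dtype),
        "Wd1": rng.normal(size=(2 * n - 1, md)).astype(dtype),
        "Wd2": rng.normal(size=(2 * n - 1, md)).astype(dtype),
        "Ws": (rng.normal(size=(m * len(widths), k)) * 0.3).astype(dtype),
        "d": (rng.normal(size=k) * 0.1).astype(dtype),
    }
    for w in widths:
        params[f"F{w}"] = (rng.normal(size=(m, w * D)) * 0.3).astype(dtype)
        params[f"b{w}"] = (rng.normal(size=m) * 0.1).astype(dtype)
    batch = {
        "word": rng.integers(0, V, size=(B, n)),
        "q1": rng.integers(0, 2 * n - 1, size=(B, n)),
        "q2": rng.integers(0, 2 * n - 1, size=(B, n)),
        "y": rng.integers(0, k, size=B),
    }
    return params, batch, widths


def test_convolve_zero_filter_gives_zero_scores():
    X = np.ones((8, 3))
    s = convolve(X, np.zeros((2, 3)), b=0.0)
    assert s.shape == (7,)
    assert np.all(s == 0)


def test_convolve_hand_computed_inner_products():
    # all-ones X of width 4, w=2, all-ones filter, b=-3: ReLU(8 - 3) = 5
    X = np.ones((5, 4))
    s = convolve(X, np.ones((2, 4)), b=-3.0)
    np.testing.assert_array_equal(s, np.full(4, 5.0))


def test_convolve_output_length_and_width_error():
    X = np.zeros((128, 2))
    assert convolve(X, np.zeros((6, 2))).shape == (123,)
    with pytest.raises(ValueError):
        convolve(np.zeros((3, 2)), np.zeros((4, 2)))


def test_pool_max_properties():
    assert pool_max([0.0, 5.0, 3.0]) == 5.0
    assert pool_max([2.0, 2.0, 2.0]) == 2.0
    rng = np.random.default_rng(0)
    s = rng.normal(size=17)
    assert pool_max(s) == pool_max(rng.permutation(s))
    bumped = s.copy()
    bumped[3] += 1.0
    assert pool_max(bumped) >= pool_max(s)
    with pytest.raises(ValueError):
        pool_max([])


def test_forward_probabilities_normalize_across_seeds():
    for seed in range(20):
        params, batch, widths = _tiny_setup(seed=seed, B=4)
        trace = forward(batch, params, widths, train=False)
        np.testing.assert_allclose(trace["probs"].sum(axis=1), 1.0, atol=1e-6)
        assert np.all(trace["probs"] >= 0)


def test_forward_zero_softmax_layer_gives_uniform_fifths():
    params, batch, widths = _tiny_setup()
    params["Ws"][:] = 0.0
    params["d"][:] = 0.0
    trace = forward(batch, params, widths, train=False)
    np.testing.assert_allclose(trace["probs"], 0.2, atol=1e-12)


def test_train_forward_with_all_ones_mask_equals_eval_forward():
    params, batch, widths = _tiny_setup()
    eval_trace = forward(batch, params, widths, train=False)
    mask = np.ones_like(eval_trace["z"])
    train_trace = forward(batch, params, widths, train=True, dropout=0.5, dropout_mask=mask)
    np.testing.assert_array_equal(train_trace["o"], eval_trace["o"])


def test_loss_uniform_predictor_equals_n_log_k():
    params, batch, widths = _tiny_setup(B=8)
    params["Ws"][:] = 0.0
    params["d"][:] = 0.0
    J, _ = loss_and_grads(batch, params, widths, l2=0.0, return_grads=False)
    assert J == pytest.approx(8 * np.log(5), rel=1e-6)


def test_loss_perfect_prediction_approaches_zero():
    params, batch, widths = _tiny_setup(B=3)
    params["Ws"][:] = 0.0
    # give every instance the same label and drive its bias up:
    # probability -> 1, cross-entropy -> 0
    params["d"][:] = -50.0
    batch["y"][:] = 2
    params["d"][2] = 50.0
    J, _ = loss_and_grads(batch, params, widths, l2=0.0, return_grads=False)
    assert J == pytest.approx(0.0, abs=1e-8)


def test_loss_with_l2_adds_squared_norm_of_softmax_weights():
    params, batch, widths = _tiny_setup()
    J0, _ = loss_and_grads(batch, params, widths, l2=0.0, return_grads=False)
    J3, _ = loss_and_grads(batch, params, widths, l2=3.0, return_grads=False)
    assert J3 - J0 == pytest.approx(3.0 * float(np.sum(params["Ws"] ** 2)), rel=1e-6)


def test_gradients_match_central_differences_everywhere():
    """Analytic gradients vs central differences on the tiny model
    (n=6, me=4, md=2, widths {2,3}, m=3), fixed dropout mask, double precision."""
    params, batch, widths = _tiny_setup(B=2)
    rng = np.random.default_rng(7)
    mask = (rng.random((2, 6)) >= 0.5) / 0.5
    J, grads = loss_and_grads(batch, params, widths, l2=3.0, dropout_mask=mask)
    eps = 1e-6
    worst = 0.0
    for key, P in params.items():
        it = np.nditer(P, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = P[idx]
            P[idx] = orig + eps
            Jp, _ = loss_and_grads(batch, params, widths, l2=3.0,
                                   dropout_mask=mask, return_grads=False)
            P[idx] = orig - eps
            Jm, _ = loss_and_grads(batch, params, widths, l2=3.0,
                                   dropout_mask=mask, return_grads=False)
            P[idx] = orig
            num = (Jp - Jm) / (2 * eps)
            ana = grads[key][idx]
            rel = abs(num - ana) / max(abs(num), abs(ana), 1e-8)
            worst = max(worst, rel)
    assert worst < 1e-4


@pytest.fixture(scope="module")
def train_instances():
    cfg = GeneratorConfig(n_documents=20, include_secondary_pairs=False)
    docs = generate_corpus(cfg, seed=3)
    instances, _ = corpus_to_instances(docs)
    return instances


def test_training_is_seed_deterministic(train_instances, tiny_model_config):
    a = CNNDDIClassifier(**tiny_model_config).fit(train_instances)
    b = CNNDDIClassifier(**tiny_model_config).fit(train_instances)
    for key in a.params_:
        np.testing.assert_array_equal(a.params_[key], b.params_[key])
    assert a.history_ == b.history_


def test_zero_epochs_leaves_initialization_untouched(train_instances, tiny_model_config):
    cfg = dict(tiny_model_config, epochs=0)
    est = CNNDDIClassifier(**cfg).fit(train_instances)
    fresh = CNNDDIClassifier(**cfg)
    fresh.n_ = est.n_
    fresh.vocab_ = est.vocab_
    rng = np.random.default_rng(cfg["seed"])
    init = fresh._init_params(rng)
    for key in est.params_:
        np.testing.assert_array_equal(est.params_[key], init[key])


def test_predictions_invariant_to_batch_partitioning(train_instances, tiny_model_config):
    est = CNNDDIClassifier(**tiny_model_config).fit(train_instances)
    preds_full = est.predict(train_instances)
    est.batch_size = 7
    preds_small = est.predict(train_instances)
    assert preds_full == preds_small


def test_argmax_tie_breaks_to_lowest_class_index():
    probs = np.array([0.2, 0.2, 0.2, 0.2, 0.2])
    assert int(probs.argmax()) == 0
    assert ClassLabel.from_index(int(np.array([0.1, 0.6, 0.1, 0.1, 0.1]).argmax())) \
        == ClassLabel.EFFECT


def test_large_l2_shrinks_softmax_weights_monotonically(train_instances, tiny_model_config):
    cfg = dict(tiny_model_config, l2=1000.0, epochs=4)
    est = CNNDDIClassifier(**cfg)
    # record ||Ws|| after each epoch by re-running with increasing epoch counts
    norms = []
    for epochs in (0, 1, 2, 3, 4):
        est = CNNDDIClassifier(**dict(cfg, epochs=epochs)).fit(train_instances)
        norms.append(float(np.linalg.norm(est.params_["Ws"])))
    assert all(b < a for a, b in zip(norms, norms[1:]))


def test_checkpoint_round_trip_is_exact(tmp_path, train_instances, tiny_model_config):
    est = CNNDDIClassifier(**tiny_model_config).fit(train_instances)
    path = tmp_path / "model.ckpt"
    est.save(path)
    back = CNNDDIClassifier.load(path)
    assert back.get_params() == est.get_params()
    assert back.vocab_ == est.vocab_ and back.n_ == est.n_
    for key in est.params_:
        np.testing.assert_array_equal(back.params_[key], est.params_[key])
    assert back.predict(train_instances) == est.predict(train_instances)


def test_fit_on_empty_set_is_an_error():
    with pytest.raises(ValueError):
        CNNDDIClassifier().fit([])
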