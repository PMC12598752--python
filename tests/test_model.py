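"""Architecture contracts and training behavior of the pair classifier."""

import numpy as np
import pytest

from cofracnet.classifier import PPIClassifier, assemble_input, co_train
from cofracnet.elution import ElutionMatrix
from cofracnet.fcgr import FCGRMatrix
from cofracnet.nn import ModelConfig, PairScoringNetwork, default_fc_sizes

# small geometry for fast unit tests: 20 profile + 16 sequence columns
TINY = dict(input_len=36, seq_offset=20)
TINY_CFG = dict(n_filters=3, kernel_width=3, fc_sizes=(16, 8, 1), seed=0)


def tiny_net(**overrides):
    cfg = ModelConfig(**{**TINY_CFG, **overrides})
    return PairScoringNetwork(n_proteins=12, config=cfg, **TINY)


def tiny_features(seed=0):
    return np.random.default_rng(seed).uniform(0, 1, size=(12, 36))


# ---------------------------------------------------------------------------
# input assembly


def padded_elution(ids, n=4, width=200):
    values = np.zeros((len(ids), width))
    values[:, :n] = 1.0 / n
    return ElutionMatrix(
        list(ids), values, original_fractions=n, normalized=True, padded_to=width
    )


def fcgr_matrix(ids, seed=0):
    rng = np.random.default_rng(seed)
    return FCGRMatrix(list(ids), rng.uniform(0, 1, size=(len(ids), 256)))


def test_assembled_width_is_456():
    ids = ["a", "b", "c"]
    X = assemble_input(padded_elution(ids), fcgr_matrix(ids))
    assert X.shape == (3, 456)


def test_zero_embedding_is_plain_concatenation():
    ids = ["a", "b"]
    E, S = padded_elution(ids), fcgr_matrix(ids)
    X = assemble_input(E, S, C=np.zeros_like(S.vectors))
    np.testing.assert_array_equal(X[:, :200], E.values)
    np.testing.assert_array_equal(X[:, 200:], S.vectors)


def test_row_permutation_equivariance():
    ids = ["a", "b", "c"]
    E, S = padded_elution(ids), fcgr_matrix(ids)
    X = assemble_input(E, S)
    perm_ids = ["c", "a", "b"]
    order = [ids.index(p) for p in perm_ids]
    Ep = ElutionMatrix(
        perm_ids, E.values[order], original_fractions=4,
        normalized=True, padded_to=200,
    )
    Sp = FCGRMatrix(perm_ids, S.vectors[order])
    np.testing.assert_array_equal(assemble_input(Ep, Sp), X[order])


def test_id_mismatch_rejected():
    with pytest.raises(ValueError, match="mismatch"):
        assemble_input(padded_elution(["a", "b"]), fcgr_matrix(["a", "x"]))


# ---------------------------------------------------------------------------
# forward-pass contracts


def test_scores_strictly_inside_unit_interval():
    net = tiny_net()
    s = net.score_pairs(tiny_features(), [(0, 1), (2, 3), (4, 11)])
    assert np.all((s > 0) & (s < 1))


def test_self_pair_score_identical_across_proteins():
    net = tiny_net()
    s = net.score_pairs(tiny_features(), [(0, 0), (3, 3), (7, 7)])
    assert s[0] == pytest.approx(s[1]) == pytest.approx(s[2])


def test_pair_order_invariance():
    net = tiny_net()
    X = tiny_features()
    rng = np.random.default_rng(1)
    pairs = [(int(a), int(b)) for a, b in rng.integers(0, 12, size=(20, 2))]
    fwd = net.score_pairs(X, pairs)
    rev = net.score_pairs(X, [(b, a) for a, b in pairs])
    np.testing.assert_allclose(fwd, rev, atol=1e-12)


def test_conv_calls_scale_with_proteins_not_pairs():
    net = tiny_net()
    X = tiny_features()
    all_pairs = [(i, j) for i in range(10) for j in range(i + 1, 10)]
    assert len(all_pairs) == 45
    before = net.n_conv_calls_
    net.score_pairs(X, all_pairs)
    assert net.n_conv_calls_ - before == 12  # one pass over protein rows


def test_conv_parameter_count_independent_of_pairs():
    net = tiny_net()
    assert net.conv_parameter_count() == 3 * 3 + 3  # kernel_width*F + F biases
    # a pair-level convolution over stacked pairs doubles the kernel weights
    assert 2 * net.params["conv_w"].size == 2 * 3 * 3


def test_pair_index_out_of_range():
    net = tiny_net()
    with pytest.raises(IndexError):
        net.score_pairs(tiny_features(), [(0, 99)])


# ---------------------------------------------------------------------------
# training


def separable_problem(seed=0):
    """Two feature blocks; within-block pairs positive."""
    rng = np.random.default_rng(seed)
    X = np.zeros((12, 36))
    X[:6, :10] = rng.uniform(0.6, 1.0, size=(6, 10))
    X[6:, 10:20] = rng.uniform(0.6, 1.0, size=(6, 10))
    X[:, 20:] = rng.uniform(0, 0.2, size=(12, 16))
    pairs, y = [], []
    for i in range(12):
        for j in range(i + 1, 12):
            pairs.append((i, j))
            y.append(int((i < 6) == (j < 6)))
    return X, np.array(pairs), np.array(y)


def test_training_reduces_loss_and_separates():
    X, pairs, y = separable_problem()
    net = tiny_net(dropout_rate=0.0)
    net.fit(X, pairs, y, epochs=150)
    assert net.loss_history_[-1] < 0.5 * net.loss_history_[0]
    scores = net.score_pairs(X, pairs)
    auc_ordering = scores[y == 1].mean() - scores[y == 0].mean()
    assert auc_ordering > 0.2


def test_seeded_training_deterministic():
    X, pairs, y = separable_problem()
    runs = [tiny_net().fit(X, pairs, y, epochs=20).loss_history_ for _ in range(2)]
    assert runs[0] == runs[1]


def test_embedding_receives_gradient():
    net = tiny_net()
    X = tiny_features()
    before = net.params["embedding"].copy()
    rng = np.random.default_rng(0)
    net.train_step(X, np.array([[0, 1]]), np.array([1.0]), rng)
    assert not np.allclose(net.params["embedding"], before)


def test_even_kernel_rejected():
    with pytest.raises(ValueError, match="odd"):
        ModelConfig(kernel_width=4)


def test_default_fc_taper_monotone():
    sizes = default_fc_sizes(456 * 33)
    assert sizes[0] > sizes[1] > sizes[2] == 1


def test_checkpoint_roundtrip(tmp_path):
    X, pairs, y = separable_problem()
    net = tiny_net().fit(X, pairs, y, epochs=5)
    path = tmp_path / "model.npz"
    net.save(path)
    back = PairScoringNetwork.load(path)
    np.testing.assert_array_equal(
        net.score_pairs(X, pairs[:10]), back.score_pairs(X, pairs[:10])
    )


# ---------------------------------------------------------------------------
# estimator interface


def test_estimator_fit_predict_and_params():
    X, pairs, y = separable_problem()
    clf = PPIClassifier(
        n_filters=3, kernel_width=3, fc_sizes=(16, 8, 1), epochs=10,
        seq_offset=20, seed=0,
    )
    clf.fit(pairs, y, features=X)
    proba = clf.predict_proba(pairs[:5])
    assert proba.shape == (5, 2)
    np.testing.assert_allclose(proba.sum(axis=1), 1.0)
    assert set(clf.predict(pairs[:5])) <= {0, 1}
    assert clf.get_params()["n_filters"] == 3
    clone_params = PPIClassifier(**clf.get_params()).get_params()
    assert clone_params == clf.get_params()


def test_estimator_requires_features():
    clf = PPIClassifier()
    with pytest.raises(ValueError, match="feature"):
        clf.fit(np.array([[0, 1]]), np.array([1]))


# ---------------------------------------------------------------------------
# co-training


def co_dataset(seed, n=14, width=36):
    rng = np.random.default_rng(seed)
    X = rng.uniform(0, 1, size=(n, width))
    pairs = rng.integers(0, n, size=(seed * 100 + 300, 2))
    pairs = pairs[pairs[:, 0] != pairs[:, 1]]
    y = rng.integers(0, 2, size=len(pairs))
    return X, pairs, y


def test_co_training_downsamples_to_smallest():
    cfg = ModelConfig(**{**TINY_CFG, "epochs": 2, "use_embedding": False})
    datasets = [co_dataset(s) for s in (1, 3, 5)]
    smallest = min(len(d[1]) for d in datasets)
    net = co_train(datasets, cfg)
    assert net.pairs_per_dataset_ == [smallest] * 3
    assert "embedding" not in net.params


def test_co_training_single_dataset_degenerates_to_plain_fit():
    cfg = ModelConfig(**{**TINY_CFG, "epochs": 3, "use_embedding": False})
    net = co_train([co_dataset(2)], cfg)
    assert net.fitted_ and len(net.loss_history_) == 3


def test_co_training_mixed_fraction_counts_after_padding():
    """Two 'species' with 27 and 61 measured fractions, both padded to 200."""
    rng = np.random.default_rng(0)

    def species(n_fractions, seed):
        X = np.zeros((10, 456))
        X[:, :n_fractions] = rng.uniform(0, 1, size=(10, n_fractions))
        X[:, 200:] = rng.uniform(0, 1, size=(10, 256))
        pairs = np.array([(i, j) for i in range(10) for j in range(i + 1, 10)])
        y = rng.integers(0, 2, size=len(pairs))
        return X, pairs, y

    cfg = ModelConfig(
        n_filters=2, kernel_width=3, fc_sizes=(8, 4, 1), epochs=1,
        use_embedding=False, seed=0,
    )
    net = co_train([species(27, 1), species(61, 2)], cfg)
    s = net.score_pairs(species(27, 3)[0], [(0, 1)])
    assert 0 < s[0] < 1


def test_co_training_incompatible_widths_rejected():
    cfg = ModelConfig(**{**TINY_CFG, "epochs": 1, "use_embedding": False})
    a = co_dataset(1)
    b = co_dataset(2, width=40)
    with pytest.raises(ValueError, match="width"):
        co_train([a, b], cfg)
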