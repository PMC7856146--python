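import math

import numpy as np
import pytest

from cdmnet.cotrain_ann import (
    NetworkConfig,
    forward,
    init_weights,
    loss,
    loss_and_grads,
    make_split,
    select_lambda,
    train_ensemble,
    train_member,
)
from cdmnet.latent_structure import enumerate_classes, ideal_response_matrix, one_hot_matrix
from cdmnet.simulate import build_qmatrix


def _toy_loss_by_hand(w, X, Y1, Y2, lam):
    """Scalar recomputation of the cost with plain Python loops."""

    def relu(v):
        return [max(x, 0.0) for x in v]

    def softmax(v):
        m = max(v)
        e = [math.exp(x - m) for x in v]
        s = sum(e)
        return [x / s for x in e]

    def affine(x, W, b):
        return [sum(x[i] * W[i][j] for i in range(len(x))) + b[j] for j in range(len(b))]

    total = 0.0
    for row, y1, y2 in zip(X, Y1, Y2):
        h1 = relu(affine(row, w.W1.tolist(), w.b1.tolist()))
        h2 = relu(affine(h1, w.W2.tolist(), w.b2.tolist()))
        t = softmax(affine(h2, w.W3.tolist(), w.b3.tolist()))
        M1 = [softmax(r) for r in w.V1.tolist()]
        M2 = [softmax(r) for r in w.V2.tolist()]
        C = len(t)
        head1 = [sum(t[j] * M1[j][k] for j in range(C)) for k in range(C)]
        head2 = [sum(t[j] * M2[j][k] for j in range(C)) for k in range(C)]
        zr = [sum(t[j] * w.Wr.tolist()[j][i] for j in range(C)) + w.br.tolist()[i] for i in range(len(row))]
        xr = [1.0 / (1.0 + math.exp(-z)) for z in zr]
        ce1 = -sum(a * math.log(b) for a, b in zip(y1, head1))
        ce2 = -sum(a * math.log(b) for a, b in zip(y2, head2))
        cer = -sum(x * math.log(p) + (1 - x) * math.log(1 - p) for x, p in zip(row, xr))
        total += ce1 + ce2 + lam * cer
    return total / len(X)


@pytest.fixture
def labelled_fixture():
    """Small separable dataset: simple-structure items, DINA labels = truth."""
    rng = np.random.default_rng(17)
    space = enumerate_classes(3)
    Q_entries = np.tile(np.eye(3, dtype=np.int8), (3, 1))
    from cdmnet.latent_structure import QMatrix

    Q = QMatrix(Q_entries)
    eta = ideal_response_matrix(space, Q, "DINA")
    labels = rng.integers(1, 9, size=240)
    flip = rng.random((240, 9)) < 0.05
    X = np.abs(eta[labels - 1] - flip).astype(float)
    Y = one_hot_matrix(labels, 8)
    split = make_split(240, rng)
    return X, Y, labels, split


class TestForward:
    def test_output_dimensions_for_thirty_item_four_attribute_form(self, rng):
        cfg = NetworkConfig()
        w = init_weights(30, 16, rng, cfg)
        out = forward(np.zeros((5, 30)), w)
        # output layer: 16 + 16 + 30 = 62 nodes
        assert out["head1"].shape == (5, 16)
        assert out["head2"].shape == (5, 16)
        assert out["reconstruction"].shape == (5, 30)
        assert w.W1.shape == (30, 200) and w.W2.shape == (200, 100)

    def test_distributions_normalize(self, rng, small_net_config):
        w = init_weights(12, 8, rng, small_net_config)
        X = (np.random.default_rng(1).random((20, 12)) < 0.5).astype(float)
        out = forward(X, w)
        np.testing.assert_allclose(out["class_posterior"].sum(axis=1), 1.0, atol=1e-10)
        np.testing.assert_allclose(out["head1"].sum(axis=1), 1.0, atol=1e-10)
        np.testing.assert_allclose(out["head2"].sum(axis=1), 1.0, atol=1e-10)
        assert ((out["reconstruction"] > 0) & (out["reconstruction"] < 1)).all()


class TestLoss:
    def test_matches_straight_line_recomputation(self, toy_weights, toy_batch):
        X, Y1, Y2 = toy_batch
        for lam in (0.0, 0.5, 1.3):
            out = forward(X, toy_weights)
            expected = _toy_loss_by_hand(toy_weights, X.tolist(), Y1.tolist(), Y2.tolist(), lam)
            assert loss(out, Y1, Y2, X, lam) == pytest.approx(expected, rel=1e-12)

    def test_zero_lambda_drops_reconstruction_term(self, toy_weights, toy_batch):
        X, Y1, Y2 = toy_batch
        out = forward(X, toy_weights)
        out_perturbed = dict(out)
        out_perturbed["reconstruction"] = np.full_like(out["reconstruction"], 0.5)
        assert loss(out, Y1, Y2, X, 0.0) == pytest.approx(
            loss(out_perturbed, Y1, Y2, X, 0.0)
        )

    def test_perfect_head_contributes_zero(self, toy_batch):
        X, Y1, Y2 = toy_batch
        out = {
            "head1": Y1.astype(float),
            "head2": Y2.astype(float),
            "reconstruction": np.full_like(X, 0.5),
        }
        assert loss(out, Y1, Y2, X, 0.0) == pytest.approx(0.0, abs=1e-9)

    def test_negative_lambda_rejected(self, toy_weights, toy_batch):
        X, Y1, Y2 = toy_batch
        with pytest.raises(ValueError):
            loss(forward(X, toy_weights), Y1, Y2, X, -0.1)


class TestGradients:
    def test_analytic_matches_central_differences_everywhere(self, toy_weights, toy_batch):
        X, Y1, Y2 = toy_batch
        lam = 0.7
        _, grads = loss_and_grads(toy_weights, X, Y1, Y2, lam)
        h = 1e-6
        for name, arr in toy_weights.arrays().items():
            numeric = np.zeros_like(arr)
            flat = arr.ravel()
            for idx in range(flat.size):
                orig = flat[idx]
                flat[idx] = orig + h
                up = loss(forward(X, toy_weights), Y1, Y2, X, lam)
                flat[idx] = orig - h
                down = loss(forward(X, toy_weights), Y1, Y2, X, lam)
                flat[idx] = orig
                numeric.ravel()[idx] = (up - down) / (2 * h)
            scale = max(np.abs(numeric).max(), 1.0)
            np.testing.assert_allclose(
                grads[name], numeric, atol=1e-5 * scale,
                err_msg=f"gradient mismatch in block {name}",
            )

    def test_full_batch_descent_reduces_training_loss(self, labelled_fixture, small_net_config):
        X, Y, _, _ = labelled_fixture
        rng = np.random.default_rng(5)
        w = init_weights(9, 8, rng, small_net_config)
        losses = []
        for _ in range(10):
            value, grads = loss_and_grads(w, X, Y, Y, 0.5)
            losses.append(value)
            for k, arr in w.arrays().items():
                arr -= 0.05 * grads[k]
        final, _ = loss_and_grads(w, X, Y, Y, 0.5)
        losses.append(final)
        assert losses[-1] < losses[0]


class TestSplit:
    def test_eighty_twenty_disjoint_exhaustive(self, rng):
        split = make_split(1000, rng)
        assert split.train_idx.size == 800 and split.valid_idx.size == 200
        union = np.union1d(split.train_idx, split.valid_idx)
        np.testing.assert_array_equal(union, np.arange(1000))

    def test_odd_sizes_within_one(self, rng):
        split = make_split(1001, rng)
        assert abs(split.train_idx.size - 0.8 * 1001) <= 1

    def test_overlap_rejected(self):
        from cdmnet.cotrain_ann import TrainSplit

        with pytest.raises(ValueError):
            TrainSplit(train_idx=np.array([0, 1]), valid_idx=np.array([1, 2]))


class TestTraining:
    def test_same_seed_same_weights(self, labelled_fixture, small_net_config):
        X, Y, _, split = labelled_fixture
        a = train_member(X, Y, Y, split, 0.5, small_net_config, seed=77)
        b = train_member(X, Y, Y, split, 0.5, small_net_config, seed=77)
        for k, arr in a["weights"].arrays().items():
            np.testing.assert_array_equal(arr, b["weights"].arrays()[k])
        np.testing.assert_array_equal(a["posterior"], b["posterior"])

    def test_best_epoch_no_worse_than_final(self, labelled_fixture, small_net_config):
        X, Y, _, split = labelled_fixture
        member = train_member(X, Y, Y, split, 0.5, small_net_config, seed=3)
        trajectory = member["val_trajectory"]
        assert member["best_val_loss"] == pytest.approx(min(trajectory))
        assert member["best_val_loss"] <= trajectory[-1]

    def test_separable_data_classified_correctly(self, labelled_fixture, small_net_config):
        X, Y, labels, split = labelled_fixture
        result = train_ensemble(X, Y, Y, split, 0.5, 3, small_net_config, seed=1)
        accuracy = (result.labels_whole == labels).mean()
        assert accuracy > 0.9

    def test_ensemble_posterior_rows_sum_to_one(self, labelled_fixture, small_net_config):
        X, Y, _, split = labelled_fixture
        result = train_ensemble(X, Y, Y, split, 0.5, 2, small_net_config, seed=2)
        np.testing.assert_allclose(result.ensemble_posterior.sum(axis=1), 1.0, atol=1e-8)

    def test_single_member_ensemble_equals_that_member(self, labelled_fixture, small_net_config):
        X, Y, _, split = labelled_fixture
        result = train_ensemble(X, Y, Y, split, 0.5, 1, small_net_config, seed=11)
        seed = int(np.random.SeedSequence(11).generate_state(1)[0] % (2**31))
        member = train_member(X, Y, Y, split, 0.5, small_net_config, seed)
        np.testing.assert_allclose(result.ensemble_posterior, member["posterior"], atol=1e-12)

    def test_members_agree_on_class_meaning(self, labelled_fixture, small_net_config):
        # anchored heads: member posteriors correlate positively class by class
        X, Y, _, split = labelled_fixture
        seeds = [int(s % (2**31)) for s in np.random.SeedSequence(4).generate_state(2)]
        posts = [
            train_member(X, Y, Y, split, 0.5, small_net_config, s)["posterior"] for s in seeds
        ]
        for c in range(8):
            r = np.corrcoef(posts[0][:, c], posts[1][:, c])[0, 1]
            assert r > 0.5

    def test_ensemble_averaging_stabilizes_accuracy(self, labelled_fixture, small_net_config):
        X, Y, labels, split = labelled_fixture
        accs = {1: [], 6: []}
        for M, seeds in ((1, range(5)), (6, range(5, 10))):
            for seed in seeds:
                res = train_ensemble(X, Y, Y, split, 0.5, M, small_net_config, seed)
                accs[M].append((res.labels_whole == labels).mean())
        assert np.var(accs[6]) <= np.var(accs[1]) + 1e-4

    def test_member_count_must_be_positive(self, labelled_fixture, small_net_config):
        X, Y, _, split = labelled_fixture
        with pytest.raises(ValueError):
            train_ensemble(X, Y, Y, split, 0.5, 0, small_net_config, seed=0)


class TestSelectLambda:
    def test_singleton_grid_short_circuits(self, labelled_fixture, small_net_config):
        X, Y, _, split = labelled_fixture
        assert select_lambda(X, Y, Y, split, grid=[0.25], config=small_net_config) == 0.25

    def test_selection_reproducible_and_from_grid(self, labelled_fixture, small_net_config):
        X, Y, _, split = labelled_fixture
        cfg = NetworkConfig(hidden=(16, 8), max_epochs=15, patience=4, dtype="float64")
        grid = (0.1, 1.0)
        a = select_lambda(X, Y, Y, split, grid, cfg, seed=6)
        b = select_lambda(X, Y, Y, split, grid, cfg, seed=6)
        assert a == b and a in grid

    def test_empty_grid_rejected(self, labelled_fixture, small_net_config):
        X, Y, _, split = labelled_fixture
        with pytest.raises(ValueError):
            select_lambda(X, Y, Y, split, grid=[], config=small_net_config)
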