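"""Factorization losses, gradients, training contracts and grid search."""

import math

import numpy as np
import pytest
from scipy.special import expit

from sidefactor.matrices import compute_weights
from sidefactor.models import (
    FactorModel,
    GRID_SEARCH_RANGES,
    SimilarityGraph,
    TrainConfig,
    fgrmf_loss,
    fgrmf_loss_grad,
    grid_search,
    init_model,
    lmf_loss,
    lmf_loss_grad,
    load_checkpoint,
    mf_loss,
    mf_loss_grad,
    predict_linear,
    predict_logistic,
    save_checkpoint,
    train,
)

def random_model(m, n, k, family, seed=0, scale=0.5):
    rng = np.random.default_rng(seed)
    return FactorModel(
        rng.normal(0, scale, (m, k)),
        rng.normal(0, scale, (n, k)),
        rng.normal(0, scale, m),
        rng.normal(0, scale, n),
        family,
    )


def all_pairs(m, n):
    return np.array([(i, j) for i in range(m) for j in range(n)])


# ---------------------------------------------------------------------------
# Predictions


class TestPredict:
    def test_bias_only_linear(self):
        model = FactorModel(np.zeros((1, 2)), np.zeros((1, 2)),
                            np.array([0.2]), np.array([0.3]), "mf")
        assert predict_linear(model, 0, 0) == pytest.approx(0.5)

    def test_dot_product(self):
        model = FactorModel(np.ones((1, 2)), np.ones((1, 2)),
                            np.zeros(1), np.zeros(1), "mf")
        assert predict_linear(model, 0, 0) == pytest.approx(2.0)

    def test_linear_matches_bruteforce_on_random_model(self):
        model = random_model(5, 4, 3, "mf", seed=1)
        for i in range(5):
            for j in range(4):
                expected = (
                    sum(model.D[i, l] * model.S[j, l] for l in range(3))
                    + model.b_drug[i] + model.b_se[j]
                )
                assert predict_linear(model, i, j) == pytest.approx(expected)

    def test_sigmoid_at_zero_and_saturation(self):
        model = FactorModel(np.zeros((1, 1)), np.zeros((1, 1)),
                            np.zeros(1), np.zeros(1), "logistic_mf")
        assert predict_logistic(model, 0, 0) == pytest.approx(0.5)
        hot = FactorModel(np.zeros((2, 1)), np.zeros((1, 1)),
                          np.array([20.0, -20.0]), np.zeros(1), "logistic_mf")
        assert predict_logistic(hot, 0, 0) == pytest.approx(1.0, abs=1e-8)
        assert predict_logistic(hot, 1, 0) == pytest.approx(0.0, abs=1e-8)

    def test_sigmoid_agrees_with_log_domain_formula(self):
        model = random_model(4, 4, 2, "logistic_mf", seed=2, scale=3.0)
        for i in range(4):
            for j in range(4):
                z = model.D[i] @ model.S[j] + model.b_drug[i] + model.b_se[j]
                log_p = -np.logaddexp(0.0, -z)
                assert predict_logistic(model, i, j) == pytest.approx(
                    math.exp(log_p), abs=1e-12
                )

    def test_index_and_family_validation(self):
        model = random_model(2, 2, 1, "logistic_mf")
        with pytest.raises(IndexError):
            predict_logistic(model, 5, 0)
        with pytest.raises(ValueError):
            predict_linear(model, 0, 0)


# ---------------------------------------------------------------------------
# Losses against brute-force oracles


def bruteforce_mf_loss(model, A, pairs, lam):
    total = 0.0
    for i, j in pairs:
        ahat = model.D[i] @ model.S[j] + model.b_drug[i] + model.b_se[j]
        total += (A[i, j] - ahat) ** 2
        total += lam * ((model.D[i] ** 2).sum() + (model.S[j] ** 2).sum())
    return total


def bruteforce_lmf_loss(model, A, W, pairs, lam):
    total = 0.0
    for i, j in pairs:
        p = expit(model.D[i] @ model.S[j] + model.b_drug[i] + model.b_se[j])
        p = min(max(p, 1e-12), 1 - 1e-12)
        total -= W[i, j] * (
            A[i, j] * math.log(p) + (1 - A[i, j]) * math.log(1 - p)
        )
        total += lam * ((model.D[i] ** 2).sum() + (model.S[j] ** 2).sum())
    return total


class TestLosses:
    def test_mf_zero_at_perfect_fit(self):
        model = FactorModel(np.zeros((2, 1)), np.zeros((2, 1)),
                            np.array([1.0, 0.0]), np.zeros(2), "mf")
        A = np.array([[1.0, 1.0], [0.0, 0.0]])
        assert mf_loss(model, A, all_pairs(2, 2), 0.0) == pytest.approx(0.0)

    def test_mf_single_pair_hand_value(self):
        model = FactorModel(np.zeros((1, 1)), np.zeros((1, 1)),
                            np.array([0.5]), np.zeros(1), "mf")
        A = np.array([[1.0]])
        assert mf_loss(model, A, np.array([[0, 0]]), 0.0) == pytest.approx(0.25)

    def test_mf_matches_bruteforce(self):
        model = random_model(3, 3, 2, "mf", seed=3)
        A = (np.random.default_rng(3).random((3, 3)) < 0.4).astype(float)
        pairs = all_pairs(3, 3)
        assert mf_loss(model, A, pairs, 0.005) == pytest.approx(
            bruteforce_mf_loss(model, A, pairs, 0.005), abs=1e-10
        )

    def test_lmf_closed_form_at_half(self):
        model = FactorModel(np.zeros((2, 2)), np.zeros((3, 2)),
                            np.zeros(2), np.zeros(3), "logistic_mf")
        A = np.zeros((2, 3))
        W = np.ones((2, 3))
        pairs = all_pairs(2, 3)
        assert lmf_loss(model, A, W, pairs, 0.0) == pytest.approx(
            6 * math.log(2), abs=1e-12
        )

    def test_lmf_matches_bruteforce_with_count_weights(self, toy_counts):
        rng = np.random.default_rng(4)
        model = random_model(4, 5, 2, "logistic_mf", seed=4)
        counts = rng.integers(0, 10, (4, 5))
        A = (counts >= 3).astype(float)
        from sidefactor.matrices import WeightMatrix
        import scipy.sparse as sp

        Wm = WeightMatrix(sp.csr_matrix(counts), 3, 10.0, 0.8)
        W = Wm.dense()
        pairs = all_pairs(4, 5)
        assert lmf_loss(model, A, W, pairs, 0.005) == pytest.approx(
            bruteforce_lmf_loss(model, A, W, pairs, 0.005), abs=1e-10
        )

    def test_fgrmf_reduces_to_mf_at_mu_zero(self):
        model = random_model(3, 4, 2, "fgrmf", seed=5)
        A = np.eye(3, 4)
        graph = SimilarityGraph(np.eye(3))
        pairs = all_pairs(3, 4)
        assert fgrmf_loss(model, A, graph, pairs, 0.01, 0.0) == pytest.approx(
            mf_loss(model, A, pairs, 0.01), abs=1e-12
        )

    def test_fgrmf_graph_term_zero_for_identical_factors(self):
        D = np.tile(np.array([[1.0, 2.0]]), (2, 1))
        model = FactorModel(D, np.zeros((2, 2)), np.zeros(2), np.zeros(2),
                            "fgrmf")
        graph = SimilarityGraph(np.ones((2, 2)))
        A = np.zeros((2, 2))
        pairs = all_pairs(2, 2)
        with_graph = fgrmf_loss(model, A, graph, pairs, 0.0, 5.0)
        without = mf_loss(model, A, pairs, 0.0)
        assert with_graph == pytest.approx(without, abs=1e-12)

    def test_fgrmf_matches_hand_expanded_regularizer(self):
        model = random_model(3, 2, 2, "fgrmf", seed=6)
        sim = np.array([[1.0, 0.5, 0.2], [0.5, 1.0, 0.1], [0.2, 0.1, 1.0]])
        graph = SimilarityGraph(sim)
        A = np.zeros((3, 2))
        pairs = all_pairs(3, 2)
        reg = sum(
            sim[i, ip] * ((model.D[i] - model.D[ip]) ** 2).sum()
            for i in range(3)
            for ip in range(3)
        )
        expected = bruteforce_mf_loss(model, A, pairs, 0.001) + 2.0 * reg
        assert fgrmf_loss(model, A, graph, pairs, 0.001, 2.0) == pytest.approx(
            expected, abs=1e-10
        )

    def test_empty_pair_set_rejected(self):
        model = random_model(2, 2, 1, "mf")
        with pytest.raises(ValueError):
            mf_loss(model, np.zeros((2, 2)), np.zeros((2, 2), dtype=bool), 0.0)


# ---------------------------------------------------------------------------
# Gradient checks


def numeric_grad(f, arr, eps=1e-6):
    g = np.zeros_like(arr, dtype=float)
    it = np.nditer(arr, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        orig = arr[idx]
        arr[idx] = orig + eps
        hi = f()
        arr[idx] = orig - eps
        lo = f()
        arr[idx] = orig
        g[idx] = (hi - lo) / (2 * eps)
    return g


def check_gradients(loss_grad, model, *args):
    _, grads = loss_grad(model, *args)
    for name, arr in (("D", model.D), ("S", model.S),
                      ("b_drug", model.b_drug), ("b_se", model.b_se)):
        num = numeric_grad(lambda: loss_grad(model, *args)[0], arr)
        denom = max(np.abs(num).max(), np.abs(grads[name]).max(), 1e-8)
        rel = np.abs(grads[name] - num).max() / denom
        assert rel <= 1e-5, f"{name}: relative error {rel}"


class TestGradients:
    def setup_method(self):
        rng = np.random.default_rng(9)
        self.m, self.n, self.k = 6, 8, 3
        self.A = (rng.random((self.m, self.n)) < 0.3).astype(float)
        counts = np.where(self.A > 0, rng.integers(3, 20, self.A.shape), 0)
        from sidefactor.matrices import WeightMatrix
        import scipy.sparse as sp

        self.W = WeightMatrix(sp.csr_matrix(counts), 3, 10.0, 0.8).dense()
        self.pairs = all_pairs(self.m, self.n)

    def test_mf_gradients(self):
        model = random_model(self.m, self.n, self.k, "mf", seed=10)
        check_gradients(mf_loss_grad, model, self.A, self.pairs, 0.005)

    def test_lmf_gradients(self):
        model = random_model(self.m, self.n, self.k, "logistic_mf", seed=11)
        check_gradients(lmf_loss_grad, model, self.A, self.W, self.pairs, 0.005)

    def test_fgrmf_gradients(self):
        rng = np.random.default_rng(12)
        raw = rng.random((self.m, self.m))
        sim = 0.5 * (raw + raw.T)
        np.fill_diagonal(sim, 1.0)
        model = random_model(self.m, self.n, self.k, "fgrmf", seed=12)
        check_gradients(
            fgrmf_loss_grad, model, self.A, SimilarityGraph(sim),
            self.pairs, 0.001, 0.01,
        )

    def test_per_param_penalty_gradients(self):
        model = random_model(self.m, self.n, self.k, "mf", seed=13)
        check_gradients(
            mf_loss_grad, model, self.A, self.pairs, 0.01, "per_param"
        )


# ---------------------------------------------------------------------------
# Training


class TestTrain:
    def test_loss_drops_tenfold_on_learnable_world(self, small_world,
                                                   small_split):
        A, split = small_split
        W = compute_weights(small_world.counts, 3, 0.0, 1.0)
        cfg = TrainConfig(k=4, lambda_l2=0.0, max_epochs=300,
                          patience=10**6, decay_patience=10**6,
                          lr_init=0.05, seed=0)
        _, hist = train("logistic_mf", A, split, cfg,
                        small_world.severe, W=W)
        assert hist.loss[-1] < hist.loss[0] / 10

    def test_same_seed_identical_history(self, small_world, small_split,
                                         quick_cfg):
        A, split = small_split
        W = compute_weights(small_world.counts, 3, 10.0, 0.8)
        m1, h1 = train("logistic_mf", A, split, quick_cfg,
                       small_world.severe, W=W)
        m2, h2 = train("logistic_mf", A, split, quick_cfg,
                       small_world.severe, W=W)
        assert h1.loss == h2.loss
        assert h1.val_metric == h2.val_metric
        np.testing.assert_array_equal(m1.D, m2.D)

    def test_patience_zero_stops_one_epoch_after_nonimprovement(
        self, small_world, small_split
    ):
        A, split = small_split
        W = compute_weights(small_world.counts, 3, 10.0, 0.8)
        cfg = TrainConfig(k=4, max_epochs=500, patience=0, lr_init=0.05,
                          seed=0)
        _, hist = train("logistic_mf", A, split, cfg, small_world.severe, W=W)
        # the run ends exactly one epoch after the last improvement
        assert len(hist.loss) == hist.best_epoch + 2

    def test_lr_sequence_nonincreasing_with_exact_decrements(
        self, small_world, small_split
    ):
        A, split = small_split
        W = compute_weights(small_world.counts, 3, 10.0, 0.8)
        cfg = TrainConfig(k=4, max_epochs=80, patience=30, decay_patience=3,
                          lr_init=0.05, lr_decay=0.1, seed=0)
        _, hist = train("logistic_mf", A, split, cfg, small_world.severe, W=W)
        lrs = np.array(hist.lr)
        assert np.all(np.diff(lrs) <= 0)
        changed = np.nonzero(np.diff(lrs))[0]
        for idx in changed:
            assert lrs[idx + 1] == pytest.approx(lrs[idx] * 0.1)

    def test_family_api_enforcement(self, small_world, small_split, quick_cfg):
        A, split = small_split
        W = compute_weights(small_world.counts, 3, 10.0, 0.8)
        with pytest.raises(ValueError):
            train("mf", A, split, quick_cfg, small_world.severe, W=W)
        with pytest.raises(ValueError):
            train("logistic_mf", A, split, quick_cfg, small_world.severe)
        with pytest.raises(ValueError):
            train("fgrmf", A, split, quick_cfg, small_world.severe)

    def test_separable_toy_reaches_log_loss_below_ln2_per_pair(self):
        # block-structured, perfectly separable associations
        import scipy.sparse as sp
        from sidefactor.matrices import AssociationMatrix, WeightMatrix
        from sidefactor.evaluation import SplitSpec

        A_arr = np.zeros((10, 12), dtype=np.int8)
        A_arr[:5, :6] = 1
        A_arr[5:, 6:] = 1
        A = AssociationMatrix(sp.csr_matrix(A_arr), 3,
                              tuple(f"d{i}" for i in range(10)),
                              tuple(f"s{j}" for j in range(12)))
        pos = np.argwhere(A_arr == 1)
        split = SplitSpec(np.arange(10), np.empty(0, int), pos,
                          np.empty((0, 2), int), np.empty((0, 2), int))
        W = WeightMatrix(sp.csr_matrix(3 * A_arr.astype(np.int64)), 3,
                         0.0, 1.0)
        cfg = TrainConfig(k=2, lambda_l2=0.0, max_epochs=400,
                          patience=10**6, lr_init=0.1, seed=0)
        _, hist = train("logistic_mf", A, split, cfg, [0, 1], W=W)
        assert hist.loss[-1] / A_arr.size < math.log(2)

    def test_mf_and_fgrmf_families_train(self, small_world, small_split,
                                         quick_cfg):
        A, split = small_split
        _, hist = train("mf", A, split, quick_cfg, small_world.severe)
        assert hist.loss[-1] < hist.loss[0]
        m = A.shape[0]
        graph = SimilarityGraph(np.eye(m))
        _, hist_g = train("fgrmf", A, split, quick_cfg, small_world.severe,
                          graph=graph)
        assert hist_g.loss[-1] < hist_g.loss[0]


class TestGridSearch:
    def test_default_grid_sizes(self):
        g = GRID_SEARCH_RANGES["logistic_mf"]
        assert len(g["lambda_l2"]) == 5
        assert len(g["alpha"]) == 6
        assert len(g["beta"]) == 5
        n_cells = (
            len(g["lambda_l2"]) * len(g["alpha"]) * len(g["beta"])
        )
        assert n_cells == 150

    def test_single_point_grid_returns_it(self, small_world, small_split,
                                          quick_cfg):
        A, split = small_split
        best, table = grid_search(
            "logistic_mf", {"lambda_l2": [0.005]}, A, split, quick_cfg,
            small_world.severe, counts=small_world.counts,
        )
        assert best == {"lambda_l2": 0.005}
        assert len(table) == 1

    def test_best_cell_matches_independent_reevaluation(
        self, small_world, small_split, quick_cfg
    ):
        A, split = small_split
        grids = {"lambda_l2": [0.001, 0.05], "beta": [0.4, 1.0]}
        best, table = grid_search(
            "logistic_mf", grids, A, split, quick_cfg, small_world.severe,
            counts=small_world.counts,
        )
        assert len(table) == 4
        # re-run every cell independently and compare the argmax
        metrics = []
        for row in table:
            cfg = TrainConfig(
                **{**quick_cfg.__dict__, "lambda_l2": row["lambda_l2"],
                   "beta": row["beta"]}
            )
            W = compute_weights(small_world.counts, 3, cfg.alpha, cfg.beta)
            _, hist = train("logistic_mf", A, split, cfg,
                            small_world.severe, W=W)
            metrics.append(max(hist.val_metric))
            assert max(hist.val_metric) == pytest.approx(row["val_metric"])
        top = table[int(np.argmax(metrics))]
        assert best == {k: top[k] for k in grids}


def test_checkpoint_roundtrip(tmp_path):
    model = random_model(4, 5, 3, "logistic_mf", seed=20)
    cfg = TrainConfig(k=3, seed=7)
    path = tmp_path / "ckpt.npz"
    save_checkpoint(model, path, cfg, ["d1", "d2", "d3", "d4"],
                    [f"s{j}" for j in range(5)])
    back, cfg2, drugs, ses = load_checkpoint(path)
    np.testing.assert_array_equal(back.D, model.D)
    np.testing.assert_array_equal(back.S, model.S)
    assert back.family == "logistic_mf"
    assert cfg2 == cfg
    assert drugs == ["d1", "d2", "d3", "d4"]
    assert len(ses) == 5


def test_init_model_is_seeded_and_small(small_world):
    a = init_model(10, 12, 3, "mf", seed=4)
    b = init_model(10, 12, 3, "mf", seed=4)
    np.testing.assert_array_equal(a.D, b.D)
    assert np.abs(a.D).max() < 1.0
    assert np.all(a.b_drug == 0)
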