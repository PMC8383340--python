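from dataclasses import replace

import numpy as np
import pytest

from resmnn.mnn import MNNPairSet
from resmnn.network import init_network
from resmnn.preprocess import PCAModel, ScaledMatrix
from resmnn.training import (PipelineConfig, TrainingConfig, TrainingError,
                             batch_loss, correct, loss_and_grad,
                             project_output, regularization_loss, total_loss,
                             train)

from oracles import batch_loss_bruteforce, project_bruteforce, reg_loss_bruteforce


def random_pca(rng, g, n_pc):
    q, _ = np.linalg.qr(rng.normal(size=(g, n_pc)))
    return PCAModel(components=q, center=rng.normal(size=g),
                    explained_variance=np.ones(n_pc))


def as_pairs(arr):
    return MNNPairSet(pairs=np.asarray(arr, dtype=np.int64))


class TestProjection:
    def test_identity_network_output_matches_input_embedding(self, rng):
        pca = random_pca(rng, 12, 4)
        x = rng.normal(size=(9, 12))
        np.testing.assert_array_equal(project_output(x, pca).coords,
                                      pca.project(x).coords)

    def test_center_projects_to_origin(self, rng):
        pca = random_pca(rng, 10, 3)
        y = np.tile(pca.center, (5, 1))
        np.testing.assert_allclose(project_output(y, pca).coords, 0,
                                   atol=1e-12)

    def test_matches_tripleloop_oracle(self, rng):
        pca = random_pca(rng, 8, 3)
        y = rng.normal(size=(6, 8))
        np.testing.assert_allclose(
            project_output(y, pca).coords,
            project_bruteforce(y, pca.center, pca.components), atol=1e-10)

    def test_uncentered_flag(self, rng):
        pca = random_pca(rng, 8, 3)
        y = rng.normal(size=(4, 8))
        np.testing.assert_allclose(project_output(y, pca, center=False).coords,
                                   y @ pca.components, atol=1e-12)


class TestLosses:
    def test_coincident_pairs_give_zero_batch_loss(self):
        coords = np.array([[1.0, 2.0], [1.0, 2.0], [0.0, 0.0], [0.0, 0.0]])
        assert batch_loss(coords, as_pairs([[0, 1], [2, 3]])) == 0.0

    def test_batch_loss_sums_euclidean_distances(self):
        coords = np.array([[0.0, 0.0], [3.0, 0.0], [0.0, 0.0], [0.0, 4.0]])
        assert batch_loss(coords, as_pairs([[0, 1], [2, 3]])) == pytest.approx(7.0)

    def test_batch_loss_matches_scalar_oracle(self, rng):
        coords = rng.normal(size=(100, 50))
        pairs = rng.choice(100, size=(50, 2), replace=True)
        pairs = pairs[pairs[:, 0] != pairs[:, 1]]
        assert batch_loss(coords, as_pairs(pairs)) == pytest.approx(
            batch_loss_bruteforce(coords, pairs), rel=1e-12)

    def test_empty_pairs_is_error(self, rng):
        with pytest.raises(TrainingError, match="empty"):
            batch_loss(rng.normal(size=(4, 2)), as_pairs(np.empty((0, 2))))

    def test_identity_has_zero_regularization(self, rng):
        x = rng.normal(size=(5, 7))
        assert regularization_loss(x, x) == 0.0

    def test_three_four_five(self):
        x = np.zeros((1, 2))
        y = np.array([[3.0, 4.0]])
        assert regularization_loss(y, x) == pytest.approx(5.0)

    def test_regularization_matches_scalar_oracle(self, rng):
        x, y = rng.normal(size=(30, 12)), rng.normal(size=(30, 12))
        assert regularization_loss(y, x) == pytest.approx(
            reg_loss_bruteforce(y, x), rel=1e-12)

    def test_shape_mismatch_is_error(self, rng):
        with pytest.raises(TrainingError, match="mismatch"):
            regularization_loss(rng.normal(size=(3, 4)), rng.normal(size=(3, 5)))

    def test_total_loss_combination(self):
        assert total_loss(5.0, 123.0, 0.0) == 5.0
        assert total_loss(2.0, 1000.0, 0.001) == pytest.approx(3.0)
        assert TrainingConfig().alpha == 0.001

    def test_loss_and_grad_consistent_with_scalar_losses(self, rng):
        pca = random_pca(rng, 10, 4)
        x = rng.normal(size=(12, 10))
        y = rng.normal(size=(12, 10))
        pairs = np.array([[0, 1], [2, 3], [4, 11]])
        lb, lr_, _ = loss_and_grad(y, x, pca, pairs, alpha=0.5)
        assert lb == pytest.approx(
            batch_loss(project_output(y, pca), as_pairs(pairs)), rel=1e-10)
        assert lr_ == pytest.approx(regularization_loss(y, x), rel=1e-10)


class TestSchedule:
    def test_step_decay_values(self):
        cfg = TrainingConfig()
        assert cfg.lr_at(0) == pytest.approx(0.1)
        assert cfg.lr_at(19) == pytest.approx(0.1)
        assert cfg.lr_at(20) == pytest.approx(0.08)
        assert cfg.lr_at(45) == pytest.approx(0.1 * 0.8 ** 2)  # = 0.064

    def test_invalid_config_rejected(self):
        with pytest.raises(TrainingError):
            TrainingConfig(alpha=-1)
        with pytest.raises(TrainingError):
            TrainingConfig(lr_decay=0.0)
        with pytest.raises(TrainingError):
            TrainingConfig(patience=0)
        with pytest.raises(TrainingError):
            TrainingConfig(reg_scope="everything")


def tiny_problem(rng, n=40, g=12, n_pc=5, n_pairs=15):
    """A small training problem: two shifted half-populations with pairs."""
    base = rng.normal(size=(n // 2, g))
    x = np.vstack([base, base + rng.normal(scale=2.0, size=g)])
    scaled = ScaledMatrix(values=x, hvg_ids=[f"g{j}" for j in range(g)],
                          mean=np.zeros(g), std=np.ones(g))
    pca = random_pca(rng, g, n_pc)
    idx = rng.choice(n // 2, size=n_pairs, replace=False)
    pairs = as_pairs(np.column_stack([idx, idx + n // 2]))
    return scaled, pca, pairs


class TestTrain:
    def test_loss_decreases_on_shifted_data(self, rng):
        scaled, pca, pairs = tiny_problem(rng)
        net = init_network(12, seed=0)
        cfg = TrainingConfig(seed=0, max_epochs=30, minibatch=8)
        net, hist = train(net, scaled, pca, pairs, cfg)
        assert hist.total_loss[hist.best_epoch] < hist.total_loss[0]
        assert hist.lr == [cfg.lr_at(e) for e in hist.epoch]

    def test_plateau_stops_after_patience(self, rng):
        # coincident pairs + alpha=0: the loss is exactly 0 every epoch, so
        # the first epoch is never improved upon and training stops at 11
        x = rng.normal(size=(10, 6))
        scaled = ScaledMatrix(values=np.vstack([x, x]), hvg_ids=list("abcdef"),
                              mean=np.zeros(6), std=np.ones(6))
        pca = random_pca(rng, 6, 3)
        pairs = as_pairs(np.column_stack([np.arange(10), np.arange(10) + 10]))
        net = init_network(6, seed=1)
        net, hist = train(net, scaled, pca, pairs,
                          TrainingConfig(alpha=0.0, seed=1, patience=10))
        assert hist.n_epochs == 11
        assert hist.reason == "early_stop"
        assert hist.best_epoch == 0
        np.testing.assert_allclose(hist.batch_loss, 0.0, atol=1e-5)

    def test_history_reproducible_given_seed(self, rng):
        scaled, pca, pairs = tiny_problem(rng)
        cfg = TrainingConfig(seed=7, max_epochs=12, minibatch=8)
        _, h1 = train(init_network(12, seed=7), scaled, pca, pairs, cfg)
        _, h2 = train(init_network(12, seed=7), scaled, pca, pairs, cfg)
        assert h1.total_loss == h2.total_loss
        assert h1.batch_loss == h2.batch_loss

    def test_mnn_pair_distance_shrinks_after_training(self, rng):
        scaled, pca, pairs = tiny_problem(rng, n=60, g=16, n_pairs=25)
        net = init_network(16, seed=3)
        pre = batch_loss(pca.project(scaled.values), pairs)
        net, _ = train(net, scaled, pca, pairs,
                       TrainingConfig(seed=3, max_epochs=40, minibatch=16))
        y = net.forward(scaled.values.astype(net.dtype))
        post = batch_loss(project_output(y, pca), pairs)
        assert post < pre

    def test_displacement_monotone_in_alpha(self, rng):
        scaled, pca, pairs = tiny_problem(rng, n=60, g=16, n_pairs=25)
        disps = []
        for alpha in (0.001, 1.0, 100.0):
            net = init_network(16, seed=5)
            net, _ = train(net, scaled, pca, pairs,
                           TrainingConfig(alpha=alpha, seed=5, max_epochs=25,
                                          minibatch=16))
            y = net.forward(scaled.values.astype(net.dtype))
            disps.append(float(np.linalg.norm(
                y - scaled.values, axis=1).mean()))
        assert disps[0] >= disps[1] >= disps[2]

    def test_divergence_reported_with_epoch(self, rng):
        scaled, pca, pairs = tiny_problem(rng)
        net = init_network(12, seed=0)
        with pytest.raises(TrainingError, match="epoch"):
            train(net, scaled, pca, pairs,
                  TrainingConfig(seed=0, lr0=1e18, max_epochs=5, minibatch=8))

    def test_no_pairs_is_error(self, rng):
        scaled, pca, _ = tiny_problem(rng)
        with pytest.raises(TrainingError, match="pairs"):
            train(init_network(12, seed=0), scaled, pca,
                  as_pairs(np.empty((0, 2))), TrainingConfig())

    def test_all_cells_reg_scope_runs(self, rng):
        scaled, pca, pairs = tiny_problem(rng)
        net = init_network(12, seed=0)
        _, hist = train(net, scaled, pca, pairs,
                        TrainingConfig(seed=0, max_epochs=5, minibatch=8,
                                       reg_scope="all_cells"))
        assert hist.n_epochs == 5
        assert all(l > 0 for l in hist.reg_loss)


class TestCorrectPipeline:
    def test_single_batch_rejected(self, small_data):
        one = small_data.subset(small_data.batch == "batch1")
        with pytest.raises(TrainingError, match="2 batches"):
            correct(one)

    def test_identical_batches_mix_after_correction(self, rng):
        # two copies of the same cells labelled as different batches: the
        # correction leaves nearly coincident copies nearly coincident
        from resmnn.metrics import build_knn_graph, label_entropy
        from resmnn.simulate import SyntheticConfig, generate

        data = generate(SyntheticConfig(
            n_batches=2, cells_per_batch=[150, 150], n_genes=300,
            n_celltypes=3, batch_shift_scale=0.0, seed=4))
        cfg = PipelineConfig(qc_min_genes_per_cell=5, qc_min_cells_per_gene=1,
                             n_hvg=150, n_pc=20, mnn_method="exact", seed=4,
                             training=TrainingConfig(seed=4, max_epochs=15,
                                                     minibatch=256))
        res = correct(data, cfg)
        graph = build_knn_graph(res.corrected_embedding, k=20)
        ent = label_entropy(graph, res.data.batch, 2)
        assert np.median(ent) > 0.8 * (np.log(2) / 2)

    def test_outputs_aligned_with_post_qc_cells(self, rng):
        from resmnn.simulate import SyntheticConfig, generate

        data = generate(SyntheticConfig(
            n_batches=2, cells_per_batch=[120, 120], n_genes=300,
            n_celltypes=2, seed=9))
        cfg = PipelineConfig(qc_min_genes_per_cell=5, qc_min_cells_per_gene=1,
                             n_hvg=100, n_pc=15, mnn_method="exact", seed=9,
                             training=TrainingConfig(seed=9, max_epochs=5,
                                                     minibatch=256))
        res = correct(data, cfg)
        n = res.data.n_cells
        assert res.corrected.shape == (n, 100)
        assert res.corrected_embedding.coords.shape == (n, 15)
        assert res.raw_embedding.coords.shape == (n, 15)
        assert res.history.n_epochs >= 1
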