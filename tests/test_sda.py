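"""Second-pass checks: supervector geometry, PCA, corruption,
reconstruction loss and its gradient, training behavior, and the
enhancer's mass-reallocation arithmetic."""

import numpy as np
import pytest

from eegevent.edf_io import ClassLabel
from eegevent.hmm import EpochPosteriorGrid
from eegevent.sda import (
    DEFAULT_HYPERPARAMS,
    DenoisingAutoencoderLayer,
    SdaHyperparams,
    SdaRole,
    apply_pca,
    augment_rare_class,
    average_triplets,
    build_epoch_vectors,
    build_network,
    corrupt,
    dae_loss,
    enhancer_combine,
    finetune_sda,
    fit_pca,
    init_layer,
    pretrain_sda,
    priority_vote,
    stack_window,
    _dae_grads,
)


def uniform_grid(n_epochs=5):
    return EpochPosteriorGrid(scores=np.full((n_epochs, 22, 6), 1 / 6))


class TestEpochVectors:
    def test_uniform_grid_values(self):
        vecs = build_epoch_vectors(uniform_grid())
        assert vecs.shape == (5, 132)
        assert np.allclose(vecs, 1 / 6)

    def test_dimension_132(self, rng):
        grid = EpochPosteriorGrid(scores=rng.dirichlet(np.ones(6),
                                                       size=(100, 22)))
        assert build_epoch_vectors(grid).shape == (100, 132)

    def test_channel_major_order(self, rng):
        scores = rng.dirichlet(np.ones(6), size=(3, 22))
        vecs = build_epoch_vectors(EpochPosteriorGrid(scores=scores))
        # channel 5's class block occupies columns 30..36
        assert np.allclose(vecs[:, 30:36], scores[:, 5, :])

    def test_class_permutation_permutes_blocks(self, rng):
        scores = rng.dirichlet(np.ones(6), size=(4, 22))
        perm = [3, 0, 5, 1, 4, 2]
        v1 = build_epoch_vectors(EpochPosteriorGrid(scores=scores[:, :, perm]))
        v2 = build_epoch_vectors(EpochPosteriorGrid(scores=scores))
        assert np.allclose(v1.reshape(4, 22, 6), v2.reshape(4, 22, 6)[:, :, perm])

    def test_wrong_channel_count_rejected(self, rng):
        grid = EpochPosteriorGrid(scores=rng.dirichlet(np.ones(6),
                                                       size=(4, 20)))
        with pytest.raises(ValueError):
            build_epoch_vectors(grid)


class TestWindows:
    def test_published_dimensions(self, rng):
        vecs = rng.random((50, 132))
        assert stack_window(vecs, 41).shape == (50, 5412)
        assert stack_window(rng.random((50, 20)), 41).shape == (50, 820)
        assert stack_window(rng.random((50, 13)), 3).shape == (50, 39)

    def test_window_one_identity(self, rng):
        vecs = rng.random((10, 7))
        assert np.allclose(stack_window(vecs, 1), vecs)

    def test_edge_replication(self, rng):
        vecs = rng.random((5, 4))
        out = stack_window(vecs, 3)
        # first epoch: left neighbor replicated -> first two blocks equal
        assert np.allclose(out[0, :4], out[0, 4:8])
        assert np.allclose(out[-1, 8:], out[-1, 4:8])

    def test_even_window_rejected(self, rng):
        with pytest.raises(ValueError):
            stack_window(rng.random((5, 4)), 4)


class TestTripletAveraging:
    def test_constant_unchanged(self):
        vecs = np.tile([1.0, 2.0], (6, 1))
        assert np.allclose(average_triplets(vecs), vecs)

    def test_impulse_spreads_one_third(self):
        vecs = np.zeros((3, 1))
        vecs[1, 0] = 1.0
        out = average_triplets(vecs)
        assert np.isclose(out[1, 0], 1 / 3)
        assert np.isclose(out[0, 0], 0.5)  # edge mean over two epochs

    def test_length_preserved(self, rng):
        vecs = rng.random((17, 13))
        assert average_triplets(vecs).shape == (17, 13)


class TestPca:
    def test_exact_subspace_reconstruction(self, rng):
        basis = rng.normal(size=(2, 40))
        coords = rng.normal(size=(60, 2))
        X = coords @ basis + 5.0
        p = fit_pca(X, 2)
        reduced = (X - p.mean) @ p.components.T
        recon = reduced @ p.components + p.mean
        assert np.max(np.abs(recon - X)) < 1e-8

    def test_output_dimension(self, rng):
        X = rng.random((200, 132))
        assert apply_pca(fit_pca(X, 13), X).shape == (200, 13)

    def test_orthonormal_rows(self, rng):
        p = fit_pca(rng.random((100, 30)), 10)
        assert np.allclose(p.components @ p.components.T, np.eye(10),
                           atol=1e-6)

    def test_scaled_outputs_in_unit_interval(self, rng):
        X = rng.normal(size=(150, 40))
        p = fit_pca(X, 5)
        out = apply_pca(p, rng.normal(size=(50, 40)))
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_beats_random_projections(self, rng):
        X = rng.normal(size=(120, 132)) * np.linspace(3, 0.1, 132)
        p = fit_pca(X, 13)
        reduced = (X - p.mean) @ p.components.T
        pca_err = np.sum((X - (reduced @ p.components + p.mean)) ** 2)
        for _ in range(100):
            Q, _ = np.linalg.qr(rng.normal(size=(132, 13)))
            proj = (X - X.mean(0)) @ Q
            err = np.sum((X - (proj @ Q.T + X.mean(0))) ** 2)
            assert pca_err <= err + 1e-9

    def test_excess_dim_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_pca(rng.random((10, 5)), 6)


class TestAugmentation:
    def test_factor_one_identity(self, rng):
        X = rng.random((20, 5))
        y = np.zeros(20, dtype=int)
        Xa, ya = augment_rare_class(X, y, 0, 1.0, rng)
        assert Xa.shape == X.shape and np.array_equal(ya, y)

    def test_count_arithmetic(self, rng):
        X = rng.random((120, 5))
        y = np.array([0] * 100 + [1] * 20)
        Xa, ya = augment_rare_class(X, y, 1, 5.0, rng)
        assert np.sum(ya == 1) == 100
        assert np.sum(ya == 0) == 100
        assert np.allclose(Xa[:120], X)  # originals untouched

    def test_identical_points_stay_close(self, rng):
        X = np.tile([1.0, 2.0], (2, 1))
        y = np.zeros(2, dtype=int)
        Xa, _ = augment_rare_class(X, y, 0, 3.0, rng)
        assert np.allclose(Xa, [1.0, 2.0], atol=1e-8)  # zero class std

    def test_too_few_examples_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 2"):
            augment_rare_class(rng.random((5, 3)), np.array([0, 0, 0, 0, 1]),
                               1, 2.0, rng)


class TestCorruption:
    def test_zero_level_identity(self, rng):
        x = rng.random(100)
        assert np.array_equal(corrupt(x, 0.0, rng), x)

    def test_full_level_zeroes(self, rng):
        x = rng.random(100) + 1.0
        assert np.all(corrupt(x, 1.0, rng) == 0.0)

    def test_masked_fraction_concentrates(self):
        rng = np.random.default_rng(123)
        x = np.ones(10 ** 5)
        frac = np.mean(corrupt(x, 0.3, rng) == 0.0)
        assert abs(frac - 0.3) <= 0.01


class TestLossAndGradient:
    def test_perfect_reconstruction_zero_loss(self):
        x = np.array([0.0, 1.0, 1.0, 0.0])
        assert dae_loss(x, x) < 1e-5

    def test_uniform_loss_log2(self):
        assert np.isclose(dae_loss(np.array([0.5]), np.array([0.5])),
                          np.log(2.0))

    def test_gradient_matches_finite_differences(self):
        """Analytic tied-weight gradient vs central differences."""
        rng = np.random.default_rng(5)
        layer = init_layer(5, 4, 0.0, rng)
        x = rng.random((7, 5))
        xt = corrupt(x, 0.3, rng)
        gW, gb, gbp, _ = _dae_grads(layer, x, xt)
        eps = 1e-6
        for target, grad in ((layer.W, gW), (layer.b, gb),
                             (layer.b_prime, gbp)):
            it = np.nditer(target, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = target[idx]
                target[idx] = orig + eps
                lp = dae_loss(x, layer.decode(layer.encode(xt)))
                target[idx] = orig - eps
                lm = dae_loss(x, layer.decode(layer.encode(xt)))
                target[idx] = orig
                num = (lp - lm) / (2 * eps)
                assert abs(num - grad[idx]) <= 1e-5 * max(1.0, abs(num))


class TestTraining:
    def test_geometry_contracts(self):
        for role in SdaRole:
            h = DEFAULT_HYPERPARAMS[role]
            net = build_network(h, role, np.random.default_rng(0))
            if role is SdaRole.SIXWAY:
                assert h.input_dim == 820 and h.n_out == 6
            else:
                assert h.input_dim == 39 and h.n_out == 2
            assert net.layers[0].W.shape[1] == h.input_dim

    def test_pretrain_heldout_loss_decreases(self, rng):
        h = SdaHyperparams(pca_dim=13, window_length=3, hidden=(30, 20),
                           n_out=2, pretrain_lr=0.3, pretrain_epochs=15,
                           pretrain_batch=32)
        X = rng.random((300, 39))
        net = build_network(h, SdaRole.SPSW2way, rng)
        histories = pretrain_sda(net, X, h, rng)
        assert histories[0][-1] < histories[0][0]

    def test_zero_learning_rate_no_change(self, rng):
        h = SdaHyperparams(pca_dim=13, window_length=3, hidden=(10,),
                           n_out=2, pretrain_lr=0.0, pretrain_epochs=3,
                           pretrain_batch=16)
        net = build_network(h, SdaRole.SPSW2way, rng)
        before = net.layers[0].W.copy()
        pretrain_sda(net, rng.random((50, 39)), h, rng)
        assert np.array_equal(net.layers[0].W, before)

    def test_fixed_seed_reproducible(self):
        h = SdaHyperparams(pca_dim=13, window_length=3, hidden=(12,),
                           n_out=2, pretrain_epochs=5, pretrain_batch=16,
                           finetune_epochs=5, finetune_batch=16)
        X = np.random.default_rng(0).random((60, 39))
        y = (X.sum(axis=1) > X.sum(axis=1).mean()).astype(int)
        nets = []
        for _ in range(2):
            r = np.random.default_rng(77)
            net = build_network(h, SdaRole.SPSW2way, r)
            pretrain_sda(net, X, h, r)
            finetune_sda(net, X, y, h, r)
            nets.append(net)
        assert np.array_equal(nets[0].layers[0].W, nets[1].layers[0].W)
        assert np.array_equal(nets[0].head_W, nets[1].head_W)

    def _clouds(self, rng, n=400, sep=4.0):
        X = np.vstack([rng.normal(0.3, 0.05, size=(n // 2, 39)),
                       rng.normal(0.3 + sep * 0.05, 0.05,
                                  size=(n // 2, 39))])
        y = np.array([0] * (n // 2) + [1] * (n // 2))
        perm = rng.permutation(n)
        return X[perm], y[perm]

    def test_separable_clouds_high_accuracy(self):
        rng = np.random.default_rng(3)
        X, y = self._clouds(rng)
        h = SdaHyperparams(pca_dim=13, window_length=3, hidden=(30, 20),
                           n_out=2, pretrain_lr=0.3, pretrain_epochs=10,
                           pretrain_batch=32, finetune_lr=0.2,
                           finetune_epochs=60, finetune_batch=32)
        net = build_network(h, SdaRole.SPSW2way, rng)
        pretrain_sda(net, X[:300], h, rng)
        finetune_sda(net, X[:300], y[:300], h, rng)
        acc = (net.predict_proba(X[300:]).argmax(axis=1) == y[300:]).mean()
        assert acc >= 0.95

    def test_permuted_labels_chance_accuracy(self):
        rng = np.random.default_rng(4)
        X, y = self._clouds(rng)
        y_perm = rng.permutation(y)
        h = SdaHyperparams(pca_dim=13, window_length=3, hidden=(30, 20),
                           n_out=2, pretrain_lr=0.3, pretrain_epochs=10,
                           pretrain_batch=32, finetune_lr=0.2,
                           finetune_epochs=60, finetune_batch=32)
        net = build_network(h, SdaRole.SPSW2way, rng)
        pretrain_sda(net, X[:300], h, rng)
        finetune_sda(net, X[:300], y_perm[:300], h, rng)
        acc = (net.predict_proba(X[300:]).argmax(axis=1)
               == y_perm[300:]).mean()
        assert abs(acc - 0.5) <= 0.1

    def test_head_posteriors_normalized(self, rng):
        h = SdaHyperparams(pca_dim=13, window_length=3, hidden=(10,), n_out=2)
        net = build_network(h, SdaRole.SPSW2way, rng)
        probs = net.predict_proba(rng.random((20, 39)))
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_bad_labels_rejected(self, rng):
        h = SdaHyperparams(pca_dim=13, window_length=3, hidden=(10,), n_out=2,
                           finetune_epochs=1)
        net = build_network(h, SdaRole.SPSW2way, rng)
        with pytest.raises(ValueError, match="labels"):
            finetune_sda(net, rng.random((10, 39)),
                         np.full(10, 3), h, rng)


class TestEnhancer:
    def test_agreement_is_noop(self):
        p6 = np.array([[0.6, 0.1, 0.1, 0.1, 0.05, 0.05]])  # argmax SPSW
        out = enhancer_combine(p6, np.array([[0.1, 0.9]]),
                               np.array([[0.9, 0.1]]))
        assert np.allclose(out, p6)

    def test_uniform_p6_mass_reallocation(self):
        p6 = np.full((1, 6), 1 / 6)
        out = enhancer_combine(p6, np.array([[0.1, 0.9]]),
                               np.array([[0.9, 0.1]]))
        # epileptiform block {SPSW, PLED, GPED} takes 0.9, split equally
        for idx in (ClassLabel.SPSW.value, ClassLabel.PLED.value,
                    ClassLabel.GPED.value):
            assert np.isclose(out[0, idx], 0.3)
        assert np.isclose(out[0].sum(), 1.0)

    def test_eyem_override(self):
        p6 = np.array([[0.05, 0.05, 0.05, 0.05, 0.05, 0.75]])
        out = enhancer_combine(p6, np.array([[0.9, 0.1]]),
                               np.array([[0.2, 0.8]]))
        assert out[0].argmax() == ClassLabel.EYEM.value
        assert np.isclose(out[0, ClassLabel.EYEM.value], 0.8)

    def test_rows_sum_to_one_random(self, rng):
        p6 = rng.dirichlet(np.ones(6), size=50)
        p_s = rng.dirichlet(np.ones(2), size=50)
        p_e = rng.dirichlet(np.ones(2), size=50)
        out = enhancer_combine(p6, p_s, p_e)
        assert np.allclose(out.sum(axis=1), 1.0, atol=1e-9)


class TestPriorityVote:
    def test_highest_priority_present_wins(self):
        labels = np.full((3, 22), ClassLabel.BCKG.value)
        labels[0, 7] = ClassLabel.SPSW.value
        labels[1, 2] = ClassLabel.ARTF.value
        labels[1, 3] = ClassLabel.GPED.value
        out = priority_vote(labels)
        assert out[0] == ClassLabel.SPSW.value
        assert out[1] == ClassLabel.GPED.value
        assert out[2] == ClassLabel.BCKG.value
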