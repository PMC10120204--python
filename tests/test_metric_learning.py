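"""Triplet loss against a scalar oracle; encoder and training contracts."""

import numpy as np
import pytest

import endofew as ef
from endofew.errors import TrainingError, ValidationError
from endofew.metric import (TrainConfig, TripletLossConfig, _eval_loss,
                            pretrain, triplet_loss)
from endofew.triplets import mine_self_supervised, mine_supervised


def oracle_loss(za, zp, zn, margin, metric="l2"):
    """Independent scalar-by-scalar evaluation of the loss formula."""
    if metric == "l2":
        dp = sum((a - b) ** 2 for a, b in zip(za, zp)) ** 0.5
        dn = sum((a - b) ** 2 for a, b in zip(za, zn)) ** 0.5
    else:
        def cos_d(u, v):
            dot = sum(x * y for x, y in zip(u, v))
            nu = sum(x * x for x in u) ** 0.5
            nv = sum(y * y for y in v) ** 0.5
            return 1.0 - dot / (nu * nv)
        dp, dn = cos_d(za, zp), cos_d(za, zn)
    return dp + max(0.0, margin - dn)


class TestTripletLoss:
    def test_hand_example(self):
        assert triplet_loss([0, 0], [3, 4], [1, 0]) == pytest.approx(24.0)

    def test_zero_case(self):
        z = [1.0, 2.0]
        far = [100.0, 2.0]
        assert triplet_loss(z, z, far, TripletLossConfig(margin=20)) == 0.0

    def test_zero_margin_reduces_to_positive_distance(self, rng):
        za, zp, zn = rng.normal(size=(3, 8))
        cfg = TripletLossConfig(margin=0.0)
        assert triplet_loss(za, zp, zn, cfg) == pytest.approx(
            np.linalg.norm(za - zp))

    @pytest.mark.parametrize("metric", ["l2", "cosine"])
    def test_matches_scalar_oracle(self, metric, rng):
        cfg = TripletLossConfig(margin=20.0, metric=metric)
        for _ in range(1000):
            za, zp, zn = rng.normal(scale=10.0, size=(3, 6))
            expected = oracle_loss(za.tolist(), zp.tolist(), zn.tolist(),
                                   20.0, metric)
            got = triplet_loss(za, zp, zn, cfg)
            assert got == pytest.approx(expected, rel=1e-6)

    def test_monotone_in_negative_distance(self, rng):
        """Pushing the negative radially away never increases the loss."""
        cfg = TripletLossConfig(margin=20.0)
        for _ in range(50):
            za, zp = rng.normal(size=(2, 5))
            direction = rng.normal(size=5)
            direction /= np.linalg.norm(direction)
            losses = [triplet_loss(za, zp, za + r * direction, cfg)
                      for r in np.linspace(0.1, 40, 20)]
            assert all(a >= b - 1e-12 for a, b in zip(losses, losses[1:]))

    def test_monotone_in_positive_distance(self, rng):
        cfg = TripletLossConfig(margin=20.0)
        for _ in range(50):
            za, zn = rng.normal(size=(2, 5))
            direction = rng.normal(size=5)
            direction /= np.linalg.norm(direction)
            losses = [triplet_loss(za, za + r * direction, zn, cfg)
                      for r in np.linspace(0.1, 40, 20)]
            assert all(b >= a - 1e-12 for a, b in zip(losses, losses[1:]))

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            triplet_loss([0, 0], [1, 1, 1], [2, 2])

    def test_negative_margin_rejected(self):
        with pytest.raises(ValidationError):
            TripletLossConfig(margin=-1.0)


class TestEncoder:
    def test_default_embedding_dim_is_64(self):
        enc = ef.build_encoder("small", seed=0)
        x = np.random.default_rng(0).random((2, 16, 16, 3))
        assert enc.embed_batch(x).shape == (2, 64)

    def test_toy_two_dim_output(self):
        enc = ef.build_encoder((4,), embedding_dim=2, seed=0)
        x = np.random.default_rng(0).random((3, 8, 8, 3))
        assert enc.embed_batch(x).shape == (3, 2)

    def test_same_seed_identical_parameters(self):
        a = ef.build_encoder((4, 8), embedding_dim=8, seed=5)
        b = ef.build_encoder((4, 8), embedding_dim=8, seed=5)
        assert all(np.array_equal(x, y)
                   for x, y in zip(a.get_weights(), b.get_weights()))

    def test_duplicate_inputs_identical_embeddings(self, tiny_encoder, rng):
        x = rng.random((8, 8, 3))
        z = tiny_encoder.embed_batch(np.stack([x, x]))
        assert np.array_equal(z[0], z[1])

    def test_batched_equals_one_by_one(self, tiny_encoder, rng):
        xs = rng.random((5, 16, 16, 3))
        z_batch = ef.embed(tiny_encoder, xs, batch_size=5)
        z_single = np.concatenate(
            [ef.embed(tiny_encoder, xs[i:i + 1]) for i in range(5)])
        assert np.allclose(z_batch, z_single, atol=1e-5)

    def test_embeddings_finite_for_any_valid_input(self, tiny_encoder):
        for x in (np.zeros((1, 16, 16, 3)), np.ones((1, 16, 16, 3))):
            assert np.isfinite(tiny_encoder.embed_batch(x)).all()

    def test_checkpoint_round_trip_bit_identical(self, tmp_path, rng):
        enc = ef.build_encoder((4, 8), embedding_dim=8, seed=3)
        enc.class_vocabulary = ["a", "b"]
        ef.save_checkpoint(enc, tmp_path / "m.npz")
        loaded = ef.load_checkpoint(tmp_path / "m.npz")
        x = rng.random((2, 16, 16, 3))
        assert np.array_equal(enc.embed_batch(x), loaded.embed_batch(x))
        assert loaded.class_vocabulary == ["a", "b"]


def _easy_corpus(n=12, size=16, seed=0):
    rng = np.random.default_rng(seed)
    return [ef.ImageSample(pixels=rng.random((size, size, 3)),
                           polyp_id=f"s{i}") for i in range(n)]


class TestTraining:
    def test_history_lengths_match_completed_epochs(self):
        enc = ef.build_encoder((4,), embedding_dim=4, seed=0)
        cfg = TrainConfig(epochs_max=3, triplets_per_epoch=8,
                          early_stop_patience=10, learning_rate=1e-3, seed=1)
        miner = lambda s, n, rng: mine_self_supervised(
            s, ef.AugmentationSpec(noise_sigma=0.05), n, rng)
        _, hist = pretrain(enc, _easy_corpus(), miner, cfg)
        assert len(hist["train"]) == len(hist["val"]) == 3

    def test_frozen_parameters_stop_after_one_plus_patience(self):
        enc = ef.build_encoder((4,), embedding_dim=4, seed=0)
        cfg = TrainConfig(epochs_max=50, triplets_per_epoch=8,
                          early_stop_patience=1, learning_rate=0.0, seed=1)
        miner = lambda s, n, rng: mine_self_supervised(
            s, ef.AugmentationSpec.identity(), n, rng)
        _, hist = pretrain(enc, _easy_corpus(), miner, cfg)
        assert len(hist["val"]) == 2  # 1 + patience

    def test_returned_model_achieves_min_validation_loss(self):
        enc = ef.build_encoder((4,), embedding_dim=4, seed=0)
        cfg = TrainConfig(epochs_max=6, triplets_per_epoch=10,
                          early_stop_patience=10, learning_rate=5e-3,
                          validation_fraction=0.25, seed=2)
        aug = ef.AugmentationSpec(noise_sigma=0.05)
        corpus = _easy_corpus(16)
        # replicate pretrain's internal split to rebuild the val triplets
        rng = np.random.default_rng(cfg.seed)
        n_val = int(round(0.25 * len(corpus)))
        perm = rng.permutation(len(corpus))
        val = [corpus[i] for i in perm[:n_val]]
        val_triplets = mine_self_supervised(
            val, aug, cfg.triplets_per_epoch,
            np.random.default_rng(rng.integers(2 ** 31)))
        miner = lambda s, n, r: mine_self_supervised(s, aug, n, r)
        model, hist = pretrain(enc, corpus, miner, cfg)
        final = _eval_loss(model, val_triplets, TripletLossConfig(),
                           cfg.batch_size)
        assert final == pytest.approx(min(hist["val"]), rel=1e-6)

    def test_validation_loss_improves_on_easy_corpus(self, polyp_ds):
        ds, _ = polyp_ds
        enc = ef.build_encoder((8, 16), embedding_dim=16, seed=0)
        cfg = TrainConfig(epochs_max=12, triplets_per_epoch=100,
                          early_stop_patience=20, learning_rate=1e-2, seed=3)
        miner = lambda s, n, rng: mine_self_supervised(
            s, ef.AugmentationSpec(noise_sigma=0.05), n, rng)
        _, hist = pretrain(enc, ds.samples, miner, cfg)
        assert min(hist["val"]) < hist["val"][0]

    def test_finetune_tightens_classes(self, polyp_ds):
        """Class triplets shrink intra-class spread relative to inter."""
        ds, _ = polyp_ds
        enc = ef.build_encoder((8, 16), embedding_dim=16, seed=1)
        labeled = ds.labeled()
        labels = [s.label for s in labeled]

        def ratio(model):
            v = ef.class_variances(ef.embed(model, labeled), labels)
            return float(np.mean(list(v.intra.values())))

        before = ratio(enc)
        cfg = TrainConfig(epochs_max=10, triplets_per_epoch=50,
                          early_stop_patience=10, learning_rate=1e-2, seed=4)
        tuned, hist = ef.finetune(enc.copy(), ds, cfg, ef.AugmentationSpec())
        assert ratio(tuned) < before

    def test_divergence_reports_epoch(self):
        enc = ef.build_encoder((4, 8), embedding_dim=4, seed=0)
        cfg = TrainConfig(epochs_max=5, triplets_per_epoch=8,
                          learning_rate=1e12, seed=1)
        miner = lambda s, n, rng: mine_self_supervised(
            s, ef.AugmentationSpec(noise_sigma=0.05), n, rng)
        with pytest.raises(TrainingError, match="epoch"):
            pretrain(enc, _easy_corpus(), miner, cfg)

    def test_finetune_requires_class_in_both_portions(self):
        samples = [ef.ImageSample(pixels=np.zeros((8, 8, 3)), label=lab,
                                  polyp_id=f"p{i}")
                   for i, lab in enumerate(["a", "a", "a", "b"])]
        ds = ef.Dataset(samples=samples, class_vocabulary=["a", "b"])
        cfg = TrainConfig(epochs_max=2, triplets_per_epoch=4, seed=0)
        enc = ef.build_encoder((4,), embedding_dim=4, seed=0)
        with pytest.raises(ef.SplitError, match="'b'"):
            ef.finetune(enc, ds, cfg)
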