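import numpy as np
import pytest

import memocf as mc
from memocf.latent_autoencoder import _sigmoid
from memocf.neighborhood_memory import MemoryTable


def constant_latent_model(values, z, u, h, w_out, b, eta, memory=None):
    """Model whose every drug latent is z and every disease latent is u.

    Built from identity-activation encoders with zero weights and the latent
    vector as encoder bias, so predictions have a closed form.
    """
    values = np.asarray(values, dtype=np.int8)
    m, n = values.shape
    d, l = len(z), len(w_out)
    drug_ids = [f"d{i}" for i in range(m)]
    disease_ids = [f"p{j}" for j in range(n)]

    def ae(n_assoc, n_sim, bias):
        return mc.AutoencoderParams(
            W1=np.zeros((d, n_assoc)), V1=np.zeros((d, n_sim)),
            b_enc=np.asarray(bias, dtype=float),
            W2=np.zeros((n_assoc, d)), b_rec_assoc=np.zeros(n_assoc),
            V2=np.zeros((n_sim, d)), b_rec_sim=np.zeros(n_sim),
            activation_enc="identity",
        )

    model = mc.TrainedModel(
        drug_ae=ae(n, m, z),
        disease_ae=ae(m, n, u),
        memory=MemoryTable(memory if memory is not None else np.zeros((m, l))),
        fusion=mc.FusionParams(np.asarray(h, float), np.asarray(w_out, float),
                               np.array([b]), eta=eta),
        training_associations=mc.AssociationMatrix(values, drug_ids, disease_ids),
        drug_sim=mc.SimilarityMatrix(np.eye(m), drug_ids, "drug"),
        disease_sim=mc.SimilarityMatrix(np.eye(n), disease_ids, "disease"),
    )
    model.refresh_latents()
    return model


class TestPredictScore:
    def test_latent_only_closed_form(self):
        model = constant_latent_model(
            np.zeros((3, 3)), z=[1.0, 1.0], u=[1.0, 1.0],
            h=[1.0, 1.0], w_out=[0.0], b=0.0, eta=1.0,
        )
        expected = 1 / (1 + np.exp(-2.0))
        assert mc.predict_score(model, 0, 0) == pytest.approx(expected, abs=1e-15)

    def test_eta_zero_zero_weights_gives_half(self, rng):
        model = constant_latent_model(
            (rng.random((4, 4)) < 0.5).astype(int),
            z=rng.normal(size=3), u=rng.normal(size=3),
            h=rng.normal(size=3), w_out=[0.0, 0.0], b=0.0, eta=0.0,
        )
        for i in range(4):
            for j in range(4):
                assert mc.predict_score(model, i, j) == 0.5

    def test_index_out_of_range(self):
        model = constant_latent_model(np.zeros((2, 2)), [0.0], [0.0],
                                      [0.0], [0.0], 0.0, 0.5)
        with pytest.raises(IndexError):
            mc.predict_score(model, 2, 0)
        with pytest.raises(IndexError):
            mc.predict_score(model, 0, 5)

    def test_matches_stepwise_module_composition(self, toy_bundle, rng):
        """Fused score == explicit composition of the three modules (oracle)."""
        bundle, _ = toy_bundle
        model = mc.init_model(bundle, mc.Architecture(8, 6, eta=0.7), seed=3)
        a = bundle.associations
        r = np.asarray(a.values, float)
        z = np.maximum(r @ model.drug_ae.W1.T
                       + bundle.drug_sim.values @ model.drug_ae.V1.T
                       + model.drug_ae.b_enc, 0)
        u = np.maximum(r.T @ model.disease_ae.W1.T
                       + bundle.disease_sim.values @ model.disease_ae.V1.T
                       + model.disease_ae.b_enc, 0)
        pairs = np.column_stack([
            rng.integers(a.n_drugs, size=100), rng.integers(a.n_diseases, size=100)
        ])
        vec = mc.predict_scores(model, pairs[:, 0], pairs[:, 1])
        fus = model.fusion
        for t, (i, j) in enumerate(pairs):
            nbrs = [k for k in range(a.n_drugs) if a.values[k, j] == 1 and k != i]
            if nbrs:
                p = np.array([z[i] @ z[k] for k in nbrs])
                e = np.exp(p - p.max())
                q = e / e.sum()
                o = q @ model.memory.values[nbrs]
            else:
                o = np.zeros(model.memory.l_mem)
            logit = (fus.eta * float(fus.h @ (z[i] * u[j]))
                     + (1 - fus.eta) * float(fus.w_out @ o) + fus.b_out[0])
            expected = 1 / (1 + np.exp(-logit))
            assert mc.predict_score(model, int(i), int(j)) == pytest.approx(
                expected, abs=1e-12)
            assert vec[t] == pytest.approx(expected, abs=1e-12)


class TestLosses:
    def test_bce_closed_forms(self):
        assert mc.bce_loss(np.array([1.0]), np.array([0.8])) == pytest.approx(
            -np.log(0.8), abs=1e-12)
        n = 7
        assert mc.bce_loss(np.ones(n) * 0, np.full(n, 0.5)) == pytest.approx(
            n * np.log(2), abs=1e-12)

    def test_bce_random_oracle(self, rng):
        labels = (rng.random(40) < 0.5).astype(float)
        scores = rng.uniform(0.01, 0.99, size=40)
        expected = -sum(
            r * np.log(s) + (1 - r) * np.log(1 - s)
            for r, s in zip(labels, scores)
        )
        assert mc.bce_loss(labels, scores) == pytest.approx(expected, abs=1e-12)

    def test_bce_length_mismatch(self):
        with pytest.raises(ValueError):
            mc.bce_loss(np.ones(3), np.full(2, 0.5))

    def test_bce_clips_extreme_scores(self):
        assert np.isfinite(mc.bce_loss(np.array([1.0]), np.array([0.0])))

    def test_total_loss_linearity(self, rng):
        cfg0 = mc.TrainingConfig(phi=0.0, psi=0.0)
        assert mc.total_loss(3.5, 100.0, 200.0, cfg0) == 3.5
        cfg1 = mc.TrainingConfig(phi=1.0, psi=1.0)
        assert mc.total_loss(1.0, 2.0, 3.0, cfg1) == 6.0
        bce, ld, lp = rng.random(3)
        phi, psi = rng.random(2)
        cfg = mc.TrainingConfig(phi=phi, psi=psi)
        assert mc.total_loss(bce, ld, lp, cfg) == pytest.approx(
            bce + phi * ld + psi * lp, abs=1e-12)
        # slopes in phi and psi recoverable by two-point evaluation
        cfg2 = mc.TrainingConfig(phi=phi + 1.0, psi=psi)
        assert mc.total_loss(bce, ld, lp, cfg2) - mc.total_loss(
            bce, ld, lp, cfg) == pytest.approx(ld, abs=1e-9)


class TestNegativeSampling:
    def _assoc(self):
        values = np.zeros((4, 5), dtype=np.int8)
        values[[0, 1, 2, 3], [0, 1, 2, 3]] = 1
        return mc.AssociationMatrix(values, list("abcd"), list("vwxyz"))

    def test_count_and_membership(self):
        a = self._assoc()
        batch = mc.sample_negatives(a, 1, seed=0)
        assert len(batch) == 4
        for i, j, r in batch.pairs:
            assert a.values[i, j] == 0 and r == 0

    def test_deterministic_given_seed_and_epoch(self):
        a = self._assoc()
        b1 = mc.sample_negatives(a, 2, seed=5, epoch=3)
        b2 = mc.sample_negatives(a, 2, seed=5, epoch=3)
        assert b1.pairs == b2.pairs
        b3 = mc.sample_negatives(a, 2, seed=5, epoch=4)
        assert b1.pairs != b3.pairs

    def test_insufficient_zero_cells(self):
        a = self._assoc()
        with pytest.raises(ValueError):
            mc.sample_negatives(a, 10, seed=0)

    def test_uniformity_over_zero_cells(self):
        values = np.zeros((4, 5), dtype=np.int8)
        values[[0, 1, 2], [0, 1, 2]] = 1
        a = mc.AssociationMatrix(values, list("abcd"), list("vwxyz"))
        n_draws = 10_000
        counts = np.zeros((4, 5))
        for epoch in range(n_draws):
            for i, j, _ in mc.sample_negatives(a, 1, seed=1, epoch=epoch).pairs:
                counts[i, j] += 1
        zeros = a.values == 0
        p = 3 / 17  # 3 sampled of 17 zero cells
        sigma = np.sqrt(p * (1 - p) / n_draws)
        freq = counts[zeros] / n_draws
        assert (np.abs(freq - p) < 3 * sigma + 1e-9).all()
        assert counts[~zeros].sum() == 0


@pytest.fixture(scope="module")
def small_run():
    bundle, _ = mc.generate_dataset(mc.SynthSpec(50, 30, 4, 0.05, seed=7))
    arch = mc.Architecture(latent_dim=8, memory_dim=8)
    cfg = mc.TrainingConfig(epochs=5, learning_rate=0.001, seed=2)
    model, trace = mc.train(bundle, arch, cfg)
    return bundle, arch, cfg, model, trace


class TestTraining:
    def test_loss_descends(self, small_run):
        *_, trace = small_run
        assert trace[4] < trace[0]

    def test_same_seed_identical_traces(self, small_run):
        bundle, arch, cfg, _, trace = small_run
        _, trace2 = mc.train(bundle, arch, cfg)
        assert trace == trace2

    def test_eta_one_ignores_memory(self):
        bundle, _ = mc.generate_dataset(mc.SynthSpec(20, 15, 3, 0.08, seed=3))
        arch = mc.Architecture(latent_dim=4, memory_dim=4, eta=1.0)
        model, _ = mc.train(bundle, arch, mc.TrainingConfig(epochs=3, seed=0))
        pairs = np.argwhere(np.ones((20, 15), dtype=bool))
        before = mc.predict_scores(model, pairs[:, 0], pairs[:, 1])
        model.memory.values[:] = np.random.default_rng(99).normal(
            size=model.memory.values.shape)
        after = mc.predict_scores(model, pairs[:, 0], pairs[:, 1])
        np.testing.assert_array_equal(before, after)

    def test_eta_zero_ignores_latent_product_weights(self):
        bundle, _ = mc.generate_dataset(mc.SynthSpec(20, 15, 3, 0.08, seed=3))
        arch = mc.Architecture(latent_dim=4, memory_dim=4, eta=0.0)
        model, _ = mc.train(bundle, arch, mc.TrainingConfig(epochs=3, seed=0))
        pairs = np.argwhere(np.ones((20, 15), dtype=bool))
        before = mc.predict_scores(model, pairs[:, 0], pairs[:, 1])
        model.fusion.h[:] = np.random.default_rng(98).normal(size=model.fusion.h.shape)
        after = mc.predict_scores(model, pairs[:, 0], pairs[:, 1])
        np.testing.assert_array_equal(before, after)

    def test_training_requires_positives(self):
        values = np.zeros((5, 5), dtype=np.int8)
        ids = [f"d{i}" for i in range(5)]
        pids = [f"p{j}" for j in range(5)]
        bundle = mc.DatasetBundle(
            mc.AssociationMatrix(values, ids, pids),
            mc.SimilarityMatrix(np.eye(5), ids, "drug"),
            mc.SimilarityMatrix(np.eye(5), pids, "disease"),
        )
        with pytest.raises(ValueError):
            mc.train(bundle, mc.Architecture(2, 2), mc.TrainingConfig(epochs=1))

    def test_early_stopping_with_validation(self):
        bundle, _ = mc.generate_dataset(mc.SynthSpec(30, 20, 3, 0.08, seed=5))
        splits = mc.cv_split(bundle.associations, 5, seed=0)
        sp = splits[0]
        tb = mc.fold_train_bundle(bundle, sp)
        pairs = np.concatenate([sp.test_positives, sp.test_negatives[:200]])
        labels = np.concatenate(
            [np.ones(len(sp.test_positives)), np.zeros(200)])
        cfg = mc.TrainingConfig(epochs=50, seed=1, patience=3)
        model, trace = mc.train(tb, mc.Architecture(4, 4), cfg,
                                validation=(pairs, labels))
        assert len(trace) <= 50

    def test_batch_label_validation(self):
        with pytest.raises(ValueError):
            mc.TrainingBatch([0], [0], [0.5])
        with pytest.raises(ValueError):
            mc.TrainingBatch([0, 1], [0], [1.0])


class TestGridSearch:
    def test_default_grid_cardinality(self):
        from memocf.fusion_model import DEFAULT_GRIDS, grid_size
        assert grid_size(DEFAULT_GRIDS) == 112500
        assert sorted(DEFAULT_GRIDS["lr"]) != DEFAULT_GRIDS["lr"]  # printed order kept

    def test_single_point_grid(self, toy_bundle):
        bundle, _ = toy_bundle
        split = mc.cv_split(bundle.associations, 4, seed=0)[0]
        best, results = mc.grid_search(
            bundle, {"eta": [0.5]}, split,
            arch=mc.Architecture(4, 4),
            cfg=mc.TrainingConfig(epochs=1, seed=0),
        )
        assert best == {"eta": 0.5}
        assert len(results) == 1

    def test_dominant_config_wins_rigged_metric(self, toy_bundle):
        bundle, _ = toy_bundle
        split = mc.cv_split(bundle.associations, 4, seed=0)[0]
        best, results = mc.grid_search(
            bundle, {"eta": [0.1, 0.9]}, split,
            metric=lambda model, s: 1.0 if model.fusion.eta == 0.9 else 0.0,
            arch=mc.Architecture(4, 4),
            cfg=mc.TrainingConfig(epochs=1, seed=0),
        )
        assert best == {"eta": 0.9}
        assert len(results) == 2

    def test_empty_grid_rejected(self, toy_bundle):
        bundle, _ = toy_bundle
        split = mc.cv_split(bundle.associations, 4, seed=0)[0]
        with pytest.raises(ValueError):
            mc.grid_search(bundle, {"eta": []}, split)


class TestModelArchive:
    def test_save_load_round_trip(self, tmp_path):
        bundle, _ = mc.generate_dataset(mc.SynthSpec(15, 10, 3, 0.1, seed=4))
        model, _ = mc.train(bundle, mc.Architecture(4, 5, eta=0.3),
                            mc.TrainingConfig(epochs=2, seed=6))
        mc.save_model(model, tmp_path / "archive")
        back = mc.load_model(tmp_path / "archive")
        pairs = np.argwhere(np.ones((15, 10), dtype=bool))
        np.testing.assert_array_equal(
            mc.predict_scores(model, pairs[:, 0], pairs[:, 1]),
            mc.predict_scores(back, pairs[:, 0], pairs[:, 1]),
        )
        assert back.training_associations == model.training_associations
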