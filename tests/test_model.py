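"""Tagger network, training losses and training loop.

The three losses are checked two ways: against hand-written brute-force
loop oracles (values) and against central finite differences (gradients).
"""

import numpy as np
import pytest

import deeptag as dt
from deeptag._autodiff import Tensor
from deeptag.model import EPS, make_batch


@pytest.fixture(scope="module")
def onto6():
    """6 codes in 3 metas of exactly 2 — handy for pairwise loss oracles."""
    return dt.CodeOntology(
        subtype_to_disease={f"S{d}": d for d in range(6)},
        disease_to_meta={0: 0, 1: 0, 2: 1, 3: 1, 4: 2, 5: 2},
        disease_names=[f"d{i}" for i in range(6)],
        meta_names=[f"m{i}" for i in range(3)],
        other_index=5,
        strict_cardinality=False,
    )


def finite_diff(fn, x, eps=1e-6):
    """Central-difference gradient of scalar fn at numpy array x."""
    g = np.zeros_like(x, dtype=float)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        k = it.multi_index
        orig = x[k]
        x[k] = orig + eps
        fp = fn(x)
        x[k] = orig - eps
        fm = fn(x)
        x[k] = orig
        g[k] = (fp - fm) / (2 * eps)
    return g


def rel_err(a, b):
    return np.abs(a - b).max() / (np.abs(b).max() + 1e-12)


class TestBceLoss:
    def test_perfect_prediction_near_zero(self):
        y = np.array([[1.0, 0.0], [0.0, 1.0]])
        p = y.copy()
        assert float(dt.bce_loss(p, y).data) < 1e-5

    def test_uniform_prediction_is_log2(self):
        y = np.array([[1, 0, 1]], dtype=float)
        p = np.full_like(y, 0.5)
        assert float(dt.bce_loss(p, y).data) == pytest.approx(np.log(2), abs=1e-12)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.01, 0.99, size=(7, 5))
        y = rng.integers(0, 2, size=(7, 5)).astype(float)
        expected = np.mean(
            [
                -(y[i, j] * np.log(p[i, j]) + (1 - y[i, j]) * np.log(1 - p[i, j]))
                for i in range(7)
                for j in range(5)
            ]
        )
        assert float(dt.bce_loss(p, y).data) == pytest.approx(expected, abs=1e-6)

    def test_nonbinary_labels_rejected(self):
        with pytest.raises(ValueError):
            dt.bce_loss(np.array([[0.5]]), np.array([[0.3]]))

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0.05, 0.95, size=(4, 6))
        y = rng.integers(0, 2, size=(4, 6)).astype(float)
        t = Tensor(p.copy(), requires_grad=True)
        dt.bce_loss(t, y).backward()
        num = finite_diff(lambda x: float(dt.bce_loss(x, y).data), p.copy())
        assert rel_err(t.grad, num) < 1e-4


class TestClusterPenalty:
    def test_identical_embeddings_closed_form(self, onto6):
        E = np.ones((6, 3))
        m = 1.5
        val = float(dt.cluster_penalty(E, onto6, margin=m).data)
        # intra 0, every inter pair at distance 0 -> m^2 (up to the sqrt epsilon)
        assert val == pytest.approx(m**2, abs=1e-4)

    def test_well_separated_clusters_zero(self, onto6):
        E = np.zeros((6, 3))
        for g, members in enumerate(onto6.meta_groups()):
            for d in members:
                E[d] = [10.0 * g, 0.0, 0.0]  # coincident within, distance 10 across
        assert float(dt.cluster_penalty(E, onto6, margin=1.0).data) < 1e-9

    def test_matches_bruteforce_double_loop(self, onto6):
        rng = np.random.default_rng(2)
        E = rng.normal(size=(6, 3))
        m = 1.0
        group_of = {d: g for g, ms in enumerate(onto6.meta_groups()) for d in ms}
        intra, inter = [], []
        for i in range(6):
            for j in range(i + 1, 6):
                d = np.linalg.norm(E[i] - E[j])
                if group_of[i] == group_of[j]:
                    intra.append(d**2)
                else:
                    inter.append(max(0.0, m - d) ** 2)
        expected = np.mean(intra) + np.mean(inter)
        assert float(dt.cluster_penalty(E, onto6, margin=m).data) == pytest.approx(
            expected, abs=1e-6
        )

    def test_gradient_matches_finite_differences(self, onto6):
        rng = np.random.default_rng(3)
        E = rng.normal(size=(6, 3))
        t = Tensor(E.copy(), requires_grad=True)
        dt.cluster_penalty(t, onto6, margin=1.0).backward()
        num = finite_diff(
            lambda x: float(dt.cluster_penalty(x, onto6, margin=1.0).data), E.copy()
        )
        assert rel_err(t.grad, num) < 1e-4

    def test_permutation_invariance(self, onto6):
        rng = np.random.default_rng(4)
        E = rng.normal(size=(6, 3))
        base = float(dt.cluster_penalty(E, onto6, margin=1.0).data)
        # swap the two codes inside each meta group: same partition geometry
        perm = np.arange(6)
        for members in onto6.meta_groups():
            perm[members[0]], perm[members[1]] = members[1], members[0]
        assert float(dt.cluster_penalty(E[perm], onto6, margin=1.0).data) == pytest.approx(
            base, abs=1e-12
        )

    def test_single_group_rejected(self):
        onto, _ = dt.generate_ontology(dt.GeneratorConfig(n_codes=3, n_metas=1, seed=0))
        with pytest.raises(ValueError):
            dt.cluster_penalty(np.zeros((3, 2)), onto)


class TestMetaLoss:
    def _noisy_or_oracle(self, p, onto):
        qs = []
        for members in onto.meta_groups():
            q = 1.0 - np.prod([1.0 - np.clip(p[:, d], EPS, 1 - EPS) for d in members], axis=0)
            qs.append(q)
        return np.stack(qs, axis=1)

    def test_noisy_or_values(self, onto6):
        members = onto6.meta_groups()[0]
        p = np.zeros((3, 6))
        p[1, members] = 0.5            # 1 - 0.5^2 = 0.75
        p[2, members[0]] = 1.0         # absorbing: q = 1
        q = self._noisy_or_oracle(p, onto6)
        assert q[0, 0] == pytest.approx(0.0, abs=1e-6)
        assert q[1, 0] == pytest.approx(0.75, abs=1e-6)
        assert q[2, 0] == pytest.approx(1.0, abs=1e-6)

    def test_matches_bruteforce_oracle(self, onto6):
        rng = np.random.default_rng(5)
        p = rng.uniform(0.05, 0.95, size=(8, 6))
        y = rng.integers(0, 2, size=(8, 6)).astype(float)
        q = self._noisy_or_oracle(p, onto6)
        y_meta = np.stack(
            [y[:, ms].max(axis=1) for ms in onto6.meta_groups()], axis=1
        )
        qc = np.clip(q, EPS, 1 - EPS)
        expected = np.mean(-(y_meta * np.log(qc) + (1 - y_meta) * np.log(1 - qc)))
        assert float(dt.meta_loss(p, y, onto6).data) == pytest.approx(expected, abs=1e-6)

    def test_noisy_or_monotone_in_member_probability(self, onto6):
        rng = np.random.default_rng(6)
        p = rng.uniform(0.1, 0.8, size=(1, 6))
        members = onto6.meta_groups()[1]
        q_before = self._noisy_or_oracle(p, onto6)[0, 1]
        p2 = p.copy()
        p2[0, members[0]] += 0.1
        assert self._noisy_or_oracle(p2, onto6)[0, 1] > q_before

    def test_gradient_matches_finite_differences(self, onto6):
        rng = np.random.default_rng(7)
        p = rng.uniform(0.05, 0.95, size=(4, 6))
        y = rng.integers(0, 2, size=(4, 6)).astype(float)
        t = Tensor(p.copy(), requires_grad=True)
        dt.meta_loss(t, y, onto6).backward()
        num = finite_diff(lambda x: float(dt.meta_loss(x, y, onto6).data), p.copy())
        assert rel_err(t.grad, num) < 1e-4


class TestTotalLoss:
    def _model(self, onto, **kw):
        vocab = dt.Vocabulary(["a", "b", "c"])
        cfg = dt.TaggerConfig(embedding_dim=4, hidden_dim=4, seed=0, **kw)
        return dt.TaggerModel(cfg, vocab, onto)

    def test_zero_weights_equal_bce(self, onto6):
        model = self._model(onto6)
        rng = np.random.default_rng(8)
        p = Tensor(rng.uniform(0.1, 0.9, size=(5, 6)))
        y = rng.integers(0, 2, size=(5, 6)).astype(float)
        assert float(dt.total_loss(p, y, model).data) == pytest.approx(
            float(dt.bce_loss(p, y).data), abs=1e-12
        )

    def test_component_sum(self, onto6):
        model = self._model(onto6, lambda_cluster=1.0, beta_meta=0.5)
        rng = np.random.default_rng(9)
        p = Tensor(rng.uniform(0.1, 0.9, size=(5, 6)))
        y = rng.integers(0, 2, size=(5, 6)).astype(float)
        expected = (
            float(dt.bce_loss(p, y).data)
            + 1.0 * float(dt.cluster_penalty(model.label_embeddings, onto6, 1.0).data)
            + 0.5 * float(dt.meta_loss(p, y, onto6).data)
        )
        assert float(dt.total_loss(p, y, model).data) == pytest.approx(expected, abs=1e-9)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            dt.TaggerConfig(lambda_cluster=-0.1)
        with pytest.raises(ValueError):
            dt.TaggerConfig(beta_meta=-1.0)

    def test_loss_finite_on_extreme_probabilities(self, onto6):
        model = self._model(onto6, lambda_cluster=0.1, beta_meta=0.1)
        p = Tensor(np.array([[0.0, 1.0, 0.0, 1.0, 0.0, 1.0]]))
        y = np.array([[1.0, 0.0, 1.0, 0.0, 1.0, 0.0]])
        assert np.isfinite(float(dt.total_loss(p, y, model).data))


class TestEncodePredict:
    @pytest.fixture(scope="class")
    def model(self, onto6):
        vocab = dt.Vocabulary([f"t{i}" for i in range(20)])
        cfg = dt.TaggerConfig(embedding_dim=8, hidden_dim=6, seed=1)
        return dt.TaggerModel(cfg, vocab, onto6)

    def test_representation_shape(self, model, onto6):
        ids = np.array([[2, 3, 4]])
        h = model.encode_batch(ids, np.array([3]))
        assert h.shape == (1, 12)  # 2 x hidden for bidirectional
        uni = dt.TaggerModel(
            dt.TaggerConfig(embedding_dim=8, hidden_dim=6, bidirectional=False, seed=1),
            model.vocabulary, onto6,
        )
        assert uni.encode_batch(ids, np.array([3])).shape == (1, 6)

    def test_order_sensitivity(self, model):
        a = model.encode_batch(np.array([[2, 3]]), np.array([2])).data
        b = model.encode_batch(np.array([[3, 2]]), np.array([2])).data
        assert not np.allclose(a, b)

    def test_eval_determinism(self, model):
        ids, lengths = np.array([[5, 6, 7]]), np.array([3])
        a = model.encode_batch(ids, lengths).data
        b = model.encode_batch(ids, lengths).data
        assert (a == b).all()

    def test_empty_sequence_and_bad_ids_rejected(self, model):
        with pytest.raises(ValueError):
            model.encode_batch(np.zeros((1, 0), dtype=int), np.array([0]))
        with pytest.raises(ValueError):
            model.encode_batch(np.array([[999]]), np.array([1]))

    def test_zero_final_layer_gives_half(self, model):
        model2 = dt.TaggerModel(model.config, model.vocabulary, model.ontology)
        model2.label_embeddings.data[:] = 0.0
        model2.label_bias.data[:] = 0.0
        h = model2.encode_batch(np.array([[2, 3]]), np.array([2]))
        probs = model2.logits(h).sigmoid().data
        assert np.allclose(probs, 0.5)

    def test_bias_monotonicity(self, model):
        notes = [dt.Note(id="x", text="", tokens=["t2", "t3"])]
        p0 = model.predict_proba(notes)[0]
        model.label_bias.data[0] += 1.0
        p1 = model.predict_proba(notes)[0]
        model.label_bias.data[0] -= 1.0
        assert p1[0] > p0[0]
        assert np.allclose(np.delete(p1, 0), np.delete(p0, 0))

    def test_batching_invariance(self, model):
        rng = np.random.default_rng(10)
        notes = [
            dt.Note(id=str(i), text="", tokens=[f"t{j}" for j in rng.integers(0, 20, size=L)])
            for i, L in enumerate([3, 7, 5, 2])
        ]
        batched = model.predict_proba(notes, batch_size=4)
        singles = np.vstack([model.predict_proba([n]) for n in notes])
        assert np.allclose(batched, singles, atol=1e-10)

    def test_encoder_gradient_matches_finite_differences(self, model, onto6):
        # end-to-end through the fused LSTM node, embeddings as the probe
        ids = np.array([[2, 3, 4], [5, 6, 0]])
        lengths = np.array([3, 2])
        y = np.array([[1, 0, 1, 0, 0, 1], [0, 1, 0, 0, 1, 0]], dtype=float)

        def loss_value(emb):
            model.embedding.data = emb
            h = model.encode_batch(ids, lengths)
            return float(dt.bce_loss(model.logits(h).sigmoid(), y).data)

        emb0 = model.embedding.data.copy()
        h = model.encode_batch(ids, lengths)
        loss = dt.bce_loss(model.logits(h).sigmoid(), y)
        model.embedding.zero_grad()
        loss.backward()
        grad = model.embedding.grad.copy()
        num = finite_diff(loss_value, emb0.copy(), eps=1e-5)
        model.embedding.data = emb0
        assert rel_err(grad, num) < 1e-4


class TestTraining:
    def test_loss_decreases_and_f1_learns(self, trained_small, small_world):
        model, log = trained_small
        assert log.epoch_losses[0] > log.epoch_losses[-1]
        probs = model.predict_proba(small_world["test"])
        labels = np.stack([n.labels for n in small_world["test"]])
        rep = dt.evaluate(probs, labels)
        assert rep.aggregates["weighted_f1"] > 0.7

    def test_training_determinism(self, small_world):
        cfg = dt.TaggerConfig(embedding_dim=16, hidden_dim=16, max_epochs=2, seed=5)
        logs = []
        for _ in range(2):
            model = dt.TaggerModel(cfg, small_world["vocab"], small_world["ontology"])
            logs.append(dt.train(model, small_world["train"][:64], small_world["val"]))
        assert logs[0].val_weighted_f1 == logs[1].val_weighted_f1
        assert logs[0].epoch_losses == logs[1].epoch_losses

    def test_empty_split_rejected(self, small_world, tiny_model_config):
        model = dt.TaggerModel(
            tiny_model_config, small_world["vocab"], small_world["ontology"]
        )
        with pytest.raises(ValueError):
            dt.train(model, [], small_world["val"])


def test_checkpoint_roundtrip(tmp_path, trained_small, small_world):
    model, _ = trained_small
    path = tmp_path / "model.ckpt.npz"
    model.save(path)
    loaded = dt.TaggerModel.load(path)
    a = model.predict_proba(small_world["test"][:8])
    b = loaded.predict_proba(small_world["test"][:8])
    assert np.allclose(a, b, atol=1e-12)


def test_make_batch_pads_and_truncates(small_world):
    vocab = small_world["vocab"]
    notes = [
        dt.Note(id="a", text="", tokens=["meta0tok0"] * 5),
        dt.Note(id="b", text="", tokens=["meta0tok0"] * 9),
    ]
    ids, lengths = make_batch(notes, vocab, max_len=7)
    assert ids.shape == (2, 7)
    assert list(lengths) == [5, 7]
    assert (ids[0, 5:] == vocab.pad_id).all()
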