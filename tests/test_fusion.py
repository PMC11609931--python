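"""Fusion head: projections, cross-modality attention, simplex weights,
classifier, loss, and whole-model gradient correctness."""

import numpy as np
import pytest

from ildim import autograd as ag
from ildim import fusion
from ildim import text_encoder as te
from ildim.synthetic import GeneratorConfig, generate_dataset

from conftest import finite_difference, relative_error


class TestProjections:
    def test_identity_projection_returns_features(self, rng):
        H = [rng.normal(size=4) for _ in range(3)]
        proj = fusion.ModalityProjection(np.eye(4), np.eye(4), np.eye(4),
                                         nonlinearity="identity")
        alphas = fusion.project_modalities(*H, proj)
        for a, h in zip(alphas, H):
            assert np.allclose(a, h, atol=1e-12)

    def test_zero_features_map_to_zero_under_tanh(self, rng):
        proj = fusion.ModalityProjection(*(rng.normal(size=(4, 4))
                                           for _ in range(3)))
        alphas = fusion.project_modalities(np.zeros(4), np.zeros(4),
                                           np.zeros(4), proj)
        for a in alphas:
            assert np.allclose(a, 0.0)

    def test_matches_matrix_vector_oracle(self, rng):
        Ws = [rng.normal(size=(5, 5)) for _ in range(3)]
        Hs = [rng.normal(size=5) for _ in range(3)]
        proj = fusion.ModalityProjection(*Ws)
        alphas = fusion.project_modalities(*Hs, proj)
        for a, W, h in zip(alphas, Ws, Hs):
            oracle = np.tanh(np.array([W[r] @ h for r in range(5)]))
            assert np.max(np.abs(a - oracle)) <= 1e-10

    def test_length_mismatch_rejected(self, rng):
        proj = fusion.ModalityProjection(*(np.eye(4) for _ in range(3)))
        with pytest.raises(ValueError, match="length"):
            fusion.project_modalities(np.zeros(5), np.zeros(4), np.zeros(4), proj)


class TestFuseAttention:
    def test_identical_tokens_give_identical_rows(self, rng):
        attn = te.init_attention(8, 2, rng)
        a = rng.normal(size=8)
        out = fusion.fuse_attention(a, a, a, attn)
        assert np.allclose(out[0], out[1], atol=1e-12)
        assert np.allclose(out[1], out[2], atol=1e-12)

    def test_swapping_tokens_swaps_rows(self, rng):
        attn = te.init_attention(8, 2, rng)
        a, b, c = (rng.normal(size=8) for _ in range(3))
        out = fusion.fuse_attention(a, b, c, attn)
        swapped = fusion.fuse_attention(b, a, c, attn)
        assert np.allclose(out[0], swapped[1], atol=1e-12)
        assert np.allclose(out[1], swapped[0], atol=1e-12)
        assert np.allclose(out[2], swapped[2], atol=1e-12)

    def test_uniform_attention_averages_tokens(self, rng):
        d = 6
        attn = te.AttentionParams(
            w_q=np.zeros((1, d, d)), w_k=np.zeros((1, d, d)),
            w_v=np.eye(d)[None], w_o=np.eye(d),
        )
        a, b, c = (rng.normal(size=d) for _ in range(3))
        out = fusion.fuse_attention(a, b, c, attn)
        mean = (a + b + c) / 3
        for row in out:
            assert np.allclose(row, mean, atol=1e-12)


class TestFusionWeightsAndFuse:
    def test_equal_scores_uniform(self):
        assert np.allclose(fusion.fusion_weights(np.zeros(3)), 1 / 3)

    def test_closed_form_log_scores(self):
        w = fusion.fusion_weights(np.log([1.0, 2.0, 1.0]))
        assert np.allclose(w, [0.25, 0.5, 0.25], atol=1e-12)

    def test_shift_invariance(self, rng):
        s = rng.normal(size=3)
        assert np.allclose(fusion.fusion_weights(s),
                           fusion.fusion_weights(s + 11.0), atol=1e-12)

    def test_non_finite_scores_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            fusion.fusion_weights(np.array([np.nan, 0.0, 0.0]))

    def test_one_hot_weight_selects_row(self, rng):
        betas = rng.normal(size=(3, 6))
        M = fusion.weighted_fuse(betas, np.array([0.0, 1.0, 0.0]))
        assert np.array_equal(M, betas[1])

    def test_identical_rows_any_simplex_weight(self, rng):
        row = rng.normal(size=6)
        betas = np.tile(row, (3, 1))
        w = fusion.fusion_weights(rng.normal(size=3))
        assert np.allclose(fusion.weighted_fuse(betas, w), row, atol=1e-12)

    def test_matches_loop_oracle(self, rng):
        for _ in range(20):
            betas = rng.normal(size=(3, 5))
            w = fusion.fusion_weights(rng.normal(size=3))
            oracle = sum(w[m] * betas[m] for m in range(3))
            assert np.max(np.abs(fusion.weighted_fuse(betas, w) - oracle)) <= 1e-10

    def test_non_simplex_weights_rejected(self, rng):
        with pytest.raises(ValueError, match="sum to 1"):
            fusion.weighted_fuse(rng.normal(size=(3, 4)),
                                 np.array([0.5, 0.2, 0.1]))


class TestClassifierAndLoss:
    def test_zero_parameters_give_uniform_binary(self):
        cls = fusion.ClassifierParams(weight=np.zeros((2, 4)), bias=np.zeros(2))
        assert np.allclose(fusion.classify(np.ones(4), cls), 0.5)

    def test_closed_form_logits(self):
        cls = fusion.ClassifierParams(weight=np.zeros((2, 3)),
                                      bias=np.array([0.0, np.log(3.0)]))
        assert np.allclose(fusion.classify(np.zeros(3), cls), [0.25, 0.75],
                           atol=1e-12)

    def test_probabilities_normalize(self, rng):
        for _ in range(100):
            cls = fusion.ClassifierParams(weight=rng.normal(size=(3, 5)),
                                          bias=rng.normal(size=3))
            p = fusion.classify(rng.normal(size=5), cls)
            assert abs(p.sum() - 1.0) < 1e-12
            assert np.all(p >= 0)

    def test_cross_entropy_closed_forms(self):
        assert fusion.cross_entropy(np.array([1.0, 0.0]),
                                    np.array([1.0, 0.0])) <= 1e-10
        assert fusion.cross_entropy(np.array([0.5, 0.5]), np.array([0.0, 1.0])
                                    ) == pytest.approx(np.log(2), abs=1e-12)
        assert fusion.cross_entropy(np.array([0.25, 0.75]), np.array([0.0, 1.0])
                                    ) == pytest.approx(np.log(4 / 3), abs=1e-12)

    def test_cross_entropy_rejects_non_one_hot(self):
        with pytest.raises(ValueError, match="one-hot"):
            fusion.cross_entropy(np.array([0.5, 0.5]), np.array([0.5, 0.5]))

    def test_shape_mismatch_rejected(self):
        cls = fusion.ClassifierParams(weight=np.zeros((2, 4)), bias=np.zeros(2))
        with pytest.raises(ValueError):
            fusion.classify(np.ones(5), cls)


class TestFullModel:
    def test_prediction_tie_breaks_to_lower_class(self, tiny_model_config,
                                                  tiny_dataset):
        samples, _ = tiny_dataset
        params = fusion.init_model(tiny_model_config, seed=0)
        params.classifier.weight[:] = 0.0
        params.classifier.bias[:] = 0.0
        probs, label = fusion.predict(samples[0], params)
        assert np.allclose(probs, 0.5)
        assert label == 0

    def test_prediction_deterministic(self, tiny_model_config, tiny_dataset):
        samples, _ = tiny_dataset
        params = fusion.init_model(tiny_model_config, seed=3)
        p1, l1 = fusion.predict(samples[0], params)
        p2, l2 = fusion.predict(samples[0], params)
        assert np.array_equal(p1, p2) and l1 == l2

    def test_predict_consistent_with_training_forward(self, tiny_model_config,
                                                      tiny_dataset):
        from ildim.harness import train
        from ildim.config import TrainConfig
        samples, _ = tiny_dataset
        params, _ = train(samples, tiny_model_config,
                          TrainConfig(epochs=1, rng_seed=5, batch_size=4))
        batch_probs = fusion.forward_batch(params, samples[:3])[0].data
        for i in range(3):
            probs, _ = fusion.predict(samples[i], params)
            assert np.max(np.abs(probs - batch_probs[i])) <= 1e-10

    def test_probabilities_and_fusion_weights_on_simplex(self, tiny_model_config):
        cfg = GeneratorConfig(
            n_cases=300, n_controls=200, image_size=16, series_length=5,
            series_channels=2, vocab_size=30, rng_seed=21,
        )
        samples, _ = generate_dataset(cfg)
        params = fusion.init_model(tiny_model_config, seed=2)
        probs = fusion.forward_batch(params, samples)[0].data
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        for s in samples:
            st = fusion.fusion_state(s, params)
            assert np.all(st.weights >= 0)
            assert abs(st.weights.sum() - 1.0) <= 1e-9

    def test_masked_model_fuses_within_remaining_tokens(self, tiny_model_config,
                                                        tiny_dataset):
        samples, _ = tiny_dataset
        cfg = tiny_model_config.with_modalities(("image", "text"))
        params = fusion.init_model(cfg, seed=4)
        st = fusion.fusion_state(samples[0], params)
        assert st.betas.shape[0] == 2
        assert len(st.weights) == 2
        assert np.all(st.fused <= st.betas.max(axis=0) + 1e-12)
        assert np.all(st.fused >= st.betas.min(axis=0) - 1e-12)

    def test_missing_modality_rejected(self, tiny_model_config, tiny_dataset):
        samples, _ = tiny_dataset
        params = fusion.init_model(tiny_model_config, seed=0)
        broken = fusion.MultimodalSample(
            sample_id="x", image=None, series=samples[0].series,
            tokens=samples[0].tokens, label=0,
        )
        with pytest.raises(ValueError, match="missing modality"):
            fusion.predict(broken, params)

    def test_full_model_gradients_match_finite_differences(
            self, tiny_model_config, tiny_dataset, rng):
        """Every parameter group of the assembled model passes a central
        finite-difference check within 1e-3 relative error."""
        samples, _ = tiny_dataset
        batch = samples[:2]
        ref = fusion.init_model(tiny_model_config, seed=9)

        def loss():
            return float(fusion.batch_loss(ref, batch).data)

        grads_params = fusion.init_model(tiny_model_config, seed=9)
        leaves = fusion.tensorize(grads_params)
        names = [n for n, _ in grads_params.named_parameters()]
        fusion.batch_loss(grads_params, batch).backward()

        ref_arrays = dict(ref.named_parameters())
        for name, leaf in zip(names, leaves):
            arr = ref_arrays[name]
            size = arr.size
            entries = rng.choice(size, size=min(4, size), replace=False)
            fd = finite_difference(loss, arr, entries)
            analytic = (np.zeros(size) if leaf.grad is None
                        else leaf.grad.reshape(-1))[entries]
            mask = np.abs(fd) > 1e-7
            if mask.any():
                err = relative_error(analytic[mask], fd[mask], floor=1e-5).max()
                assert err < 1e-3, f"{name}: {err}"


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, tiny_model_config,
                                              tiny_dataset, tmp_path):
        samples, _ = tiny_dataset
        params = fusion.init_model(tiny_model_config, seed=6)
        probs_before, _ = fusion.predict(samples[0], params)
        path = tmp_path / "ckpt.zip"
        fusion.save_checkpoint(params, path)
        loaded = fusion.load_checkpoint(path)
        probs_after, _ = fusion.predict(samples[0], loaded)
        assert np.array_equal(probs_before, probs_after)

    def test_missing_checkpoint_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="nowhere.zip"):
            fusion.load_checkpoint(tmp_path / "nowhere.zip")
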