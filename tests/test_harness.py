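"""Training loop, metrics, ablation runner, and introspection tables."""

import numpy as np
import pytest

from ildim import fusion, harness
from ildim.config import ModelConfig, TrainConfig
from ildim.synthetic import MultimodalSample, split_samples


def auc_all_pairs(y, scores):
    """Brute-force Mann-Whitney: count pairs, ties worth 1/2."""
    y = np.asarray(y)
    pos = np.asarray(scores)[y == 1]
    neg = np.asarray(scores)[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestTrain:
    def test_zero_learning_rate_leaves_parameters_unchanged(
            self, tiny_model_config, tiny_dataset):
        samples, _ = tiny_dataset
        tc = TrainConfig(epochs=3, learning_rate=0.0, rng_seed=2, batch_size=4)
        params, history = harness.train(samples, tiny_model_config, tc)
        fresh = fusion.init_model(tiny_model_config, seed=2)
        for (_, a), (_, b) in zip(params.named_parameters(),
                                  fresh.named_parameters()):
            assert np.array_equal(a, b)
        assert np.allclose(history, history[0], atol=1e-12)

    def test_training_reduces_loss_on_strong_signal(self, tiny_model_config,
                                                    tiny_dataset):
        samples, _ = tiny_dataset
        tc = TrainConfig(epochs=8, rng_seed=11, batch_size=7)
        _, history = harness.train(samples, tiny_model_config, tc)
        assert history[-1] < history[0]

    def test_identical_seeds_reproduce_loss_history(self, tiny_model_config,
                                                    tiny_dataset):
        samples, _ = tiny_dataset
        tc = TrainConfig(epochs=3, rng_seed=4, batch_size=4)
        _, h1 = harness.train(samples, tiny_model_config, tc)
        _, h2 = harness.train(samples, tiny_model_config, tc)
        assert np.array_equal(h1, h2)

    def test_single_class_training_set_rejected(self, tiny_model_config,
                                                tiny_dataset):
        samples, _ = tiny_dataset
        cases = [s for s in samples if s.label == 1]
        with pytest.raises(ValueError, match="both classes"):
            harness.train(cases, tiny_model_config, TrainConfig(epochs=1))


class TestMetrics:
    def test_confusion_arithmetic(self):
        precision, recall, f1 = harness.classification_metrics(8, 2, 1, 9)
        assert precision == pytest.approx(9 / 11)
        assert recall == pytest.approx(0.9)
        assert f1 == pytest.approx(2 * (9 / 11) * 0.9 / (9 / 11 + 0.9))

    def test_auc_matches_all_pairs_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 30))
            y = rng.integers(0, 2, size=n)
            if len(np.unique(y)) < 2:
                y[0], y[1] = 0, 1
            scores = np.round(rng.random(n), 1)  # coarse grid forces ties
            assert abs(harness.auc_mann_whitney(y, scores)
                       - auc_all_pairs(y, scores)) <= 1e-12

    def test_perfect_separation(self):
        y = np.array([0, 0, 1, 1])
        assert harness.auc_mann_whitney(y, [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_auc_requires_both_classes(self):
        with pytest.raises(ValueError, match="both classes"):
            harness.auc_mann_whitney(np.array([1, 1]), [0.2, 0.8])

    def test_evaluate_on_single_class_split_returns_metrics_without_auc(
            self, tiny_model_config, tiny_dataset):
        samples, _ = tiny_dataset
        params = fusion.init_model(tiny_model_config, seed=0)
        report = harness.evaluate(params, [s for s in samples if s.label == 1])
        assert report.auc is None
        assert report.roc_points == []
        assert report.confusion.sum() == sum(s.label == 1 for s in samples)

    def test_evaluate_counts_sum_to_test_size(self, tiny_model_config,
                                              tiny_dataset):
        samples, _ = tiny_dataset
        params = fusion.init_model(tiny_model_config, seed=1)
        report = harness.evaluate(params, samples)
        assert report.confusion.sum() == len(samples)
        assert report.roc_points == sorted(report.roc_points)


class TestAblate:
    def test_full_subset_equals_plain_run(self, tiny_model_config, tiny_dataset):
        tc = TrainConfig(epochs=2, rng_seed=3, batch_size=4)
        reports = harness.ablate(tiny_dataset, tiny_model_config, tc,
                                 subsets=[("image", "series", "text")])
        _, _, plain = harness.run_experiment(tiny_dataset, tiny_model_config, tc)
        rep = reports[("image", "series", "text")]
        assert rep.to_dict() == plain.to_dict()

    def test_empty_subset_rejected(self, tiny_model_config, tiny_dataset):
        with pytest.raises(ValueError, match="non-empty"):
            harness.ablate(tiny_dataset, tiny_model_config,
                           TrainConfig(epochs=1), subsets=[()])

    def test_six_default_subsets(self):
        assert len(harness.ABLATION_SUBSETS) == 6
        assert ("image", "series", "text") in harness.ABLATION_SUBSETS

    def test_ranking_orders_by_auc(self, tiny_model_config, tiny_dataset):
        tc = TrainConfig(epochs=1, rng_seed=3, batch_size=4)
        reports = harness.ablate(tiny_dataset, tiny_model_config, tc,
                                 subsets=[("image",), ("series",)])
        ranking = harness.rank_subsets(reports)
        aucs = [reports[s].auc for s in ranking]
        assert aucs == sorted(aucs, reverse=True)


class TestIntrospection:
    def test_dense_and_conv_param_arithmetic(self):
        assert harness.dense_param_count(256, 10) == 2570
        assert harness.conv_param_count(3, 64, 3, 3) == 1792
        assert harness.dense_param_count(4, 2, bias=False) == 8

    @pytest.mark.parametrize("seed", range(10))
    def test_count_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        d_model = int(rng.choice([8, 16]))
        heads = int(rng.choice([2, 4]))
        mods = [("image",), ("series", "text"),
                ("image", "series", "text")][seed % 3]
        cfg = ModelConfig(
            d_model=d_model,
            image_size=int(rng.choice([16, 32])),
            series_length=int(rng.integers(4, 10)),
            modalities=mods,
        )
        cfg.image_encoder.channels = tuple(
            int(c) for c in rng.choice([2, 4, 8], size=rng.integers(1, 3))
        )
        cfg.sequence_encoder.hidden_size = int(rng.integers(3, 12))
        cfg.text_encoder.vocab_size = int(rng.integers(25, 80))
        cfg.text_encoder.heads = heads
        cfg.fusion.heads = heads
        _, total = harness.count_parameters(cfg)
        assert total == fusion.init_model(cfg, seed=0).n_parameters()

    def test_zero_layer_image_branch_total(self):
        cfg = ModelConfig(modalities=("series",))
        rows, total = harness.count_parameters(cfg)
        assert all("Conv" not in r.layer for r in rows)
        assert total == fusion.init_model(cfg, seed=0).n_parameters()

    def test_flops_closed_forms(self):
        # 1x1 conv over an HxW single-channel image costs exactly H*W MACs
        cfg = ModelConfig(modalities=("image",), image_size=20)
        cfg.image_encoder.channels = (1,)
        cfg.image_encoder.kernel_size = 1
        rows, _, _ = harness.estimate_flops(cfg)
        macs = dict(rows)
        assert macs["conv0"] == 20 * 20
        # a d x d matrix-vector product costs d^2 MACs per modality token
        assert macs["projections"] == cfg.d_model ** 2

    def test_doubling_image_side_quadruples_1x1_conv_macs(self):
        def conv_macs(size):
            cfg = ModelConfig(modalities=("image",), image_size=size)
            cfg.image_encoder.channels = (1,)
            cfg.image_encoder.kernel_size = 1
            return dict(harness.estimate_flops(cfg)[0])["conv0"]

        assert conv_macs(40) == 4 * conv_macs(20)

    def test_flops_are_twice_macs(self):
        _, macs, flops = harness.estimate_flops(ModelConfig())
        assert flops == 2 * macs
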