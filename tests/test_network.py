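"""Network construction, losses, freeze contracts, and desk-scale training
behavior of the three-step transfer-learning harness."""

import numpy as np
import pytest

from idrlig.network import (
    NetworkBundle,
    NetworkConfig,
    REFERENCE_FULL_SCALE_COUNTS,
    build_network,
    build_site_target,
    make_predictor_examples,
    pearson_loss,
    predict,
    train_site_decoder,
)
from idrlig import network as nw
from idrlig.sequences import AA_INDEX, Sequence, encode_pair_tensor, featurize, smooth_tensor

from conftest import FAMILIES, PIPELINE_SEED, RULES, pooled_site_scores


def rank_auc(scores, labels):
    """Mann-Whitney AUC with tie averaging (independent of any ROC code)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    order = np.argsort(scores, kind="mergesort")
    ranks = np.empty(len(scores))
    sorted_scores = scores[order]
    i = 0
    while i < len(scores):
        j = i
        while j + 1 < len(scores) and sorted_scores[j + 1] == sorted_scores[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    n_pos = labels.sum()
    n_neg = (~labels).sum()
    return (ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


class TestBuild:
    def test_dense_layer_parameter_arithmetic(self):
        bundle = build_network(NetworkConfig(), rng_seed=0)
        assert bundle.params["encoder/dense2_W"].size + bundle.params["encoder/dense2_b"].size == 8_020
        assert bundle.params["predictor/out_W"].size + bundle.params["predictor/out_b"].size == 34_887

    def test_counts_are_deterministic_in_config(self):
        counts8 = build_network(
            NetworkConfig.reduced(output_classes=3), rng_seed=0
        ).parameter_counts()
        counts16 = build_network(
            NetworkConfig.reduced(output_classes=3), rng_seed=5
        ).parameter_counts()
        assert counts8 == counts16  # independent of init seed

    def test_doubling_filters_changes_only_conv_dependent_terms(self):
        from dataclasses import replace

        base_cfg = NetworkConfig.reduced(output_classes=3)
        double_cfg = replace(base_cfg, conv_filters=2 * base_cfg.conv_filters)
        base = build_network(base_cfg, rng_seed=0)
        double = build_network(double_cfg, rng_seed=0)
        # decoder has no convolution: identical count
        assert base.parameter_counts()["decoder"] == double.parameter_counts()["decoder"]
        window = 20 * 20 * 3
        positions = 18
        f = base_cfg.conv_filters
        d1 = base_cfg.encoder_dense[0]
        expected_delta = (window * f + f) + positions * f * d1
        delta = double.parameter_counts()["encoder"] - base.parameter_counts()["encoder"]
        assert delta == expected_delta

    def test_reference_counts_are_logged_not_asserted(self):
        bundle = build_network(NetworkConfig(), rng_seed=0)
        counts = bundle.parameter_counts()
        # counts exist for the same part names as the reference figures
        assert set(REFERENCE_FULL_SCALE_COUNTS) <= set(counts)

    def test_invalid_encoding_dimension_rejected(self):
        with pytest.raises(ValueError, match="encoding dimension"):
            NetworkConfig(encoder_dense=(400, 10))


class TestPearsonLoss:
    def test_identity_and_negation_give_zero(self):
        x = np.arange(10.0)
        assert pearson_loss(x, x) == pytest.approx(0.0)
        assert pearson_loss(x, -x) == pytest.approx(0.0)

    def test_constant_input_gives_one(self):
        assert pearson_loss(np.arange(5.0), np.ones(5)) == pytest.approx(1.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            pearson_loss(np.zeros(3), np.zeros(4))

    def test_gradients_match_numerics(self):
        rng = np.random.default_rng(0)
        pred = rng.random((2, 50))
        target = rng.random((2, 50))
        _, grad, _ = nw._pearson_batch_loss(pred, target)
        eps = 1e-6
        for b, i in [(0, 3), (1, 17)]:
            pred_hi = pred.copy()
            pred_hi[b, i] += eps
            pred_lo = pred.copy()
            pred_lo[b, i] -= eps
            numeric = (
                nw._pearson_batch_loss(pred_hi, target)[0]
                - nw._pearson_batch_loss(pred_lo, target)[0]
            ) / (2 * eps)
            assert grad[b, i] == pytest.approx(numeric, abs=1e-6)


class TestSiteTarget:
    def test_single_site_hand_enumeration(self):
        seq = Sequence("t", "ACA")
        target = build_site_target(seq, {2})
        full = smooth_tensor(encode_pair_tensor(seq, site_positions={2}))
        np.testing.assert_allclose(target.values, full.values)
        # before smoothing: only (A,C,1), (C,A,1) pairs and C's k=0 count
        raw = encode_pair_tensor(seq, site_positions={2}).values
        A, C = AA_INDEX["A"], AA_INDEX["C"]
        assert raw[A, C, 1] == pytest.approx(1 / 3)
        assert raw[C, A, 1] == pytest.approx(1 / 3)
        assert raw[C, C, 0] == pytest.approx(1 / 60)
        assert raw[A, A, 0] == 0.0
        assert raw[A, A, 2] == 0.0

    def test_all_sites_equals_plain_encoding(self):
        seq = Sequence("t", "ACDEFGHIK")
        target = build_site_target(seq, set(range(1, 10)))
        np.testing.assert_allclose(target.values, featurize(seq).values)

    def test_empty_sites_give_zero_tensor(self):
        target = build_site_target(Sequence("t", "ACDE"), set())
        assert target.values.sum() == 0.0


class TestTrainingContracts:
    def test_freeze_contract_step2(self, trained_pipeline):
        before, after = trained_pipeline["encoder_checksums_step2"]
        assert before == after

    def test_freeze_contract_step3(self, trained_pipeline):
        before, after = trained_pipeline["frozen_checksums_step3"]
        assert before == after

    def test_autoencoder_loss_improves(self, trained_pipeline):
        history = trained_pipeline["history1"]
        assert history[-1]["train_loss"] < history[0]["train_loss"]

    def test_training_is_deterministic_under_seed(self, study_tensors):
        from dataclasses import replace

        cfg = NetworkConfig.reduced(output_classes=3)
        cfg = replace(cfg, epochs={**cfg.epochs, "step1": 3})
        _, h1 = nw.train_autoencoder(study_tensors[:40], cfg, rng_seed=13)
        _, h2 = nw.train_autoencoder(study_tensors[:40], cfg, rng_seed=13)
        assert h1 == h2

    def test_zero_epoch_training_leaves_decoder_unchanged(self, study_tensors):
        from dataclasses import replace

        cfg = NetworkConfig.reduced(output_classes=3)
        cfg_zero = replace(cfg, epochs={**cfg.epochs, "step2": 0})
        bundle = build_network(cfg_zero, rng_seed=1)
        bundle.step = "step1"
        before = bundle.checksum("decoder")
        seq = Sequence("s", "ACDEFGHIKLMNPQRSTVWY")
        pairs = [(featurize(seq), build_site_target(seq, {3}))] * 4
        bundle, history = train_site_decoder(bundle, pairs, cfg_zero, rng_seed=1)
        assert history == []
        assert bundle.checksum("decoder") == before

    def test_memorization_of_identical_tensors(self):
        from dataclasses import replace

        cfg = NetworkConfig.reduced(output_classes=3)
        cfg = replace(cfg, epochs={**cfg.epochs, "step1": 40})
        seq = Sequence("m", "ACDEFGHIKLMNPQRSTVWYACDEFGHIKL")
        tensors = [featurize(seq)] * 20
        _, history = nw.train_autoencoder(tensors, cfg, rng_seed=2)
        assert history[-1]["test_corr"] > 0.9


class TestPrediction:
    def test_output_shapes_and_normalization(self, trained_pipeline):
        seq = Sequence("q", "ACDEFGHIKLMNPQRSTVWYPEPSEKG")
        encoding, scores, groups = predict(trained_pipeline["bundle"], seq)
        assert encoding.shape == (20,)
        assert (np.abs(encoding) < 1).all()
        assert len(scores.normalized) == len(seq)
        assert groups.raw.sum() == pytest.approx(1.0, abs=1e-6)
        assert groups.normalized.max() == pytest.approx(1.0)

    def test_predictor_softmax_sums_to_one_for_batches(self, trained_pipeline):
        rng = np.random.default_rng(0)
        x = rng.random((5, 20, 20, 20)) * 1e-3
        probs, _ = nw.predictor_forward(x.reshape(5, -1), trained_pipeline["bundle"])
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_untrained_bundles_score_sites_at_chance(self, heldout_records):
        """Random-weight control: mean site AUC over 20 inits stays near 0.5."""
        cfg = NetworkConfig.reduced(output_classes=3)
        aucs = []
        for init in range(20):
            bundle = build_network(cfg, rng_seed=1000 + init)
            scores, labels = pooled_site_scores(bundle, heldout_records[:20])
            aucs.append(rank_auc(scores, labels))
        assert 0.4 <= float(np.mean(aucs)) <= 0.6


class TestCheckpointIO:
    def test_save_load_roundtrip(self, tmp_path, trained_pipeline):
        bundle = trained_pipeline["bundle"]
        path = tmp_path / "weights.h5"
        bundle.save(path)
        back = NetworkBundle.load(path)
        assert back.step == bundle.step
        assert back.cfg == bundle.cfg
        for part in ("encoder", "decoder", "predictor"):
            assert back.checksum(part) == bundle.checksum(part)


class TestExampleExpansion:
    def test_multilabel_records_expand_per_protogroup(self, site_records):
        from idrlig.datasets import InteractionRecord

        rec = site_records[0]
        multi = InteractionRecord(
            segment=rec.segment, site_positions=rec.site_positions,
            protogroup_ids={1, 2, 3},
        )
        examples = make_predictor_examples([multi], vocab_size=3)
        assert len(examples) == 3
        onehots = np.stack([e[1] for e in examples])
        np.testing.assert_allclose(onehots, np.eye(3))
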