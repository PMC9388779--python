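"""CNN building blocks: labelling, oversampling, shapes, gradients,
revert-style early stopping and frozen-layer fine-tuning."""

import numpy as np
import pytest

from tdcsfc.cnn_transfer import (
    CnnArchitecture,
    TrainConfig,
    assign_cgi_labels,
    build_cnn,
    oversample_balance,
    softmax_cross_entropy,
    train_with_revert,
    transfer_finetune,
)
from tdcsfc.synthetic import PretrainRecord


def _rec(i, group="HC", cgi=0, sex=0, age=30.0):
    return PretrainRecord(f"r{i}", group, cgi, sex, age, np.zeros((2, 2, 2)))


class TestAssignCgiLabels:
    def test_rule_and_totality(self):
        records = [
            _rec(0, "HC", 0),
            _rec(1, "FDR", 0),
            _rec(2, "SZ", 5),
            _rec(3, "OCD", 4),
            _rec(4, "SZ", 3),  # boundary: strictly > 3 required
            _rec(5, "HC", 2),  # healthy with nonzero CGI matches no rule
        ]
        labelled, excluded = assign_cgi_labels(records)
        assert len(labelled) + excluded == len(records)
        assert [l for _, l in labelled] == [0, 0, 1, 1]
        assert excluded == 2


class TestOversampleBalance:
    def test_already_balanced_unchanged(self):
        labelled = [(_rec(i), i % 2) for i in range(10)]
        assert oversample_balance(labelled, seed=0) == labelled

    def test_three_one_gives_six_with_triplicate(self):
        labelled = [(_rec(0), 0), (_rec(1), 0), (_rec(2), 0), (_rec(3), 1)]
        out = oversample_balance(labelled, seed=0)
        assert len(out) == 6
        assert sum(1 for r, l in out if l == 1) == 3
        assert all(r.record_id == "r3" for r, l in out if l == 1)

    def test_majority_class_untouched(self):
        rng = np.random.default_rng(0)
        labelled = [
            (_rec(i, sex=int(rng.random() < 0.5), age=float(rng.uniform(20, 50))),
             0 if i < 30 else 1)
            for i in range(50)
        ]
        out = oversample_balance(labelled, seed=1)
        assert len(out) == 60
        maj_in = sorted(r.record_id for r, l in labelled if l == 0)
        maj_out = sorted(r.record_id for r, l in out if l == 0)
        assert maj_in == maj_out


SMALL_ARCH = CnnArchitecture(
    input_dims=(8, 8, 8),
    conv_blocks=((3, 1, 1, 4), (3, 1, 4, 8)),
    pool=(2, 2),
    fc_units=8,
    dropout_rate=0.0,
)


def _blobs(n, cls, rng):
    X = rng.normal(0, 0.3, size=(n, 8, 8, 8))
    if cls == 0:
        X[:, 2:5, 2:5, 2:5] += 1.0
    else:
        X[:, 4:7, 4:7, 4:7] += 1.0
    return X


@pytest.fixture(scope="module")
def blob_data():
    rng = np.random.default_rng(0)
    Xtr = np.concatenate([_blobs(20, 0, rng), _blobs(20, 1, rng)])
    ytr = np.array([0] * 20 + [1] * 20)
    Xv = np.concatenate([_blobs(8, 0, rng), _blobs(8, 1, rng)])
    yv = np.array([0] * 8 + [1] * 8)
    return (Xtr, ytr), (Xv, yv)


class TestBuildCnn:
    def test_forward_returns_two_logits_default_arch(self):
        model = build_cnn(CnnArchitecture(dropout_rate=0.0), seed=0)
        x = np.zeros((2, 24, 28, 24))
        logits = model.forward(x)
        assert logits.shape == (2, 2)

    def test_all_zero_input_logits_are_input_independent(self):
        model = build_cnn(SMALL_ARCH, seed=0)
        a = model.forward(np.zeros((1, 8, 8, 8)))
        b = model.forward(np.zeros((3, 8, 8, 8)))
        np.testing.assert_allclose(np.tile(a, (3, 1)), b, atol=1e-12)

    def test_parameter_count_arithmetic_on_filter_doubling(self):
        import dataclasses

        m1 = build_cnn(SMALL_ARCH, seed=0)
        doubled = dataclasses.replace(
            SMALL_ARCH, conv_blocks=((3, 1, 1, 8), (3, 1, 8, 8))
        )
        m2 = build_cnn(doubled, seed=0)
        # closed form: conv1 gains 4*(27+1); conv2 input channels 4 -> 8
        delta_conv1 = 4 * (1 * 27 + 1)
        delta_conv2 = 8 * (8 - 4) * 27
        assert m2.parameter_count() - m1.parameter_count() == delta_conv1 + delta_conv2

    def test_shape_underflow_names_offending_block(self):
        bad = CnnArchitecture(
            input_dims=(8, 8, 8),
            conv_blocks=((3, 1, 1, 2), (3, 1, 2, 2), (3, 1, 2, 2), (3, 1, 2, 2)),
        )
        with pytest.raises(ValueError, match="block"):
            build_cnn(bad)

    def test_backprop_matches_numerical_gradient(self):
        arch = CnnArchitecture(
            input_dims=(6, 6, 6), conv_blocks=((3, 1, 1, 2), (3, 1, 2, 3)),
            pool=(2, 2), fc_units=4, dropout_rate=0.0,
        )
        model = build_cnn(arch, seed=0)
        rng = np.random.default_rng(1)
        X = rng.normal(size=(3, 6, 6, 6))
        y = np.array([0, 1, 0])
        loss, d = softmax_cross_entropy(model.forward(X), y)
        model.backward(d)
        eps = 1e-5
        for layer in model.layers:
            for name, p in layer.params.items():
                idx = tuple(rng.integers(0, s) for s in p.shape)
                p[idx] += eps
                l1, _ = softmax_cross_entropy(model.forward(X), y)
                p[idx] -= 2 * eps
                l2, _ = softmax_cross_entropy(model.forward(X), y)
                p[idx] += eps
                num = (l1 - l2) / (2 * eps)
                np.testing.assert_allclose(layer.grads[name][idx], num, atol=1e-7)


class TestTrainWithRevert:
    def test_loss_decreases_on_separable_blobs(self, blob_data):
        train, val = blob_data
        successes = 0
        for seed in range(10):
            model = build_cnn(SMALL_ARCH, seed=seed)
            hist = train_with_revert(
                model, train, val,
                TrainConfig(learning_rate=1e-3, max_epochs=10, patience_epochs=9,
                            seed=seed),
            )
            if hist["train_loss"][-1] < hist["train_loss"][0]:
                successes += 1
        assert successes >= 9

    def test_strictly_decreasing_error_never_reverts(self, blob_data):
        train, val = blob_data
        model = build_cnn(SMALL_ARCH, seed=0)
        errs = iter(1.0 / (e + 1) for e in range(100))
        hist = train_with_revert(
            model, (train[0][:4], train[1][:4]), val,
            TrainConfig(learning_rate=1e-3, max_epochs=15, patience_epochs=10, seed=0),
            eval_fn=lambda m, e: next(errs),
        )
        assert hist["reverted_to_epoch"] is None
        assert hist["stopped_epoch"] == 14

    def test_scripted_flat_error_reverts_to_last_improvement(self, blob_data):
        train, val = blob_data
        model = build_cnn(SMALL_ARCH, seed=1)
        snaps = {}

        def eval_fn(m, epoch):
            snaps[epoch] = m.get_state()
            return 1.0 / (epoch + 1) if epoch < 37 else 1.0 / 38

        hist = train_with_revert(
            model, (train[0][:4], train[1][:4]), val,
            TrainConfig(learning_rate=1e-3, max_epochs=200, patience_epochs=10, seed=0),
            eval_fn=eval_fn,
        )
        assert hist["reverted_to_epoch"] == 37
        assert hist["stopped_epoch"] == 47
        for a, b in zip(model.get_state(), snaps[37]):
            np.testing.assert_array_equal(a, b)

    def test_nonfinite_loss_aborts(self, blob_data):
        train, val = blob_data
        model = build_cnn(SMALL_ARCH, seed=0)
        corrupted = train[0].copy()
        corrupted[0, 0, 0, 0] = np.nan
        with pytest.raises(FloatingPointError):
            train_with_revert(
                model, (corrupted, train[1]), val,
                TrainConfig(learning_rate=1e-3, max_epochs=5, patience_epochs=4,
                            seed=0),
            )


class TestTransferFinetune:
    def test_frozen_parameters_bit_identical(self, blob_data):
        train, val = blob_data
        pre = build_cnn(SMALL_ARCH, seed=0)
        hist = train_with_revert(
            pre, train, val,
            TrainConfig(learning_rate=1e-3, max_epochs=5, patience_epochs=4, seed=0),
        )
        before = pre.frozen_checksum(2)
        ft, _ = transfer_finetune(
            pre, train, val,
            TrainConfig(learning_rate=1e-3, max_epochs=5, patience_epochs=4, seed=1),
            n_frozen_layers=2,
        )
        assert ft.frozen_checksum(2) == before
        for a, b in zip(pre.feature_layers, ft.feature_layers):
            for k in a.params:
                np.testing.assert_array_equal(a.params[k], b.params[k])

    def test_zero_frozen_layers_allows_feature_updates(self, blob_data):
        train, val = blob_data
        pre = build_cnn(SMALL_ARCH, seed=0)
        ft, _ = transfer_finetune(
            pre, train, val,
            TrainConfig(learning_rate=1e-2, max_epochs=3, patience_epochs=2, seed=1),
            n_frozen_layers=0,
        )
        changed = any(
            not np.array_equal(a.params[k], b.params[k])
            for a, b in zip(pre.feature_layers, ft.feature_layers)
            for k in a.params
        )
        assert changed

    def test_pretrained_init_reaches_loss_faster(self):
        """Paired runs isolating the initialization advantage: warm start
        (pre-trained features, fresh head, all layers trainable) vs. random
        init on a target task sharing the source structure.  The task is a
        corner-parity labelling (not linearly decodable from random conv
        features), so trained features genuinely matter."""
        corners = [(1, 1, 1), (5, 5, 1), (1, 5, 5), (5, 1, 5)]

        def xor_task(n_per, rng, noise=0.5):
            X, y = [], []
            for ci, c in enumerate(corners):
                for _ in range(n_per):
                    v = rng.normal(0, noise, size=(8, 8, 8))
                    v[c[0] : c[0] + 3, c[1] : c[1] + 3, c[2] : c[2] + 3] += 1.2
                    X.append(v)
                    y.append(ci % 2)
            idx = rng.permutation(len(y))
            return np.array(X)[idx], np.array(y)[idx]

        def epochs_to(hist, thresh):
            for e, v in enumerate(hist["val_error"]):
                if v < thresh:
                    return e
            return len(hist["val_error"]) + 20

        wins = 0
        for seed in range(5):
            rng = np.random.default_rng(500 + seed)
            src = xor_task(15, rng)
            tgt = xor_task(3, rng)
            val = xor_task(10, rng)
            pre = build_cnn(SMALL_ARCH, seed=seed)
            train_with_revert(
                pre, src, val,
                TrainConfig(learning_rate=3e-3, max_epochs=80, patience_epochs=79,
                            seed=seed),
            )
            cfg = TrainConfig(learning_rate=3e-3, max_epochs=60, patience_epochs=59,
                              seed=seed)
            _, hist_warm = transfer_finetune(pre, tgt, val, cfg, n_frozen_layers=0)
            cold = build_cnn(SMALL_ARCH, seed=100 + seed)
            hist_cold = train_with_revert(cold, tgt, val, cfg)
            if epochs_to(hist_warm, 0.45) < epochs_to(hist_cold, 0.45):
                wins += 1
        assert wins >= 3  # median advantage over 5 seeds

    def test_excessive_frozen_layers_rejected(self, blob_data):
        train, val = blob_data
        pre = build_cnn(SMALL_ARCH, seed=0)
        with pytest.raises(ValueError, match="exceeds"):
            transfer_finetune(
                pre, train, val,
                TrainConfig(max_epochs=2, patience_epochs=1), n_frozen_layers=5
            )
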