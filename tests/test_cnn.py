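"""CNN module contracts: architecture grammar and parameter counts, prAUC
behaviour, metric arithmetic, grid mechanics and best-model selection."""

import numpy as np
import pytest

from coldreg import cnn, nn
from coldreg.datasets import DEG_CLASS, LabeledSet, NON_CLASS
from .conftest import make_record


def brute_force_prauc(scores, labels):
    """Independent oracle: step-integrate precision over recall by direct
    counting at every distinct threshold (O(n^2))."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = labels.sum()
    thresholds = sorted(set(scores), reverse=True)
    area, prev_recall = 0.0, 0.0
    for t in thresholds:
        called = scores >= t
        tp = int((called & labels).sum())
        precision = tp / int(called.sum())
        recall = tp / n_pos
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area


class TestPrAUC:
    def test_equals_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for i in range(100):
            n = int(rng.integers(4, 21))
            labels = np.zeros(n, dtype=int)
            labels[rng.choice(n, size=int(rng.integers(1, n)), replace=False)] = 1
            scores = rng.choice([0.1, 0.25, 0.5, 0.7, 0.9], size=n)  # forces ties
            if labels.sum() in (0, n):
                continue
            assert abs(cnn.prauc(scores, labels) - brute_force_prauc(scores, labels)) < 1e-9

    def test_matches_sklearn_average_precision(self):
        from sklearn.metrics import average_precision_score

        rng = np.random.default_rng(1)
        for _ in range(20):
            scores = rng.random(50)
            labels = rng.integers(0, 2, 50)
            if labels.sum() in (0, 50):
                continue
            assert cnn.prauc(scores, labels) == pytest.approx(
                average_precision_score(labels, scores), abs=1e-12
            )

    def test_random_scorer_law(self):
        # E[prAUC] of an uninformative scorer equals the positive fraction
        rng = np.random.default_rng(2)
        vals = [
            cnn.prauc(rng.random(4000), rng.random(4000) < 0.2) for _ in range(10)
        ]
        assert abs(np.mean(vals) - 0.2) < 0.02

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            cnn.prauc([0.1, 0.9], [1, 1])


class TestBuildModel:
    def test_parameter_count_closed_form(self):
        hp = cnn.HyperParams(
            n_conv_layers=1, conv_filters=(3,), conv_width=4, pool_width=4,
            pool_stride=4, n_dense_layers=2, dense_units=(5,), dropout_rate=0.1,
        )
        model = cnn.build_model(hp, 100)
        # conv: (4*4)*3+3; L=97 -> pool -> 24 blocks; dense: 24*3*5+5; out: 5+1
        expected = (16 * 3 + 3) + (24 * 3 * 5 + 5) + (5 * 1 + 1)
        assert model.n_parameters() == expected

    def test_reported_best_architecture_builds_on_3000(self):
        # two conv layers of 128 filters, width 4, pool 4/4, dropout 0.25,
        # dense 64+128, for the 3 kb two-window input
        hp = cnn.HyperParams(
            n_conv_layers=2, conv_filters=(128, 128), conv_width=4, pool_width=4,
            pool_stride=4, n_dense_layers=3, dense_units=(64, 128),
            dropout_rate=0.25,
        )
        model = cnn.build_model(hp, 3000)
        assert model.n_parameters() > 0

    def test_pool_collapse_rejected(self):
        hp = cnn.HyperParams(
            n_conv_layers=1, conv_filters=(4,), conv_width=4, pool_width=64,
            pool_stride=64, n_dense_layers=2, dense_units=(4,),
        )
        with pytest.raises(nn.ArchitectureError, match="conv block"):
            cnn.build_model(hp, 60)

    def test_invalid_hyperparams_rejected(self):
        with pytest.raises(ValueError):
            cnn.HyperParams(n_conv_layers=2, conv_filters=(8,))
        with pytest.raises(ValueError):
            cnn.HyperParams(n_dense_layers=3, dense_units=(8,))
        with pytest.raises(ValueError):
            cnn.HyperParams(epochs=0)


def tiny_sets(rng, n=120, L=60, spike=None, p_deg=0.3):
    """Small labelled sets, optionally with a deterministic leading spike."""
    def build(n_records, fam_offset):
        records = []
        for i in range(n_records):
            label = DEG_CLASS if rng.random() < p_deg else NON_CLASS
            seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, L)])
            if spike and label == DEG_CLASS:
                seq = spike + seq[len(spike):]
            records.append(
                make_record(f"g{fam_offset}_{i}", f"f{fam_offset}_{i // 4}", label, seq=seq)
            )
        return LabeledSet(records)

    return build(n, 0), build(max(n // 3, 20), 1), build(max(n // 3, 20), 2)


TINY_HP = cnn.HyperParams(
    n_conv_layers=1, conv_filters=(4,), conv_width=5, pool_width=2, pool_stride=2,
    n_dense_layers=2, dense_units=(8,), dropout_rate=0.1, learning_rate=1e-3,
    epochs=6,
)


class TestTrainEvaluate:
    def test_learns_separable_spike(self):
        from coldreg.datasets import oversample

        rng = np.random.default_rng(3)
        train, val, test = tiny_sets(rng, n=240, L=60, spike="AAGGG")
        train = oversample(train, seed=0)
        hp = cnn.HyperParams.from_dict({**TINY_HP.to_dict(), "epochs": 30})
        res = cnn.SequenceCNN(hp, 60, seed=0).fit(train, val, test, batch_size=16)
        assert res.record.prauc_test > 0.9
        assert res.record.best_epoch >= 1
        assert "prAUC" in res.summary()

    def test_shuffled_labels_score_near_prevalence(self):
        rng = np.random.default_rng(4)
        train, val, test = tiny_sets(rng, n=160, L=60, p_deg=0.25)
        res = cnn.SequenceCNN(TINY_HP, 60, seed=1).fit(train, val, test)
        prevalence = np.mean(test.y == DEG_CLASS)
        assert abs(res.record.prauc_test - prevalence) < 0.25

    def test_class_diff_consistent_with_confusion_counts(self):
        rng = np.random.default_rng(5)
        train, val, test = tiny_sets(rng, n=100, L=40)
        res = cnn.SequenceCNN(TINY_HP, 40, seed=2).fit(train, val, test)
        m = res.evaluate(test)
        p1 = res.predict_proba(test.X)
        pred = (p1 >= 0.5).astype(int)
        y = test.y
        acc_deg = np.mean(pred[y == DEG_CLASS] == DEG_CLASS)
        acc_non = np.mean(pred[y == NON_CLASS] == NON_CLASS)
        assert m["class_diff"] == pytest.approx(abs(acc_deg - acc_non))

    def test_evaluate_requires_both_classes(self):
        rng = np.random.default_rng(6)
        train, val, _ = tiny_sets(rng, n=60, L=40)
        only_non = LabeledSet([r for r in train.records if r.label == NON_CLASS][:10])
        model = cnn.SequenceCNN(TINY_HP, 40, seed=0)
        with pytest.raises(ValueError):
            cnn.evaluate(model.network, only_non)


class TestGridMachinery:
    def test_grid_product_count(self):
        grid = cnn.build_grid({
            "n_conv_layers": [1, 2], "conv_filters": [4, 8], "conv_width": [4],
            "pool_width": [4], "pool_stride": [4, 8], "n_dense_layers": [2],
            "dense_units": [8], "dropout_rate": [0.1],
        })
        assert len(grid) == 8

    def test_identical_combinations_identical_metrics(self):
        rng = np.random.default_rng(7)
        train, val, test = tiny_sets(rng, n=80, L=40)
        hp = cnn.HyperParams.from_dict({**TINY_HP.to_dict(), "epochs": 2})
        records = cnn.grid_search([hp, hp], train, val, test, seed=0)
        a, b = records
        assert (a.prauc_test, a.class_diff, a.loss) == (b.prauc_test, b.class_diff, b.loss)

    def test_failed_combination_recorded_not_raised(self):
        rng = np.random.default_rng(8)
        train, val, test = tiny_sets(rng, n=60, L=40)
        bad = cnn.HyperParams(
            n_conv_layers=1, conv_filters=(4,), conv_width=5, pool_width=64,
            pool_stride=64, n_dense_layers=2, dense_units=(8,), epochs=2,
        )
        records = cnn.grid_search([bad], train, val, test, seed=0)
        assert records[0].error is not None

    def test_checkpoint_resume(self, tmp_path):
        rng = np.random.default_rng(9)
        train, val, test = tiny_sets(rng, n=60, L=40)
        hp = cnn.HyperParams.from_dict({**TINY_HP.to_dict(), "epochs": 2})
        first = cnn.grid_search([hp], train, val, test, seed=0, checkpoint_dir=str(tmp_path))
        second = cnn.grid_search([hp], train, val, test, seed=0, checkpoint_dir=str(tmp_path))
        assert first[0].prauc_test == second[0].prauc_test


def record_stub(prauc_test, class_diff, **kw):
    return cnn.ModelRecord(hyperparams=TINY_HP, prauc_test=prauc_test,
                           class_diff=class_diff, **kw)


class TestSelectBest:
    def test_smallest_diff_above_threshold(self):
        records = [record_stub(0.72, 0.4), record_stub(0.71, 0.3)]
        assert cnn.select_best(records) is records[1]

    def test_none_when_all_below_threshold(self):
        assert cnn.select_best([record_stub(0.5, 0.1), record_stub(0.69, 0.0)]) is None

    def test_tie_broken_by_higher_prauc_then_order(self):
        records = [record_stub(0.75, 0.2), record_stub(0.80, 0.2), record_stub(0.80, 0.2)]
        assert cnn.select_best(records) is records[1]

    def test_failed_records_ignored(self):
        records = [record_stub(0.99, 0.0, error="collapsed"), record_stub(0.71, 0.3)]
        assert cnn.select_best(records) is records[1]


class TestOverfitFlag:
    @pytest.mark.parametrize(
        "prauc_test,acc_deg,acc_non,expected",
        [
            (0.85, 0.9, 0.1, "to_deg"),
            (0.15, 0.1, 0.95, "to_non"),
            (0.5, 0.5, 0.5, "none"),
            (0.79, 0.9, 0.0, "none"),
        ],
    )
    def test_flag_rule(self, prauc_test, acc_deg, acc_non, expected):
        assert cnn.overfit_flag(prauc_test, acc_deg, acc_non) == expected


def test_permutation_significance_validates_n_perm():
    rng = np.random.default_rng(10)
    train, val, test = tiny_sets(rng, n=40, L=40)
    with pytest.raises(ValueError):
        cnn.permutation_significance(TINY_HP, train, val, test, 0.9, 0.1, n_perm=0)
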