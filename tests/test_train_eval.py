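import numpy as np
import pytest

from rbfgcn import (
    BlockConnectivity,
    ConfusionCounts,
    RBFConfig,
    SyntheticCohortConfig,
    TASKS,
    TrainConfig,
    compute_metrics,
    cross_validate,
    filter_task,
    generate_cohort,
    make_folds,
    train_model,
)

from _oracles import brute_confusion


class TestFolds:
    def test_balanced_small_cohort_one_of_each_per_fold(self):
        labels = np.array([0, 1] * 10)
        folds = make_folds(labels, k=10, seed=0)
        for _, test in folds:
            assert len(test) == 2
            assert sorted(labels[test]) == [0, 1]

    def test_partition_property(self, rng):
        labels = rng.integers(0, 3, size=47)
        folds = make_folds(labels, k=5, seed=3)
        all_test = np.concatenate([te for _, te in folds])
        assert sorted(all_test) == list(range(47))
        for (tr, te) in folds:
            assert set(tr).isdisjoint(te)
            assert sorted(np.concatenate([tr, te])) == list(range(47))

    def test_determinism(self, rng):
        labels = rng.integers(0, 2, size=30)
        a = make_folds(labels, k=5, seed=11)
        b = make_folds(labels, k=5, seed=11)
        for (tra, tea), (trb, teb) in zip(a, b):
            np.testing.assert_array_equal(tra, trb)
            np.testing.assert_array_equal(tea, teb)

    def test_tiny_class_warns(self):
        labels = np.array([0] * 18 + [1] * 2)
        with pytest.warns(UserWarning, match="best-effort"):
            make_folds(labels, k=5, seed=0)


class TestMetrics:
    def test_worked_example(self):
        m = compute_metrics(ConfusionCounts(tp=5, tn=3, fp=1, fn=1))
        assert m.acc == 0.8
        assert m.sen == pytest.approx(5 / 6)
        assert m.spe == 0.75

    def test_degenerate_all_positive(self):
        m = compute_metrics(ConfusionCounts(tp=7, tn=0, fp=0, fn=0))
        assert m.acc == 1.0 and m.sen == 1.0 and m.spe is None

    def test_perfect_predictions(self, rng):
        labels = rng.integers(0, 2, size=50)
        counts = ConfusionCounts.from_predictions(labels, labels)
        m = compute_metrics(counts)
        assert (m.acc, m.sen, m.spe) == (1.0, 1.0, 1.0)

    def test_matches_brute_force_recount(self, rng):
        for _ in range(1000):
            n = int(rng.integers(1, 30))
            preds = rng.integers(0, 2, size=n)
            labels = rng.integers(0, 2, size=n)
            counts = ConfusionCounts.from_predictions(preds, labels)
            tp, fp, tn, fn = brute_confusion(preds, labels)
            assert (counts.tp, counts.fp, counts.tn, counts.fn) == (tp, fp, tn, fn)
            assert counts.total == n


def separable_cohort(n_per_class=30):
    """Strong effects, tiny noise: linearly separable two-class cohort."""
    config = SyntheticCohortConfig(
        n_per_class=(n_per_class, 0, n_per_class),
        m=6,
        base_connectivity=BlockConnectivity(intra_mean=8.0, inter_mean=2.0,
                                            decay=0.5, dispersion=5.0),
        affinity_profile=np.full(6, 0.8),
        noise_sd=0.05,
        subject_sd=0.0,
        severity_sd=0.0,
        seed=21,
    )
    networks, _ = generate_cohort(config)
    return networks


class TestTraining:
    def test_separable_cohort_reaches_high_training_accuracy(self):
        networks = separable_cohort()
        nets, ys = filter_task(networks, TASKS["NC_vs_AD"])
        config = RBFConfig.from_arm("baseline", n_classes=2, hidden=8,
                                    mlp_hidden=8)
        model, trace = train_model(nets, ys, config,
                                   TrainConfig(epochs=60, seed=0))
        assert len(trace) == 60
        assert np.all(np.isfinite(trace))
        preds = model.predict(model.prepare_inputs(nets))
        assert np.mean(preds == ys) >= 0.95

    def test_zero_learning_rate_leaves_parameters_unchanged(self):
        networks = separable_cohort(n_per_class=10)
        nets, ys = filter_task(networks, TASKS["NC_vs_AD"])
        config = RBFConfig.from_arm("anna", n_classes=2, hidden=4, mlp_hidden=4)
        model, _ = train_model(
            nets, ys, config, TrainConfig(epochs=3, learning_rate=0.0, seed=4)
        )
        fresh = type(model)(config, m=nets[0].m, d=nets[0].d, seed=4)
        for name, value in fresh.get_params().items():
            np.testing.assert_array_equal(model.get_params()[name], value)

    def test_same_seed_identical_loss_traces(self):
        networks = separable_cohort(n_per_class=10)
        nets, ys = filter_task(networks, TASKS["NC_vs_AD"])
        config = RBFConfig.from_arm("baseline", n_classes=2, hidden=4,
                                    mlp_hidden=4)
        _, t1 = train_model(nets, ys, config, TrainConfig(epochs=5, seed=8))
        _, t2 = train_model(nets, ys, config, TrainConfig(epochs=5, seed=8))
        assert t1 == t2


def oracle_trainer(train_nets, train_labels, model_config, train_config):
    """Cheating classifier that reads the diagnosis straight off the label."""
    from rbfgcn.network_data import LABEL_TO_INT

    classes = sorted({LABEL_TO_INT[n.label] for n in train_nets})
    mapping = {c: i for i, c in enumerate(classes)}

    def predict(test_nets):
        return np.array([mapping[LABEL_TO_INT[n.label]] for n in test_nets])

    return predict


def constant_trainer(train_nets, train_labels, model_config, train_config):
    def predict(test_nets):
        return np.zeros(len(test_nets), dtype=int)

    return predict


class TestCrossValidation:
    def test_oracle_classifier_scores_perfectly(self, worked_cohort):
        result = cross_validate(
            worked_cohort, "NC_vs_AD",
            RBFConfig.from_arm("baseline", n_classes=2),
            TrainConfig(epochs=1, folds=4, seed=0),
            trainer=oracle_trainer,
        )
        assert result.mean("acc") == 1.0
        assert result.sd("acc") == 0.0
        assert all(m.acc == 1.0 for m in result.per_fold)

    def test_constant_classifier_on_balanced_binary(self, worked_cohort):
        result = cross_validate(
            worked_cohort, "NC_vs_AD",
            RBFConfig.from_arm("baseline", n_classes=2),
            TrainConfig(epochs=1, folds=4, seed=0),
            trainer=constant_trainer,
        )
        assert result.mean("acc") == pytest.approx(0.5)
        for m in result.per_fold:
            assert m.sen == 0.0 and m.spe == 1.0

    def test_multiclass_reports_accuracy_only(self, worked_cohort):
        result = cross_validate(
            worked_cohort, "NC_vs_MCI_vs_AD",
            RBFConfig.from_arm("baseline", n_classes=3),
            TrainConfig(epochs=1, folds=4, seed=0),
            trainer=oracle_trainer,
        )
        assert result.mean("acc") == 1.0
        assert set(result.summary()) == {"ACC"}
        assert all(m.sen is None and m.spe is None for m in result.per_fold)

    def test_class_count_mismatch_rejected(self, worked_cohort):
        with pytest.raises(ValueError, match="classes"):
            cross_validate(
                worked_cohort, "NC_vs_AD",
                RBFConfig.from_arm("baseline", n_classes=3),
                TrainConfig(epochs=1, folds=4, seed=0),
            )

    def test_filter_task_binarizes_with_patient_as_one(self, worked_cohort):
        nets, ys = filter_task(worked_cohort, TASKS["MCI_vs_AD"])
        assert len(nets) == 8
        assert set(ys) == {0, 1}
        assert all(
            (n.label == "AD") == (y == 1) for n, y in zip(nets, ys)
        )
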