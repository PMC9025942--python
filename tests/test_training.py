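"""Loss arithmetic, learning-rate schedule, fold plans, splits, the training
loop's contracts and grid search."""

import numpy as np
import pytest

from ecgscalonet.network import ConvBlockSpec, ModelSpec, build_model
from ecgscalonet.records import CLASSES
from ecgscalonet.training import (
    FoldPlan,
    Hyperparams,
    cross_entropy_loss,
    grid_search,
    holdout_split,
    learning_rate_at,
    loss_and_grad,
    make_fold_plan,
    run_cv,
    train,
)

TOY_SPEC = ModelSpec(
    input_shape=(8, 8, 3),
    conv_blocks=(ConvBlockSpec(4, norm="batch"),),
    lstm_hidden_units=4,
    fc_sizes=(8,),
    dropout_rate=0.0,
)


def toy_images(n_per_class=6, size=8, classes=("ARR", "NSR"), noise=0.02):
    """Constant-colour images per class: linearly separable by construction."""
    rng = np.random.default_rng(99)
    colors = {"ARR": (0.9, 0.1, 0.1), "CHF": (0.1, 0.9, 0.1),
              "NSR": (0.1, 0.1, 0.9)}
    images, labels = [], []
    for cls in classes:
        for _ in range(n_per_class):
            img = np.ones((size, size, 3), dtype=np.float32) * colors[cls]
            img += rng.normal(0, noise, img.shape).astype(np.float32)
            images.append(np.clip(img, 0, 1))
            labels.append(cls)
    return np.stack(images), labels


class TestLoss:
    def test_uniform_prediction_closed_form(self):
        """U for the uniform 3-class prediction is -[log(1/3) + 2 log(2/3)]."""
        s = np.array([[1 / 3, 1 / 3, 1 / 3]])
        r = np.array([[1.0, 0.0, 0.0]])
        expected = -(np.log(1 / 3) + 2 * np.log(2 / 3))
        assert cross_entropy_loss(s, r, 1) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(1.9095, abs=5e-5)

    def test_perfect_prediction_is_zero(self):
        s = np.array([[1.0, 0.0, 0.0]])
        r = np.array([[1.0, 0.0, 0.0]])
        assert cross_entropy_loss(s, r, 1) <= 1e-10

    def test_batch_loss_is_mean_of_items(self, rng):
        s = rng.dirichlet(np.ones(3), size=10)
        r = np.eye(3)[rng.integers(0, 3, size=10)]
        per_item = [cross_entropy_loss(s[i:i + 1], r[i:i + 1], 1)
                    for i in range(10)]
        assert cross_entropy_loss(s, r) == pytest.approx(np.mean(per_item))

    def test_nonnegative(self, rng):
        s = rng.dirichlet(np.ones(3), size=50)
        r = np.eye(3)[rng.integers(0, 3, size=50)]
        assert cross_entropy_loss(s, r) >= 0.0

    @pytest.mark.parametrize("mode", ["binary_ovr", "categorical"])
    def test_logit_gradient_matches_numeric(self, mode, rng):
        z = rng.normal(size=(4, 3))
        r = np.eye(3)[rng.integers(0, 3, size=4)]
        _, grad = loss_and_grad(z, r, mode=mode)
        eps = 1e-6
        for i in range(4):
            for j in range(3):
                zp, zm = z.copy(), z.copy()
                zp[i, j] += eps
                zm[i, j] -= eps
                num = (loss_and_grad(zp, r, mode=mode)[0]
                       - loss_and_grad(zm, r, mode=mode)[0]) / (2 * eps)
                assert grad[i, j] == pytest.approx(num, abs=1e-6)


class TestSchedule:
    def test_stepwise_decay(self):
        hp = Hyperparams(learning_rate=1e-4, lr_decay_rate=0.95,
                         lr_decay_steps=1000)
        assert learning_rate_at(hp, 0) == 1e-4
        assert learning_rate_at(hp, 999) == 1e-4
        assert learning_rate_at(hp, 1000) == pytest.approx(0.95e-4)
        assert learning_rate_at(hp, 2500) == pytest.approx(1e-4 * 0.95**2)


class TestFoldPlans:
    def test_900_items_10_equal_folds(self):
        labels = [c for c in CLASSES for _ in range(300)]
        plan = make_fold_plan(labels, K=10, seed=1)
        sizes = np.bincount(plan.assignments, minlength=10)
        assert (sizes == 90).all()

    def test_stratified_folds_balanced_per_class(self):
        labels = [c for c in CLASSES for _ in range(300)]
        plan = make_fold_plan(labels, K=10, seed=1)
        for fold in range(10):
            idx = np.flatnonzero(plan.assignments == fold)
            for cls in CLASSES:
                assert sum(labels[i] == cls for i in idx) == 30

    def test_leave_one_out(self):
        labels = (["ARR"] * 4) + (["NSR"] * 4)
        plan = make_fold_plan(labels, K=8, stratified=False, seed=0)
        assert (np.bincount(plan.assignments, minlength=8) == 1).all()

    def test_k_exceeding_items_rejected(self):
        with pytest.raises(ValueError):
            make_fold_plan(["ARR", "NSR"], K=3)

    def test_record_split_keeps_chunks_together(self):
        labels, groups = [], []
        for cls in CLASSES:
            for rec in range(4):
                labels.extend([cls] * 5)  # 5 chunks per recording
                groups.extend([f"{cls}{rec}"] * 5)
        plan = make_fold_plan(labels, K=4, split_unit="record",
                              groups=groups, seed=2)
        for g in set(groups):
            folds = {plan.assignments[i] for i, gg in enumerate(groups) if gg == g}
            assert len(folds) == 1

    def test_folds_partition_items(self):
        labels = [CLASSES[i % 3] for i in range(47)]
        plan = make_fold_plan(labels, K=5, seed=3)
        assert set(plan.assignments) == set(range(5))
        assert len(plan.assignments) == 47


class TestHoldout:
    def test_900_items_70_30(self):
        labels = [c for c in CLASSES for _ in range(300)]
        tr, te = holdout_split(labels, 0.30, seed=1)
        assert len(te) == 270 and len(tr) == 630
        for cls in CLASSES:
            assert sum(labels[i] == cls for i in te) == 90

    def test_half_split_of_four(self):
        tr, te = holdout_split(["ARR", "ARR", "NSR", "NSR"], 0.5, seed=0)
        assert len(tr) == 2 and len(te) == 2

    def test_disjoint_and_exhaustive(self):
        labels = [CLASSES[i % 3] for i in range(31)]
        tr, te = holdout_split(labels, 0.3, seed=5)
        assert set(tr) | set(te) == set(range(31))
        assert set(tr) & set(te) == set()

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            holdout_split(["ARR", "NSR"], 1.0)


class TestTrainLoop:
    def test_separable_toy_images_reach_full_train_accuracy(self):
        images, labels = toy_images()
        model = build_model(TOY_SPEC, seed=0)
        hp = Hyperparams(learning_rate=1e-2, batch_size=4, epochs=5, seed=0,
                         dropout_rate=0.0)
        result = train(model, images, labels, hp)
        assert result.history[-1]["train_accuracy"] == 1.0

    def test_fixed_seed_reproduces_loss_history(self):
        images, labels = toy_images(n_per_class=4)
        histories = []
        for _ in range(2):
            model = build_model(TOY_SPEC, seed=1)
            hp = Hyperparams(learning_rate=1e-3, batch_size=4, epochs=2, seed=1)
            histories.append(train(model, images, labels, hp).history)
        assert histories[0] == histories[1]

    def test_zero_epochs_returns_initial_weights(self):
        images, labels = toy_images(n_per_class=2)
        model = build_model(TOY_SPEC, seed=2)
        before = model.get_state()
        result = train(model, images, labels,
                       Hyperparams(epochs=0, seed=0))
        assert result.history == []
        after = model.get_state()
        for k in before:
            np.testing.assert_array_equal(before[k], after[k])

    def test_single_class_rejected(self):
        images, labels = toy_images(n_per_class=4, classes=("ARR",))
        model = build_model(TOY_SPEC, seed=0)
        with pytest.raises(ValueError):
            train(model, images, labels, Hyperparams(epochs=1, seed=0))


class TestCVAndGridSearch:
    def test_cv_reports_and_pooled_conservation(self):
        images, labels = toy_images(n_per_class=10)  # 20 items
        plan = make_fold_plan(labels, K=2, seed=0)
        hp = Hyperparams(learning_rate=1e-2, batch_size=4, epochs=2, seed=0)
        reports, pooled = run_cv(images, labels, TOY_SPEC, hp, plan)
        assert len(reports) == 2
        for c in pooled.counts:
            assert c.total == 20

    def test_grid_evaluation_count_is_cartesian_product(self):
        images, labels = toy_images(n_per_class=4)
        plan = make_fold_plan(labels, K=2, seed=0)
        grid = {"learning_rate": [1e-3, 1e-2, 1e-1],
                "batch_size": [4, 8],
                "epochs": [1, 2]}
        base = Hyperparams(seed=0, dropout_rate=0.0)
        results = grid_search(grid, images, labels, TOY_SPEC, plan, base)
        assert len(results) == 12
        scores = [s for _, s in results]
        assert scores == sorted(scores, reverse=True)

    def test_single_point_grid(self):
        images, labels = toy_images(n_per_class=4)
        plan = make_fold_plan(labels, K=2, seed=0)
        results = grid_search({"epochs": [1]}, images, labels, TOY_SPEC, plan,
                              Hyperparams(seed=0))
        assert len(results) == 1

    def test_good_learning_rate_outranks_divergent_one(self):
        images, labels = toy_images(n_per_class=8)
        plan = make_fold_plan(labels, K=2, seed=0)
        base = Hyperparams(batch_size=4, epochs=3, seed=0, dropout_rate=0.0)
        results = grid_search({"learning_rate": [1e-2, 10.0]},
                              images, labels, TOY_SPEC, plan, base)
        best_hp, best_score = results[0]
        worst_hp, worst_score = results[-1]
        assert best_hp.learning_rate == 1e-2
        assert best_score > worst_score

    def test_empty_grid_rejected(self):
        images, labels = toy_images(n_per_class=2)
        plan = make_fold_plan(labels, K=2, seed=0)
        with pytest.raises(ValueError):
            grid_search({}, images, labels, TOY_SPEC, plan)
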