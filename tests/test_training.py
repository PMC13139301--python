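import numpy as np
import pytest

from cpifusion.train_eval import (
    CPIFeaturizer,
    TrainConfig,
    cross_validate,
    finetune,
    fit_on_dataset,
    make_split,
    train,
)

from conftest import SMALL_MODEL


def prepared(dataset, seed=0):
    """Featurize a dataset with a small model on a fixed split."""
    split = make_split(dataset, seed=seed)
    fz = CPIFeaturizer().fit(dataset, split.train_indices_for_fold(0))
    return split, fz


class TestTrainLoop:
    def test_loss_decreases_on_learnable_signal(self, noiseless_dataset):
        dataset, _ = noiseless_dataset
        split, fz = prepared(dataset)
        from cpifusion.model_core import build_model

        model = build_model(fz.model_config(random_seed=0, **SMALL_MODEL))
        result = train(
            model,
            fz.transform(dataset, split.train_indices_for_fold(0)),
            fz.transform(dataset, split.folds[0]),
            TrainConfig(max_epochs=8, patience=8, seed=0, batch_size=64),
        )
        h = result.history
        assert h.train_mse.iloc[-1] < h.train_mse.iloc[0]

    def test_same_seed_identical_histories(self, small_dataset):
        dataset, _ = small_dataset
        split = make_split(dataset, seed=0)
        runs = []
        for _ in range(2):
            res = fit_on_dataset(
                dataset,
                split.train_indices_for_fold(0),
                split.folds[0],
                model_overrides=SMALL_MODEL,
                train_config=TrainConfig(max_epochs=4, patience=4, seed=3, batch_size=32),
            )
            runs.append(res.history)
        assert np.allclose(runs[0].train_mse, runs[1].train_mse, rtol=1e-7)
        assert np.allclose(runs[0].val_mse, runs[1].val_mse, rtol=1e-7)

    def test_patience_zero_stops_one_epoch_after_best(self, small_dataset, rng):
        dataset, _ = small_dataset
        split = make_split(dataset, seed=0)
        # random labels: validation MSE fluctuates, so early stop must trigger
        shuffled = dataset.__class__(
            compounds=dataset.compounds,
            proteins=dataset.proteins,
            interactions=[
                type(it)(it.compound_id, it.protein_id, float(v), it.scale_tag)
                for it, v in zip(
                    dataset.interactions,
                    rng.permutation([i.affinity for i in dataset.interactions]),
                )
            ],
        )
        res = fit_on_dataset(
            shuffled,
            split.train_indices_for_fold(0),
            split.folds[0],
            model_overrides=SMALL_MODEL,
            train_config=TrainConfig(max_epochs=40, patience=0, seed=0, batch_size=32),
        )
        assert len(res.history) < 40, "early stop should trigger on random labels"
        assert len(res.history) == res.best_epoch + 1

    def test_empty_training_set_rejected(self, small_dataset):
        dataset, _ = small_dataset
        split, fz = prepared(dataset)
        from cpifusion.model_core import build_model

        model = build_model(fz.model_config(random_seed=0, **SMALL_MODEL))
        X, y = fz.transform(dataset, split.folds[0])
        with pytest.raises(ValueError):
            train(model, (X.take([]), y[:0]), (X, y), TrainConfig(seed=0))


@pytest.fixture(scope="module")
def pretrained(small_dataset):
    dataset, _ = small_dataset
    split = make_split(dataset, seed=0)
    return dataset, split, fit_on_dataset(
        dataset,
        split.train_indices_for_fold(0),
        split.folds[0],
        model_overrides=SMALL_MODEL,
        train_config=TrainConfig(max_epochs=6, patience=6, seed=1, batch_size=32),
    )


class TestFinetune:

    def test_zero_learning_rate_leaves_predictions_unchanged(self, pretrained):
        dataset, split, pre = pretrained
        fz = pre.model.featurizer
        X, y = fz.transform(dataset, split.test_indices)
        before = pre.model.predict(X)
        res = finetune(
            pre.model,
            fz.transform(dataset, split.train_indices_for_fold(0)),
            fz.transform(dataset, split.folds[0]),
            TrainConfig(max_epochs=3, patience=3, seed=2, fine_tune_learning_rate=0.0),
        )
        assert (res.model.predict(X) == before).all()

    def test_finetune_does_not_modify_input_model(self, pretrained):
        dataset, split, pre = pretrained
        fz = pre.model.featurizer
        w_before = pre.model.get_weights()
        finetune(
            pre.model,
            fz.transform(dataset, split.train_indices_for_fold(0)),
            fz.transform(dataset, split.folds[0]),
            TrainConfig(max_epochs=2, patience=2, seed=2),
        )
        w_after = pre.model.get_weights()
        assert all((w_before[k] == w_after[k]).all() for k in w_before)

    def test_freeze_local_updates_only_global_side(self, pretrained):
        dataset, split, pre = pretrained
        fz = pre.model.featurizer
        res = finetune(
            pre.model,
            fz.transform(dataset, split.train_indices_for_fold(0)),
            fz.transform(dataset, split.folds[0]),
            TrainConfig(
                max_epochs=2, patience=2, seed=2,
                fine_tune_learning_rate=1e-3, freeze="local",
            ),
        )
        w0, w1 = pre.model.get_weights(), res.model.get_weights()
        local = [k for k in w0 if k.startswith(("compound_local", "protein_local"))]
        other = [k for k in w0 if not k.startswith(("compound_local", "protein_local"))]
        assert all((w0[k] == w1[k]).all() for k in local)
        assert any((w0[k] != w1[k]).any() for k in other)

    def test_finetune_on_pretraining_task_does_not_degrade(self, pretrained):
        dataset, split, pre = pretrained
        fz = pre.model.featurizer
        val = fz.transform(dataset, split.folds[0])
        res = finetune(
            pre.model,
            fz.transform(dataset, split.train_indices_for_fold(0)),
            val,
            TrainConfig(max_epochs=5, patience=5, seed=2),
        )
        assert res.best_val_mse <= pre.best_val_mse * 1.10


class TestCrossValidate:
    def test_zero_noise_signal_recovered(self, noiseless_dataset):
        dataset, _ = noiseless_dataset
        report = cross_validate(
            dataset,
            TrainConfig(max_epochs=120, patience=30, seed=0, batch_size=32),
            model_overrides=SMALL_MODEL,
        )
        assert len(report.per_fold) == 5
        assert report.mean["r2"] > 0.9
        assert set(report.std) == {"mse", "ci", "r2", "pcc"}
        assert all(v >= 0 for v in report.std.values())
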