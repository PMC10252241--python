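import numpy as np
import pytest

from helpers import make_tiny_set
from kneeoa.data import balance_classes, num_classes_for, split_dataset, AugmentPolicy
from kneeoa.losses import delta_coefficient
from kneeoa.trainer import RunConfig, evaluate, train_with_adaptive_stopping
from kneeoa.synthetic import SyntheticConfig, generate_dataset


class ScriptedModel:
    """Stub obeying the trainer's model protocol with scripted eval losses.

    ``eval_losses`` is consumed call by call (micro checks and the epoch-end
    full-validation evaluation draw from the same sequence); the last value
    repeats once the script runs out.  ``train_losses`` cycles.
    """

    def __init__(self, eval_losses, train_losses=(1.0,), num_classes=2,
                 predict="uniform"):
        self.eval_losses = list(eval_losses)
        self.train_losses = list(train_losses)
        self.num_classes = num_classes
        self.predict = predict
        self.train_calls = 0
        self.eval_calls = 0

    def train_step(self, x, y, lr, grad_scale=None):
        loss = self.train_losses[self.train_calls % len(self.train_losses)]
        self.train_calls += 1
        return loss

    def eval_loss(self, x, y):
        i = min(self.eval_calls, len(self.eval_losses) - 1)
        self.eval_calls += 1
        return self.eval_losses[i]

    def predict_proba(self, x):
        n, c = len(x), self.num_classes
        if self.predict == "majority":
            probs = np.zeros((n, c))
            probs[:, 0] = 1.0
            return probs
        return np.full((n, c), 1.0 / c)

    def get_state(self):
        return []

    def set_state(self, state):
        pass


class PerfectModel(ScriptedModel):
    """Oracle predictor: reads the labels it is asked to score."""

    def __init__(self, dataset, task):
        super().__init__([1.0], num_classes=num_classes_for(task))
        x, y = dataset.subset("test").arrays(task)
        self._lookup = {hash(img.tobytes()): lab for img, lab in zip(x, y)}

    def predict_proba(self, x):
        probs = np.zeros((len(x), self.num_classes))
        for i, img in enumerate(np.asarray(x, dtype=np.float32)):
            probs[i, self._lookup[hash(img.tobytes())]] = 1.0
        return probs


@pytest.fixture()
def flat_dataset():
    """60 train + 20 val + 20 test records of two grades, tiny images."""
    ds = make_tiny_set({0: 50, 2: 50}, split="unassigned", seed=1)
    return split_dataset(ds, (0.6, 0.2, 0.2), seed=1)


def run_config(**kw):
    base = dict(task="two", max_epochs=10, batch_size=10, micro_check_every=1,
                macro_window=3, micro_window=3, min_epochs=3, seed=0,
                image_size=32, growth_rate=4, block_layers=(1, 1, 1, 1))
    base.update(kw)
    return RunConfig(**base)


class TestMacroStopping:
    def test_plateau_stops_window_after_plateau(self, flat_dataset):
        # per-epoch val losses: improve for 3 epochs then flat from epoch 4
        losses = [1.0, 0.9, 0.8] + [0.8] * 20
        model = ScriptedModel(losses)
        cfg = run_config(micro_enabled=False, batch_size=20)
        trace, _, summary = train_with_adaptive_stopping(cfg, flat_dataset, model)
        # stalls accumulate at epochs 4,5,6 -> macro stop at plateau + window
        assert summary["stopped_epoch"] == 3 + cfg.macro_window

    def test_strictly_improving_runs_all_epochs(self, flat_dataset):
        model = ScriptedModel([1.0 - 0.05 * i for i in range(40)])
        cfg = run_config(micro_enabled=False, max_epochs=8, batch_size=20)
        _, _, summary = train_with_adaptive_stopping(cfg, flat_dataset, model)
        assert summary["stopped_epoch"] is None
        assert summary["epochs_run"] == 8

    def test_min_epochs_guard_delays_stop(self, flat_dataset):
        model = ScriptedModel([0.5] * 40)  # flat from the very start
        cfg = run_config(micro_enabled=False, min_epochs=6, macro_window=2, batch_size=20)
        _, _, summary = train_with_adaptive_stopping(cfg, flat_dataset, model)
        assert summary["stopped_epoch"] is not None
        assert summary["stopped_epoch"] > 6


class TestMicroStopping:
    def test_flat_micro_losses_abort_epoch(self, flat_dataset):
        model = ScriptedModel([0.7] * 200)
        cfg = run_config(micro_check_every=1, micro_window=2, max_epochs=2,
                         min_epochs=1, macro_window=99)
        trace, _, _ = train_with_adaptive_stopping(cfg, flat_dataset, model)
        df = trace.to_frame()
        epoch_rows = df[df.split == "train_epoch"]
        assert (epoch_rows.decision == "micro").all()
        # epoch 1: checks after batches 1,2,3 -> stop at third check (2 stalls)
        assert df[(df.epoch == 1) & (df.split == "train")].shape[0] == 3

    def test_micro_abort_logs_gce_epoch_loss(self, flat_dataset):
        train_losses = [0.9, 0.7, 0.5, 0.3, 0.2, 0.1]
        model = ScriptedModel([0.7] * 200, train_losses=train_losses)
        cfg = run_config(micro_check_every=1, micro_window=2, max_epochs=1,
                         min_epochs=1, macro_window=99, batch_size=10)
        trace, _, _ = train_with_adaptive_stopping(cfg, flat_dataset, model)
        df = trace.to_frame()
        batch_losses = df[df.split == "train"].monitored_value.to_numpy()
        n_alloc = len(flat_dataset.subset("train"))
        consumed = len(batch_losses) * cfg.batch_size
        assert consumed < n_alloc  # epoch really was aborted
        delta = delta_coefficient(n_alloc, consumed)
        expected = delta / n_alloc * (batch_losses * cfg.batch_size).sum()
        logged = df[df.split == "train_epoch"].monitored_value.iloc[0]
        assert logged == pytest.approx(expected, abs=1e-10)
        # with delta = N/l this is exactly the mean over consumed examples
        assert logged == pytest.approx(batch_losses.mean(), abs=1e-10)

    def test_micro_stop_does_not_end_training(self, flat_dataset):
        model = ScriptedModel([0.7] * 500)
        cfg = run_config(micro_check_every=1, micro_window=2, max_epochs=4,
                         min_epochs=1, macro_window=99)
        trace, _, summary = train_with_adaptive_stopping(cfg, flat_dataset, model)
        assert summary["epochs_run"] == 4
        assert summary["stopped_epoch"] is None


class TestEfficiency:
    def test_early_stopping_processes_fewer_batches(self, flat_dataset):
        losses = [1.0, 0.9, 0.8] + [0.8] * 100
        cfg = run_config(micro_enabled=False, max_epochs=12, batch_size=20)
        _, _, stopped = train_with_adaptive_stopping(
            cfg, flat_dataset, ScriptedModel(losses)
        )
        cfg_off = run_config(micro_enabled=False, max_epochs=12, macro_window=999, batch_size=20)
        _, _, unstopped = train_with_adaptive_stopping(
            cfg_off, flat_dataset, ScriptedModel(losses)
        )
        assert stopped["total_batches"] < unstopped["total_batches"]
        batches_per_epoch = -(-len(flat_dataset.subset("train")) // cfg.batch_size)
        assert unstopped["total_batches"] == 12 * batches_per_epoch


class TestDeterminism:
    def test_identical_config_and_seed_identical_trace(self, flat_dataset):
        def run():
            cfg = run_config(micro_check_every=2, max_epochs=3, min_epochs=1)
            model = ScriptedModel([1.0 - 0.01 * i for i in range(100)])
            trace, _, _ = train_with_adaptive_stopping(cfg, flat_dataset, model)
            return trace.to_frame()

        a, b = run(), run()
        assert a.equals(b)


class TestEvaluate:
    def test_perfect_stub_scores_one(self, flat_dataset):
        model = PerfectModel(flat_dataset, "two")
        result = evaluate(model, flat_dataset, "two")
        for row in result["metrics"]:
            assert row["accuracy"] == 1.0
            assert row["f1"] == 1.0
        assert result["accuracy"] == 1.0

    def test_majority_stub_micro_accuracy(self, flat_dataset):
        model = ScriptedModel([1.0], num_classes=2, predict="majority")
        result = evaluate(model, flat_dataset, "two")
        _, y = flat_dataset.subset("test").arrays("two")
        majority_fraction = (y == 0).mean()
        micro = next(r for r in result["metrics"] if r["averaging"] == "micro")
        assert micro["accuracy"] == pytest.approx(majority_fraction)

    def test_class_count_mismatch_rejected(self, flat_dataset):
        model = ScriptedModel([1.0], num_classes=4)
        with pytest.raises(ValueError):
            evaluate(model, flat_dataset, "two")

    def test_metrics_json_roundtrip(self, flat_dataset, tmp_path):
        import json

        from kneeoa.metrics import write_metrics

        model = ScriptedModel([1.0], num_classes=2, predict="majority")
        result = evaluate(model, flat_dataset, "two")
        path = tmp_path / "metrics.json"
        write_metrics(result["metrics"], path)
        assert json.loads(path.read_text()) == result["metrics"]


class TestEndToEndSmall:
    def test_real_model_end_to_end(self, tmp_path):
        cfg_data = SyntheticConfig(
            image_size=32, counts_per_grade=(10, 8, 9, 7, 6), seed=2
        )
        ds, _ = generate_dataset(cfg_data)
        ds = split_dataset(ds, (0.5, 0.25, 0.25), seed=2)
        ds = balance_classes(ds, 8, AugmentPolicy(), seed=2)
        cfg = run_config(
            task="two", max_epochs=2, min_epochs=1, batch_size=8,
            micro_check_every=2, learning_rate=0.05, out_dir=str(tmp_path / "run"),
        )
        trace, model, summary = train_with_adaptive_stopping(cfg, ds)
        assert (tmp_path / "run" / "trace.csv").exists()
        assert (tmp_path / "run" / "checkpoint.npz").exists()
        assert summary["total_batches"] > 0
        result = evaluate(model, ds, "two")
        assert 0.0 <= result["accuracy"] <= 1.0

    def test_empty_split_rejected(self):
        ds = make_tiny_set({0: 5, 2: 5}, split="train")
        with pytest.raises(ValueError):
            train_with_adaptive_stopping(run_config(), ds, ScriptedModel([1.0]))
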