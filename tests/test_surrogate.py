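import numpy as np
import pytest

from vnsmpc.actuation import VNSCommand
from vnsmpc.datagen import Dataset, Trial, split_dataset
from vnsmpc.surrogate import (SurrogateConfig, baseline_mae,
                              evaluate, load_model, predict_recursive,
                              save_model, train)


_TOY_W = np.array([[100.0, 0.5, 60.0, 0.2, 30.0, 0.1],
                   [0.0, 1.2, 20.0, 0.8, 10.0, 0.4]])


def _toy_drive(u):
    return _TOY_W @ u


def _toy_dataset(n_trials=40, decay=0.9, gain=0.1, seed=0):
    """First-order linear toy plant: y_{k+1} = decay*y_k + gain*(W u).

    All six command components feed a known mixing matrix; every trial
    starts from y0 = (150, 100) in raw units.
    """
    rng = np.random.default_rng(seed)
    trials = []
    for i in range(n_trials):
        pw = rng.uniform(0, 0.5, 3)
        pf = rng.uniform(0, 50, 3)
        cmd = VNSCommand(pw=tuple(pw), pf=tuple(pf), on=(1, 1, 1))
        drive = _toy_drive(cmd.as_vector())
        y = np.empty((100, 2))
        yk = np.array([150.0, 100.0])
        for k in range(100):
            yk = decay * yk + gain * drive
            y[k] = yk
        trials.append(Trial(i, cmd, y))
    ds = Dataset(trials=trials, split=np.zeros(n_trials, dtype=np.int64),
                 seed=seed, variant="toy")
    return split_dataset(ds, seed=seed + 1)


@pytest.fixture(scope="module")
def toy_model():
    ds = _toy_dataset(n_trials=100)
    cfg = SurrogateConfig(epochs=400, recursive_epochs=150, recursive_lr=1e-2,
                          batch_size=16, seed=1)
    model, history = train(cfg, ds)
    return ds, model, history


class TestTraining:
    def test_validation_loss_decreases(self, toy_model):
        _, _, history = toy_model
        assert history["val"][-1] < history["val"][0]

    def test_recursive_rollout_matches_closed_form(self, toy_model):
        # analytic oracle: y_k = d^k y_0 + (1 - d^k)/(1 - d) * g * (W u);
        # accuracy is measured relative to each channel's dynamic range,
        # averaged over the 99-step rollout of every held-out trial
        ds, model, _ = toy_model
        decay = 0.9
        span = ds.norm.span[:2]
        rels = []
        for idx in ds.indices("test"):
            t = ds.trials[idx]
            u = t.command.as_vector()
            drive = _toy_drive(u)
            y0 = t.outputs[0]
            pred = predict_recursive(model, y0, np.tile(u, (99, 1)))
            ks = np.arange(1, 100)[:, None]
            exact = decay ** ks * y0 + (1 - decay ** ks) * drive
            rel = np.abs(pred - exact) / span
            rels.append(rel.mean())
            assert rel.max() < 0.15  # no trial goes badly wrong
        assert np.mean(rels) < 0.02

    def test_constant_outputs_learned_exactly(self):
        rng = np.random.default_rng(3)
        trials = []
        for i in range(20):
            c = rng.uniform(80, 160)
            cmd = VNSCommand(pw=tuple(rng.uniform(0, 0.5, 3)),
                             pf=tuple(rng.uniform(0, 50, 3)))
            trials.append(Trial(i, cmd, np.full((100, 2), c)))
        ds = split_dataset(Dataset(trials, np.zeros(20, dtype=np.int64), 0, "c"))
        model, hist = train(SurrogateConfig(epochs=600, recursive_epochs=200,
                                            batch_size=8, seed=2,
                                            learning_rate=1e-2), ds)
        assert hist["train"][-1] < 1e-3

    def test_saturating_output_needs_normalization_headroom(self):
        # one extreme trial pushes a normalized training target past the
        # tanh-compatible range; training must refuse rather than saturate
        from vnsmpc.datagen import fit_norm_stats
        rng = np.random.default_rng(5)
        trials = []
        for i in range(50):
            val = 300.0 if i == 0 else rng.uniform(99, 101)
            cmd = VNSCommand(pw=tuple(rng.uniform(0, 0.5, 3)),
                             pf=tuple(rng.uniform(0, 50, 3)))
            trials.append(Trial(i, cmd, np.full((100, 2), val)))
        ds = split_dataset(Dataset(trials, np.zeros(50, dtype=np.int64), 0, "x"),
                           seed=12)
        if 0 not in ds.indices("train"):  # the outlier must sit in train
            j = ds.indices("train")[0]
            ds.split[0], ds.split[j] = 0, ds.split[0]
            ds.norm = fit_norm_stats([ds.trials[i] for i in ds.indices("train")])
        with pytest.raises(Exception):
            train(SurrogateConfig(epochs=2), ds)


class TestPrediction:
    def test_single_step_equals_forward_pass(self, toy_model):
        ds, model, _ = toy_model
        t = ds.trials[0]
        u = t.command.as_vector()
        one = predict_recursive(model, t.outputs[0], u.reshape(1, 6))
        assert one.shape == (1, 2)
        many = predict_recursive(model, t.outputs[0], np.tile(u, (99, 1)))
        assert many.shape == (99, 2)
        assert np.allclose(one[0], many[0])

    def test_empty_command_sequence_rejected(self, toy_model):
        _, model, _ = toy_model
        with pytest.raises(ValueError):
            predict_recursive(model, (150.0, 100.0), np.empty((0, 6)))

    def test_normalization_travels_with_model(self, toy_model):
        from vnsmpc.datagen import denormalize, normalize
        _, model, _ = toy_model
        sy = model.norm.slice(slice(0, 2))
        y = np.array([[140.0, 95.0]])
        assert np.allclose(denormalize(normalize(y, sy), sy), y)


class TestBaseline:
    def test_identical_to_model_that_copies_initial_value(self, toy_model):
        ds, _, _ = toy_model
        X, Y = ds.sequences("test")
        manual = float(np.mean(np.abs(X[:, :1, :2] - Y)))
        assert baseline_mae(ds, "test") == pytest.approx(manual)

    def test_trained_model_beats_persistence(self, toy_model):
        ds, model, _ = toy_model
        assert evaluate(model, ds, "test") < 0.5 * baseline_mae(ds, "test")


class TestPersistence:
    def test_save_load_round_trip(self, toy_model, tmp_path):
        ds, model, _ = toy_model
        save_model(model, tmp_path / "m")
        back = load_model(tmp_path / "m")
        for a, b in zip(model.params(), back.params()):
            assert np.array_equal(a, b)
        assert np.allclose(back.norm.mu, model.norm.mu)
        assert evaluate(back, ds) == pytest.approx(evaluate(model, ds))

    def test_loader_refuses_orphan_weights(self, toy_model, tmp_path):
        _, model, _ = toy_model
        save_model(model, tmp_path / "m")
        (tmp_path / "m.json").unlink()
        with pytest.raises(FileNotFoundError):
            load_model(tmp_path / "m")

    def test_loader_detects_weight_tampering(self, toy_model, tmp_path):
        _, model, _ = toy_model
        save_model(model, tmp_path / "m")
        with np.load(tmp_path / "m.npz") as f:
            arrays = {k: f[k].copy() for k in f.files}
        arrays["p0"][0, 0] += 1.0
        np.savez(tmp_path / "m.npz", **arrays)
        with pytest.raises(ValueError):
            load_model(tmp_path / "m")


class TestArchitectureComparison:
    def test_single_entry_grid(self):
        from vnsmpc.surrogate import compare_architectures
        ds = _toy_dataset(n_trials=20)
        cfg = SurrogateConfig(epochs=30, recursive_epochs=10, batch_size=8)
        rows = compare_architectures(ds, [cfg])
        assert len(rows) == 1
        assert rows[0]["cell"] == "lstm"

    def test_all_cells_beat_baseline_on_smooth_toy(self):
        from vnsmpc.surrogate import compare_architectures
        ds = _toy_dataset(n_trials=30)
        grid = [SurrogateConfig(cell=c, epochs=150, recursive_epochs=60,
                                batch_size=8, seed=4) for c in
                ("rnn", "gru", "lstm")]
        rows = compare_architectures(ds, grid)
        base = baseline_mae(ds, "test")
        assert all(r["test_mae"] < base for r in rows)
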