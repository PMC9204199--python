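"""Synthetic open-loop dataset generation for surrogate identification.

Each trial holds a randomly sampled stimulation command constant for 100
consecutive cardiac cycles, starting from the calibrated resting state:
pulse widths ~ U(0, 0.5) ms, pulse frequencies ~ U(0, 50) Hz, each location
independently on/off with probability 1/2. Trials are split 40/20/40 into
train/validation/test by trial, and every channel (HR, MAP and the six
command components) is normalized with training-split statistics:

    x_hat = (x - mu) / (x_max - x_min)

Datasets persist to HDF5 (with a CSV export) and are byte-reproducible from
their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .actuation import (PF_MAX, PW_MAX, RecruitmentParams, VNSCommand,
                        firing_deltas_from_vectors)
from .cardio import CardioSim, resting_state, simulate_trials
from .params import PlantParameters

__all__ = [
    "Trial", "NormStats", "Dataset", "sample_command", "generate_dataset",
    "fit_norm_stats", "normalize", "denormalize", "split_dataset",
]

TRIAL_CYCLES = 100
CHANNELS = ("hr", "map", "pw1", "pf1", "pw2", "pf2", "pw3", "pf3")
SPLIT_FRACTIONS = (0.4, 0.2, 0.4)  # train / val / test


@dataclass(frozen=True)
class Trial:
    """One open-loop trial: a constant command and its 100-cycle response."""

    trial_id: int
    command: VNSCommand
    outputs: np.ndarray  # (TRIAL_CYCLES, 2): HR bpm, MAP mmHg

    def __post_init__(self):
        if self.outputs.shape != (TRIAL_CYCLES, 2):
            raise ValueError(f"trial must span {TRIAL_CYCLES} cycles")


@dataclass(frozen=True)
class NormStats:
    """Per-channel training-split mean and extrema for Eq-style scaling."""

    mu: np.ndarray
    x_min: np.ndarray
    x_max: np.ndarray

    def __post_init__(self):
        if np.any(self.x_max <= self.x_min):
            raise ValueError("degenerate channel: x_max must exceed x_min")

    @property
    def span(self) -> np.ndarray:
        return self.x_max - self.x_min

    def slice(self, idx) -> "NormStats":
        return NormStats(self.mu[idx], self.x_min[idx], self.x_max[idx])


def normalize(x, s: NormStats):
    """(x - mu) / (x_max - x_min), channel-wise on the last axis."""
    return (np.asarray(x, dtype=float) - s.mu) / s.span


def denormalize(x_hat, s: NormStats):
    return np.asarray(x_hat, dtype=float) * s.span + s.mu


def sample_command(rng: np.random.Generator) -> VNSCommand:
    """Draw one open-loop stimulation command.

    Pw_i ~ U(0, 0.5) ms and Pf_i ~ U(0, 50) Hz per location; each location's
    on/off flag is a rounded U(0,1) draw, i.e. Bernoulli(1/2).
    """
    pw = rng.uniform(0.0, PW_MAX, 3)
    pf = rng.uniform(0.0, PF_MAX, 3)
    on = (rng.uniform(0.0, 1.0, 3) >= 0.5).astype(int)
    return VNSCommand(pw=tuple(pw), pf=tuple(pf), on=tuple(on))


@dataclass
class Dataset:
    """Open-loop trials with split labels and training-split normalization."""

    trials: list[Trial]
    split: np.ndarray            # per-trial label: 0 train, 1 val, 2 test
    seed: int
    variant: str
    norm: NormStats | None = None
    extra: dict = field(default_factory=dict)

    SPLIT_NAMES = ("train", "val", "test")

    def __len__(self) -> int:
        return len(self.trials)

    def indices(self, split: str) -> np.ndarray:
        return np.flatnonzero(self.split == self.SPLIT_NAMES.index(split))

    def commands_matrix(self) -> np.ndarray:
        return np.stack([t.command.as_vector() for t in self.trials])

    def outputs_tensor(self) -> np.ndarray:
        return np.stack([t.outputs for t in self.trials])

    def sequences(self, split: str) -> tuple[np.ndarray, np.ndarray]:
        """Normalized teacher-forcing sequences for a split.

        Returns (X, Y): X is (n, T-1, 8) of [y_k, u] steps, Y is (n, T-1, 2)
        of next-cycle outputs, both in normalized units.
        """
        if self.norm is None:
            raise ValueError("dataset has no normalization statistics")
        idx = self.indices(split)
        y = self.outputs_tensor()[idx]                      # (n, 100, 2)
        u = self.commands_matrix()[idx]                     # (n, 6)
        yn = normalize(y, self.norm.slice(slice(0, 2)))
        un = normalize(u, self.norm.slice(slice(2, 8)))
        X = np.concatenate(
            [yn[:, :-1, :], np.repeat(un[:, None, :], TRIAL_CYCLES - 1, axis=1)],
            axis=2)
        Y = yn[:, 1:, :]
        return X, Y

    # -- persistence -------------------------------------------------------
    def to_hdf5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.attrs["seed"] = self.seed
            f.attrs["variant"] = self.variant
            f.create_dataset("split", data=self.split)
            f.create_dataset("commands", data=self.commands_matrix())
            f.create_dataset("outputs", data=self.outputs_tensor())
            f.create_dataset("on_flags",
                             data=np.stack([t.command.on for t in self.trials]))
            if self.norm is not None:
                g = f.create_group("norm")
                g.create_dataset("mu", data=self.norm.mu)
                g.create_dataset("x_min", data=self.norm.x_min)
                g.create_dataset("x_max", data=self.norm.x_max)

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "Dataset":
        with h5py.File(path, "r") as f:
            cmds = f["commands"][...]
            outs = f["outputs"][...]
            ons = f["on_flags"][...]
            split = f["split"][...]
            norm = None
            if "norm" in f:
                norm = NormStats(f["norm/mu"][...], f["norm/x_min"][...],
                                 f["norm/x_max"][...])
            trials = [
                Trial(i, VNSCommand(pw=(c[0], c[2], c[4]), pf=(c[1], c[3], c[5]),
                                    on=tuple(int(v) for v in o)), y)
                for i, (c, y, o) in enumerate(zip(cmds, outs, ons))
            ]
            return cls(trials=trials, split=split, seed=int(f.attrs["seed"]),
                       variant=str(f.attrs["variant"]), norm=norm)

    def to_csv(self, path: str | Path) -> None:
        rows = []
        for t, lab in zip(self.trials, self.split):
            u = t.command.as_vector()
            for k in range(TRIAL_CYCLES):
                rows.append((t.trial_id, k + 1, *u, t.outputs[k, 0],
                             t.outputs[k, 1], self.SPLIT_NAMES[lab]))
        pd.DataFrame(rows, columns=["trial", "cycle", "pw1", "pf1", "pw2",
                                    "pf2", "pw3", "pf3", "hr", "map",
                                    "split"]).to_csv(path, index=False)


def fit_norm_stats(trials: list[Trial]) -> NormStats:
    """Channel statistics (mu, min, max) over the given (training) trials.

    Channels: HR, MAP pooled over all cycles; the six command components
    pooled over trials (off locations contribute zeros).
    """
    y = np.stack([t.outputs for t in trials]).reshape(-1, 2)
    u = np.stack([t.command.as_vector() for t in trials])
    mu = np.concatenate([y.mean(axis=0), u.mean(axis=0)])
    lo = np.concatenate([y.min(axis=0), u.min(axis=0)])
    hi = np.concatenate([y.max(axis=0), u.max(axis=0)])
    return NormStats(mu=mu, x_min=lo, x_max=hi)


def split_dataset(ds: Dataset, seed: int | None = None) -> Dataset:
    """Assign 40/20/40 train/val/test labels by trial and refit NormStats."""
    n = len(ds)
    if n < 5:
        raise ValueError("need at least 5 trials to split")
    rng = np.random.default_rng(ds.seed + 1 if seed is None else seed)
    order = rng.permutation(n)
    n_train = int(round(SPLIT_FRACTIONS[0] * n))
    n_val = int(round(SPLIT_FRACTIONS[1] * n))
    split = np.full(n, 2, dtype=np.int64)
    split[order[:n_train]] = 0
    split[order[n_train:n_train + n_val]] = 1
    ds = Dataset(trials=ds.trials, split=split, seed=ds.seed,
                 variant=ds.variant, extra=ds.extra)
    ds.norm = fit_norm_stats([ds.trials[i] for i in ds.indices("train")])
    return ds


def generate_dataset(p: PlantParameters, n_trials: int, seed: int,
                     rp: RecruitmentParams | None = None,
                     variant: str = "healthy",
                     rest: CardioSim | None = None,
                     do_split: bool = True) -> Dataset:
    """Simulate ``n_trials`` open-loop trials under random constant commands.

    Deterministic given ``seed``; all trials start from the settled resting
    state of the calibrated plant.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if rp is None:
        rp = RecruitmentParams()
    rng = np.random.default_rng(seed)
    commands = [sample_command(rng) for _ in range(n_trials)]
    u = np.stack([c.as_vector() for c in commands])
    deltas = firing_deltas_from_vectors(u, rp)
    if rest is None:
        rest, _ = resting_state(p)
    out = simulate_trials(p, deltas, TRIAL_CYCLES, rest=rest)
    bad = ~np.all(np.isfinite(out.reshape(n_trials, -1)), axis=1)
    while np.any(bad):  # regenerate failed trials with fresh commands
        idx = np.flatnonzero(bad)
        for i in idx:
            commands[i] = sample_command(rng)
        u = np.stack([commands[i].as_vector() for i in idx])
        out[idx] = simulate_trials(p, firing_deltas_from_vectors(u, rp),
                                   TRIAL_CYCLES, rest=rest)
        bad[idx] = ~np.all(np.isfinite(out[idx].reshape(len(idx), -1)), axis=1)
    trials = [Trial(i, c, out[i]) for i, c in enumerate(commands)]
    ds = Dataset(trials=trials, split=np.zeros(n_trials, dtype=np.int64),
                 seed=seed, variant=variant)
    if do_split and n_trials >= 5:
        ds = split_dataset(ds)
    return ds
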