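"""Stochastic excitatory drive to pyramidal cells and their glutamate output.

Each pyramidal cell receives an external current I_P built as a Poisson train
of rectangular pulses (mean rate ``F_in`` of 0-400 Hz, fixed 2-ms duration,
amplitudes i.i.d. uniform on [0, 2.5] uA/cm^2).  Pulse trains of distinct
cells are independent; overlapping pulses superpose additively.

A spiking pyramidal cell releases glutamate into its synaptic cleft; the
cleft concentration G (model units) follows

    dG/dt = -alpha_G G + beta_G / (1 + exp(-V/0.5)),

with relaxation rate alpha_G = 25 s^-1 and production rate beta_G = 500 s^-1.
The paired astrocyte senses this G.  Rates are stated in s^-1; the simulator
rescales them by 1e-3 when integrating on the millisecond grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DriveConfig",
    "PoissonPulseTrain",
    "ALPHA_G",
    "BETA_G",
    "substream",
    "sample_pulse_train",
    "drive_current_at",
    "glutamate_derivative",
    "trains_to_frame",
    "trains_from_frame",
]

ALPHA_G = 25.0  # s^-1, glutamate clearance
BETA_G = 500.0  # s^-1, glutamate release while the cell is depolarized
GLU_GATE_SLOPE = 0.5  # mV


@dataclass(frozen=True)
class DriveConfig:
    """Poisson rectangular-pulse drive parameters."""

    F_in: float = 260.0  # mean pulse rate, s^-1
    pulse_duration: float = 2.0  # ms
    amp_min: float = 0.0  # uA/cm^2
    amp_max: float = 2.5  # uA/cm^2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.F_in < 0:
            raise ValueError("F_in must be nonnegative")
        if self.pulse_duration <= 0:
            raise ValueError("pulse_duration must be positive")
        if self.amp_min > self.amp_max:
            raise ValueError("amp_min must not exceed amp_max")


@dataclass
class PoissonPulseTrain:
    """Pulse onsets (ms, strictly increasing) and their amplitudes (uA/cm^2)."""

    onset_times: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        self.onset_times = np.asarray(self.onset_times, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.onset_times.shape != self.amplitudes.shape:
            raise ValueError("onsets and amplitudes must have equal length")
        if self.onset_times.size > 1 and not np.all(
            np.diff(self.onset_times) > 0
        ):
            raise ValueError("onset_times must be strictly increasing")


def substream(master_seed: int, *key: int) -> np.random.Generator:
    """Independent, reproducible RNG stream identified by a counter key.

    Built on ``np.random.SeedSequence(master_seed, spawn_key=key)``, so the
    stream for (e.g.) pyramidal cell ``i`` does not depend on how many other
    streams exist — per-cell pulse trains are stable across network sizes.
    """
    ss = np.random.SeedSequence(int(master_seed), spawn_key=tuple(int(k) for k in key))
    return np.random.Generator(np.random.PCG64(ss))


def sample_pulse_train(
    config: DriveConfig,
    T: float,
    rng: np.random.Generator,
) -> PoissonPulseTrain:
    """Draw one Poisson pulse train on [0, T) ms.

    The number of pulses is Poisson(F_in * T / 1000); onsets are then uniform
    on [0, T) (sorted), amplitudes i.i.d. uniform on [amp_min, amp_max].
    """
    if T <= 0:
        raise ValueError("duration T must be positive")
    n = int(rng.poisson(config.F_in * T / 1000.0))
    onsets = np.sort(rng.uniform(0.0, T, size=n))
    amps = rng.uniform(config.amp_min, config.amp_max, size=n)
    return PoissonPulseTrain(onset_times=onsets, amplitudes=amps)


def drive_current_at(
    train: PoissonPulseTrain, t: float, pulse_duration: float = 2.0
) -> float:
    """I_P at time ``t`` (ms): summed amplitudes of all pulses whose half-open
    window [onset, onset + duration) contains ``t``."""
    if t < 0:
        raise ValueError("t must be nonnegative")
    on = train.onset_times
    active = (on <= t) & (t < on + pulse_duration)
    return float(train.amplitudes[active].sum())


def glutamate_derivative(
    G: float,
    V_pyr: float,
    alpha_G: float = ALPHA_G,
    beta_G: float = BETA_G,
) -> float:
    """dG/dt in s^-1 units (the simulator rescales to the ms grid)."""
    x = V_pyr / GLU_GATE_SLOPE
    if x >= 0:
        gate = 1.0 / (1.0 + math.exp(-x))
    else:
        e = math.exp(x)
        gate = e / (1.0 + e)
    return -alpha_G * G + beta_G * gate


def trains_to_frame(trains: list[PoissonPulseTrain]):
    """Long-format event list (neuron_id, onset_ms, amplitude) for CSV export."""
    import pandas as pd

    rows = {
        "neuron_id": np.concatenate(
            [np.full(t.onset_times.size, i, dtype=int) for i, t in enumerate(trains)]
        )
        if trains
        else np.array([], dtype=int),
        "onset_ms": np.concatenate([t.onset_times for t in trains])
        if trains
        else np.array([]),
        "amplitude": np.concatenate([t.amplitudes for t in trains])
        if trains
        else np.array([]),
    }
    return pd.DataFrame(rows)


def trains_from_frame(frame, n_neurons: int) -> list[PoissonPulseTrain]:
    """Inverse of :func:`trains_to_frame`, for exact replay of saved drives."""
    trains = []
    for i in range(n_neurons):
        sub = frame[frame["neuron_id"] == i].sort_values("onset_ms")
        trains.append(
            PoissonPulseTrain(
                onset_times=sub["onset_ms"].to_numpy(dtype=float),
                amplitudes=sub["amplitude"].to_numpy(dtype=float),
            )
        )
    return trains
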