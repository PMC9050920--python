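"""Coherence and frequency measures of interneuron network activity.

Activity is analyzed in 500-ms epochs.  Within each epoch the network mean
firing frequency Omega is the inverse of the mean interspike interval
(pooled across neurons by default), spike trains are binarized in windows of
width tau = 0.1/Omega, and the coherence of a pair of trains is the
normalized zero-lag correlation

    k_ij(tau) = sum_l X(l) Y(l) / sqrt( sum_l X(l) * sum_l Y(l) ),

which is 1 for identical trains and ~0 for asynchronous ones.  The network
coherence k of an epoch is the mean of k_ij over all unordered pairs; a pair
involving an empty train contributes 0 (the asynchrony limit of the
undefined 0/0).

During astrocytic modulation the relevant summary is k_astro: within each
interval where the astrocytic Ca2+ summary exceeds 0.3 uM take the maximum
of k (facilitation, g_astro > 0) or the minimum (depression, g_astro < 0),
then average over Ca2+ pulses.  The gamma frequency F_gamma is the mean
Omega over epochs with k > 0.2, and 0 if there are none.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SpikeRaster",
    "CoherenceConfig",
    "CoherenceResult",
    "mean_frequency",
    "binarize",
    "pairwise_coherence",
    "epoch_coherence",
    "network_coherence",
    "k_astro",
    "gamma_frequency",
]


@dataclass
class SpikeRaster:
    """Spike times (ms, sorted) of each neuron within [t_start, t_end)."""

    spike_times: list[np.ndarray]
    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        self.spike_times = [np.asarray(t, dtype=float) for t in self.spike_times]
        for t in self.spike_times:
            if t.size and (t.min() < self.t_start or t.max() > self.t_end):
                raise ValueError("spike time outside [t_start, t_end]")
            if t.size > 1 and np.any(np.diff(t) < 0):
                raise ValueError("spike times must be sorted")

    @property
    def n_neurons(self) -> int:
        return len(self.spike_times)

    @classmethod
    def from_result(cls, result, t_start: float | None = None,
                    t_end: float | None = None) -> "SpikeRaster":
        cfg = result.config
        t0 = cfg.T_discard if t_start is None else t_start
        t1 = cfg.T_total if t_end is None else t_end
        return cls(result.spikes_per_neuron(t0, t1), t0, t1)

    @classmethod
    def from_frame(cls, frame, n_neurons: int, t_start: float,
                   t_end: float) -> "SpikeRaster":
        """Build from a (time_ms, neuron_id) event table as written by the
        simulator's raster CSV export."""
        trains = []
        for i in range(n_neurons):
            t = frame.loc[frame["neuron_id"] == i, "time_ms"].to_numpy(float)
            t = np.sort(t[(t >= t_start) & (t < t_end)])
            trains.append(t)
        return cls(trains, t_start, t_end)


@dataclass(frozen=True)
class CoherenceConfig:
    epoch_ms: float = 500.0
    tau_fraction: float = 0.1  # bin width tau = tau_fraction / Omega
    detect_threshold_mV: float = 0.0  # upward crossing, used by the simulator
    k_min_for_fgamma: float = 0.2
    ca_threshold: float = 0.3  # uM
    pooled_isi: bool = True  # False: per-neuron rates averaged

    def __post_init__(self) -> None:
        if self.epoch_ms <= 0:
            raise ValueError("epoch_ms must be positive")
        if not 0.0 < self.tau_fraction < 1.0:
            raise ValueError("tau_fraction must lie in (0, 1)")


@dataclass
class CoherenceResult:
    epoch_starts: np.ndarray  # ms
    k: np.ndarray  # network coherence per epoch, in [0, 1]
    omega: np.ndarray  # Hz per epoch
    k_astro: float | None = None
    f_gamma: float = 0.0

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"epoch_start_ms": self.epoch_starts,
                             "k": self.k, "omega_hz": self.omega})

    def summary(self) -> dict:
        return {
            "k_mean": float(self.k.mean()) if self.k.size else 0.0,
            "omega_mean_hz": float(self.omega.mean()) if self.omega.size else 0.0,
            "k_astro": self.k_astro,
            "f_gamma_hz": self.f_gamma,
        }


def mean_frequency(trains: list[np.ndarray], pooled: bool = True) -> float:
    """Mean firing frequency Omega (Hz) = 1000 / mean interspike interval.

    ``pooled=True`` pools the ISIs of all neurons before averaging; the
    alternative averages each neuron's rate.  Returns 0 if no neuron has at
    least two spikes.
    """
    isis = [np.diff(t) for t in trains if t.size >= 2]
    if not isis:
        return 0.0
    if pooled:
        all_isis = np.concatenate(isis)
        return 1000.0 / all_isis.mean()
    return float(np.mean([1000.0 / isi.mean() for isi in isis]))


def binarize(trains: list[np.ndarray], t0: float, epoch_ms: float,
             tau: float) -> np.ndarray:
    """(n_neurons, L) 0/1 matrix; bin l covers [t0 + l*tau, t0 + (l+1)*tau).

    L = floor(epoch_ms / tau); the trailing partial bin is dropped.  A bin is
    1 if at least one spike falls in it.
    """
    L = int(epoch_ms / tau)
    out = np.zeros((len(trains), L), dtype=np.int8)
    for i, t in enumerate(trains):
        idx = np.floor((t - t0) / tau).astype(int)
        idx = idx[(idx >= 0) & (idx < L)]
        out[i, idx] = 1
    return out


def pairwise_coherence(X: np.ndarray, Y: np.ndarray) -> float:
    """Normalized zero-lag correlation of two binary patterns; 0 when either
    pattern is empty (denominator would vanish)."""
    X = np.asarray(X)
    Y = np.asarray(Y)
    if X.shape != Y.shape:
        raise ValueError("patterns must have equal length")
    sx = int(X.sum())
    sy = int(Y.sum())
    if sx == 0 or sy == 0:
        return 0.0
    return float((X * Y).sum() / np.sqrt(sx * sy))


def epoch_coherence(patterns: np.ndarray) -> float:
    """Mean pairwise coherence over all unordered pairs of rows."""
    B = patterns.astype(np.float64)
    n = B.shape[0]
    if n < 2:
        return 0.0
    counts = B.sum(axis=1)
    dots = B @ B.T
    denom = np.sqrt(np.outer(counts, counts))
    with np.errstate(divide="ignore", invalid="ignore"):
        K = np.where(denom > 0, dots / np.where(denom > 0, denom, 1.0), 0.0)
    iu = np.triu_indices(n, k=1)
    return float(K[iu].mean())


def network_coherence(raster: SpikeRaster,
                      config: CoherenceConfig = CoherenceConfig()
                      ) -> CoherenceResult:
    """Per-epoch network coherence k and mean frequency Omega.

    Epochs tile [t_start, t_end) in steps of ``epoch_ms``; a trailing
    partial epoch is dropped.  An epoch with Omega = 0 has k = 0.
    """
    span = raster.t_end - raster.t_start
    n_epochs = int(span / config.epoch_ms)
    if n_epochs < 1:
        raise ValueError("raster must cover at least one full epoch")
    starts = raster.t_start + config.epoch_ms * np.arange(n_epochs)
    k = np.zeros(n_epochs)
    omega = np.zeros(n_epochs)
    for e, t0 in enumerate(starts):
        t1 = t0 + config.epoch_ms
        sub = [t[(t >= t0) & (t < t1)] for t in raster.spike_times]
        om = mean_frequency(sub, pooled=config.pooled_isi)
        omega[e] = om
        if om <= 0:
            continue
        tau = 1000.0 * config.tau_fraction / om  # ms
        if tau >= config.epoch_ms:
            continue
        k[e] = epoch_coherence(binarize(sub, t0, config.epoch_ms, tau))
    result = CoherenceResult(epoch_starts=starts, k=k, omega=omega)
    result.f_gamma = gamma_frequency(k, omega, config)
    return result


def _pulse_intervals(t: np.ndarray, ca: np.ndarray,
                     threshold: float) -> list[tuple[float, float]]:
    """Maximal contiguous intervals of the trace with ca > threshold."""
    above = ca > threshold
    if not above.any():
        return []
    d = np.diff(above.astype(int))
    starts = list(np.where(d == 1)[0] + 1)
    ends = list(np.where(d == -1)[0] + 1)
    if above[0]:
        starts = [0] + starts
    if above[-1]:
        ends = ends + [above.size]
    return [(float(t[s]), float(t[e - 1])) for s, e in zip(starts, ends)]


def k_astro(result: CoherenceResult, t_ca: np.ndarray, ca: np.ndarray,
            config: CoherenceConfig = CoherenceConfig(),
            direction: str = "potentiation",
            epoch_ms: float | None = None) -> float | None:
    """Average extremal coherence during astrocytic Ca2+ elevations.

    ``ca`` is the astrocyte-network Ca2+ summary (network mean by default in
    the simulator; a per-cell trace can be passed instead).  Within each
    maximal interval of ca > threshold, take max(k) for ``potentiation``
    (g_astro > 0) or min(k) for ``depression`` (g_astro < 0) over the epochs
    overlapping the interval; return the mean over intervals, or None when no
    Ca2+ pulse (or no overlapping epoch) exists.
    """
    if direction not in ("potentiation", "depression"):
        raise ValueError("direction must be 'potentiation' or 'depression'")
    epoch = config.epoch_ms if epoch_ms is None else epoch_ms
    intervals = _pulse_intervals(np.asarray(t_ca), np.asarray(ca),
                                 config.ca_threshold)
    extrema = []
    for (a, b) in intervals:
        mask = (result.epoch_starts + epoch > a) & (result.epoch_starts < b)
        if not mask.any():
            continue
        ks = result.k[mask]
        extrema.append(ks.max() if direction == "potentiation" else ks.min())
    if not extrema:
        return None
    return float(np.mean(extrema))


def gamma_frequency(k: np.ndarray, omega: np.ndarray,
                    config: CoherenceConfig = CoherenceConfig()) -> float:
    """Mean Omega over epochs with k above the coherence floor; 0 if none."""
    k = np.asarray(k)
    omega = np.asarray(omega)
    if k.shape != omega.shape:
        raise ValueError("k and omega must be aligned")
    mask = k > config.k_min_for_fgamma
    if not mask.any():
        return 0.0
    return float(omega[mask].mean())
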