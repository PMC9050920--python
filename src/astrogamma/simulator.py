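"""Full-network simulation: configuration, initial conditions, RK4 run.

The network couples 200 interneurons (mutually inhibitory ring), 200
Poisson-driven pyramidal cells (one excitatory synapse each onto the
like-indexed interneuron), their released glutamate, and 200 astrocytes
(gap-junction ring) whose Ca2+ modulates synaptic weights.  Everything is
advanced together by classical fixed-step RK4 at dt = 5e-3 ms; the
stochastic pulse drive is held piecewise-constant within a step.

Initial conditions: neurons start at the rest equilibrium of the isolated
cell (gates at their voltage-clamped steady states) with a small seeded
per-cell voltage jitter (uniform +/-1 mV) to break symmetry; glutamate at 0;
astrocytes at the glutamate-free fixed point.  The discarded transient makes
results insensitive to these choices.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np

from . import _kernel
from .astrocyte import AstrocyteParams, astrocyte_rest_state
from .drive import ALPHA_G, BETA_G, DriveConfig, sample_pulse_train, substream
from .hh import NeuronParams, resting_potential, steady_state_gates
from .synapses import ModulationConfig, ModulationTarget
from .topology import NetworkTopology, TopologyConfig, build_full_network

__all__ = ["SimConfig", "SimResult", "SimulationDiverged", "run_simulation",
            "initial_state", "reference_derivatives", "config_from_dict",
            "rk4_step"]


def rk4_step(y: np.ndarray, f, t: float, dt: float) -> np.ndarray:
    """One classical fourth-order Runge-Kutta step for dy/dt = f(t, y).

    The network kernel uses a fused version of exactly this update; this
    generic form backs the integrator-order tests and small models.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    k1 = f(t, y)
    k2 = f(t + 0.5 * dt, y + 0.5 * dt * k1)
    k3 = f(t + 0.5 * dt, y + 0.5 * dt * k2)
    k4 = f(t + dt, y + dt * k3)
    return y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)

_STREAM_DRIVE = 1  # spawn_key tags for the independent RNG streams
_STREAM_JITTER = 2

_MOD_CODE = {
    ModulationTarget.NONE: _kernel.MOD_NONE,
    ModulationTarget.INHIBITORY: _kernel.MOD_INHIBITORY,
    ModulationTarget.EXCITATORY: _kernel.MOD_EXCITATORY,
}


class SimulationDiverged(RuntimeError):
    """Raised when the integration blows up or a state bound is violated."""

    def __init__(self, message: str, t_ms: float, max_abs_v: float):
        super().__init__(message)
        self.t_ms = t_ms
        self.max_abs_v = max_abs_v


@dataclass(frozen=True)
class SimConfig:
    """One simulation run.

    ``T_total``/``T_discard`` default to desk-scale values (5 s simulated,
    1 s discarded); the full-length study protocol is 180 s with the first
    15 s discarded.
    """

    dt: float = 5e-3  # ms
    T_total: float = 5_000.0  # ms
    T_discard: float = 1_000.0  # ms
    seed: int = 0
    n_cells: int = 200
    g_syn: float = 0.01  # mS/cm^2, interneuron-interneuron
    g_syn_P: float = 0.7  # mS/cm^2, pyramidal-to-interneuron
    drive: DriveConfig = field(default_factory=DriveConfig)
    modulation: ModulationConfig = field(default_factory=ModulationConfig)
    neuron: NeuronParams = field(default_factory=NeuronParams)
    astro: AstrocyteParams = field(default_factory=AstrocyteParams)
    topology: TopologyConfig | None = None  # derived from the above if None
    astro_enabled: bool = True  # False compiles the astrocyte layer out
    jitter_mV: float = 1.0
    record_every_ms: float = 1.0
    record_astro_traces: bool = False  # per-cell Ca/IP3/z, subsampled
    exact_rates: bool = False  # exact exps instead of lookup tables (slow)

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not self.T_discard < self.T_total:
            raise ValueError("T_discard must be smaller than T_total")

    def resolved_topology(self) -> TopologyConfig:
        if self.topology is not None:
            return self.topology
        return TopologyConfig(
            n_cells=self.n_cells, g_syn=self.g_syn, g_syn_P=self.g_syn_P,
            seed=self.seed,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["modulation"]["target"] = self.modulation.target.value
        if self.topology is None:
            d.pop("topology")
        return d


@dataclass
class SimResult:
    """Spike raster, subsampled traces and run provenance."""

    config: SimConfig
    spike_times: np.ndarray  # ms, full resolution
    spike_ids: np.ndarray
    t_rec: np.ndarray  # ms, subsampled trace grid
    ca_mean: np.ndarray  # network-mean astrocytic Ca2+ (uM) on t_rec
    mean_abs_iexc: np.ndarray  # per-interneuron time-averaged |I_exc|, analysis window
    ca_full: np.ndarray | None = None
    ip3_full: np.ndarray | None = None
    z_full: np.ndarray | None = None

    def spikes_per_neuron(self, t_start: float | None = None,
                          t_end: float | None = None) -> list[np.ndarray]:
        """Sorted spike times of each interneuron within [t_start, t_end)."""
        cfg = self.config
        t0 = cfg.T_discard if t_start is None else t_start
        t1 = cfg.T_total if t_end is None else t_end
        out = []
        for i in range(cfg.n_cells):
            t = self.spike_times[self.spike_ids == i]
            out.append(t[(t >= t0) & (t < t1)])
        return out

    def raster_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"time_ms": self.spike_times, "neuron_id": self.spike_ids}
        )

    def write_raster_csv(self, path: str | Path) -> None:
        # %.17g keeps spike times exactly round-trippable for replay
        self.raster_frame().to_csv(path, index=False, float_format="%.17g")

    def write_manifest(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.config.to_dict(), indent=2,
                                          default=str))


def config_from_dict(d: dict) -> SimConfig:
    """Build a SimConfig from a nested plain dict (e.g. parsed YAML).

    Sections ``drive``, ``modulation``, ``neuron``, ``astro`` and
    ``topology`` mirror the corresponding dataclasses; remaining keys are
    top-level SimConfig fields.
    """
    d = dict(d)
    kwargs: dict = {}
    if "drive" in d:
        kwargs["drive"] = DriveConfig(**d.pop("drive"))
    if "modulation" in d:
        m = dict(d.pop("modulation"))
        if "target" in m:
            m["target"] = ModulationTarget(m["target"])
        kwargs["modulation"] = ModulationConfig(**m)
    if "neuron" in d:
        kwargs["neuron"] = NeuronParams(**d.pop("neuron"))
    if "astro" in d:
        kwargs["astro"] = AstrocyteParams(**d.pop("astro"))
    if "topology" in d:
        kwargs["topology"] = TopologyConfig(**d.pop("topology"))
    kwargs.update(d)
    return SimConfig(**kwargs)


@lru_cache(maxsize=4)
def _tables(k_syn: float) -> np.ndarray:
    return _kernel.build_tables(k_syn)


@lru_cache(maxsize=8)
def _neuron_rest(params: NeuronParams) -> tuple[float, float, float, float]:
    v = resting_potential(params)
    m, n, h = steady_state_gates(v)
    return v, m, n, h


@lru_cache(maxsize=8)
def _astro_rest(params: AstrocyteParams) -> tuple[float, float, float]:
    s = astrocyte_rest_state(params)
    return s.ca, s.ip3, s.z


def initial_state(config: SimConfig) -> np.ndarray:
    """(12, n) state array at t = 0 (see kernel row layout)."""
    n = config.n_cells
    Y = np.zeros((12, n))
    v, m, mm, h = _neuron_rest(config.neuron)
    jit = substream(config.seed, _STREAM_JITTER).uniform(
        -config.jitter_mV, config.jitter_mV, size=2 * n
    )
    Y[0] = v + jit[:n]
    Y[4] = v + jit[n:]
    Y[1] = Y[5] = m
    Y[2] = Y[6] = mm
    Y[3] = Y[7] = h
    Y[8] = 0.0
    ca, ip3, z = _astro_rest(config.astro)
    Y[9] = ca
    Y[10] = ip3
    Y[11] = z
    return Y


def _drive_events(config: SimConfig):
    """Per-pyramidal pulse onsets snapped to the step grid, CSR-packed."""
    n = config.n_cells
    onsets, amps, counts = [], [], np.zeros(n + 1, dtype=np.int64)
    for i in range(n):
        rng = substream(config.seed, _STREAM_DRIVE, i)
        train = sample_pulse_train(config.drive, config.T_total, rng)
        steps = np.floor(train.onset_times / config.dt).astype(np.int64)
        onsets.append(steps)
        amps.append(train.amplitudes)
        counts[i + 1] = counts[i] + steps.size
    ev_onset = (np.concatenate(onsets) if onsets else
                np.array([], dtype=np.int64))
    ev_amp = np.concatenate(amps) if amps else np.array([])
    return counts, ev_onset, ev_amp


def _astro_param_vector(p: AstrocyteParams) -> np.ndarray:
    return np.array([
        p.c0, p.c1, p.v1, p.v2, p.v3, p.v4, p.v5, p.v6,
        p.k1, p.k2, p.k3, p.k4, p.a2, p.d1, p.d2, p.d3, p.d5,
        p.alpha, p.tau_IP3, p.IP3_star, p.d_Ca, p.d_IP3, p.alpha_Glu,
    ])


def run_simulation(config: SimConfig,
                   topology: NetworkTopology | None = None) -> SimResult:
    """Integrate the full network and return raster, traces and summaries.

    Deterministic: identical (config, seed) gives bit-identical output.
    Raises :class:`SimulationDiverged` if the state blows up.
    """
    if topology is None:
        topology = build_full_network(config.resolved_topology())
    n = config.n_cells
    if topology.n_cells != n:
        raise ValueError("topology size does not match config.n_cells")

    Y = initial_state(config)
    # out-adjacency: the kernel scatters each active presynaptic gate
    indptr, indices = topology.inhib_csr(direction="out")
    ev_indptr, ev_onset, ev_amp = _drive_events(config)

    dt = config.dt
    n_steps = int(round(config.T_total / dt))
    discard_step = int(round(config.T_discard / dt))
    dur_steps = max(1, int(round(config.drive.pulse_duration / dt)))
    rec_every = max(1, int(round(config.record_every_ms / dt)))
    # generous cap: 500 Hz per interneuron
    spike_cap = int(n * config.T_total / 2.0) + 1000

    mod = config.modulation
    neu = config.neuron
    out = _kernel.run_kernel(
        Y, dt, n_steps, discard_step,
        indptr, indices,
        ev_indptr, ev_onset, ev_amp, dur_steps,
        config.g_syn, config.g_syn_P, mod.k_syn,
        -90.0, 0.0, 1.0 if mod.corrected_sign else -1.0,
        neu.C, neu.g_Na, neu.g_K, neu.g_Leak,
        neu.E_Na, neu.E_K, neu.E_Leak, neu.I_app,
        _MOD_CODE[mod.target], mod.g_astro, mod.ca_threshold,
        mod.clamp_nonnegative,
        config.astro_enabled, _astro_param_vector(config.astro),
        ALPHA_G, BETA_G,
        _tables(mod.k_syn), config.exact_rates,
        rec_every, config.record_astro_traces,
        spike_cap,
    )
    (status, fail_step, spike_t, spike_id, n_spikes, ca_mean,
     ca_full, ip3_full, z_full, acc_iexc, n_acc) = out

    if status != _kernel.OK:
        t_fail = fail_step * dt
        max_v = float(np.nanmax(np.abs(Y[0]))) if np.isfinite(Y[0]).any() else float("inf")
        reasons = {
            _kernel.DIVERGED: "membrane potential diverged",
            _kernel.STATE_VIOLATION: "state bound violated beyond tolerance (dt too large?)",
            _kernel.SPIKE_OVERFLOW: "spike buffer overflow",
        }
        raise SimulationDiverged(
            f"{reasons.get(status, 'integration failure')} at t = {t_fail:.3f} ms "
            f"(max |V| = {max_v:.1f} mV)", t_fail, max_v)

    t_rec = np.arange(ca_mean.size) * rec_every * dt
    return SimResult(
        config=config,
        spike_times=spike_t[:n_spikes].copy(),
        spike_ids=spike_id[:n_spikes].copy(),
        t_rec=t_rec,
        ca_mean=ca_mean,
        mean_abs_iexc=acc_iexc / max(n_acc, 1),
        ca_full=ca_full if config.record_astro_traces else None,
        ip3_full=ip3_full if config.record_astro_traces else None,
        z_full=z_full if config.record_astro_traces else None,
    )


def reference_derivatives(Y: np.ndarray, ip_amp: np.ndarray,
                          config: SimConfig,
                          topology: NetworkTopology) -> np.ndarray:
    """Pure-numpy derivative of the full coupled system.

    Built from the per-module reference operations; used as the independent
    oracle the jitted kernel is checked against in the tests.
    """
    from . import astrocyte as astro_mod
    from .drive import glutamate_derivative
    from .hh import NeuronState, neuron_derivatives
    from .synapses import presynaptic_gate, modulated_weight

    n = config.n_cells
    mod = config.modulation
    dY = np.zeros_like(Y)
    indptr, indices = topology.inhib_csr()
    sign = 1.0 if mod.corrected_sign else -1.0

    gates_i = np.array([presynaptic_gate(v, mod.k_syn) for v in Y[0]])
    gates_p = np.array([presynaptic_gate(v, mod.k_syn) for v in Y[4]])
    for i in range(n):
        ca = Y[9, i]
        on = config.astro_enabled
        w_inh = modulated_weight(
            config.g_syn, ca, mod,
            edge_targeted=on and mod.target == ModulationTarget.INHIBITORY)
        w_exc = modulated_weight(
            config.g_syn_P, ca, mod,
            edge_targeted=on and mod.target == ModulationTarget.EXCITATORY)
        s = gates_i[indices[indptr[i]:indptr[i + 1]]].sum()
        I_syn = (w_inh * s * sign * (-90.0 - Y[0, i])
                 + w_exc * gates_p[i] * sign * (0.0 - Y[0, i]))
        st = NeuronState(V=Y[0, i], m=Y[1, i], n=Y[2, i], h=Y[3, i])
        dY[0, i], dY[1, i], dY[2, i], dY[3, i] = neuron_derivatives(
            st, config.neuron, I_syn)
        stp = NeuronState(V=Y[4, i], m=Y[5, i], n=Y[6, i], h=Y[7, i])
        dY[4, i], dY[5, i], dY[6, i], dY[7, i] = neuron_derivatives(
            stp, config.neuron, ip_amp[i])
        dY[8, i] = 1e-3 * glutamate_derivative(Y[8, i], Y[4, i])

    if config.astro_enabled:
        states = [astro_mod.AstrocyteState(ca=Y[9, i], ip3=Y[10, i],
                                           z=Y[11, i]) for i in range(n)]
        for i in range(n):
            dca, dz = astro_mod.calcium_derivatives(i, states, config.astro)
            dip3 = astro_mod.ip3_derivative(i, states, Y[8, i], config.astro)
            dY[9, i] = 1e-3 * dca
            dY[10, i] = 1e-3 * dip3
            dY[11, i] = 1e-3 * dz
    return dY
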