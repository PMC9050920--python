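"""Parameter sweeps over the synchronization maps.

A sweep evaluates the network on a 1D or 2D grid over any of the four
operating parameters (g_syn, g_syn_P, F_in, g_astro), running several
seeded replicate simulations per grid point and tabulating the epoch-mean
coherence k (and k_astro when astrocytic modulation is active), the mean
network frequency, and the gamma frequency F_gamma.  Per-pixel seeds are
derived deterministically from the master seed and the grid indices, so a
sweep is a pure function of (spec, master seed) and can be split across
processes without coordination.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .drive import DriveConfig
from .metrics import (CoherenceConfig, SpikeRaster, k_astro,
                      network_coherence)
from .simulator import SimConfig, SimulationDiverged, run_simulation
from .synapses import ModulationConfig, ModulationTarget

__all__ = ["SweepSpec", "run_sweep", "run_point", "region_bounds"]

SWEEPABLE = ("g_syn", "g_syn_P", "F_in", "g_astro")


@dataclass(frozen=True)
class SweepSpec:
    """Grid + replication plan for one coherence map.

    ``base`` carries every non-swept setting.  Desk-scale durations are the
    base config's defaults (5 s / 1 s discard); studies measuring k_astro
    need tens of seconds of simulation so astrocytic Ca2+ pulses occur.
    """

    axis1: str
    values1: tuple[float, ...]
    axis2: str | None = None
    values2: tuple[float, ...] = ()
    replicates: int = 3
    master_seed: int = 0
    base: SimConfig = field(default_factory=SimConfig)
    coherence: CoherenceConfig = field(default_factory=CoherenceConfig)

    def __post_init__(self) -> None:
        if self.axis1 not in SWEEPABLE:
            raise ValueError(f"axis1 must be one of {SWEEPABLE}")
        if self.axis2 is not None and self.axis2 not in SWEEPABLE:
            raise ValueError(f"axis2 must be one of {SWEEPABLE}")
        if not self.values1 or (self.axis2 is not None and not self.values2):
            raise ValueError("value grids must be non-empty")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def _pixel_seed(master_seed: int, i1: int, i2: int, rep: int) -> int:
    ss = np.random.SeedSequence(entropy=int(master_seed),
                                spawn_key=(int(i1), int(i2), int(rep)))
    return int(ss.generate_state(1)[0] % (2**31))


def _with_param(cfg: SimConfig, name: str, value: float) -> SimConfig:
    if name == "g_syn":
        return replace(cfg, g_syn=value)
    if name == "g_syn_P":
        return replace(cfg, g_syn_P=value)
    if name == "F_in":
        return replace(cfg, drive=dataclasses.replace(cfg.drive, F_in=value))
    if name == "g_astro":
        return replace(cfg, modulation=dataclasses.replace(
            cfg.modulation, g_astro=value))
    raise ValueError(name)


def run_point(cfg: SimConfig, seed: int,
              coherence: CoherenceConfig = CoherenceConfig()) -> dict:
    """One seeded simulation reduced to its scalar summaries."""
    cfg = replace(cfg, seed=seed)
    res = run_simulation(cfg)
    cr = network_coherence(SpikeRaster.from_result(res), coherence)
    out = {
        "seed": seed,
        "k_mean": float(cr.k.mean()),
        "omega_mean": float(cr.omega.mean()),
        "f_gamma": cr.f_gamma,
        "k_astro": None,
    }
    mod = cfg.modulation
    if cfg.astro_enabled and mod.target != ModulationTarget.NONE \
            and mod.g_astro != 0.0:
        mask = res.t_rec >= cfg.T_discard
        direction = "potentiation" if mod.g_astro > 0 else "depression"
        out["k_astro"] = k_astro(cr, res.t_rec[mask], res.ca_mean[mask],
                                 coherence, direction)
    return out


def run_sweep(spec: SweepSpec, progress: bool = False) -> pd.DataFrame:
    """Long-format coherence map table.

    One row per grid point with mean and SD of k over replicates, the mean
    k_astro (when measured), mean F_gamma and the replicate count.  A
    diverged run is recorded in the ``error`` column and excluded from the
    means rather than silently dropped.
    """
    vals2 = spec.values2 if spec.axis2 is not None else (None,)
    rows = []
    for i1, v1 in enumerate(spec.values1):
        for i2, v2 in enumerate(vals2):
            cfg = _with_param(spec.base, spec.axis1, v1)
            if spec.axis2 is not None:
                cfg = _with_param(cfg, spec.axis2, v2)
            ks, oms, fgs, kas, errors = [], [], [], [], []
            for rep in range(spec.replicates):
                seed = _pixel_seed(spec.master_seed, i1, i2, rep)
                try:
                    r = run_point(cfg, seed, spec.coherence)
                except SimulationDiverged as exc:
                    errors.append(f"seed {seed}: {exc}")
                    continue
                ks.append(r["k_mean"])
                oms.append(r["omega_mean"])
                fgs.append(r["f_gamma"])
                if r["k_astro"] is not None:
                    kas.append(r["k_astro"])
            row = {
                spec.axis1: v1,
                "k_mean": float(np.mean(ks)) if ks else np.nan,
                "k_sd": float(np.std(ks, ddof=1)) if len(ks) > 1 else 0.0,
                "omega_mean": float(np.mean(oms)) if oms else np.nan,
                "f_gamma_mean": float(np.mean(fgs)) if fgs else np.nan,
                "k_astro_mean": float(np.mean(kas)) if kas else np.nan,
                "n_reps": len(ks),
                "error": "; ".join(errors) if errors else "",
            }
            if spec.axis2 is not None:
                row[spec.axis2] = v2
            rows.append(row)
            if progress:
                print(f"{spec.axis1}={v1}"
                      + (f" {spec.axis2}={v2}" if spec.axis2 else "")
                      + f": k={row['k_mean']:.3f}", flush=True)
    cols = [spec.axis1] + ([spec.axis2] if spec.axis2 else []) + [
        "k_mean", "k_sd", "omega_mean", "f_gamma_mean", "k_astro_mean",
        "n_reps", "error"]
    return pd.DataFrame(rows)[cols]


def region_bounds(table: pd.DataFrame, level: float,
                  value_col: str = "k_mean",
                  axis: str | None = None,
                  by: str | None = None) -> pd.DataFrame:
    """Bounds of the {value >= level} region of a coherence map.

    For each value of ``by`` (or once, for a 1D map) report the min and max
    of ``axis`` where the mean coherence reaches ``level``; rows with an
    empty region are omitted.
    """
    if axis is None:
        axis = table.columns[0]
    groups = [((), table)] if by is None else list(table.groupby(by))
    rows = []
    for key, sub in groups:
        hit = sub[sub[value_col] >= level]
        if hit.empty:
            continue
        row = {} if by is None else {by: key}
        row["lower"] = float(hit[axis].min())
        row["upper"] = float(hit[axis].max())
        rows.append(row)
    cols = ([by] if by else []) + ["lower", "upper"]
    return pd.DataFrame(rows, columns=cols)
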