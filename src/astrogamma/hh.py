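"""Mainen-modified Hodgkin-Huxley dynamics for fast-spiking interneurons.

Both the interneurons and the pyramidal cells of the network use the same
single-compartment membrane model

    C dV/dt = I_channel + I_app + I_ext
    dx/dt   = alpha_x(V) (1 - x) - beta_x(V) x,   x = m, n, h

with sodium, delayed-rectifier potassium and leak channels,

    I_channel = g_Na m^3 h (E_Na - V) + g_K n (E_K - V) + g_Leak (E_Leak - V).

``I_ext`` is whatever the network supplies (Poisson pulse drive plus synaptic
current); the constant shift current ``I_app`` places an isolated cell in the
rest mode (a stable focus), so every spike is input-driven.

Units: mV, ms, uA/cm^2, mS/cm^2, uF/cm^2 throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "NeuronParams",
    "NeuronState",
    "gating_rates",
    "steady_state_gates",
    "neuron_derivatives",
    "resting_potential",
]

# Width of the window around a removable singularity of the rate functions
# within which the analytic limit is used instead of the raw expression.
SINGULARITY_EPS = 1e-6


@dataclass(frozen=True)
class NeuronParams:
    """Membrane constants of one Hodgkin-Huxley cell.

    Defaults are the fast-spiking basket-cell values used throughout:
    C = 1 uF/cm^2, g_Na = 40, g_K = 35, g_Leak = 0.3 mS/cm^2,
    E_Na = 55, E_K = -77 mV and a shift current I_app = 0.7 uA/cm^2 that
    keeps the isolated cell at rest.

    The leak reversal defaults to -64.4 mV, which places the cell in the
    excitable rest mode this network architecture requires: a stable focus
    at I_app = 0.7 with a Hopf bifurcation near I = 0.85, so every spike is
    input-driven.  With the classic squid value -54.4 mV (selectable here)
    the same kinetics make the cell intrinsically oscillatory (~48 Hz) at
    any shift current, which abolishes the drive-gated regime.
    """

    C: float = 1.0
    g_Na: float = 40.0
    g_K: float = 35.0
    g_Leak: float = 0.3
    E_Na: float = 55.0
    E_K: float = -77.0
    E_Leak: float = -64.4
    I_app: float = 0.7

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("membrane capacitance C must be positive")
        if min(self.g_Na, self.g_K, self.g_Leak) < 0:
            raise ValueError("conductances must be nonnegative")


@dataclass
class NeuronState:
    """Membrane potential (mV) and the three gating variables."""

    V: float
    m: float
    n: float
    h: float

    def validate(self) -> None:
        for name in ("m", "n", "h"):
            x = getattr(self, name)
            if not 0.0 <= x <= 1.0:
                raise ValueError(f"gating variable {name}={x} outside [0, 1]")
        if not math.isfinite(self.V):
            raise ValueError("non-finite membrane potential")


def _rate_linexp(v: float, scale: float, k: float) -> float:
    """scale * v / (1 - exp(-v/k)), with the analytic limit scale*k at v = 0."""
    if abs(v) < SINGULARITY_EPS:
        return scale * k
    return scale * v / (1.0 - math.exp(-v / k))


def gating_rates(V: float) -> tuple[float, float, float, float, float, float]:
    """Opening/closing rates (alpha_m, beta_m, alpha_n, beta_n, alpha_h, beta_h)
    in ms^-1 at membrane potential ``V`` (mV).

    The m and n rates have removable singularities (at V = -35 mV and
    V = +25 mV respectively); within ``SINGULARITY_EPS`` of those points the
    analytic limit is returned.
    """
    if not math.isfinite(V):
        raise ValueError("membrane potential must be finite")
    vm = V + 35.0
    vn = V - 25.0
    alpha_m = _rate_linexp(vm, 0.182, 9.0)
    beta_m = _rate_linexp(-vm, 0.124, 9.0)
    alpha_n = _rate_linexp(vn, 0.02, 9.0)
    beta_n = _rate_linexp(-vn, 0.002, 9.0)
    alpha_h = 0.25 * math.exp(-(V + 90.0) / 12.0)
    beta_h = 0.25 * math.exp((V + 62.0) / 6.0 - (V + 90.0) / 12.0)
    return alpha_m, beta_m, alpha_n, beta_n, alpha_h, beta_h


def steady_state_gates(V: float) -> tuple[float, float, float]:
    """Voltage-clamped fixed points x_inf = alpha/(alpha+beta) for m, n, h."""
    am, bm, an, bn, ah, bh = gating_rates(V)
    return am / (am + bm), an / (an + bn), ah / (ah + bh)


def neuron_derivatives(
    state: NeuronState,
    params: NeuronParams = NeuronParams(),
    I_ext: float = 0.0,
) -> tuple[float, float, float, float]:
    """Time derivatives (dV/dt, dm/dt, dn/dt, dh/dt).

    ``I_ext`` is the total non-intrinsic current (Poisson drive plus synaptic
    current) supplied by the caller; ``I_app`` comes from ``params``.
    """
    state.validate()
    p = params
    V, m, n, h = state.V, state.m, state.n, state.h
    I_channel = (
        p.g_Na * m**3 * h * (p.E_Na - V)
        + p.g_K * n * (p.E_K - V)
        + p.g_Leak * (p.E_Leak - V)
    )
    dV = (I_channel + p.I_app + I_ext) / p.C
    am, bm, an, bn, ah, bh = gating_rates(V)
    dm = am * (1.0 - m) - bm * m
    dn = an * (1.0 - n) - bn * n
    dh = ah * (1.0 - h) - bh * h
    return dV, dm, dn, dh


def resting_potential(params: NeuronParams = NeuronParams()) -> float:
    """Resting membrane potential: the root of dV/dt = 0 with gating variables
    at their voltage-clamped steady states.

    For the default parameters this is the stable focus of the rest mode; the
    simulator uses it (plus steady-state gates) as the initial condition.
    """
    from scipy.optimize import brentq

    def f(V: float) -> float:
        m, n, h = steady_state_gates(V)
        s = NeuronState(V=V, m=m, n=n, h=h)
        return neuron_derivatives(s, params, 0.0)[0]

    return float(brentq(f, -90.0, -40.0, xtol=1e-12))
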