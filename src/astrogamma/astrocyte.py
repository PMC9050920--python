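"""Astrocytic IP3 and Ca2+ dynamics with gap-junction diffusion on a ring.

Each astrocyte carries three state variables: cytosolic Ca2+ (uM), IP3 (uM)
and the fraction z of IP3 receptors not inactivated by Ca2+.  IP3 relaxes
toward a resting level IP3* and is produced by PLC-delta (Ca2+-dependent) and
by glutamate spillover from the paired pyramidal synapse; Ca2+ follows the
classic CICR balance of ER release, SERCA pump, ER leak and plasma-membrane
exchange.  Neighboring astrocytes on the ring are coupled by gap-junction
diffusion of both Ca2+ and IP3 (discrete Laplacian, indices wrap modulo N).

    dIP3_i/dt = (IP3* - IP3_i)/tau_IP3 + J_PLC + J_IP3diff + J_Glu
    dCa_i/dt  = J_ER - J_pump + J_leak + J_in - J_out + J_Cadiff
    dz_i/dt   = a2 ( d2 (IP3+d1)/(IP3+d3) (1 - z) - Ca z )

All rate constants are in s^-1 / uM s^-1; the simulator multiplies these
derivatives by 1e-3 when stepping on the millisecond grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AstrocyteParams",
    "AstrocyteState",
    "compute_fluxes",
    "j_plc",
    "j_glu",
    "ip3_derivative",
    "calcium_derivatives",
    "astrocyte_rest_state",
]


@dataclass(frozen=True)
class AstrocyteParams:
    """Flux constants of the astrocytic Ca2+/IP3 model.

    Defaults: c0 total free Ca2+ 2 uM, c1 ER/cytosol volume ratio 0.185,
    CICR channel rate v1 = 6 s^-1, leak v2 = 0.11 s^-1, pump v3 = 2.2 uM/s
    (half-saturation k3 = 0.1 uM), PLC production v4 = 0.3 uM/s, membrane
    influx v5 = 0.025 uM/s plus IP3-gated v6 = 0.2 uM/s (k2 = 1 uM),
    extrusion k1 = 0.5 s^-1, receptor kinetics a2 = 0.14, d1 = 0.13,
    d2 = 1.049, d3 = 0.9434, d5 = 0.082, PLC Ca2+-independence fraction
    alpha = 0.8 with k4 = 1.1, IP3 relaxation tau_IP3 = 7.143 s toward
    IP3* = 0.16 uM, gap-junction rates d_Ca = 0.001 and d_IP3 = 0.12 s^-1,
    glutamate-to-IP3 gain alpha_Glu = 2 uM/s.
    """

    c0: float = 2.0
    c1: float = 0.185
    v1: float = 6.0
    v2: float = 0.11
    v3: float = 2.2
    v4: float = 0.3
    v5: float = 0.025
    v6: float = 0.2
    k1: float = 0.5
    k2: float = 1.0
    k3: float = 0.1
    k4: float = 1.1
    a2: float = 0.14
    d1: float = 0.13
    d2: float = 1.049
    d3: float = 0.9434
    d5: float = 0.082
    alpha: float = 0.8
    tau_IP3: float = 7.143
    IP3_star: float = 0.16
    d_Ca: float = 0.001
    d_IP3: float = 0.12
    alpha_Glu: float = 2.0

    def __post_init__(self) -> None:
        if self.tau_IP3 <= 0:
            raise ValueError("tau_IP3 must be positive")
        for name in ("v1", "v2", "v3", "v4", "v5", "v6", "k1", "k2", "k3",
                     "k4", "a2", "d_Ca", "d_IP3"):
            if getattr(self, name) < 0:
                raise ValueError(f"rate constant {name} must be nonnegative")


@dataclass
class AstrocyteState:
    """Ca2+ (uM), IP3 (uM) and non-inactivated IP3R fraction z of one cell."""

    ca: float
    ip3: float
    z: float

    def validate(self) -> None:
        if self.ca < 0 or self.ip3 < 0:
            raise ValueError("Ca2+ and IP3 concentrations must be nonnegative")
        if not 0.0 <= self.z <= 1.0:
            raise ValueError("z must lie in [0, 1]")


def compute_fluxes(
    state: AstrocyteState, params: AstrocyteParams = AstrocyteParams()
) -> tuple[float, float, float, float, float]:
    """Single-cell Ca2+ fluxes (J_ER, J_pump, J_leak, J_in, J_out) in uM/s."""
    p = params
    ca, ip3, z = state.ca, state.ip3, state.z
    er_drive = p.c0 / p.c1 - (1.0 + 1.0 / p.c1) * ca
    J_ER = (
        p.c1
        * p.v1
        * (ip3 * ca * z / ((ip3 + p.d1) * (ca + p.d5))) ** 3
        * er_drive
    )
    J_pump = p.v3 * ca**2 / (p.k3**2 + ca**2)
    J_leak = p.c1 * p.v2 * er_drive
    J_in = p.v5 + p.v6 * ip3**2 / (p.k2**2 + ip3**2)
    J_out = p.k1 * ca
    return J_ER, J_pump, J_leak, J_in, J_out


def j_plc(ca: float, params: AstrocyteParams = AstrocyteParams()) -> float:
    """Ca2+-dependent PLC production of IP3 (uM/s)."""
    p = params
    return p.v4 * (ca + (1.0 - p.alpha) * p.k4) / (ca + p.k4)


def j_glu(G: float, params: AstrocyteParams = AstrocyteParams()) -> float:
    """Glutamate-induced IP3 production (uM/s): a sharp switch at G = 0.25."""
    x = (G - 0.25) / 0.01
    if x >= 0:
        return params.alpha_Glu / (1.0 + np.exp(-x))
    e = np.exp(x)
    return params.alpha_Glu * e / (1.0 + e)


def _laplacian(values: np.ndarray, index: int) -> float:
    n = values.shape[0]
    return float(
        values[(index - 1) % n] + values[(index + 1) % n] - 2.0 * values[index]
    )


def ip3_derivative(
    index: int,
    states: list[AstrocyteState],
    G: float,
    params: AstrocyteParams = AstrocyteParams(),
) -> float:
    """dIP3/dt (uM/s) of astrocyte ``index`` on the ring."""
    p = params
    s = states[index]
    ip3_all = np.array([st.ip3 for st in states])
    relax = (p.IP3_star - s.ip3) / p.tau_IP3
    diff = p.d_IP3 * _laplacian(ip3_all, index)
    return relax + j_plc(s.ca, p) + diff + j_glu(G, p)


def calcium_derivatives(
    index: int,
    states: list[AstrocyteState],
    params: AstrocyteParams = AstrocyteParams(),
) -> tuple[float, float]:
    """(dCa/dt, dz/dt) (uM/s, s^-1) of astrocyte ``index`` on the ring."""
    p = params
    s = states[index]
    ca_all = np.array([st.ca for st in states])
    J_ER, J_pump, J_leak, J_in, J_out = compute_fluxes(s, p)
    dca = J_ER - J_pump + J_leak + J_in - J_out + p.d_Ca * _laplacian(ca_all, index)
    dz = p.a2 * (
        p.d2 * (s.ip3 + p.d1) / (s.ip3 + p.d3) * (1.0 - s.z) - s.ca * s.z
    )
    return dca, dz


def astrocyte_rest_state(
    params: AstrocyteParams = AstrocyteParams(),
) -> AstrocyteState:
    """Steady state of an isolated astrocyte with no glutamate input (G = 0).

    Found by relaxing the single-cell ODEs for 500 s and polishing with a
    root-finder; for the default parameters the resting Ca2+ sits well below
    the 0.3 uM gliotransmission threshold.
    """
    from scipy.integrate import solve_ivp
    from scipy.optimize import fsolve

    p = params

    def rhs(_t, y):
        st = AstrocyteState(ca=max(y[0], 0.0), ip3=max(y[1], 0.0),
                            z=min(max(y[2], 0.0), 1.0))
        J_ER, J_pump, J_leak, J_in, J_out = compute_fluxes(st, p)
        dca = J_ER - J_pump + J_leak + J_in - J_out
        dip3 = (p.IP3_star - st.ip3) / p.tau_IP3 + j_plc(st.ca, p)
        dz = p.a2 * (
            p.d2 * (st.ip3 + p.d1) / (st.ip3 + p.d3) * (1.0 - st.z)
            - st.ca * st.z
        )
        return [dca, dip3, dz]

    sol = solve_ivp(rhs, (0.0, 500.0), [0.1, params.IP3_star, 0.7],
                    method="LSODA", rtol=1e-10, atol=1e-12)
    y = fsolve(lambda v: rhs(0.0, v), sol.y[:, -1], xtol=1e-13)
    return AstrocyteState(ca=float(y[0]), ip3=float(y[1]), z=float(y[2]))
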