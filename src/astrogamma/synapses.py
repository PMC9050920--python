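"""Chemical synapses with sigmoidal presynaptic gating and astrocytic
weight modulation.

The current a postsynaptic cell ``i`` receives from its presynaptic partners is

    I_syn_i = sum_j  g~_syn  (E_syn - V_i) / (1 + exp(-V_j / k_syn))

with a very steep presynaptic gate (k_syn = 0.2 mV), so transmission is
effectively on only while the presynaptic cell is spiking.  The reversal
potential is -90 mV for inhibitory (GABAergic) synapses and 0 mV for
excitatory ones.

The astrocyte paired with the postsynaptic interneuron modulates the weight
of its incoming connections through Ca2+-triggered gliotransmitter release:

    g~_syn = g_syn (1 + g_astro [Ca2+]_i)   if [Ca2+]_i >= 0.3 uM
           = g_syn                          otherwise

g_astro > 0 is facilitation, g_astro < 0 depression; the modulation targets
either the inhibitory interneuron-interneuron synapses or the excitatory
pyramidal-to-interneuron synapse, never both.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

__all__ = [
    "SynapseKind",
    "ModulationTarget",
    "SynapseEdge",
    "ModulationConfig",
    "presynaptic_gate",
    "modulated_weight",
    "total_synaptic_current",
]

E_SYN_INHIBITORY = -90.0  # mV
E_SYN_EXCITATORY = 0.0  # mV
K_SYN_DEFAULT = 0.2  # mV
CA_THRESHOLD_DEFAULT = 0.3  # uM


class SynapseKind(str, Enum):
    INHIBITORY = "inhibitory"
    EXCITATORY = "excitatory"


class ModulationTarget(str, Enum):
    """Which incoming synapses of an interneuron the paired astrocyte acts on."""

    NONE = "none"
    INHIBITORY = "inhibitory-incoming"
    EXCITATORY = "excitatory-incoming"


@dataclass(frozen=True)
class SynapseEdge:
    """One directed chemical synapse pre -> post."""

    pre: int
    post: int
    g_syn: float
    kind: SynapseKind = SynapseKind.INHIBITORY
    E_syn: float | None = None

    def __post_init__(self) -> None:
        if self.g_syn < 0:
            raise ValueError("synaptic weight g_syn must be nonnegative")
        if self.E_syn is None:
            default = (
                E_SYN_INHIBITORY
                if self.kind == SynapseKind.INHIBITORY
                else E_SYN_EXCITATORY
            )
            object.__setattr__(self, "E_syn", default)


@dataclass(frozen=True)
class ModulationConfig:
    """Astrocytic modulation rule applied to synaptic weights.

    ``corrected_sign=True`` (default) uses the driving force (E_syn - V_post),
    consistent with the (E - V) channel convention, so inhibition
    hyperpolarizes; the alternative evaluates (V_post - E_syn) as sometimes
    printed for this model.
    """

    target: ModulationTarget = ModulationTarget.NONE
    g_astro: float = 0.0
    ca_threshold: float = CA_THRESHOLD_DEFAULT
    k_syn: float = K_SYN_DEFAULT
    clamp_nonnegative: bool = True
    corrected_sign: bool = True

    def __post_init__(self) -> None:
        if self.ca_threshold <= 0:
            raise ValueError("ca_threshold must be positive")
        if self.k_syn <= 0:
            raise ValueError("k_syn must be positive")


def presynaptic_gate(V_pre: float, k_syn: float = K_SYN_DEFAULT) -> float:
    """Sigmoid 1 / (1 + exp(-V_pre/k_syn)), overflow-safe for any |V_pre|."""
    x = V_pre / k_syn
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    # exp(x) underflows harmlessly to 0 for very negative x
    e = math.exp(x)
    return e / (1.0 + e)


def modulated_weight(
    g_syn: float,
    ca: float,
    config: ModulationConfig,
    edge_targeted: bool = True,
) -> float:
    """Effective weight g~_syn of one synapse given the paired astrocyte's Ca2+.

    Below the Ca2+ threshold (or for edges the modulation does not target) the
    baseline weight is returned unchanged.  Above it the weight is scaled by
    (1 + g_astro * ca); a negative scaled weight (possible under strong
    depression) is clamped at zero when ``clamp_nonnegative`` is set, since a
    negative conductance is unphysical.
    """
    if g_syn < 0:
        raise ValueError("g_syn must be nonnegative")
    if not edge_targeted or ca < config.ca_threshold:
        return g_syn
    w = g_syn * (1.0 + config.g_astro * ca)
    if config.clamp_nonnegative and w < 0.0:
        return 0.0
    return w


def total_synaptic_current(
    post_index: int,
    V: Sequence[float] | np.ndarray,
    edges: Sequence[SynapseEdge],
    ca: float = 0.0,
    config: ModulationConfig = ModulationConfig(),
) -> float:
    """Total synaptic current (uA/cm^2) onto neuron ``post_index``.

    ``ca`` is the Ca2+ concentration of the astrocyte paired with the
    postsynaptic interneuron; only edges whose kind matches ``config.target``
    are modulated.
    """
    V = np.asarray(V, dtype=float)
    total = 0.0
    for e in edges:
        if e.post != post_index:
            continue
        if e.pre < 0 or e.pre >= V.size or e.post >= V.size:
            raise IndexError("edge endpoint outside the network")
        targeted = (
            config.target == ModulationTarget.INHIBITORY
            and e.kind == SynapseKind.INHIBITORY
        ) or (
            config.target == ModulationTarget.EXCITATORY
            and e.kind == SynapseKind.EXCITATORY
        )
        w = modulated_weight(e.g_syn, ca, config, edge_targeted=targeted)
        gate = presynaptic_gate(float(V[e.pre]), config.k_syn)
        drive = (e.E_syn - V[post_index]) if config.corrected_sign else (
            V[post_index] - e.E_syn
        )
        total += w * drive * gate
    return float(total)
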