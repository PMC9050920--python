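"""Three-layer network construction.

The modeled circuit has 200 fast-spiking interneurons on a virtual ring, each
randomly connected by inhibitory synapses to its 100 nearest neighbors (50 per
side) with probability 0.5; 200 pyramidal cells, each projecting one
excitatory synapse onto its like-indexed interneuron; and 200 astrocytes on a
ring with nearest-neighbor gap junctions, astrocyte i paired with interneuron
i (and sensing the glutamate of pyramidal cell i).  Pyramidal cells receive
no synapses — they are a drive-only layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synapses import SynapseEdge, SynapseKind
from .drive import substream

__all__ = [
    "TopologyConfig",
    "NetworkTopology",
    "ring_distance",
    "build_interneuron_ring",
    "build_full_network",
    "edges_to_frame",
]

_STREAM_TOPOLOGY = 3  # spawn_key tag for the connectivity RNG


@dataclass(frozen=True)
class TopologyConfig:
    n_cells: int = 200
    neighborhood: int = 100  # nearest neighbors considered, 50 per side
    p_connect: float = 0.5
    g_syn: float = 0.01  # interneuron-interneuron weight, mS/cm^2
    g_syn_P: float = 0.7  # pyramidal-to-interneuron weight, mS/cm^2
    symmetric: bool = False  # sample undirected pairs instead of ordered ones
    seed: int = 0

    def __post_init__(self) -> None:
        if self.neighborhood % 2 != 0:
            raise ValueError("neighborhood must be even (50 per side by default)")
        if self.neighborhood >= self.n_cells:
            raise ValueError("neighborhood must be smaller than the ring")
        if not 0.0 <= self.p_connect <= 1.0:
            raise ValueError("p_connect must be a probability")


@dataclass
class NetworkTopology:
    """Edge sets and pairings of the interneuron/pyramidal/astrocyte circuit."""

    n_cells: int
    inhib_edges: list[SynapseEdge]
    excit_edges: list[SynapseEdge]
    config: TopologyConfig

    @property
    def astro_pairing(self) -> np.ndarray:
        """astro_pairing[i] = index of the interneuron paired with astrocyte i."""
        return np.arange(self.n_cells)

    def astro_neighbors(self, i: int) -> tuple[int, int]:
        """Gap-junction partners of astrocyte i on the ring."""
        n = self.n_cells
        return ((i - 1) % n, (i + 1) % n)

    def inhib_csr(self, direction: str = "in") -> tuple[np.ndarray, np.ndarray]:
        """Inhibitory adjacency in CSR form.

        ``direction="in"``: indices[indptr[i]:indptr[i+1]] lists the
        presynaptic partners of postsynaptic cell i; ``"out"``: the
        postsynaptic targets of presynaptic cell i.
        """
        if direction not in ("in", "out"):
            raise ValueError("direction must be 'in' or 'out'")
        buckets: list[list[int]] = [[] for _ in range(self.n_cells)]
        for e in self.inhib_edges:
            if direction == "in":
                buckets[e.post].append(e.pre)
            else:
                buckets[e.pre].append(e.post)
        indptr = np.zeros(self.n_cells + 1, dtype=np.int64)
        for i, b in enumerate(buckets):
            indptr[i + 1] = indptr[i] + len(b)
        if indptr[-1] == 0:
            return indptr, np.array([], dtype=np.int64)
        indices = np.concatenate(
            [np.sort(np.array(b, dtype=np.int64)) for b in buckets if b]
        )
        return indptr, indices


def ring_distance(i: int, j: int, n: int) -> int:
    """Shortest distance on a ring of n cells: min(|i-j|, n-|i-j|)."""
    d = abs(i - j) % n
    return min(d, n - d)


def build_interneuron_ring(
    n: int,
    neighborhood: int,
    p: float,
    g_syn: float,
    rng: np.random.Generator,
    symmetric: bool = False,
) -> list[SynapseEdge]:
    """Random inhibitory connectivity of the interneuron ring.

    Each ordered pair (j -> i) with ring distance <= neighborhood/2 receives a
    directed inhibitory edge independently with probability ``p`` (expected
    in-degree = neighborhood * p).  With ``symmetric=True`` one draw per
    unordered pair creates edges in both directions.
    """
    if neighborhood >= n:
        raise ValueError("neighborhood must be smaller than the ring")
    half = neighborhood // 2
    edges: list[SynapseEdge] = []
    if symmetric:
        for i in range(n):
            for d in range(1, half + 1):
                j = (i + d) % n
                if rng.random() < p:
                    edges.append(SynapseEdge(pre=j, post=i, g_syn=g_syn,
                                             kind=SynapseKind.INHIBITORY))
                    edges.append(SynapseEdge(pre=i, post=j, g_syn=g_syn,
                                             kind=SynapseKind.INHIBITORY))
    else:
        for i in range(n):  # postsynaptic cell draws its inputs
            for d in range(-half, half + 1):
                if d == 0:
                    continue
                j = (i + d) % n
                if rng.random() < p:
                    edges.append(SynapseEdge(pre=j, post=i, g_syn=g_syn,
                                             kind=SynapseKind.INHIBITORY))
    return edges


def build_full_network(config: TopologyConfig = TopologyConfig()) -> NetworkTopology:
    """Build the full three-layer topology, reproducibly from ``config.seed``."""
    rng = substream(config.seed, _STREAM_TOPOLOGY)
    inhib = build_interneuron_ring(
        config.n_cells,
        config.neighborhood,
        config.p_connect,
        config.g_syn,
        rng,
        symmetric=config.symmetric,
    )
    excit = [
        SynapseEdge(pre=i, post=i, g_syn=config.g_syn_P,
                    kind=SynapseKind.EXCITATORY)
        for i in range(config.n_cells)
    ]
    return NetworkTopology(
        n_cells=config.n_cells,
        inhib_edges=inhib,
        excit_edges=excit,
        config=config,
    )


def edges_to_frame(topology: NetworkTopology):
    """Edge list (pre, post, kind, weight) as a DataFrame for CSV export."""
    import pandas as pd

    rows = [
        {"pre": e.pre, "post": e.post, "kind": e.kind.value, "weight": e.g_syn}
        for e in topology.inhib_edges + topology.excit_edges
    ]
    return pd.DataFrame(rows, columns=["pre", "post", "kind", "weight"])
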