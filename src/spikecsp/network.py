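"""Network description: neurons, directed synapses, and group bookkeeping.

A :class:`NetworkSpec` is a plain container describing a network of
stochastically firing spiking neurons.  Neurons carry a bias (the intrinsic
log-excitability), a rectangular-PSP duration ``tau`` and a refractory
period.  Synapses are *directed* and weighted; each synapse may carry its
own transmission delay and PSP duration (defaulting to the presynaptic
neuron's ``tau``).  A subset of neurons is marked *principal*: those are
the interface to the computational problem, and the symmetric sub-network
they form defines the Boltzmann energy of the network.  Auxiliary neurons
(winner-take-all inhibitors, OR-gadget neurons, temperature-control
circuitry) may be wired asymmetrically.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = ["NeuronParams", "Synapse", "NetworkSpec", "DEFAULT_TAU"]

#: Default PSP duration / refractory period in seconds (10 ms).
DEFAULT_TAU = 0.010


@dataclass
class NeuronParams:
    """Parameters of a single stochastic neuron.

    Parameters
    ----------
    bias
        Intrinsic excitability ``b_k`` (dimensionless, log-intensity units).
    psp_duration
        Length ``tau`` of the rectangular PSP the neuron's spikes produce,
        in seconds.  Also the width of the window used to define the
        neuron's binary state.
    refractory_period
        Time after a spike during which the neuron cannot fire, in
        seconds.  Defaults to ``psp_duration``.
    """

    bias: float = 0.0
    psp_duration: float = DEFAULT_TAU
    refractory_period: float | None = None

    def __post_init__(self) -> None:
        if self.refractory_period is None:
            self.refractory_period = self.psp_duration
        if not self.psp_duration > 0:
            raise ValueError("psp_duration must be positive")
        if not self.refractory_period > 0:
            raise ValueError("refractory_period must be positive")
        if not math.isfinite(self.bias):
            raise ValueError("bias must be finite")


@dataclass
class Synapse:
    """Directed synapse ``pre -> post`` with weight ``w_kl``.

    ``delay`` is the transmission delay in seconds; the PSP at the target
    is active on the interval ``(s + delay, s + delay + psp_duration]``
    for a presynaptic spike at time ``s``.  ``psp_duration`` defaults to
    the presynaptic neuron's value (resolved by :class:`NetworkSpec`).
    """

    pre: int
    post: int
    weight: float
    delay: float = 0.0
    psp_duration: float | None = None

    def __post_init__(self) -> None:
        if self.pre == self.post:
            raise ValueError("self-connections are not allowed")
        if self.delay < 0:
            raise ValueError("delay must be >= 0")
        if not math.isfinite(self.weight):
            raise ValueError("weight must be finite")


@dataclass
class NetworkSpec:
    """A network of stochastic spiking neurons.

    Attributes
    ----------
    neurons
        List of :class:`NeuronParams`; the neuron id is the list index.
    synapses
        List of directed :class:`Synapse` objects.  Absent synapses have
        weight 0.
    principal_ids
        Ids of principal neurons (the problem-variable interface).
    wta_groups
        Mapping from group label to the list of principal ids forming one
        winner-take-all group (one multinomial problem variable).
    metadata
        Free-form annotations (readout maps, compiler provenance).
    """

    neurons: list[NeuronParams] = field(default_factory=list)
    synapses: list[Synapse] = field(default_factory=list)
    principal_ids: list[int] = field(default_factory=list)
    wta_groups: dict[str, list[int]] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    # -- construction helpers -------------------------------------------------

    def add_neuron(self, params: NeuronParams, principal: bool = False) -> int:
        self.neurons.append(params)
        nid = len(self.neurons) - 1
        if principal:
            self.principal_ids.append(nid)
        return nid

    def add_synapse(
        self,
        pre: int,
        post: int,
        weight: float,
        delay: float = 0.0,
        psp_duration: float | None = None,
    ) -> Synapse:
        n = len(self.neurons)
        if not (0 <= pre < n) or not (0 <= post < n):
            raise KeyError(f"synapse endpoints ({pre}, {post}) out of range")
        syn = Synapse(pre, post, weight, delay, psp_duration)
        self.synapses.append(syn)
        return syn

    def add_symmetric(self, a: int, b: int, weight: float, delay: float = 0.0) -> None:
        """Add a symmetric (bidirectional, equal-weight) connection."""
        self.add_synapse(a, b, weight, delay)
        self.add_synapse(b, a, weight, delay)

    def register_wta_group(self, label: str, members: list[int]) -> None:
        for g, ms in self.wta_groups.items():
            overlap = set(ms) & set(members)
            if overlap:
                raise ValueError(
                    f"neurons {sorted(overlap)} already belong to WTA group {g!r}"
                )
        self.wta_groups[label] = list(members)

    # -- queries --------------------------------------------------------------

    @property
    def n_neurons(self) -> int:
        return len(self.neurons)

    @property
    def n_synapses(self) -> int:
        return len(self.synapses)

    def synapse_psp_duration(self, syn: Synapse) -> float:
        """PSP duration of a synapse, resolving the presynaptic default."""
        if syn.psp_duration is not None:
            return syn.psp_duration
        return self.neurons[syn.pre].psp_duration

    def weight(self, pre: int, post: int) -> float:
        """Total weight pre->post (0 if no synapse; sums duplicates)."""
        return sum(s.weight for s in self.synapses if s.pre == pre and s.post == post)

    def weight_matrix(self, ids: list[int] | None = None) -> np.ndarray:
        """Dense weight matrix W[post_index, pre_index] over ``ids``.

        ``W[k, l]`` is the weight of the synapse l -> k, so that the
        membrane potential of neuron k is ``b_k + (W @ x)[k]``.
        """
        if ids is None:
            ids = list(range(self.n_neurons))
        index = {nid: i for i, nid in enumerate(ids)}
        W = np.zeros((len(ids), len(ids)))
        for s in self.synapses:
            if s.pre in index and s.post in index:
                W[index[s.post], index[s.pre]] += s.weight
        return W

    def biases(self, ids: list[int] | None = None) -> np.ndarray:
        if ids is None:
            ids = list(range(self.n_neurons))
        return np.array([self.neurons[i].bias for i in ids], dtype=float)

    def validate(self) -> None:
        n = self.n_neurons
        for s in self.synapses:
            if not (0 <= s.pre < n) or not (0 <= s.post < n):
                raise ValueError(f"synapse ({s.pre}->{s.post}) references missing neuron")
        for i in self.principal_ids:
            if not 0 <= i < n:
                raise ValueError(f"principal id {i} out of range")
        seen: set[int] = set()
        for label, members in self.wta_groups.items():
            for m in members:
                if m in seen:
                    raise ValueError(f"neuron {m} in more than one WTA group")
                seen.add(m)

    # -- serialization --------------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "neurons": [asdict(p) for p in self.neurons],
            "synapses": [asdict(s) for s in self.synapses],
            "principal_ids": list(self.principal_ids),
            "wta_groups": {k: list(v) for k, v in self.wta_groups.items()},
            "metadata": self.metadata,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "NetworkSpec":
        payload = json.loads(text)
        net = cls(
            neurons=[NeuronParams(**p) for p in payload["neurons"]],
            synapses=[Synapse(**s) for s in payload["synapses"]],
            principal_ids=list(payload.get("principal_ids", [])),
            wta_groups={k: list(v) for k, v in payload.get("wta_groups", {}).items()},
            metadata=payload.get("metadata", {}),
        )
        net.validate()
        return net

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "NetworkSpec":
        with open(path) as fh:
            return cls.from_json(fh.read())

    def content_hash(self) -> str:
        import hashlib

        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]

    def set_uniform_delay(self, delay: float) -> "NetworkSpec":
        """Set the same transmission delay on every synapse (in place)."""
        if delay < 0:
            raise ValueError("delay must be >= 0")
        for s in self.synapses:
            s.delay = delay
        return self
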