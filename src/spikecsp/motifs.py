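"""Stereotypical circuit motifs: winner-take-all, OR, and temperature control.

Each motif splices a small set of auxiliary neurons (with possibly
asymmetric connections) into an existing :class:`~spikecsp.network.NetworkSpec`
and thereby adds an approximately linear, state-dependent contribution to
the energy function over the principal neurons:

* **WTA** — one inhibitory auxiliary neuron reciprocally connected to a
  group of principal neurons lowers the energy of states in which exactly
  one group member is active; a group encodes one multinomial problem
  variable.
* **OR** — two auxiliary neurons (I excites the targets, II curtails that
  excitation once one of them fires) raise the energy of states in which
  none of the target neurons is active; one OR gadget encodes one
  disjunctive clause.
* **Temperature control** — duplicated OR gadgets with stronger weights
  (III/IV), one status neuron per clause that fires only when its clause is
  fully violated, and a single global neuron that is tonically active
  unless silenced by a status neuron.  When every clause is satisfied the
  global neuron enables the strong duplicates and sharpens the principal
  biases, which rescales the energy landscape to a low temperature and
  locks the network into the solution it has found.
"""

from __future__ import annotations

from dataclasses import dataclass

from .network import DEFAULT_TAU, NetworkSpec, NeuronParams

__all__ = [
    "WTAParams",
    "ORParams",
    "TempControlParams",
    "add_wta",
    "add_or",
    "add_temperature_control",
]


@dataclass
class WTAParams:
    """Winner-take-all parameters.

    The inhibitory auxiliary neuron has a very low bias ``b_inh`` so that
    inhibition triggers only when a principal neuron spikes; ``w_exc``
    (principal -> auxiliary) must be strong enough to activate it almost
    immediately, ``w_WTA`` (auxiliary -> principal) strong enough to
    silence the other principals.
    """

    b_WTA: float = 2.0
    b_inh: float = -10.0
    w_WTA: float = -100.0
    w_exc: float = 100.0

    def __post_init__(self) -> None:
        if not (self.w_WTA < 0 < self.w_exc):
            raise ValueError("require w_WTA < 0 < w_exc")


@dataclass
class ORParams:
    """OR-gadget parameters: scale constant B and the excitation ``w_OR``
    the gadget applies to its target neurons (the gadget's strength sets
    the energy penalty on all-targets-inactive states)."""

    B: float = 40.0
    w_OR: float = 2.5

    def __post_init__(self) -> None:
        if not self.B > 0:
            raise ValueError("B must be positive")


@dataclass
class TempControlParams:
    """Temperature-control parameters.

    ``w_OR2`` is the strength of the duplicated (low-temperature) OR
    gadgets; the gap to the base ``w_OR`` sets the temperature contrast.
    The global neuron has a shortened refractory period (9 ms) and
    lengthened outgoing PSPs (11 ms) to its gadget targets so its drive is
    gapless while it keeps respiking.  ``w_status`` silences the global
    neuron whenever one clause is fully violated.
    """

    B: float = 40.0
    w_OR2: float = 10.0
    b_glob: float = 10.0
    w_glob: float = 0.5
    w_status: float | None = None  # default -3B
    global_refractory: float = 0.009
    global_psp: float = 0.011

    def __post_init__(self) -> None:
        if self.w_status is None:
            self.w_status = -3.0 * self.B
        if not self.global_psp > self.global_refractory:
            raise ValueError("global PSP duration must exceed its refractory period")


def add_wta(
    net: NetworkSpec,
    principal_ids: list[int],
    params: WTAParams | None = None,
    label: str | None = None,
    set_biases: bool = True,
) -> int:
    """Form a WTA circuit over ``principal_ids``; returns the auxiliary id.

    Adds one inhibitory auxiliary neuron (bias ``b_inh``) with synapses
    principal -> aux of weight ``w_exc`` and aux -> principal of weight
    ``w_WTA`` for every listed principal (2K synapses for K principals).
    Principal biases are set to ``b_WTA`` unless ``set_biases`` is False.
    The group is registered in ``net.wta_groups`` (a neuron may belong to
    at most one group).
    """
    params = params or WTAParams()
    pset = set(net.principal_ids)
    for k in principal_ids:
        if k not in pset:
            raise ValueError(f"neuron {k} is not a principal neuron")
    label = label if label is not None else f"wta{len(net.wta_groups)}"
    net.register_wta_group(label, list(principal_ids))
    aux = net.add_neuron(NeuronParams(bias=params.b_inh))
    for k in principal_ids:
        if set_biases:
            net.neurons[k].bias = params.b_WTA
        net.add_synapse(k, aux, params.w_exc)
        net.add_synapse(aux, k, params.w_WTA)
    return aux


def add_or(
    net: NetworkSpec,
    target_ids: list[int],
    params: ORParams | None = None,
) -> tuple[int, int]:
    """Attach an OR gadget to ``target_ids`` (>= 2 principal neurons).

    Adds auxiliary neuron I (bias 0.5B) and II (bias -3.5B).  For each
    target: I -> target with weight ``w_OR``, target -> I with ``-B``,
    II -> target with ``-w_OR``, target -> II with ``B``; plus one I -> II
    synapse of weight 3B.  With k targets this is 4k + 1 synapses.  I fires
    as soon as all targets are inactive (raising the energy of those
    states); a target spike suppresses I and, via II, retracts the
    excitation so the gadget does not bias which target stays on.
    Returns the ids (I, II).
    """
    params = params or ORParams()
    if len(target_ids) < 2:
        raise ValueError("an OR gadget needs at least 2 targets")
    B, w_OR = params.B, params.w_OR
    aux1 = net.add_neuron(NeuronParams(bias=0.5 * B))
    aux2 = net.add_neuron(NeuronParams(bias=-3.5 * B))
    for k in target_ids:
        net.add_synapse(aux1, k, w_OR)
        net.add_synapse(k, aux1, -B)
        net.add_synapse(aux2, k, -w_OR)
        net.add_synapse(k, aux2, B)
    net.add_synapse(aux1, aux2, 3.0 * B)
    return aux1, aux2


def add_temperature_control(
    net: NetworkSpec,
    clause_target_sets: list[list[int]],
    params: TempControlParams | None = None,
    violation_sets: list[list[int]] | None = None,
) -> dict:
    """Add an internal temperature controller for the given clauses.

    ``clause_target_sets`` are the same principal tuples the OR gadgets
    were attached to (the neurons whose activity makes each clause true).
    ``violation_sets`` are, per clause, the principal neurons encoding the
    *negations* of the clause's literals (all active == clause fully
    violated); they feed the status neurons.  If omitted they are read
    from the clause's WTA groups: for each target, the other member of its
    group.

    Per clause this adds auxiliary neurons III (bias -0.5B) and IV (bias
    -6.5B), wired like I/II but with weights ``w_OR2``/-B and -``w_OR2``/B
    plus III -> IV of 3B, and one status neuron (bias -2.5B) receiving B
    from each violation neuron and sending ``w_status`` to the global
    neuron.  One global neuron (bias ``b_glob``, refractory 9 ms) drives
    every III with B and every IV with 3B through 11 ms PSPs — making
    III/IV behave exactly like I/II while it is active — and every
    principal neuron with ``w_glob``.  Total neurons added: 3M + 1.
    """
    params = params or TempControlParams()
    B = params.B
    if violation_sets is None:
        group_of: dict[int, list[int]] = {}
        for members in net.wta_groups.values():
            for m in members:
                group_of[m] = members
        violation_sets = []
        for targets in clause_target_sets:
            vs = []
            for k in targets:
                if k not in group_of:
                    raise ValueError(f"clause target {k} not in any WTA group")
                others = [m for m in group_of[k] if m != k]
                if len(others) != 1:
                    raise ValueError(
                        "violation neurons can only be inferred for binary WTA groups"
                    )
                vs.append(others[0])
            violation_sets.append(vs)
    if len(violation_sets) != len(clause_target_sets):
        raise ValueError("one violation set per clause required")

    glob = net.add_neuron(
        NeuronParams(
            bias=params.b_glob,
            psp_duration=DEFAULT_TAU,
            refractory_period=params.global_refractory,
        )
    )
    info = {"global": glob, "clauses": []}
    for targets, violators in zip(clause_target_sets, violation_sets):
        aux3 = net.add_neuron(NeuronParams(bias=-0.5 * B))
        aux4 = net.add_neuron(NeuronParams(bias=-6.5 * B))
        for k in targets:
            net.add_synapse(aux3, k, params.w_OR2)
            net.add_synapse(k, aux3, -B)
            net.add_synapse(aux4, k, -params.w_OR2)
            net.add_synapse(k, aux4, B)
        net.add_synapse(aux3, aux4, 3.0 * B)
        net.add_synapse(glob, aux3, B, psp_duration=params.global_psp)
        net.add_synapse(glob, aux4, 3.0 * B, psp_duration=params.global_psp)
        status = net.add_neuron(NeuronParams(bias=-2.5 * B))
        for v in violators:
            net.add_synapse(v, status, B)
        net.add_synapse(status, glob, params.w_status)
        info["clauses"].append({"aux3": aux3, "aux4": aux4, "status": status})
    for k in net.principal_ids:
        net.add_synapse(glob, k, params.w_glob)
    net.metadata.setdefault("temperature_control", info)
    return info
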