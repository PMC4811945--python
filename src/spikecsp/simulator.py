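"""Exact event-driven simulation of stochastic spiking networks.

Each neuron fires as an inhomogeneous Poisson process with instantaneous
rate ``exp(u_k(t)) / tau_k``, where the membrane potential ``u_k`` is the
neuron's bias plus the weighted sum of currently active rectangular PSPs.
Between events every membrane potential is constant, so the waiting time
to the next candidate spike of a non-refractory neuron is exactly
exponential: ``tau_k * exp(-u_k) * E`` with ``E ~ Exp(1)``.  By
memorylessness a candidate only needs to be redrawn when the neuron's
membrane potential changes (a presynaptic PSP starts or ends) or when its
refractory period expires.  Deterministic events (PSP onsets after a
transmission delay, PSP offsets, refractory expirations) live in a heap;
stochastic candidates live in a per-neuron array.  The earliest pending
event is committed and the affected candidates are redrawn, which makes
the simulation exact — no time discretization is involved.

Simultaneous events are committed in the order (time, PSP-offset before
PSP-onset before refractory-expiry before spike, insertion order), so a
run is a deterministic function of ``(net, t_end, seed, initial)``.
"""

from __future__ import annotations

import bisect
import heapq
import json
from dataclasses import dataclass, field

import numpy as np

from .network import NetworkSpec

__all__ = [
    "firing_rate",
    "membrane_potential",
    "simulate",
    "state_at",
    "state_change_times",
    "Trajectory",
    "StateChange",
]

# heap-event kind priorities: offsets strictly before onsets at equal times
_K_PSP_OFF = 0
_K_PSP_ON = 1
_K_REFRAC = 2


def firing_rate(u: float, tau: float) -> float:
    """Instantaneous firing rate ``exp(u)/tau`` in events per second.

    Underflows gracefully to 0 for very negative ``u``.
    """
    if not tau > 0:
        raise ValueError("tau must be positive")
    with np.errstate(over="ignore", under="ignore"):
        return float(np.exp(u) / tau)


@dataclass(frozen=True)
class StateChange:
    """A single on/off transition of one neuron's binary state."""

    time: float
    neuron: int
    on: bool


@dataclass
class Trajectory:
    """Time-ordered spike events of one simulation run.

    ``times`` and ``neurons`` are parallel arrays (times non-decreasing).
    The binary network state at any time t is derived from the spikes:
    ``x_k(t) = 1`` iff neuron k spiked in ``(t - tau_k, t]`` where
    ``tau_k`` is the neuron's own PSP duration.
    """

    times: np.ndarray
    neurons: np.ndarray
    t_end: float
    network: NetworkSpec
    seed: int | None = None
    _per_neuron: dict[int, np.ndarray] = field(default_factory=dict, repr=False)

    @property
    def n_events(self) -> int:
        return len(self.times)

    def spikes_of(self, neuron: int) -> np.ndarray:
        """Sorted spike times of one neuron."""
        if neuron not in self._per_neuron:
            self._per_neuron[neuron] = self.times[self.neurons == neuron]
        return self._per_neuron[neuron]

    def last_spike_before(self, neuron: int, t: float) -> float | None:
        """Most recent spike time of ``neuron`` at or before ``t``."""
        s = self.spikes_of(neuron)
        i = np.searchsorted(s, t, side="right")
        return float(s[i - 1]) if i > 0 else None

    # -- export ---------------------------------------------------------------

    def to_jsonl(self, path) -> None:
        """Write a JSON header line followed by one event per line."""
        header = {
            "seed": self.seed,
            "t_end": self.t_end,
            "network_hash": self.network.content_hash(),
            "n_events": int(self.n_events),
        }
        with open(path, "w") as fh:
            fh.write(json.dumps(header) + "\n")
            for t, k in zip(self.times, self.neurons):
                fh.write(json.dumps({"t": float(t), "neuron": int(k)}) + "\n")

    @classmethod
    def from_jsonl(cls, path, network: NetworkSpec) -> "Trajectory":
        with open(path) as fh:
            header = json.loads(fh.readline())
            times, neurons = [], []
            for line in fh:
                ev = json.loads(line)
                times.append(ev["t"])
                neurons.append(ev["neuron"])
        return cls(
            times=np.asarray(times, dtype=float),
            neurons=np.asarray(neurons, dtype=np.int64),
            t_end=header["t_end"],
            network=network,
            seed=header.get("seed"),
        )


def membrane_potential(k: int, t: float, traj: Trajectory) -> float:
    """Membrane potential of neuron ``k`` at time ``t``, from the trajectory.

    ``u_k(t) = b_k + sum over synapses (l -> k) of w_kl * [a spike of l at
    time s satisfies s + delay < t <= s + delay + psp_duration]``.
    """
    net = traj.network
    if not 0 <= k < net.n_neurons:
        raise KeyError(f"unknown neuron id {k}")
    if t > traj.t_end:
        raise ValueError("t beyond end of trajectory")
    u = net.neurons[k].bias
    for syn in net.synapses:
        if syn.post != k:
            continue
        psp = net.synapse_psp_duration(syn)
        s = traj.spikes_of(syn.pre)
        # active iff some spike in [t - delay - psp, t - delay)
        lo = bisect.bisect_left(s, t - syn.delay - psp)
        hi = bisect.bisect_left(s, t - syn.delay)
        if hi > lo:
            u += syn.weight
    return float(u)


def state_at(traj: Trajectory, t: float, neurons=None) -> np.ndarray:
    """Binary network state x(t): ``x_k = 1`` iff k spiked in ``(t - tau_k, t]``."""
    if not 0 <= t <= traj.t_end:
        raise ValueError(f"t={t} outside [0, {traj.t_end}]")
    net = traj.network
    ids = list(range(net.n_neurons)) if neurons is None else list(neurons)
    x = np.zeros(len(ids), dtype=np.int8)
    for i, k in enumerate(ids):
        s = traj.last_spike_before(k, t)
        if s is not None and s > t - net.neurons[k].psp_duration:
            x[i] = 1
    return x


def state_change_times(traj: Trajectory, neurons=None) -> list[StateChange]:
    """All on/off transitions of the network state, time-ordered.

    Every spike contributes one on-entry at the spike time and one
    off-entry one PSP duration later (the neuron's own ``tau``).  Off
    entries later than ``t_end`` are outside the trajectory and dropped.
    Ties are broken (time, off-before-on, neuron id).
    """
    net = traj.network
    keep = None if neurons is None else set(neurons)
    entries = []
    for t, k in zip(traj.times, traj.neurons):
        k = int(k)
        if keep is not None and k not in keep:
            continue
        entries.append((float(t), 1, k))
        t_off = float(t) + net.neurons[k].psp_duration
        if t_off <= traj.t_end:
            entries.append((t_off, 0, k))
    entries.sort(key=lambda e: (e[0], e[1], e[2]))
    return [StateChange(t, k, bool(on)) for t, on, k in entries]


def _out_groups(net: NetworkSpec):
    """Group each neuron's outgoing synapses by (delay, psp_duration).

    Returns ``groups[l] = [[delay, psp, targets, weights, box_count], ...]``.
    One heap event per group per spike instead of one per synapse.  The
    ``box_count`` tracks overlapping PSP windows of the same group: a PSP
    is the *indicator* that the presynaptic neuron fired within the
    window, so overlapping windows (possible when the refractory period is
    shorter than the PSP duration) contribute the weight once, not twice.
    """
    raw: list[dict] = [dict() for _ in range(net.n_neurons)]
    for s in net.synapses:
        key = (s.delay, net.synapse_psp_duration(s))
        raw[s.pre].setdefault(key, []).append((s.post, s.weight))
    groups = []
    for l in range(net.n_neurons):
        gl = []
        for (delay, psp), pairs in raw[l].items():
            targets = np.array([p for p, _ in pairs], dtype=np.int64)
            weights = np.array([w for _, w in pairs], dtype=float)
            gl.append([delay, psp, targets, weights, 0])
        groups.append(gl)
    return groups


def simulate(
    net: NetworkSpec,
    t_end: float,
    seed: int,
    initial=None,
    max_events: int | None = None,
) -> Trajectory:
    """Run an exact event-driven simulation up to time ``t_end``.

    Parameters
    ----------
    net
        The network to simulate.
    t_end
        Simulated duration in seconds.
    seed
        Seed for the single RNG stream of the run.
    initial
        Optional iterable of neuron ids that start in the active state.
        They are realized as spikes at t = 0 (recorded in the trajectory),
        with their PSPs and refractory periods starting there.
    max_events
        Optional cap on the number of spikes; simulation stops early when
        reached (``t_end`` of the returned trajectory is the time of the
        last committed event in that case).
    """
    if not t_end > 0:
        raise ValueError("t_end must be positive")
    if not np.isfinite(t_end) and max_events is None:
        raise ValueError("infinite t_end requires max_events")
    net.validate()
    n = net.n_neurons
    rng = np.random.default_rng(seed)

    b = net.biases()
    tau = np.array([p.psp_duration for p in net.neurons])
    refrac = np.array([p.refractory_period for p in net.neurons])
    if not (np.all(np.isfinite(b)) and np.all(tau > 0) and np.all(refrac > 0)):
        raise ValueError("non-finite bias or non-positive time constant")

    groups = _out_groups(net)
    u = b.copy()
    next_spike = np.full(n, np.inf)
    refrac_until = np.zeros(n)

    heap: list[tuple] = []  # (time, kind, seq, payload)
    seq = 0
    ev_times: list[float] = []
    ev_neurons: list[int] = []

    def redraw(ids: np.ndarray, t: float) -> None:
        """Redraw spike candidates for neurons whose potential changed."""
        if len(ids) == 0:
            return
        uk = u[ids]
        if not np.all(np.isfinite(uk)):
            bad = ids[~np.isfinite(uk)]
            raise FloatingPointError(f"non-finite membrane potential at neuron {bad[0]}")
        with np.errstate(over="ignore", under="ignore"):
            wait = tau[ids] * np.exp(-uk) * rng.standard_exponential(len(ids))
        cand = t + wait
        cand[t < refrac_until[ids]] = np.inf
        next_spike[ids] = cand

    def box_on(group, t: float) -> None:
        group[4] += 1
        if group[4] == 1:  # indicator semantics: weight applied once
            u[group[2]] += group[3]
            redraw(group[2], t)

    def box_off(group, t: float) -> None:
        group[4] -= 1
        if group[4] == 0:
            u[group[2]] -= group[3]
            redraw(group[2], t)

    def commit_spike(k: int, t: float) -> None:
        nonlocal seq
        ev_times.append(t)
        ev_neurons.append(k)
        refrac_until[k] = t + refrac[k]
        next_spike[k] = np.inf
        heapq.heappush(heap, (t + refrac[k], _K_REFRAC, seq, k))
        seq += 1
        for group in groups[k]:
            delay, psp = group[0], group[1]
            if delay == 0.0:
                box_on(group, t)
            else:
                heapq.heappush(heap, (t + delay, _K_PSP_ON, seq, group))
                seq += 1
            heapq.heappush(heap, (t + delay + psp, _K_PSP_OFF, seq, group))
            seq += 1

    # initial active set: spikes at t = 0
    if initial:
        for k in sorted(set(initial)):
            commit_spike(int(k), 0.0)
    # every neuron without a pending candidate gets its first draw
    # (initial spikers stay at inf: they are refractory at t = 0)
    redraw(np.flatnonzero(np.isinf(next_spike)), 0.0)

    t_now = 0.0
    n_spikes = len(ev_times)
    while True:
        t_det = heap[0][0] if heap else np.inf
        k_sp = int(np.argmin(next_spike))
        t_sp = next_spike[k_sp]
        t_next = min(t_det, t_sp)
        if t_next > t_end or not np.isfinite(t_next):
            break
        if t_det <= t_sp:  # deterministic events first at ties (off-before-on)
            t_now, kind, _, payload = heapq.heappop(heap)
            if kind == _K_PSP_OFF:
                box_off(payload, t_now)
            elif kind == _K_PSP_ON:
                box_on(payload, t_now)
            else:  # refractory expiry: draw a fresh candidate
                redraw(np.array([payload], dtype=np.int64), t_now)
        else:
            t_now = t_sp
            commit_spike(k_sp, t_now)
            n_spikes += 1
            if max_events is not None and n_spikes >= max_events:
                t_end = t_now
                break

    return Trajectory(
        times=np.asarray(ev_times, dtype=float),
        neurons=np.asarray(ev_neurons, dtype=np.int64),
        t_end=float(t_end),
        network=net,
        seed=seed,
    )


def state_changes_to_csv(changes: list[StateChange], path) -> None:
    """CSV export (time, neuron, direction) of a state-change list."""
    with open(path, "w") as fh:
        fh.write("time,neuron,direction\n")
        for c in changes:
            fh.write(f"{c.time:.9f},{c.neuron},{'on' if c.on else 'off'}\n")
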