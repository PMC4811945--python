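"""Energy functions, exact stationary distributions, and transition-rate theory.

A network of stochastic spiking neurons with symmetric weights, zero
transmission delays and refractory period equal to the PSP duration has a
Boltzmann stationary distribution

    p(x) ∝ exp(-E(x)),   E(x) = -Σ_k b_k x_k - ½ Σ_kl x_k x_l w_kl ,

over its binary network states x.  This module provides the energy
function and exact enumeration of p(x) for small networks, temperature
scaling E/T, the neural-computability-condition membrane potential, the
analytical event-rate laws of the spiking sampler and of a matched
continuous-time Gibbs sampler, and the run statistics (energy-jump
histograms, undefined-problem-variable tallies, time-weighted empirical
distributions) used to compare the two dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulator import StateChange, Trajectory, state_at, state_change_times

__all__ = [
    "EnergyModel",
    "energy",
    "boltzmann_exact",
    "apply_temperature",
    "ncc_membrane",
    "event_rate_spiking",
    "event_rate_gibbs",
    "rate_ratio",
    "JumpHistogram",
    "energy_jump_histogram",
    "UndefinedStats",
    "undefined_variable_stats",
    "marginal_energy",
    "empirical_distribution",
    "tv_distance",
    "all_states",
]


@dataclass
class EnergyModel:
    """Biases b and symmetric zero-diagonal weight matrix W of a Boltzmann
    energy over binary units."""

    biases: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.biases = np.asarray(self.biases, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.biases)
        if self.weights.shape != (n, n):
            raise ValueError("weight matrix shape does not match biases")
        if not np.allclose(self.weights, self.weights.T, atol=1e-9):
            raise ValueError("weight matrix must be symmetric")
        if not np.allclose(np.diag(self.weights), 0.0):
            raise ValueError("weight matrix must have zero diagonal")

    @property
    def n_units(self) -> int:
        return len(self.biases)


def energy(x, model: EnergyModel) -> float:
    """Boltzmann energy ``E(x) = -Σ b_k x_k - ½ Σ x_k x_l w_kl``."""
    x = np.asarray(x, dtype=float)
    if x.shape != (model.n_units,):
        raise ValueError("state dimension does not match model")
    return float(-(model.biases @ x) - 0.5 * x @ model.weights @ x)


def all_states(n: int) -> np.ndarray:
    """All 2^n binary states as an array of shape (2^n, n); row index is the
    little-endian bit pattern (unit 0 = least significant bit)."""
    if n > 20:
        raise ValueError("state enumeration capped at 20 units")
    idx = np.arange(2**n, dtype=np.int64)
    return ((idx[:, None] >> np.arange(n)) & 1).astype(np.int8)


def _energies_all(model: EnergyModel) -> np.ndarray:
    X = all_states(model.n_units).astype(float)
    return -(X @ model.biases) - 0.5 * np.einsum("si,ij,sj->s", X, model.weights, X)


def boltzmann_exact(model: EnergyModel) -> np.ndarray:
    """Exact stationary distribution over all 2^N states.

    Returns p of length 2^N indexed by the little-endian bit pattern of the
    state; ``p[i] ∝ exp(-E(x_i))`` and sums to 1.
    """
    E = _energies_all(model)
    logp = -E - np.max(-E)
    p = np.exp(logp)
    return p / p.sum()


def apply_temperature(model: EnergyModel, T: float) -> EnergyModel:
    """Rescale the energy landscape, ``E_T(x) = E(x) / T``."""
    if not T > 0:
        raise ValueError("temperature must be positive")
    return EnergyModel(model.biases / T, model.weights / T)


def ncc_membrane(k: int, x, model: EnergyModel) -> float:
    """Membrane potential demanded by the neural computability condition:
    ``u_k = E(x_k=0, x_\\k) - E(x_k=1, x_\\k) = b_k + Σ_l w_kl x_l``,
    the log-odds of unit k given the rest."""
    x = np.asarray(x, dtype=float)
    if not 0 <= k < model.n_units:
        raise IndexError(f"unit index {k} out of range")
    return float(model.biases[k] + model.weights[k] @ x - model.weights[k, k] * x[k])


# -- transition-rate theory ----------------------------------------------------


def _sigmoid(u):
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-np.asarray(u, dtype=float)))


def event_rate_spiking(u, tau: float):
    """Mean state-change rate of a spiking neuron at fixed potential u.

    The on-period is deterministic (tau) and the off-period is exponential
    with mean ``tau * exp(-u)``, so the rate of state changes (on plus off)
    is ``2 / (m_on + m_off) = (2 / tau) * sigma(u)``.
    """
    if not tau > 0:
        raise ValueError("tau must be positive")
    return (2.0 / tau) * _sigmoid(u)


def event_rate_gibbs(u, rho0: float = 1.0):
    """Mean flip rate of a continuous-time Gibbs-sampler unit at fixed u:
    ``2 rho0 / (2 + exp(u) + exp(-u))``, symmetric and peaked at u = 0."""
    if not rho0 > 0:
        raise ValueError("rho0 must be positive")
    u = np.asarray(u, dtype=float)
    with np.errstate(over="ignore"):
        out = 2.0 * rho0 / (2.0 + np.exp(u) + np.exp(-u))
    return out if out.ndim else float(out)


def rate_ratio(u, tau: float, rho0: float = 1.0):
    """Factor relating spiking to Gibbs event rates:
    ``F(u) = R(u)/R_sym(u) = (1 + exp(u)) / (tau * rho0)``, strictly
    increasing in u — the spiking sampler changes state relatively more
    often exactly where energy barriers are high."""
    if not tau > 0 or not rho0 > 0:
        raise ValueError("tau and rho0 must be positive")
    u = np.asarray(u, dtype=float)
    out = (1.0 + np.exp(u)) / (tau * rho0)
    return out if out.ndim else float(out)


# -- run statistics -------------------------------------------------------------


@dataclass
class JumpHistogram:
    """Histogram of energy jumps ΔE caused by single state changes."""

    bin_edges: np.ndarray
    counts: np.ndarray
    total_transitions: int
    underflow: int = 0
    overflow: int = 0
    jumps: np.ndarray | None = None  # raw ΔE values, kept for threshold queries

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("bin_left,bin_right,count\n")
            for lo, hi, c in zip(self.bin_edges[:-1], self.bin_edges[1:], self.counts):
                fh.write(f"{lo},{hi},{int(c)}\n")

    def frequency_abs_above(self, threshold: float) -> float:
        """Fraction of transitions with |ΔE| > threshold (uses raw jumps)."""
        if self.total_transitions == 0 or self.jumps is None:
            return 0.0
        return float(np.sum(np.abs(self.jumps) > threshold)) / self.total_transitions


def energy_jump_histogram(
    changes: list[StateChange] | list[tuple],
    model: EnergyModel,
    bins=None,
    initial_state=None,
) -> JumpHistogram:
    """Histogram of energy jumps ``ΔE = E(after) - E(before)`` along a
    state-change list over the model's units.

    ``changes`` entries carry (time, unit index, on/off direction); unit
    indices must index into ``model``.  Because the energy is second order,
    a single flip of unit k changes the energy by ``∓ (b_k + Σ w_kl x_l)``
    (− for on, + for off), which is accumulated incrementally.
    """
    n = model.n_units
    x = np.zeros(n) if initial_state is None else np.asarray(initial_state, dtype=float)
    if bins is None:
        bins = np.arange(-40.0, 41.0, 1.0)
    bins = np.asarray(bins, dtype=float)
    jumps = []
    for c in changes:
        t, k, on = (c.time, c.neuron, c.on) if isinstance(c, StateChange) else c
        u_k = model.biases[k] + model.weights[k] @ x
        if on:
            jumps.append(-u_k)
            x[k] = 1.0
        else:
            jumps.append(+u_k)
            x[k] = 0.0
    jumps = np.asarray(jumps, dtype=float)
    counts, edges = np.histogram(jumps, bins=bins)
    return JumpHistogram(
        bin_edges=edges,
        counts=counts,
        total_transitions=len(jumps),
        underflow=int(np.sum(jumps < edges[0])),
        overflow=int(np.sum(jumps >= edges[-1])),
        jumps=jumps,
    )


@dataclass
class UndefinedStats:
    """Tally of transitions into states with k problem variables undefined
    (a WTA group is undefined when it has != 1 active member)."""

    counts: dict[int, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def frequency(self, k: int) -> float:
        return self.counts.get(k, 0) / self.total if self.total else 0.0

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("n_undefined,count\n")
            for k in sorted(self.counts):
                fh.write(f"{k},{self.counts[k]}\n")


def undefined_variable_stats(
    traj_or_changes,
    wta_groups: dict[str, list[int]] | None = None,
    initial_active=None,
) -> UndefinedStats:
    """Count, per state change, how many WTA groups are left undefined.

    The initial state (t = 0) is tallied once, then every subsequent state
    change contributes the count of the state it transitions *into*.
    Accepts a spiking :class:`Trajectory` or a raw state-change list (e.g.
    Gibbs flips) plus ``wta_groups`` and the initially active neurons.
    """
    is_traj = isinstance(traj_or_changes, Trajectory)
    if wta_groups is None:
        if not is_traj:
            raise ValueError("wta_groups required with a raw change list")
        wta_groups = traj_or_changes.network.wta_groups
    if not wta_groups:
        raise ValueError("no WTA groups defined")
    labels = sorted(wta_groups)
    group_of = {}
    for gi, lab in enumerate(labels):
        for m in wta_groups[lab]:
            group_of[m] = gi
    members = sorted(group_of)
    gcount = np.zeros(len(labels), dtype=int)
    if is_traj:
        active = np.asarray(state_at(traj_or_changes, 0.0, neurons=members), dtype=int)
        for i, m in enumerate(members):
            gcount[group_of[m]] += active[i]
        changes = state_change_times(traj_or_changes, neurons=members)
    else:
        for m in initial_active or ():
            if m in group_of:
                gcount[group_of[m]] += 1
        changes = [c for c in traj_or_changes if c.neuron in group_of]
    stats = UndefinedStats()

    def tally():
        k = int(np.sum(gcount != 1))
        stats.counts[k] = stats.counts.get(k, 0) + 1

    tally()
    for c in changes:
        if is_traj and c.time == 0.0 and c.on:
            continue  # initial virtual spikes are part of the t=0 state
        gcount[group_of[c.neuron]] += 1 if c.on else -1
        tally()
    return stats


def marginal_energy(model: EnergyModel, principal: list[int]) -> np.ndarray:
    """Energy table over principal states with auxiliary units marginalized
    out: ``E(x) = -log Σ_ξ exp(-E(x, ξ))``, shifted so that min = 0.

    Indexed by the little-endian bit pattern of the principal state.
    """
    n = model.n_units
    principal = list(principal)
    if n > 20:
        raise ValueError("marginalization capped at 20 units")
    E = _energies_all(model)
    idx = np.arange(2**n, dtype=np.int64)
    pbits = np.zeros(2**n, dtype=np.int64)
    for j, k in enumerate(principal):
        pbits |= ((idx >> k) & 1) << j
    np_states = 2 ** len(principal)
    Em = np.full(np_states, np.inf)
    from scipy.special import logsumexp

    for s in range(np_states):
        mask = pbits == s
        Em[s] = -logsumexp(-E[mask])
    return Em - Em.min()


# -- empirical distributions ----------------------------------------------------


def empirical_distribution(
    traj_or_changes,
    neurons: list[int],
    t_end: float | None = None,
    burn_in: float = 1.0,
    initial_state=None,
) -> np.ndarray:
    """Time-weighted (occupancy) distribution of the binary state of
    ``neurons``, as a vector of length 2^len(neurons) indexed little-endian.

    Accepts a :class:`Trajectory` (its state changes are derived) or a
    pre-computed state-change list together with ``t_end`` and the state at
    time 0.  Occupancy before ``burn_in`` is discarded.
    """
    if isinstance(traj_or_changes, Trajectory):
        traj = traj_or_changes
        changes = state_change_times(traj, neurons=neurons)
        t_end = traj.t_end
        x0 = np.zeros(len(neurons), dtype=int)
        for c in changes:
            if c.time == 0.0 and c.on:
                x0[neurons.index(c.neuron)] = 1
        changes = [c for c in changes if not (c.time == 0.0 and c.on)]
    else:
        changes = traj_or_changes
        if t_end is None:
            raise ValueError("t_end required with a raw change list")
        x0 = (
            np.zeros(len(neurons), dtype=int)
            if initial_state is None
            else np.asarray(initial_state, dtype=int)
        )
    pos = {k: i for i, k in enumerate(neurons)}
    occ = np.zeros(2 ** len(neurons))
    code = int(sum(int(x0[i]) << i for i in range(len(neurons))))
    t_prev = 0.0
    for c in changes:
        t = min(c.time, t_end)
        seg_lo, seg_hi = max(t_prev, burn_in), max(t, burn_in)
        if seg_hi > seg_lo:
            occ[code] += seg_hi - seg_lo
        i = pos[c.neuron]
        bit = 1 << i
        code = (code | bit) if c.on else (code & ~bit)
        t_prev = t
    if t_end > max(t_prev, burn_in):
        occ[code] += t_end - max(t_prev, burn_in)
    total = occ.sum()
    if total <= 0:
        raise ValueError("no occupancy after burn-in")
    return occ / total


def tv_distance(p, q) -> float:
    """Total-variation distance ``½ Σ |p - q|`` between two distributions."""
    return 0.5 * float(np.sum(np.abs(np.asarray(p) - np.asarray(q))))


def distribution_to_csv(p: np.ndarray, n_units: int, path) -> None:
    """CSV export (state bitstring, probability/occupancy)."""
    with open(path, "w") as fh:
        fh.write("state,probability\n")
        for i, v in enumerate(p):
            bits = "".join(str((i >> k) & 1) for k in range(n_units))
            fh.write(f"{bits},{v}\n")
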