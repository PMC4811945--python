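"""Continuous-time Boltzmann machine (Gibbs sampler) baseline.

A binary unit k with membrane potential ``u_k = b_k + sum_l w_kl x_l``
turns on at rate ``rho0 * sigma(u_k)`` while off, and off at rate
``rho0 * sigma(-u_k)`` while on.  Detailed balance then makes the chain's
stationary distribution the Boltzmann distribution of the same energy
model the spiking network samples from — but with symmetric transition
dynamics: units with large |u| barely move, whereas the spiking sampler's
deterministic PSP expiry forces every active neuron off after one tau.
This module provides the exact event-driven simulation of the chain, the
extraction of an energy model from a compiled spiking network, and a
search-efficiency comparison harness (state changes to reach a tour-cost
threshold, with a two-sample Kolmogorov-Smirnov test).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import ks_2samp

from .energy import EnergyModel
from .network import NetworkSpec
from .simulator import StateChange, simulate, state_change_times

__all__ = [
    "GibbsParams",
    "GibbsTrajectory",
    "simulate_gibbs",
    "gibbs_state_changes",
    "spiking_model_to_gibbs",
    "compare_samplers_tsp",
]


@dataclass
class GibbsParams:
    """Overall sampling-speed constant rho0 (events per unit |u| -> inf)."""

    rho0: float = 1.0

    def __post_init__(self) -> None:
        if not self.rho0 > 0:
            raise ValueError("rho0 must be positive")


@dataclass
class GibbsTrajectory:
    """Flip events of one continuous-time Gibbs run.

    ``times``/``units``/``ons`` are parallel arrays; ``unit_ids`` maps the
    sampler's unit index back to the originating neuron id (identity when
    the model was not derived from a network).
    """

    times: np.ndarray
    units: np.ndarray
    ons: np.ndarray
    t_end: float
    seed: int | None
    model: EnergyModel
    unit_ids: list[int] = field(default_factory=list)

    @property
    def n_events(self) -> int:
        return len(self.times)

    def final_state(self) -> np.ndarray:
        x = np.zeros(self.model.n_units, dtype=np.int8)
        for u, on in zip(self.units, self.ons):
            x[u] = 1 if on else 0
        return x


def _sigmoid(u):
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-u))


def simulate_gibbs(
    model: EnergyModel,
    t_end: float,
    seed: int,
    params: GibbsParams | None = None,
    initial=None,
    max_events: int | None = None,
    unit_ids: list[int] | None = None,
) -> GibbsTrajectory:
    """Exact event-driven simulation of the continuous-time Gibbs sampler.

    Exponential flip clocks are redrawn after every committed flip (valid
    by memorylessness); the earliest clock fires.  Stops at ``t_end`` or
    after ``max_events`` flips, whichever comes first (``t_end`` may be
    ``inf`` when ``max_events`` is given).
    """
    params = params or GibbsParams()
    if not t_end > 0:
        raise ValueError("t_end must be positive")
    if not np.isfinite(t_end) and max_events is None:
        raise ValueError("infinite t_end requires max_events")
    n = model.n_units
    rng = np.random.default_rng(seed)
    x = np.zeros(n)
    if initial is not None:
        for k in initial:
            x[k] = 1.0
    u = model.biases + model.weights @ x

    times, units, ons = [], [], []
    t = 0.0
    while True:
        rates = params.rho0 * np.where(x > 0, _sigmoid(-u), _sigmoid(u))
        with np.errstate(divide="ignore"):
            waits = rng.standard_exponential(n) / rates
        k = int(np.argmin(waits))
        t_next = t + waits[k]
        if t_next > t_end or not np.isfinite(t_next):
            break
        t = t_next
        on = x[k] == 0.0
        x[k] = 1.0 if on else 0.0
        u += model.weights[:, k] if on else -model.weights[:, k]
        times.append(t)
        units.append(k)
        ons.append(on)
        if max_events is not None and len(times) >= max_events:
            t_end = t
            break

    return GibbsTrajectory(
        times=np.asarray(times, dtype=float),
        units=np.asarray(units, dtype=np.int64),
        ons=np.asarray(ons, dtype=bool),
        t_end=float(t_end),
        seed=seed,
        model=model,
        unit_ids=list(unit_ids) if unit_ids is not None else list(range(n)),
    )


def gibbs_state_changes(gtraj: GibbsTrajectory) -> list[StateChange]:
    """Flip list as state changes (every flip is one state change), with
    unit indices mapped back to originating neuron ids."""
    ids = gtraj.unit_ids
    return [
        StateChange(float(t), int(ids[u]), bool(on))
        for t, u, on in zip(gtraj.times, gtraj.units, gtraj.ons)
    ]


def spiking_model_to_gibbs(
    net: NetworkSpec, mode: str = "lateral", atol: float = 1e-9
) -> tuple[EnergyModel, list[int]]:
    """Extract a Boltzmann machine from a spiking network.

    Modes
    -----
    ``"principal"``
        Units are the principal neurons; weights are the (required
        symmetric) principal-to-principal synapses.  WTA auxiliaries are
        dropped entirely.
    ``"lateral"`` (default)
        As ``"principal"``, but each WTA group's auxiliary neuron is
        replaced by its effective contribution: direct symmetric lateral
        inhibition between all pairs of group members, with the strength
        of the auxiliary's outgoing inhibitory weight.  This preserves the
        winner-take-all constraint in the baseline sampler.
    ``"full"``
        Every neuron becomes a unit and the weight matrix is symmetrized
        by the arithmetic mean (W + W^T)/2; preserves the unit count but
        averages away purely asymmetric couplings.
    """
    principal = list(net.principal_ids)
    if mode in ("principal", "lateral"):
        W = net.weight_matrix(principal)
        if not np.allclose(W, W.T, atol=atol):
            raise ValueError("principal subnetwork weights are not symmetric")
        W = 0.5 * (W + W.T)
        b = net.biases(principal)
        if mode == "lateral":
            index = {nid: i for i, nid in enumerate(principal)}
            aux_out: dict[int, float] = {}
            for s in net.synapses:
                aux_out[(s.pre, s.post)] = s.weight
            for label, members in net.wta_groups.items():
                # find the group's auxiliary: a non-principal common target
                cand = None
                pset = set(net.principal_ids)
                targets = [
                    s.post
                    for s in net.synapses
                    if s.pre == members[0] and s.post not in pset
                ]
                for a in targets:
                    if all((a, m) in aux_out for m in members):
                        cand = a
                        break
                if cand is None:
                    raise ValueError(f"no WTA auxiliary found for group {label!r}")
                w_lat = aux_out[(cand, members[0])]
                for i, mi in enumerate(members):
                    for mj in members[i + 1 :]:
                        W[index[mi], index[mj]] += w_lat
                        W[index[mj], index[mi]] += w_lat
        np.fill_diagonal(W, 0.0)
        return EnergyModel(b, W), principal
    if mode == "full":
        ids = list(range(net.n_neurons))
        A = net.weight_matrix(ids)
        W = 0.5 * (A + A.T)
        np.fill_diagonal(W, 0.0)
        return EnergyModel(net.biases(ids), W), ids
    raise ValueError(f"unknown mode {mode!r}")


def compare_samplers_tsp(
    tspnet,
    cost_threshold: float,
    n_runs: int = 20,
    budget: int = 100_000,
    seed: int = 0,
    rho0: float = 1.0,
    mode: str = "lateral",
):
    """Search-efficiency comparison: state changes until a tour of cost
    <= threshold, for the spiking network and the matched Gibbs baseline.

    Each run gets ``budget`` state changes (spikes + PSP offsets for the
    spiking network, flips for the Gibbs sampler).  Runs that never reach
    the threshold within the budget are excluded from the samples.
    Returns per-sampler samples, mean and sd, and the two-sample
    Kolmogorov-Smirnov statistic and p-value.
    """
    from .tsp import state_changes_to_cost

    model, ids = spiking_model_to_gibbs(tspnet.net, mode=mode)
    root = np.random.SeedSequence(seed)
    spiking, gibbs = [], []
    for i, child in enumerate(root.spawn(n_runs)):
        s = int(child.generate_state(1)[0] % (2**31))
        traj = simulate(tspnet.net, t_end=np.inf, seed=s, max_events=budget // 2)
        changes = state_change_times(traj)[:budget]
        r = state_changes_to_cost(changes, tspnet, cost_threshold)
        if r is not None:
            spiking.append(r)
        gtraj = simulate_gibbs(
            model, t_end=np.inf, seed=s + 1, params=GibbsParams(rho0),
            max_events=budget, unit_ids=ids,
        )
        r = state_changes_to_cost(
            gibbs_state_changes(gtraj), tspnet, cost_threshold, mode="active"
        )
        if r is not None:
            gibbs.append(r)
    result = {
        "spiking": np.asarray(spiking),
        "gibbs": np.asarray(gibbs),
        "spiking_mean": float(np.mean(spiking)) if spiking else None,
        "spiking_sd": float(np.std(spiking, ddof=1)) if len(spiking) > 1 else None,
        "gibbs_mean": float(np.mean(gibbs)) if gibbs else None,
        "gibbs_sd": float(np.std(gibbs, ddof=1)) if len(gibbs) > 1 else None,
        "n_excluded_spiking": n_runs - len(spiking),
        "n_excluded_gibbs": n_runs - len(gibbs),
        "mapping_mode": mode,
    }
    if len(spiking) >= 2 and len(gibbs) >= 2:
        ks = ks_2samp(spiking, gibbs)
        result["ks_statistic"] = float(ks.statistic)
        result["ks_pvalue"] = float(ks.pvalue)
    return result
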