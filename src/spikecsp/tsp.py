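"""Compiling traveling-salesman instances into spiking networks.

A tour through N cities is encoded by N' = N + N_resting winner-take-all
modules of N principal neurons each (one module per tour step, one neuron
per city), plus one inhibitory auxiliary neuron per module.  Excitatory
connections between adjacent modules encode the cost matrix,

    w(step n city i, step n+1 city j) = w_offset + (1 - c~_ij) * w_scale ,

with costs normalized by the maximum off-diagonal cost; the two directions
of travel map onto distinct neuron pairs, so asymmetric cost matrices are
representable.  Strong negative connections ``w_unique`` between neurons
coding the same city in non-adjacent modules penalize revisits (adjacent
repeats are permitted "resting" steps and carry no cost).  The ring of
modules closes from step N' back to step 1.  Low-cost tours then occupy
the low-energy states of the network, and the stochastic spiking dynamics
searches for them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np

from .motifs import WTAParams, add_wta
from .network import NetworkSpec, NeuronParams
from .simulator import StateChange, Trajectory, state_change_times

__all__ = [
    "TSPInstance",
    "TSPNetworkParams",
    "TSPNetwork",
    "TourReadout",
    "UNDEFINED",
    "normalize_costs",
    "compile_tsp",
    "read_tour",
    "tour_cost",
    "performance_trace",
    "state_changes_to_cost",
    "best_cost_vs_changes",
    "generate_planar_instance",
    "generate_asymmetric_instance",
    "brute_force_tsp",
    "held_karp_tsp",
    "read_tsplib",
    "write_tsplib",
    "neuron_count_formula",
    "connection_count_formula",
]

#: Sentinel for a tour step whose WTA module has not fired yet.
UNDEFINED = None


@dataclass
class TSPInstance:
    """A TSP instance: an N x N cost matrix (diagonal ignored)."""

    costs: np.ndarray
    symmetric: bool | None = None
    optimal_cost: float | None = None
    name: str = "tsp"
    coords: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.costs = np.asarray(self.costs, dtype=float)
        if self.costs.ndim != 2 or self.costs.shape[0] != self.costs.shape[1]:
            raise ValueError("cost matrix must be square")
        off = ~np.eye(self.n_cities, dtype=bool)
        if np.any(self.costs[off] < 0):
            raise ValueError("costs must be non-negative")
        if self.symmetric is None:
            self.symmetric = bool(np.allclose(self.costs, self.costs.T))
        elif self.symmetric and not np.allclose(self.costs, self.costs.T):
            raise ValueError("symmetric flag set but cost matrix is not symmetric")

    @property
    def n_cities(self) -> int:
        return self.costs.shape[0]


@dataclass
class TSPNetworkParams:
    """Compiler parameters; defaults are the reference planar-TSP setting."""

    N_resting: int = 7
    b_WTA: float = -0.45
    b_P: float = 100.0
    b_N: float = -100.0
    b_inh: float = -10.0
    w_WTA: float = -100.0
    w_exc: float = 100.0
    w_unique: float = -14.7
    w_scale: float = 19.4
    w_offset: float = -5.0
    clamp_first: bool = True

    def __post_init__(self) -> None:
        if self.N_resting < 0:
            raise ValueError("N_resting must be >= 0")
        if not self.w_unique < 0:
            raise ValueError("w_unique must be negative")
        if not self.w_scale > 0:
            raise ValueError("w_scale must be positive")

    @classmethod
    def asymmetric_defaults(cls) -> "TSPNetworkParams":
        """Reference parameter set for asymmetric cost matrices."""
        return cls(
            N_resting=8, b_WTA=1.3, w_unique=-14.1, w_offset=-7.9, w_scale=20.8
        )


@dataclass
class TSPNetwork:
    """A compiled TSP network plus its readout map.

    ``modules[n][i]`` is the principal-neuron id for city ``i`` at tour
    step ``n``.
    """

    net: NetworkSpec
    modules: list[list[int]]
    instance: TSPInstance
    params: TSPNetworkParams
    connection_counts: dict = field(default_factory=dict)

    @property
    def n_steps(self) -> int:
        return len(self.modules)

    @property
    def module_of(self) -> dict[int, tuple[int, int]]:
        return {nid: (n, i) for n, mod in enumerate(self.modules) for i, nid in enumerate(mod)}

    def connection_count(self) -> int:
        """Connection count with each symmetric adjacent-module cost pair
        counted once (the accounting the printed formula uses); WTA and
        same-city connections are counted per direction."""
        c = self.connection_counts
        return c["wta"] + c["cost"] // 2 + c["unique"]


def neuron_count_formula(n_cities: int, n_resting: int) -> int:
    """(N + 1)(N + N_resting) neurons: N principals + 1 inhibitory
    auxiliary per module."""
    return (n_cities + 1) * (n_cities + n_resting)


def connection_count_formula(n_cities: int, n_resting: int) -> int:
    """N (N + N_resting)(2N + N_resting - 2) connections."""
    return n_cities * (n_cities + n_resting) * (2 * n_cities + n_resting - 2)


def normalize_costs(instance: TSPInstance) -> np.ndarray:
    """Costs divided by the maximum off-diagonal cost, in [0, 1]."""
    c = instance.costs
    off = ~np.eye(instance.n_cities, dtype=bool)
    cmax = c[off].max()
    if cmax <= 0:
        raise ValueError("all off-diagonal costs are zero")
    out = c / cmax
    np.fill_diagonal(out, 0.0)
    return out


def compile_tsp(instance: TSPInstance, params: TSPNetworkParams | None = None) -> TSPNetwork:
    """Compile a TSP instance into a spiking network."""
    params = params or TSPNetworkParams()
    N = instance.n_cities
    if N < 3:
        raise ValueError("need at least 3 cities")
    n_steps = N + params.N_resting
    ctil = normalize_costs(instance)
    net = NetworkSpec(metadata={"problem": "tsp", "n_cities": N, "n_steps": n_steps})

    modules: list[list[int]] = []
    for n in range(n_steps):
        modules.append([net.add_neuron(NeuronParams(), principal=True) for _ in range(N)])
    wta = WTAParams(
        b_WTA=params.b_WTA, b_inh=params.b_inh, w_WTA=params.w_WTA, w_exc=params.w_exc
    )
    for n in range(n_steps):
        add_wta(net, modules[n], wta, label=f"step{n}")
    if params.clamp_first:
        # pin the first step to city 0
        net.neurons[modules[0][0]].bias = params.b_P
        for i in range(1, N):
            net.neurons[modules[0][i]].bias = params.b_N

    counts = {"wta": 2 * N * n_steps, "cost": 0, "unique": 0}
    # cost connections between ring-adjacent modules (same-city pairs excluded)
    for n in range(n_steps):
        m = (n + 1) % n_steps
        for i in range(N):
            for j in range(N):
                if i == j:
                    continue
                w = params.w_offset + (1.0 - ctil[i, j]) * params.w_scale
                net.add_symmetric(modules[n][i], modules[m][j], w)
                counts["cost"] += 2
    # uniqueness: same city in non-adjacent modules
    for n in range(n_steps):
        for m in range(n + 1, n_steps):
            d = (m - n) % n_steps
            if d in (1, n_steps - 1):
                continue
            for i in range(N):
                net.add_symmetric(modules[n][i], modules[m][i], params.w_unique)
                counts["unique"] += 2
    net.metadata["readout_modules"] = modules
    return TSPNetwork(net, modules, instance, params, counts)


# -- readout --------------------------------------------------------------------


@dataclass
class TourReadout:
    """Decoded tour: one city (or UNDEFINED) per step, the collapsed cyclic
    tour after merging consecutive duplicates, validity and cost."""

    steps: list
    collapsed_tour: list[int]
    valid: bool
    cost: float | None


def _collapse_and_validate(steps: list, instance: TSPInstance) -> TourReadout:
    n = instance.n_cities
    if any(s is UNDEFINED for s in steps):
        return TourReadout(list(steps), [], False, None)
    collapsed: list[int] = []
    for s in steps:
        if not collapsed or collapsed[-1] != s:
            collapsed.append(s)
    if len(collapsed) > 1 and collapsed[0] == collapsed[-1]:  # cyclic wrap repeat
        collapsed.pop()
    valid = sorted(collapsed) == list(range(n))
    cost = None
    if valid:
        cost = float(
            sum(
                instance.costs[collapsed[i], collapsed[(i + 1) % len(collapsed)]]
                for i in range(len(collapsed))
            )
        )
    return TourReadout(list(steps), collapsed if valid else collapsed, valid, cost)


def read_tour(
    traj: Trajectory, t: float, tspnet: TSPNetwork, mode: str = "most_recent"
) -> TourReadout:
    """Decode the tour represented by the network at time ``t``.

    ``mode="most_recent"`` (default) takes, per module, the city of the
    most recently fired principal neuron at or before ``t`` — even if that
    spike's PSP has expired.  ``mode="active"`` requires exactly one
    currently active principal per module (else UNDEFINED).
    """
    steps: list = []
    for mod in tspnet.modules:
        if mode == "most_recent":
            best_t, best_city = -np.inf, UNDEFINED
            for city, nid in enumerate(mod):
                s = traj.last_spike_before(nid, t)
                if s is not None and s > best_t:
                    best_t, best_city = s, city
            steps.append(best_city)
        elif mode == "active":
            net = traj.network
            active = [
                city
                for city, nid in enumerate(mod)
                if (s := traj.last_spike_before(nid, t)) is not None
                and s > t - net.neurons[nid].psp_duration
            ]
            steps.append(active[0] if len(active) == 1 else UNDEFINED)
        else:
            raise ValueError(f"unknown readout mode {mode!r}")
    return _collapse_and_validate(steps, tspnet.instance)


def tour_cost(readout: TourReadout, instance: TSPInstance) -> float:
    """Cost of a valid collapsed cyclic tour."""
    if not readout.valid:
        raise ValueError("tour readout is not valid")
    tour = readout.collapsed_tour
    return float(
        sum(instance.costs[tour[i], tour[(i + 1) % len(tour)]] for i in range(len(tour)))
    )


def _ensure_optimal(instance: TSPInstance) -> float:
    if instance.optimal_cost is None:
        if instance.n_cities > 10:
            raise ValueError("optimal_cost unknown and instance too large to brute-force")
        _, instance.optimal_cost = brute_force_tsp(instance)
    return instance.optimal_cost


def performance_trace(
    traj: Trajectory, instance: TSPInstance, times, tspnet: TSPNetwork
) -> np.ndarray:
    """(optimal cost) / (current tour cost) at each requested time; NaN where
    the read-out tour is invalid."""
    opt = _ensure_optimal(instance)
    out = np.full(len(times), np.nan)
    for i, t in enumerate(times):
        r = read_tour(traj, t, tspnet)
        if r.valid:
            out[i] = opt / r.cost
    return out


def _scan_tours(changes: list[StateChange], tspnet: TSPNetwork, mode: str = "most_recent"):
    """Incrementally scan a state-change list, yielding (index, readout)
    each time a module's decoded city changes.

    ``most_recent`` decodes a module as the city that fired last;
    ``active`` (currently-on semantics, for Gibbs flip lists) requires
    exactly one active member per module.
    """
    module_of = tspnet.module_of
    if mode == "most_recent":
        recent: list = [UNDEFINED] * tspnet.n_steps
        for idx, c in enumerate(changes):
            if c.on and c.neuron in module_of:
                n, city = module_of[c.neuron]
                if recent[n] != city:
                    recent[n] = city
                    yield idx, _collapse_and_validate(recent, tspnet.instance)
    elif mode == "active":
        active: list[set[int]] = [set() for _ in range(tspnet.n_steps)]
        decode: list = [UNDEFINED] * tspnet.n_steps
        for idx, c in enumerate(changes):
            if c.neuron not in module_of:
                continue
            n, city = module_of[c.neuron]
            if c.on:
                active[n].add(city)
            else:
                active[n].discard(city)
            new = next(iter(active[n])) if len(active[n]) == 1 else UNDEFINED
            if new != decode[n]:
                decode[n] = new
                yield idx, _collapse_and_validate(decode, tspnet.instance)
    else:
        raise ValueError(f"unknown readout mode {mode!r}")


def state_changes_to_cost(
    traj_or_changes,
    tspnet: TSPNetwork,
    cost_threshold: float,
    mode: str = "most_recent",
) -> int | None:
    """Number of state changes until the read-out tour is first valid with
    cost <= ``cost_threshold`` (the achieving change included); None if the
    threshold is never reached.

    Accepts a spiking :class:`Trajectory` (state changes = spikes plus PSP
    offsets) or a pre-computed state-change list (e.g. Gibbs flips).
    """
    if not cost_threshold > 0:
        raise ValueError("cost threshold must be positive")
    changes = (
        state_change_times(traj_or_changes)
        if isinstance(traj_or_changes, Trajectory)
        else traj_or_changes
    )
    for idx, readout in _scan_tours(changes, tspnet, mode):
        if readout.valid and readout.cost <= cost_threshold:
            return idx + 1
    return None


def best_cost_vs_changes(
    traj_or_changes, tspnet: TSPNetwork, mode: str = "most_recent"
) -> list[tuple[int, float]]:
    """Trace of (state-change count, best tour cost so far) improvements."""
    changes = (
        state_change_times(traj_or_changes)
        if isinstance(traj_or_changes, Trajectory)
        else traj_or_changes
    )
    best = math.inf
    out = []
    for idx, readout in _scan_tours(changes, tspnet, mode):
        if readout.valid and readout.cost < best:
            best = readout.cost
            out.append((idx + 1, best))
    return out


# -- instance generation and oracles --------------------------------------------


def generate_planar_instance(n_cities: int, seed: int) -> TSPInstance:
    """Uniform points in the unit square with Euclidean costs."""
    if n_cities < 3:
        raise ValueError("need at least 3 cities")
    rng = np.random.default_rng(seed)
    pts = rng.uniform(size=(n_cities, 2))
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    return TSPInstance(costs=d, symmetric=True, name=f"planar{n_cities}-s{seed}", coords=pts)


def generate_asymmetric_instance(n_cities: int, seed: int) -> TSPInstance:
    """Uniform costs in (0, 1], independently per ordered pair."""
    if n_cities < 3:
        raise ValueError("need at least 3 cities")
    rng = np.random.default_rng(seed)
    c = 1.0 - rng.uniform(size=(n_cities, n_cities))  # in (0, 1]
    np.fill_diagonal(c, 0.0)
    return TSPInstance(costs=c, symmetric=False, name=f"asym{n_cities}-s{seed}")


def brute_force_tsp(instance: TSPInstance) -> tuple[tuple[int, ...], float]:
    """Exhaustive search over all cyclic permutations (city 0 fixed)."""
    n = instance.n_cities
    if n > 10:
        raise ValueError("brute force capped at 10 cities")
    c = instance.costs
    best_tour, best_cost = None, math.inf
    for perm in permutations(range(1, n)):
        tour = (0,) + perm
        cost = sum(c[tour[i], tour[(i + 1) % n]] for i in range(n))
        if cost < best_cost:
            best_tour, best_cost = tour, cost
    return best_tour, float(best_cost)


def held_karp_tsp(instance: TSPInstance) -> tuple[tuple[int, ...], float]:
    """Held–Karp dynamic program; exact optimum in O(2^N N^2)."""
    n = instance.n_cities
    if n > 16:
        raise ValueError("Held-Karp capped at 16 cities")
    c = instance.costs
    # dp[S][j]: min cost of a path 0 -> ... -> j visiting exactly set S (0 in S)
    size = 1 << n
    dp = np.full((size, n), np.inf)
    parent = np.full((size, n), -1, dtype=int)
    dp[1, 0] = 0.0
    for S in range(1, size):
        if not S & 1:
            continue
        for j in range(n):
            if not (S >> j) & 1 or not np.isfinite(dp[S, j]):
                continue
            for k in range(n):
                if (S >> k) & 1:
                    continue
                S2 = S | (1 << k)
                cand = dp[S, j] + c[j, k]
                if cand < dp[S2, k]:
                    dp[S2, k] = cand
                    parent[S2, k] = j
    full = size - 1
    closing = dp[full, :] + c[:, 0]
    j = int(np.argmin(closing))
    best = float(closing[j])
    tour = [j]
    S = full
    while parent[S, j] >= 0:
        pj = int(parent[S, j])
        S ^= 1 << j
        j = pj
        tour.append(j)
    tour.reverse()
    return tuple(tour), best


# -- TSPLIB I/O -------------------------------------------------------------------


def _tsplib_nint(x: float) -> int:
    return int(x + 0.5)


def read_tsplib(path) -> TSPInstance:
    """Read a TSPLIB file (EUC_2D or EXPLICIT/FULL_MATRIX)."""
    header: dict[str, str] = {}
    body: list[str] = []
    section = None
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line == "EOF":
                continue
            up = line.upper()
            if up.startswith(("NODE_COORD_SECTION", "EDGE_WEIGHT_SECTION")):
                section = up.split()[0]
                continue
            if section is None:
                if ":" not in line:
                    raise ValueError(f"malformed TSPLIB header line: {line!r}")
                key, _, val = line.partition(":")
                header[key.strip().upper()] = val.strip()
            else:
                body.append(line)
    try:
        n = int(header["DIMENSION"])
    except KeyError:
        raise ValueError("TSPLIB file missing DIMENSION") from None
    ewt = header.get("EDGE_WEIGHT_TYPE", "").upper()
    name = header.get("NAME", "tsplib")
    if ewt == "EUC_2D":
        coords = np.zeros((n, 2))
        for line in body:
            parts = line.split()
            i = int(parts[0]) - 1
            coords[i] = [float(parts[1]), float(parts[2])]
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                if i != j:
                    d[i, j] = _tsplib_nint(float(np.hypot(*(coords[i] - coords[j]))))
        return TSPInstance(costs=d, symmetric=True, name=name, coords=coords)
    if ewt == "EXPLICIT":
        fmt = header.get("EDGE_WEIGHT_FORMAT", "").upper()
        if fmt != "FULL_MATRIX":
            raise ValueError(f"unsupported TSPLIB EDGE_WEIGHT_FORMAT: {fmt or 'missing'}")
        vals = [float(v) for line in body for v in line.split()]
        if len(vals) != n * n:
            raise ValueError(f"expected {n * n} matrix entries, got {len(vals)}")
        c = np.asarray(vals).reshape(n, n)
        np.fill_diagonal(c, 0.0)
        return TSPInstance(costs=c, name=name)
    raise ValueError(f"unsupported TSPLIB EDGE_WEIGHT_TYPE: {ewt or 'missing'}")


def write_tsplib(instance: TSPInstance, path) -> None:
    """Write an instance as EXPLICIT / FULL_MATRIX TSPLIB."""
    n = instance.n_cities
    with open(path, "w") as fh:
        fh.write(f"NAME: {instance.name}\n")
        fh.write("TYPE: TSP\n" if instance.symmetric else "TYPE: ATSP\n")
        fh.write(f"DIMENSION: {n}\n")
        fh.write("EDGE_WEIGHT_TYPE: EXPLICIT\n")
        fh.write("EDGE_WEIGHT_FORMAT: FULL_MATRIX\n")
        fh.write("EDGE_WEIGHT_SECTION\n")
        for row in instance.costs:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")
        fh.write("EOF\n")
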