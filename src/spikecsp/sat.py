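"""Compiling k-SAT formulas into spiking networks.

Each Boolean variable X_n is represented by a two-principal-neuron
winner-take-all pair (nu_n0, nu_n1); a spike of nu_ni sets X_n = i for one
PSP duration, and the WTA auxiliary keeps exactly one of the pair active
most of the time.  Each clause gets an OR gadget on the principal neurons
whose activity makes one of its literals true, raising the energy of
states that violate the clause — so the network's energy over defined
assignments is proportional to the number of violated clauses and the
stochastic dynamics performs an incomplete stochastic local search.  An
optional internal temperature controller (duplicated, stronger OR gadgets
gated by a global neuron that is silenced while any clause is fully
violated) rescales the energy landscape once a solution is found and locks
the network into it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .motifs import ORParams, TempControlParams, WTAParams, add_or, add_temperature_control, add_wta
from .network import NetworkSpec, NeuronParams
from .simulator import StateChange, Trajectory, state_at, state_change_times

__all__ = [
    "CNFFormula",
    "SATNetworkParams",
    "SATNetwork",
    "AssignmentReadout",
    "compile_sat",
    "read_assignment",
    "solve_time",
    "satisfied_fraction_trace",
    "performance_trace_sat",
    "mean_satisfied_fraction",
    "generate_random_3sat",
    "complete_solver",
    "check_assignment",
    "read_dimacs",
    "write_dimacs",
]


@dataclass
class CNFFormula:
    """A CNF formula: clauses are tuples of nonzero signed literals
    (DIMACS convention, variables 1..n_vars; -v means NOT X_v)."""

    n_vars: int
    clauses: list[tuple[int, ...]]

    def __post_init__(self) -> None:
        for cl in self.clauses:
            vs = [abs(l) for l in cl]
            if any(l == 0 for l in cl):
                raise ValueError("literal 0 is not allowed")
            if any(v > self.n_vars for v in vs):
                raise ValueError(f"clause {cl} references a variable beyond n_vars")
            if len(set(vs)) != len(vs):
                raise ValueError(f"clause {cl} references a variable twice")

    @property
    def n_clauses(self) -> int:
        return len(self.clauses)


@dataclass
class SATNetworkParams:
    """Compiler parameters; defaults are the reference 3-SAT setting."""

    b_WTA: float = 2.0
    b_inh: float = -10.0
    w_WTA: float = -100.0
    w_exc: float = 100.0
    B: float = 40.0
    w_OR1: float = 2.5
    w_OR2: float = 10.0
    b_glob: float = 10.0
    w_glob: float = 0.5
    temp_control: bool = False


@dataclass
class SATNetwork:
    """A compiled SAT network plus its readout map.

    ``var_neurons[n] = (id of nu_n0, id of nu_n1)`` for variable n+1
    (0-based list over 1-based DIMACS variables).
    """

    net: NetworkSpec
    var_neurons: list[tuple[int, int]]
    formula: CNFFormula
    params: SATNetworkParams
    clause_targets: list[list[int]] = field(default_factory=list)

    def literal_neuron(self, lit: int) -> int:
        """Principal neuron whose activity makes the literal true."""
        v = abs(lit) - 1
        return self.var_neurons[v][1] if lit > 0 else self.var_neurons[v][0]


def compile_sat(formula: CNFFormula, params: SATNetworkParams | None = None) -> SATNetwork:
    """Compile a CNF formula into a spiking network.

    Neuron count is 3N + 2M without temperature control and
    3N + 2M + 3M + 1 with it.
    """
    params = params or SATNetworkParams()
    if formula.n_clauses == 0:
        if formula.n_vars == 0:
            raise ValueError("empty formula")
    for cl in formula.clauses:
        if len(cl) < 2:
            raise ValueError("clauses must have at least 2 literals")
    net = NetworkSpec(
        metadata={"problem": "sat", "n_vars": formula.n_vars, "n_clauses": formula.n_clauses}
    )
    wta = WTAParams(
        b_WTA=params.b_WTA, b_inh=params.b_inh, w_WTA=params.w_WTA, w_exc=params.w_exc
    )
    var_neurons = []
    for n in range(formula.n_vars):
        nu0 = net.add_neuron(NeuronParams(), principal=True)
        nu1 = net.add_neuron(NeuronParams(), principal=True)
        add_wta(net, [nu0, nu1], wta, label=f"x{n + 1}")
        var_neurons.append((nu0, nu1))
    compiled = SATNetwork(net, var_neurons, formula, params)
    orp = ORParams(B=params.B, w_OR=params.w_OR1)
    for cl in formula.clauses:
        targets = [compiled.literal_neuron(l) for l in cl]
        add_or(net, targets, orp)
        compiled.clause_targets.append(targets)
    if params.temp_control:
        violation_sets = [
            [compiled.literal_neuron(-l) for l in cl] for cl in formula.clauses
        ]
        tcp = TempControlParams(
            B=params.B,
            w_OR2=params.w_OR2,
            b_glob=params.b_glob,
            w_glob=params.w_glob,
        )
        add_temperature_control(net, compiled.clause_targets, tcp, violation_sets)
    net.metadata["var_neurons"] = var_neurons
    return compiled


# -- readout --------------------------------------------------------------------


@dataclass
class AssignmentReadout:
    """Decoded truth assignment: per-variable True/False/None (undefined),
    the number of satisfied clauses and the satisfied fraction."""

    values: list
    satisfied_clauses: int
    fraction: float


def _values_from_active(satnet: SATNetwork, active: set[int]) -> list:
    values = []
    for nu0, nu1 in satnet.var_neurons:
        a0, a1 = nu0 in active, nu1 in active
        values.append(True if (a1 and not a0) else False if (a0 and not a1) else None)
    return values


def _clauses_satisfied(satnet: SATNetwork, values: list) -> int:
    """A clause is satisfied iff some literal is true under a *defined*
    variable; clauses whose participating variables are all undefined (or
    defined the wrong way) count as unsatisfied."""
    return sum(
        1
        for cl in satnet.formula.clauses
        if any(values[abs(l) - 1] is (l > 0) for l in cl)
    )


def read_assignment(traj: Trajectory, t: float, satnet: SATNetwork) -> AssignmentReadout:
    """Decode the assignment at time ``t`` from currently active neurons.

    A variable is TRUE/FALSE iff exactly the corresponding principal
    neuron is active; undefined if neither or both.  A clause counts as
    satisfied iff at least one of its literals is true under a defined
    variable (an undefined variable satisfies nothing), so the satisfied
    fraction is well defined at every time point and a fraction of 1.0
    certifies an assignment that satisfies the formula.
    """
    principal = satnet.net.principal_ids
    x = state_at(traj, t, neurons=principal)
    active = {nid for nid, xi in zip(principal, x) if xi}
    values = _values_from_active(satnet, active)
    m = satnet.formula.n_clauses
    sat = _clauses_satisfied(satnet, values)
    return AssignmentReadout(values, sat, sat / m if m else 1.0)


def _satisfaction_scan(changes: list[StateChange], satnet: SATNetwork):
    """Yield (time, n_satisfied_clauses) after every state change.

    Incremental: per clause a count of its currently *true* literals
    (matching neuron active and partner neuron inactive); a clause is
    satisfied while that count is positive.
    """
    f = satnet.formula
    # var index and polarity of each principal neuron
    var_of: dict[int, int] = {}
    for v, (nu0, nu1) in enumerate(satnet.var_neurons):
        var_of[nu0] = v
        var_of[nu1] = v
    # clause occurrences per variable: (clause index, literal sign)
    occ: list[list[tuple[int, int]]] = [[] for _ in range(f.n_vars)]
    for ci, cl in enumerate(f.clauses):
        for l in cl:
            occ[abs(l) - 1].append((ci, 1 if l > 0 else -1))
    active = np.zeros(satnet.net.n_neurons, dtype=bool)
    true_lits = np.zeros(f.n_clauses, dtype=int)
    n_sat = 0

    def lit_true(v: int, sign: int) -> bool:
        nu0, nu1 = satnet.var_neurons[v]
        return (active[nu1] and not active[nu0]) if sign > 0 else (
            active[nu0] and not active[nu1]
        )

    for c in changes:
        v = var_of.get(c.neuron)
        if v is None:
            yield c.time, n_sat
            continue
        before = {s: lit_true(v, s) for s in (1, -1)}
        active[c.neuron] = c.on
        for ci, sign in occ[v]:
            delta = int(lit_true(v, sign)) - int(before[sign])
            if delta:
                true_lits[ci] += delta
                if delta > 0 and true_lits[ci] == 1:
                    n_sat += 1
                elif delta < 0 and true_lits[ci] == 0:
                    n_sat -= 1
        yield c.time, n_sat


def _changes(traj_or_changes) -> list[StateChange]:
    if isinstance(traj_or_changes, Trajectory):
        return state_change_times(traj_or_changes)
    return traj_or_changes


def solve_time(traj_or_changes, satnet: SATNetwork) -> float | None:
    """First time at which every clause is satisfied; None if never."""
    m = satnet.formula.n_clauses
    for t, n_sat in _satisfaction_scan(_changes(traj_or_changes), satnet):
        if n_sat == m:
            return float(t)
    return None


def satisfied_fraction_trace(traj_or_changes, satnet: SATNetwork, times) -> np.ndarray:
    """Satisfied fraction evaluated at each requested time."""
    times = np.asarray(times, dtype=float)
    order = np.argsort(times, kind="stable")
    m = satnet.formula.n_clauses or 1
    out = np.zeros(len(times))
    frac = 0.0
    ti = 0
    for t, n_sat in _satisfaction_scan(_changes(traj_or_changes), satnet):
        while ti < len(order) and times[order[ti]] < t:
            out[order[ti]] = frac
            ti += 1
        frac = n_sat / m
    while ti < len(order):
        out[order[ti]] = frac
        ti += 1
    return out


def performance_trace_sat(traj_or_changes, satnet: SATNetwork, times) -> np.ndarray:
    """Alias for :func:`satisfied_fraction_trace` (quality-of-solution trace)."""
    return satisfied_fraction_trace(traj_or_changes, satnet, times)


def mean_satisfied_fraction(
    traj_or_changes, satnet: SATNetwork, t_start: float, t_end: float
) -> float:
    """Time-weighted mean satisfied fraction over [t_start, t_end]."""
    if not t_end > t_start:
        raise ValueError("empty averaging window")
    m = satnet.formula.n_clauses or 1
    acc = 0.0
    t_prev, frac = t_start, 0.0
    for t, n_sat in _satisfaction_scan(_changes(traj_or_changes), satnet):
        if t > t_start:
            seg_hi = min(t, t_end)
            if seg_hi > t_prev:
                acc += frac * (seg_hi - t_prev)
                t_prev = seg_hi
            if t >= t_end:
                break
        frac = n_sat / m
    if t_end > t_prev:
        acc += frac * (t_end - t_prev)
    return acc / (t_end - t_start)


# -- generation and oracle --------------------------------------------------------


def generate_random_3sat(
    n_vars: int,
    ratio: float | None = None,
    n_clauses: int | None = None,
    seed: int = 0,
    require_satisfiable: bool = False,
    k: int = 3,
    solver_cap: int = 40,
) -> CNFFormula:
    """Uniform random k-SAT: each clause draws k distinct variables without
    replacement and independent random polarities.

    The clause count is ``n_clauses`` if given, else round(ratio * n_vars)
    (half away from zero).  With ``require_satisfiable`` the formula is
    rejection-sampled against the complete solver (n_vars capped).
    """
    if n_vars < 3:
        raise ValueError("need at least 3 variables")
    if n_clauses is None:
        if ratio is None:
            raise ValueError("give ratio or n_clauses")
        n_clauses = int(np.floor(ratio * n_vars + 0.5))
    if require_satisfiable and n_vars > solver_cap:
        raise ValueError(f"require_satisfiable capped at {solver_cap} variables")
    rng = np.random.default_rng(seed)
    while True:
        clauses = []
        for _ in range(n_clauses):
            vs = rng.choice(n_vars, size=k, replace=False) + 1
            signs = rng.integers(0, 2, size=k) * 2 - 1
            clauses.append(tuple(int(v * s) for v, s in zip(vs, signs)))
        formula = CNFFormula(n_vars, clauses)
        if not require_satisfiable:
            return formula
        sat, _ = complete_solver(formula, cap=solver_cap)
        if sat:
            return formula


def check_assignment(formula: CNFFormula, values: list[bool]) -> bool:
    """True iff the assignment satisfies every clause."""
    if len(values) != formula.n_vars:
        raise ValueError("assignment length mismatch")
    return all(
        any((l > 0) == values[abs(l) - 1] for l in cl) for cl in formula.clauses
    )


def complete_solver(formula: CNFFormula, cap: int = 40):
    """DPLL with unit propagation: exact satisfiability decision.

    Returns ``(True, witness)`` with a verified satisfying assignment, or
    ``(False, None)``.
    """
    if formula.n_vars > cap:
        raise ValueError(f"complete solver capped at {cap} variables")

    def propagate(clauses, assign):
        clauses = list(clauses)
        changed = True
        while changed:
            changed = False
            new = []
            for cl in clauses:
                vals = [assign.get(abs(l)) for l in cl]
                if any(v is not None and (l > 0) == v for l, v in zip(cl, vals)):
                    continue  # satisfied
                rem = [l for l, v in zip(cl, vals) if v is None]
                if not rem:
                    return None  # conflict
                if len(rem) == 1:
                    assign[abs(rem[0])] = rem[0] > 0
                    changed = True
                else:
                    new.append(tuple(rem))
            clauses = new
        return clauses

    def dpll(clauses, assign):
        clauses = propagate(clauses, assign)
        if clauses is None:
            return None
        if not clauses:
            return assign
        # branch on the first literal of the shortest clause
        lit = min(clauses, key=len)[0]
        for val in ((lit > 0), not (lit > 0)):
            trial = dict(assign)
            trial[abs(lit)] = val
            res = dpll(clauses, trial)
            if res is not None:
                return res
        return None

    res = dpll([tuple(cl) for cl in formula.clauses], {})
    if res is None:
        return False, None
    values = [res.get(v, True) for v in range(1, formula.n_vars + 1)]
    assert check_assignment(formula, values), "solver returned a non-satisfying witness"
    return True, values


# -- DIMACS I/O --------------------------------------------------------------------


def read_dimacs(path) -> CNFFormula:
    """Read a DIMACS CNF file ('p cnf N M' header, 0-terminated clauses)."""
    n_vars = n_clauses = None
    clauses: list[tuple[int, ...]] = []
    current: list[int] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("c") or line.startswith("%"):
                continue
            if line.startswith("p"):
                parts = line.split()
                if len(parts) != 4 or parts[1] != "cnf":
                    raise ValueError(f"malformed DIMACS problem line: {line!r}")
                n_vars, n_clauses = int(parts[2]), int(parts[3])
                continue
            for tok in line.split():
                lit = int(tok)
                if lit == 0:
                    clauses.append(tuple(current))
                    current = []
                else:
                    current.append(lit)
    if n_vars is None:
        raise ValueError("missing 'p cnf' header")
    if current:
        raise ValueError("unterminated clause at end of file")
    if len(clauses) != n_clauses:
        raise ValueError(f"header promises {n_clauses} clauses, found {len(clauses)}")
    return CNFFormula(n_vars, clauses)


def write_dimacs(formula: CNFFormula, path, comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if comment:
            fh.write(f"c {comment}\n")
        fh.write(f"p cnf {formula.n_vars} {formula.n_clauses}\n")
        for cl in formula.clauses:
            fh.write(" ".join(str(l) for l in cl) + " 0\n")
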