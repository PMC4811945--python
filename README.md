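# spikecsp

Stochastic spiking networks that solve constraint satisfaction problems by
neural sampling.

Networks of stochastically firing spiking neurons with symmetric weights
sample from a Boltzmann distribution over their binary network states,

    p(x) ∝ exp(−E(x)),    E(x) = −Σ_k b_k x_k − ½ Σ_kl w_kl x_k x_l ,

where `x_k(t) = 1` iff neuron k fired within the last PSP duration τ.
That makes the energy function a programming language: compose a network
out of circuit motifs that each add a known term to E(x), and the noisy
spiking dynamics performs stochastic search for low-energy states — i.e.
for solutions of a constraint satisfaction problem.  `spikecsp` implements
this framework end to end:

- **`simulator`** — exact event-driven simulation of networks of neurons
  with firing intensity `exp(u)/τ`, rectangular PSPs, refractory periods,
  and per-synapse transmission delays.  Fully reproducible from a seed.
- **`energy`** — energy functions, exact stationary distributions for small
  networks (≤ 20 units), temperature scaling E/T, the membrane potential
  demanded by the neural computability condition, analytical event-rate
  laws, energy-jump histograms and undefined-variable statistics.
- **`motifs`** — winner-take-all (multinomial problem variables), OR
  (disjunctive clauses), and an internal spike-based temperature controller
  that locks the network into solutions once found.
- **`tsp`** — compiles traveling-salesman instances (TSPLIB EUC_2D /
  FULL_MATRIX, or generated) into spiking networks, reads tours out of
  spike trains, and ships brute-force and Held–Karp oracles.
- **`sat`** — compiles k-SAT formulas (DIMACS CNF, or generated random
  3-SAT) into spiking networks, with optional temperature control, plus a
  DPLL complete solver as oracle.
- **`gibbs`** — a matched continuous-time Boltzmann machine (Gibbs sampler)
  over the same energy function, for comparing spike-based and Gibbs
  stochastic search (the spiking dynamics crosses high energy barriers far
  more often, because PSP expiry forces every active neuron off after τ
  regardless of how deep the state is).

## Worked example

```python
from spikecsp import sat, simulate

formula = sat.generate_random_3sat(20, ratio=4.3, seed=3, require_satisfiable=True)
satnet = sat.compile_sat(formula, sat.SATNetworkParams(temp_control=True))
print("neurons:", satnet.net.n_neurons, " synapses:", satnet.net.n_synapses)

traj = simulate(satnet.net, t_end=10.0, seed=1)
st = sat.solve_time(traj, satnet)
print(f"solve time: {st:.3f} s")

r = sat.read_assignment(traj, st, satnet)
print("assignment verifies:",
      sat.check_assignment(formula, [bool(v) for v in r.values]))
print(f"mean satisfied fraction over the 5 s after the solve: "
      f"{sat.mean_satisfied_fraction(traj, satnet, st, st + 5.0):.4f}")
```

prints

```
neurons: 491  synapses: 2872
solve time: 0.020 s
assignment verifies: True
mean satisfied fraction over the 5 s after the solve: 1.0000
```

A 20-variable random 3-SAT instance at the hard clause/variable ratio 4.3
compiles to 491 neurons (three per variable, two per clause, and 3M + 1
temperature-control neurons).  The network finds a verified satisfying
assignment after 20 ms of simulated time, and the temperature controller
then locks it in: every clause stays satisfied for the rest of the run.
Without `temp_control=True` the network keeps searching and jumps out of
solutions again (compare `mean_satisfied_fraction` of the two variants).

The same workflow is available from the shell:

```
spikecsp generate-sat --n 20 --ratio 4.3 --seed 3 --require-satisfiable --out f.cnf
spikecsp solve-sat --cnf f.cnf --temp-control --t-end 10 --seed 1 --out run/
spikecsp generate-tsp --n 6 --seed 42 --out toy.tsp
spikecsp solve-tsp --instance toy.tsp --n-resting 2 --t-end 20 --seed 1 --out run2/
spikecsp compare --instance toy.tsp --cost-threshold 2.5 --runs 20 --out cmp/
```

Every run writes a config snapshot, the spike log (JSONL), trace CSVs and a
JSON summary, and is exactly replayable from its saved config and seed.
TSPLIB files (EUC_2D and explicit full-matrix, including asymmetric
instances) are accepted directly by `solve-tsp`.

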