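# Methods

## Neuron model and exact event-driven simulation

A neuron `k` fires stochastically with instantaneous intensity
`exp(u_k(t)) / tau`, where the membrane potential

    u_k(t) = b_k + sum_l w_kl x_l(t)

is its bias plus the weighted sum of currently active presynaptic inputs.
`x_l(t)` is the *indicator* that neuron `l` fired within the last PSP
duration (shifted by the synaptic transmission delay where one is set):
PSPs are rectangular and binary, so two overlapping windows from the same
presynaptic neuron contribute the weight once, not twice.  This matters
only when a neuron's refractory period is shorter than its PSP duration —
the temperature-control global neuron (9 ms refractory, 11 ms outgoing
PSPs) is the one such neuron in this package, and treating its PSPs
additively would double its drive during the 2 ms overlap and break the
temperature controller.  After a spike the neuron is refractory for
`refractory_period` seconds (default: one PSP duration, 10 ms); the
refractory period blocks spiking only, not synaptic integration.

Between events every membrane potential is piecewise constant, so the
waiting time to a neuron's next candidate spike is exactly exponential,
`tau * exp(-u_k) * E` with `E ~ Exp(1)`.  The simulator keeps one candidate
per neuron and a heap of deterministic events (delayed PSP onsets, PSP
offsets, refractory expirations); the earliest pending event is committed
and, by memorylessness, only neurons whose potential changed are redrawn.
No time discretization or thinning is involved — the simulation is exact.
Simultaneous events are committed in the order (time, PSP-offset before
PSP-onset before refractory-expiry before spike, insertion order), making
every trajectory a deterministic function of (network, duration, seed,
initial state).  Exact ties have probability zero for continuous draws and
arise only through delay-induced alignments.  Membrane potentials around
±100 (winner-take-all clamps) are handled in plain double precision;
`exp(-u)` underflows to an immediate-spike candidate only beyond u ≈ 745,
and a guard rejects non-finite potentials.  An optional initial active set
is realized as recorded spikes at t = 0.

## Energy function and stationary distribution

With symmetric weights, zero delays, and refractory = PSP duration, the
binary network state `x(t)` (which neurons fired within the last tau) is a
Markov process whose stationary distribution is Boltzmann,
`p(x) ∝ exp(-E(x))` with

    E(x) = - sum_k b_k x_k - 1/2 sum_kl w_kl x_k x_l .

`boltzmann_exact` enumerates this for up to 20 units;
`empirical_distribution` estimates it from a trajectory as time-weighted
occupancy (not event-weighted) after a default burn-in of 1 s of simulated
time.  Marginalizing auxiliary units uses
`E(x) = -log sum_xi exp(-E(x, xi))`; the marginal table is reported shifted
to minimum 0 since the energy is defined only up to an additive constant.
Temperature scaling divides biases and weights by T.

The *neural computability condition* ties the two views together: the
membrane potential of unit k must equal the conditional log-odds
`log p(x_k=1|rest) - log p(x_k=0|rest)`, which for a second-order energy is
exactly the linear sum above (verified against enumeration in the tests).

## Spiking versus Gibbs transition statistics

A continuous-time Gibbs sampler over the same energy model flips unit k on
at rate `rho0 * sigma(u_k)` and off at `rho0 * sigma(-u_k)`; detailed
balance gives it the same stationary distribution.  The mean state-change
rates differ structurally: `(2/tau) * sigma(u)` for the spiking neuron
(deterministic on-period tau, exponential off-period `tau * exp(-u)`)
versus `2 rho0 / (2 + exp(u) + exp(-u))` for the Gibbs unit.  Their ratio
`(1 + exp(u)) / (tau * rho0)` grows monotonically with u: the spiking
sampler keeps changing state exactly where the Gibbs sampler freezes (large
|u|, i.e. deep local structure), which is why it crosses high energy
barriers and visits states with undefined problem variables far more often.
Energy-jump histograms are computed over the principal energy model only
(auxiliary activity enters through the dynamics, not the measured energy),
with default unit-width bins on [-40, 40] plus under/overflow counters and
the raw jumps retained for threshold queries.

## Circuit motifs

*WTA*: one inhibitory auxiliary per group (bias −10) with principal→aux
weight +100 and aux→principal weight −100.  The auxiliary fires essentially
immediately after any group member and suppresses the group for one PSP,
so states with exactly one active member dominate.

*OR*: auxiliary I (bias 0.5B) excites the clause's target neurons with
`w_OR` and is suppressed by −B from each active target; auxiliary II (bias
−3.5B, driven 3B by I and +B by targets) applies −`w_OR` as soon as one
target fires, retracting the excitation so the gadget raises the energy of
the all-targets-inactive states without biasing which target stays active.
B = 40 throughout.

*Temperature control*: per clause a duplicate OR gadget (III: bias −0.5B,
IV: bias −6.5B, weights ±`w_OR2` with `w_OR2 = 10` versus the base
`w_OR1 = 2.5`) gated by one global neuron (bias 10, refractory 9 ms,
11 ms PSPs to III/IV so its drive is gapless while it respikes): while the
global neuron is active, III/IV receive +B and +3B and behave exactly like
I/II, multiplying the clause penalty by `w_OR2/w_OR1` — an effective
temperature drop.  One status neuron per clause (bias −2.5B) receives +B
from the three principal neurons encoding the *negations* of the clause's
literals — with a −2.5B bias it can reach threshold only when all three
are active, i.e. exactly when the clause is fully violated — and inhibits
the global neuron with −3B (strong enough that a single active status
neuron silences it).  The global neuron also excites every principal
neuron with `w_glob` (default 0.5), mildly sharpening the winner-take-all
races in the low-temperature regime; lock-in quality is insensitive to
`w_glob` in the 0–6 range because the locking comes from the strong clause
gadgets, not from the bias shift.

## Problem compilers

*TSP*: `N' = N + N_resting` WTA modules of N principal neurons (one per
city), ring-connected.  Adjacent modules get symmetric weights
`w_offset + (1 - c~_ij) * w_scale` for i ≠ j, with costs normalized by the
maximum off-diagonal cost; same-city adjacent pairs are left unconnected
(resting steps are free).  Same-city pairs in non-adjacent modules get
`w_unique` (strongly negative).  Step 1 is pinned to city 1 via biases
`b_P = 100` / `b_N = -100`.  Defaults are the planar reference setting
(`b_WTA = -0.45`, `w_unique = -14.7`, `w_scale = 19.4`, `w_offset = -5`,
7 resting steps); `TSPNetworkParams.asymmetric_defaults()` carries the
asymmetric setting (`b_WTA = 1.3`, `w_unique = -14.1`, `w_offset = -7.9`,
`w_scale = 20.8`, 8 resting steps).  Neuron count is
`(N+1)(N+N_resting)`.  The closed-form connection count for this
architecture, `N (N+N_resting)(2N+N_resting-2)`, counts each symmetric
adjacent-module cost pair once (the pair shares a single weight value)
while counting WTA and uniqueness connections per direction;
`TSPNetwork.connection_count()` reports that accounting (the network
itself stores directed synapses).

Tour readout takes, per module, the city of the most recently fired
principal neuron (even if its PSP has expired; a currently-active variant
is available for cross-checks and is used for Gibbs flip sequences).
Consecutive duplicates are collapsed cyclically; a tour is valid iff every
module is defined and the collapsed sequence is a permutation of the
cities.  Resting steps carry no cost.

*k-SAT*: one two-principal WTA per variable (`b_WTA = 2`), one OR gadget
per clause on the neurons whose activity makes its literals true, plus the
optional temperature controller.  Neuron counts: `3N + 2M`, plus `3M + 1`
with control; synapse counts `4N + 13M`, plus `19M + 2N` with control
(19 per clause: 13 for the duplicate gadget and its global gating, 4 for
the status neuron, plus the status→global synapse; the count is reported
from the constructed network).  A
variable reads TRUE/FALSE iff exactly the corresponding principal neuron
is active; a clause counts satisfied iff at least one literal is true
under a *defined* variable, so the satisfied fraction is well defined at
every instant, equals 1.0 only for verified satisfying assignments, and
undefined variables satisfy nothing (the all-neurons-fire startup
transient therefore does not register as a solution).

## Gibbs baseline construction

`spiking_model_to_gibbs` offers three mappings.  `principal` extracts the
(required symmetric) principal subnetwork.  `lateral` (default for
compiled networks) additionally replaces each WTA auxiliary by direct
symmetric inhibition of the auxiliary's outgoing strength between all
group members — the auxiliary's function in closed form — so the baseline
sampler retains a working winner-take-all constraint; averaging the
auxiliary's ±100 in/out weights instead would zero them and leave the
baseline unable to represent tours at all.  `full` keeps every neuron and
symmetrizes by the arithmetic mean, preserving the unit count at the price
of averaging away purely asymmetric couplings.  The comparison harness
reports which mapping was used.  Search-efficiency comparisons count state
changes (spikes plus PSP offsets for the spiking network, flips for the
Gibbs sampler) to reach a tour-cost threshold, excluding runs that never
reach it within the budget (default 100,000 state changes), and apply a
two-sample Kolmogorov–Smirnov test.

## Synthetic instances

Planar TSP instances are uniform points in the unit square with Euclidean
costs (so they satisfy the triangle inequality); asymmetric instances draw
each ordered pair's cost uniformly from (0, 1].  Random 3-SAT draws, per
clause, 3 distinct variables without replacement and independent
polarities; the clause count is `round(ratio * N)` with ratio 4.3 by
default (near the satisfiability crossover), and `require_satisfiable`
rejection-samples against the built-in DPLL solver (capped at 40
variables).  Allowing duplicate/tautological literals would match a purely
literal-uniform reading of the model but deviates from the standard random
3-SAT ensemble that the crossover ratio refers to.  These generators
emulate the *structure* of benchmark instances, not any particular named
instance; conclusions about specific TSPLIB problems require loading the
corresponding files through `read_tsplib`.

## Problem sizes used in the test suite

Stationarity and rate-law checks use single neurons and a seeded 6-unit
symmetric model with ≥ 10^5 events after 1 s burn-in (tolerances: TV 0.02,
rates 5%).  Solution recovery uses a seeded 6-city planar instance with 2
resting steps, 10 runs of 20 s (≥ 8 must recover the brute-force optimum);
3-SAT uses a seeded satisfiable 20-variable, ratio-4.3 instance, 10 runs
of 10 s with and without temperature control.  The energy-jump contrast
uses a seeded 10-city instance with 50,000 spikes versus 100,000 Gibbs
flips.  These are scaled down relative to the benchmark-size networks the
compilers target (38/39 cities, 50 variables) so the full suite runs in a
few minutes; the mechanisms under test are size-independent, but absolute
solve times and jump histograms of course are not.

## Known limitations

- Only rectangular PSPs: other kernels lose the exact stationary
  distribution, so they are deliberately unsupported.
- The modularity of motif energy contributions is exact only in the limit
  of instantaneous auxiliary responses; empirically, cross-motif
  interference on a two-principal toy network is below 0.1 energy units
  for moderate motif strengths (tested), but grows with motif strength.
- The spiking SAT solver is incomplete by construction: it can certify
  satisfiability (every reported solution is checked against the formula)
  but can never prove unsatisfiability.
- `state_change_times` pairs each spike with an off-entry one PSP later;
  for neurons with refractory < PSP duration the binary state itself stays
  1 across overlapping windows, so on/off entries strictly alternate only
  under the default refractory = PSP setting.
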