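# Methods

## The triplet motif and its expansion

Every condensed node represents one molecule with three interconvertible
forms `x_0` (inactive), `x_1` (intermediate), `x_2` (active), as produced
by two sequential post-translational modifications. An influence edge acts
purely catalytically through one *pole* of its source — the active form
(pole 2) by default, the inactive form (pole 0) where the opposing state is
the agent, as in the self-inhibition of the AM node. Activation adds the
catalysed conversions `t_0→t_1`, `t_1→t_2`; inhibition adds `t_2→t_1`,
`t_1→t_0`; the catalyst appears unchanged on both sides. Consequences used
throughout:

- every expanded reaction is bimolecular, so uniform scaling of all
  concentrations by c is equivalent to speeding time up by c (verified as a
  property test for c ∈ {0.5, 2, 10});
- each node's three forms are strictly conserved; per-node totals are a
  left-null-space basis of the stoichiometric matrix;
- expanding one node with one self-activation (pole 2) and one
  self-inhibition (pole 0) yields exactly the four approximate-majority
  rules under X=x_2, B=x_1, Y=x_0.

Concentrations are dimensionless with default per-node total 1; rates are
per concentration per time. Clamped species are constant inputs: they are
carried in the state vector but their derivative is forced to zero and SSA
never changes their counts.

The solid/dashed line style of the usual wiring diagrams is ambiguous about
which pole acts; all encodings here are fixed at the reaction level by
requiring the documented validation property of each model (AM's expansion
must equal the four protocol rules, the bundled morphisms must certify),
not by line style.

## Signed graphs and feedback loops

Two graph views exist. The *condensed* view has one node per molecule and
one signed edge per influence (+ for activation, − for inhibition). The
*extremal* view has one vertex per extremal form; an activation catalysed
by form c contributes c→t_2 (+) and c→t_0 (−), an inhibition the reverse.
The extremal view is the wiring-diagram picture in which the AM node shows
its decided-state antagonism: two autocatalytic extremal forms that
mutually suppress each other — three positive loops (two pure, one
double-negative), zero negative. Loops are simple directed cycles; a
cycle's sign is the parity of its negative edges; parallel edges of
opposite sign yield distinct loops. Enumeration uses networkx simple
cycles expanded over parallel signed edges and is cross-checked against a
brute-force DFS oracle on random graphs of up to 8 nodes.

## Model library

All switch models run at unit rates. Wirings (act/inh, catalyst pole 2
unless noted):

- **AM** — one node: self-act, self-inh (pole 0).
- **MI / PAR** — two nodes, each self-activating, mutually inhibiting
  through their active forms. PAR is the same topology under
  polarity-complex names.
- **SI** — two nodes, mutual activation through the active forms
  (double-positive loop) and mutual inhibition through the inactive forms
  (double-negative loop).
- **EPI** — one nucleosome node (methylated = active pole, acetylated =
  inactive pole); identical in structure to AM.
- **CC** — Cdk, Cdc25, Wee1 with Cdc25→act→Cdk, Wee1→inh→Cdk,
  Cdk→act→Cdc25, Cdk→inh→Wee1, plus constant inputs i→inh→Cdc25 and
  a→act→Wee1 standing in for an unregulated counteracting phosphatase.
  Input level a = i = 0.25: at this level the default undecided state
  switches decisively upward while the constant opposition keeps the upper
  steady state visibly below the maximum (cdk_2 ≈ 0.93, cdc25_2 ≈ 0.75);
  at 1.0 the same initial state falls into the low-Cdk basin instead.
- **GW** — CC without the constant inputs; a PP node (PP1/PP2A) takes
  their role: PP→act→Wee1, PP→inh→Cdc25, Cdk→inh→PP (the
  Greatwall route), PP→act→PP. Under the map (cdk→x, cdc25→x, ~wee1→x,
  ~pp→x) — `~` meaning orientation reversal, active Wee1/PP corresponding
  to the opposing decided state — all 16 reactions project onto the 4 AM
  rules and the stoichiometric balance holds, so GW emulates AM exactly.
- **GWO_A / GWO_B** — GW embedded in the Cdc20/APC negative feedback:
  Cdk→act→Cdc20, Cdc20→inh→Cdk (cyclin degradation), a constant input
  e→inh→Cdc20 (APC reset) and a constant input s→act→Cdk (cyclin
  synthesis; in a conserved triplet encoding degradation-plus-resynthesis
  must appear as an inhibition plus a constant activation, and without the
  restoring drive the low-Cdk state is absorbing, so no variant could
  cycle). Variant B replaces PP autocatalysis with Cdc20→act→PP.

### Oscillator parameters

The two Cdc20-turnover edges run at rate 0.3 against the unit-rate switch,
with e = 0.4 and s = 0.2. The separation of timescales is what makes the
negative loop read the switch quasi-statically: at unit Cdc20 turnover the
coupled system settles into an intermediate fixed point instead of
cycling. With these values variant A locks into the high-PP/low-Cdk state
(the PP autocatalysis maintains phosphatase activity after Cdc20 falls —
no oscillation), while variant B, where phosphatase activity collapses
once Cdc20 is reset, shows a relaxation limit cycle of period ≈ 111 time
units and peak-to-trough Cdk amplitude ≈ 0.7. Both verdicts are unchanged
when the simulation horizon doubles from 1000 to 2000, which is the
robustness notion used in the tests.

### Initial conditions

The default "undecided" state splits each node's total as
(0.33, 0.33, 0.34) over (inactive, intermediate, active). Equal thirds is
an unstable fixed point of every bundled switch; the 1% active-form
surplus makes a simulation started undecided actually decide, without
materially changing the transient. Emulation checks never use this
default: they draw target initial conditions uniformly from [0, 1] per
species and pull them back through the species map.

## Simulation

**Deterministic.** `solve_ivp` with LSODA (stiffness-switching), default
`rtol 1e-9`, `atol = rtol·1e-3`, output on a uniform grid (default 500
points, t_end 50 for switch demos; 4000 points, t_end 1000 for oscillator
runs — chosen to resolve ≥ 4 post-transient periods). Per-node totals are
preserved to better than 1e-6 relative along every tested trajectory.
Integration failures raise, never pass silently.

**Stochastic.** Exact Gillespie direct method over integer counts.
Propensity of a bimolecular reaction is rate·n_i·n_j, and rate·n·(n−1) for
two identical reactants (distinct ordered pairs; no bundled network needs
it, but the simulator is correct for networks that do). A run terminates
at an absorbing state (all propensities zero) or at `max_events`, in which
case the partial trace is flagged. Replicates draw their seeds from
`numpy.random.SeedSequence(seed)`, so each run is independently
reproducible. For the AM protocol every run absorbs at consensus: any
state with undecided agents or with both decided species present has an
enabled reaction.

The SSA at counts (600, 0, 400) is compared with the mass-action ODE at
the same scale: means over 200 replicates stay within 3 Monte-Carlo
standard errors of the ODE across the whole transition, and the worst
absolute gap stays below 0.5% of the population. At much higher replicate
counts the comparison resolves the small systematic finite-size gap
between the mean of the stochastic process and its mean-field limit
(order 1/N, concentrated at the transition), which is a property of the
process, not a simulator error; the replicate count is chosen so the
statistical envelope, not that bias, dominates.

## Trajectory analyses

**Oscillation detection.** The first half of the trace (settle_frac 0.5)
is discarded. Peaks and troughs come from `scipy.signal.find_peaks` with
prominence 5% of the analysed range. Sustained requires ≥ 4 peaks whose
heights vary by < 10% *of the oscillation amplitude* (mean peak minus mean
trough — judging the spread against the mean level would let a decaying
ripple on a large offset pass) and inter-peak intervals varying < 10% of
their mean. Period is the mean interval, amplitude the mean peak-to-trough
difference. The thresholds are package choices; the models they classify
sit far on either side of them.

**Distinct traces.** Species are partitioned by sup-norm closeness
(< tol, default 1e-6) with transitive closure (connected components of the
overlap relation). From equal initial conditions MI, PAR and SI each show
3 classes among 6 species: the two nodes move in lockstep.

**Hysteresis scans.** A clamped input is swept across a value list; each
point relaxes to steady state (‖f‖∞ < 1e-9, or t_max 2000 with the
residual reported) starting from the previous point's endpoint, so up- and
down-sweeps track their own branch. For CC swept in i, the branches
disagree over an interval (the down branch stays at cdk_2 = 0, which is
itself a fixed point at any input since the network has no constant
activator) — the all-or-none bistability of the switch.

## Morphism checking

The stoichiomorphism condition is implemented as the per-(species, target
reaction) balance given in the README. Its ground truth is the
vector-field oracle: at random nonnegative target states, after setting
each source species to its image's value, the source derivative of s must
equal the target derivative of m(s). Checker and oracle are verified to
agree (pass ⇔ residual < 1e-10) on all bundled morphisms, deliberately
broken variants, and random network/map fixtures.

Emulation verification integrates both networks from pulled-back initial
conditions at rtol 1e-9 and takes the sup-norm deviation on the common
grid; the 1e-6 verdict threshold separates true emulations (machine
precision here, since the collapsed source equations are arithmetically
identical to the target's) from non-emulations (≫ 1e-3) by many orders of
magnitude. Perturbing any single source rate by 10% breaks both the
structural check and the trajectory overlap.

`solve_source_rates` exploits that the balance is linear in the source
rates once the reaction map is fixed: a nonnegative least-squares solve
(`scipy.optimize.nnls`) either recovers exact rates (residual ≤ 1e-9,
re-verified by the oracle) or reports the violated constraints.
`find_emulations` enumerates all triplet-respecting species maps (each
source node to a target node, preserving or reversing orientation; clamped
inputs only onto clamped inputs) and returns the certified ones — for
MI→AM exactly the two mirror maps, for CC→AM none, since the clamped
inputs a, i have no admissible image and the reactions they catalyse
cannot be projected.

## Random fixtures

`generate_random_inet` emulates the *structural* class the bundled models
live in — every node carries at least one activation and one inhibition,
mandatory self-edges follow the autocatalysis convention, extra edges are
Bernoulli per (source, pole, effect, target) slot — so property tests
exercise expansion, conservation, loop enumeration and the checker/oracle
agreement on it. It does not emulate biological plausibility: no
degree/sparsity statistics, no guarantee of bistability or of emulating
AM, and unit rates throughout. Tests passing on these fixtures certify
the algebra and the simulators, not the biology of any particular random
wiring.

## Known limitations

- Kinetics are mass-action only; no Hill or Michaelis–Menten laws, at most
  two reactants per reaction.
- Emulation is exact-only; approximate (epsilon) emulation is out of
  scope, as are stochastic-distribution comparisons — AM and GW provably
  differ in their transient copy-number distributions even though their
  deterministic kinetics coincide.
- The hysteresis scan is a quasi-static sweep, not a continuation method:
  it finds coexisting attractors reachable from the sweep history, without
  locating bifurcation points precisely.
- The exhaustive emulation search is restricted to triplet-respecting maps
  and is exponential in the number of source nodes (guarded by
  `max_species`).
- Larger published cell-cycle encodings (e.g. the extended NCC network)
  are not bundled; user-supplied `.inet` files are accepted by every tool,
  but no behaviour is guaranteed for them.
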