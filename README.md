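# switchnet

Biological switches as chemical reaction networks: expand condensed
influence networks into mass-action kinetics, simulate them
deterministically and stochastically, and *prove* — by structural network
morphisms — that seemingly different switches have exactly the same
dynamics.

## The problem

All-or-none cellular decisions (the G2/M transition of the cell cycle,
epigenetic memory, cell polarity, septation initiation) are driven by
networks of interlocked positive feedback loops. These networks look very
different on paper, yet at equal kinetic rates they produce *identical*
time courses. The common core is the **approximate-majority (AM)
population protocol**: two decided agent states X and Y and an undecided
state B, with four bimolecular rules at unit rates

```
X + Y -> X + B      X + B -> X + X
X + Y -> B + Y      B + Y -> Y + Y
```

which drive any mixed population to an all-X or all-Y consensus, the
initial majority winning with high probability. `switchnet` ships the
protocol, a library of biological switch models encoded in a condensed
influence notation, and the machinery to compare them.

**Condensed notation.** A node x stands for three species x_0, x_1, x_2
(inactive, intermediate, active — e.g. phosphoforms of a multi-site
substrate). An influence edge acts catalytically through one extremal form
of its source: activation drives the target up the chain (x_0→x_1→x_2),
inhibition down, two catalytic bimolecular reactions per edge. Expansion of
a node with one self-activation (via x_2) and one self-inhibition (via x_0)
reproduces the four AM rules exactly.

**Morphisms.** For reaction networks S → S′, a species-and-reaction map m is

- a **homomorphism** if every reaction's reactant and product multisets are
  preserved under m;
- a **stoichiomorphism** if for every source species s and target reaction
  r′:  Σ_{r ↦ r′} rate(r)·netstoich(s, r) = rate(r′)·netstoich(m(s), r′);
- an **emulation** if, for every target initial condition, starting each
  source species at its image's value makes every source trajectory
  coincide exactly with its image's trajectory.

Homomorphism + stoichiomorphism ⇒ emulation. Both conditions are checked
symbolically on the network, backed by an independent numerical oracle
(vector-field equality at random states) and trajectory-level verification.

## Bundled models

| id | description | relation to AM |
|----|-------------|----------------|
| AM | the protocol as one condensed node | — |
| MI | two autocatalytic, mutually inhibiting species | emulates AM |
| PAR | polarity establishment (same topology as MI) | emulates AM |
| SI | septation-initiation asymmetry (double-positive + double-negative loops) | emulates AM |
| EPI | nucleosome modification switch | isomorphic to AM |
| CC | classical G2/M module (Cdk, Cdc25, Wee1, constant inputs a/i) | fails structurally |
| GW | CC extended with the Greatwall-regulated PP1/PP2A phosphatase | emulates AM |
| GWO_A | GW in the Cdc20 negative-feedback loop, autocatalytic PP | no oscillation |
| GWO_B | same, PP activated by Cdc20 instead | limit-cycle oscillator |

## Worked example

```python
from switchnet import *
from switchnet.morphism import *

am = library("AM"); am_net = expand(am)
gw = library("GW"); gw_net = expand(gw)

smap = parse_node_map("cdk -> x\ncdc25 -> x\n~wee1 -> x\n~pp -> x", gw, am)
m, report = check_morphism(smap, gw_net, am_net)
print("homomorphism:", report.is_homomorphism)
print("stoichiomorphism:", report.is_stoichiomorphism)

er = verify_emulation(m, gw_net, am_net, n_random=20, seed=0)
print("max trajectory deviation:", er.max_deviation)

loops = enumerate_feedback_loops(extremal_influence_graph(am))
print("AM loops:", sum(l.sign == '+' for l in loops), "positive,",
      sum(l.sign == '-' for l in loops), "negative")

cs = consensus_stats(am_protocol(), {"X": 60, "B": 0, "Y": 40},
                     replicates=1000, seed=1)
print("majority wins:", cs.frac_x_wins, " parallel time:", cs.parallel_time)
```

prints

```
homomorphism: True
stoichiomorphism: True
max trajectory deviation: 4.440892098500626e-16
AM loops: 3 positive, 0 negative
majority wins: 0.975  parallel time: 2.71056
```

The 12-species Greatwall cell-cycle switch maps onto the 3-species protocol
(`~` marks nodes mapped with reversed orientation: active Wee1 and PP
correspond to the opposing decided state); both structural checks pass, so
its trajectories collapse onto AM's exactly — the measured sup-norm
deviation over 20 random initial conditions is at machine precision. The
decided-state wiring diagram of AM carries three positive and no negative
feedback loops, and from a 60:40 split the stochastic protocol reaches
consensus in ~2.7 interactions per agent with the majority winning 97.5%
of the time.

The same functionality is available from the shell:

```
switchnet library --list
switchnet expand GW -o gw.crn
switchnet simulate MI --t-end 30 --out mi.csv
switchnet ssa am_protocol --counts X=60,B=0,Y=40 --seed 1 --reps 1000
switchnet loops AM
switchnet verify-emulation GW AM gw_am.map --random-ics 20
switchnet scan CC --clamp i --from 0 --to 1.5 --steps 16   # hysteresis
switchnet demo                                             # all headline results
```

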