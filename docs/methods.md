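# Methods

## Model

The simulator evolves a population of `N = side²` agents on a toroidal
square lattice with von Neumann adjacency (degree κ = 4, periodic
boundaries, fully populated).  An agent's heritable state is the pair
`(s, α)`: the strategy bit `s` (0 = cooperate, 1 = defect) and an
abstention probability `α` restricted to the 2κ + 1 = 9 evenly spaced
levels `{0, 1/8, …, 1}`.  α is stored as a grid *index*, so imitation
copies are bit-exact and the level set is closed under the dynamics: no
update rule can create a level that was not present initially.

A realised interaction between x and y first draws one abstention Bernoulli
per endpoint (probability α of abstaining).  If either abstains, both
receive the loner's payoff `L`; otherwise the pair payoff comes from the
matrix `(C,C) → (R,R)`, `(C,D) → (S,T)`, `(D,C) → (T,S)`, `(D,D) → (P,P)`.
The effective cooperation rate `ε = (1 − s)(1 − α)` is the per-agent
probability of cooperating *and* playing; population means of ε, α, the
strategy fractions and the α-level occupancies are the recorded
observables.

### Synchronous updating

Each Monte Carlo (MC) step every undirected edge is realised exactly once —
one abstention draw per endpoint, payoffs credited to both — so every
agent's utility is a sum of exactly κ payoffs, each in `{P, S, L, R, T}`.
All agents then update simultaneously: agent x adopts the `(s, α)` of the
neighbour with the strictly largest utility, but only if that utility
strictly exceeds both x's own utility and every other neighbour's.  Any tie
at the neighbourhood maximum — between neighbours, or between the best
neighbour and x itself — leaves x unchanged.  Realising each edge once per
pair (rather than once per direction) avoids stochastic double-counting of
the same encounter; the alternative would only fatten the utility noise.

The freeze-on-tie reading is deliberate and load-bearing.  Because payoffs
are short sums over `{0, L, 1, T}`, exact utility ties are common, and the
conservative rule is what preserves the characteristic two-level stationary
α support under synchronous updating; a variant that adopts from tied
neighbours whenever they carry identical states collapses the population
onto a single α level (we verified this empirically and exposed no such
option).  A consequence worth knowing: a lone cooperator in a sea of
defectors (with every α = 0) is *frozen* — its four exploiting neighbours
tie at `u = T` — so heterogeneous absorbing states exist.

### Asynchronous updating

Each MC step performs N elementary moves, drawing the focal site uniformly
with replacement ("each agent is selected once on average").  A move
realises the focal agent x's four interactions afresh (utility `u_x`),
picks one neighbour y uniformly, realises y's four interactions likewise
(`u_y`), and — only if `u_y > u_x` — lets x adopt `(s_y, α_y)` with the
Fermi probability

    W = 1 / (1 + exp[(u_x − u_y) / (κ K)]),

applied immediately.  The shared x–y edge is drawn independently inside
`u_x` and `u_y`: the two utility evaluations are modelled as separate
encounters, which is the natural reading when each evaluation is a fresh
realisation, and the choice only affects a correlation of order 1/κ between
the two utilities.  The comparison `u_y > u_x` is exact (utilities are
exactly representable sums); W is evaluated as a logistic sigmoid, which is
stable for any utility gap.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| `T` | temptation to defect (payoff units) | 1.4 | dilemma requires 1 < T < 2 |
| `L` | loner's payoff | 0.4 | dilemma requires 0 < L < 1 |
| `R, P, S` | reward / punishment / sucker | 1, 0, 0 | fixed in the standard game |
| `K` | Fermi noise amplitude | 0.1 | must be > 0; K → 0 is deterministic better-copying |
| `side` | lattice side | 102 (full scale) / 60 (desk) | N = side² |
| `mc_steps` | MC steps per run | 10⁵ / 2·10⁴ | thermalisation to the stationary state |
| runs | ensemble size | 100 / 20 | independent seeds, base + i |
| `record_every` | sampling interval | 100 / 10 | metrics also recorded at steps 0 and final |

Dilemma-bound validation warns by default and raises only in strict mode,
so limiting cases (e.g. `T = 1` exactly) remain runnable for analysis.

Initialisation modes set the study conditions: `pd` puts all agents at
α = 0 (the abstention-free limit — the loner's payoff can then never be
awarded, and results are provably invariant to `L`); `opd` draws α from
{0, 1} with equal probability (pure loners); `pdpa` draws α uniformly over
all nine levels.  Strategies are always a fair coin.

## Randomness contract

One seeded numpy PCG64 `Generator` drives an entire run.  The numba update
kernels consume *pre-drawn* uniform arrays in a fixed documented order
(initialisation: strategy draws then α draws; synchronous accrual: sites
row-major, East edge then South edge, focal endpoint's draw before the
neighbour's; asynchronous move: a 19-uniform block — site pick, 8
interaction draws, neighbour pick, 8 more, Fermi coin).  The Fermi coin is
drawn every move and consulted only when `u_y > u_x`, keeping each move a
pure function of its uniform block.  This is what makes runs bit-identical
under a fixed seed and lets the test suite compare the engine *exactly*
against an independent pure-Python brute-force reference that honours the
same order.  Sweep cells derive their seeds from `SeedSequence` keyed on
(game, scheme, bit pattern of T, run index) — not on grid position or on L
— so sweep tables are invariant to cell execution order and the L axis uses
common random numbers.

## Numerical choices

* Utility comparisons in the synchronous tie rule use absolute tolerance
  1e-9; true ties are representable, so the tolerance only guards against
  summation-order effects.
* Neighbour order is fixed (N, S, W, E); coordinates are 0-based (row,
  column).
* `side = 2` is permitted outside strict mode as a degenerate multigraph
  torus (wrap-around duplicates neighbours; duplicated maximal neighbours
  count as ties, so synchronous imitation never fires there).  `side < 2`
  is rejected.
* Optional early stopping when the state is absorbing (homogeneous `(s, α)`
  under synchronous updating; all-defect or all-α = 1 under asynchronous)
  is available but off by default, mirroring the fixed-length protocol.
* Stationary summaries use each run's final-step snapshot averaged across
  runs; no within-run time averaging.  Standard errors are across runs —
  lattice sites are correlated by clustering, runs are independent.
* The "number of surviving α levels" statistic counts levels with ≥ 1%
  occupancy by default (exposed as a parameter); the threshold filters
  single-agent relics and is a reporting choice, not part of the dynamics.

## What the desk scale shows — and does not

The desk preset (60 × 60, 2·10⁴ steps, 20 runs) was sized so the end-to-end
suite runs in minutes while reproducing the stationary phenomenology of the
full protocol: the collapse of the α support to two levels (synchronous)
or three (asynchronous) at `T = 1.4, L = 0.4`, the decrease of stationary ε
with T, and the PDPA's retention of cooperators at temptations where the PD
and OPD limits lose them.  Smaller lattices have larger fluctuation-driven
extinction probabilities, so individual runs can deviate from the modal
outcome; ensemble modes and means are the meaningful desk-scale statistics.

The transient of the ensemble-mean α deserves a precise statement.  Under
asynchronous updating at `T = 1.4` the curve is bell-shaped early on: it
rises from its initial value 0.5 to a peak (≈ 0.57 around step 30 at desk
scale) as booming pure defectors make abstention briefly the best refuge,
then falls (to ≈ 0.38) as cooperator clusters consolidate, before relaxing
to its stationary value.  Under synchronous updating at the same T the
ensemble-mean α decays monotonically — deterministic best-neighbour copying
lets cooperator clusters win before abstention gets its window; at higher
temptation (T = 1.9) the synchronous curve instead rises to a high
stationary plateau.  Both behaviours are pinned by tests; we verified the
synchronous monotone decay at both desk and full scale and under both tie
readings, so it is a property of the model class, not of the reduced size.

## Limitations

* Regular lattices only: no scale-free, small-world, multilayer or
  coevolving topologies, no Moore neighbourhoods, no dilution.
* No mutation or drift: α levels can only be lost, never re-created, so
  absorbing states are permanent and very long runs ratchet toward reduced
  diversity.
* All interactions are realised Bernoulli draws; expected-payoff
  (mixed-strategy) variants are out of scope.
* The asynchronous engine's per-move utilities are single-step
  realisations, not averages over repeated plays; noisier than an
  expected-utility Fermi rule at the same K.
* Heat-map rendering is out of scope; sweep commands emit tidy tables.
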