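# Methods

## Model

A population of `N` individuals lives on the complete territorial-raider
graph with `M = N` places; individual `i` owns place `i`. Each round every
individual ends up on one place, co-located individuals form a group, and
each group plays one multiplayer game. The home-fidelity parameter `h > 0`
sets the target marginal: an individual is at home with probability
`h/(h+M-1)` and at each other place with probability `1/(h+M-1)`.

### Coordinated movement

Movement is *row-dependent*: an individual's choice may depend on the other
individuals' current-round choices. Four mechanisms are implemented, all
*faithful* (their realized marginals equal the territorial target):

- **independent** — each mover draws its place independently;
- **follow-the-majority** — movers are placed sequentially in a uniformly
  random order; the first samples the apriori, later movers join the most
  occupied place. Maximal herding: all movers end up in one group;
- **Polya urn** — sequential placement with probability proportional to
  `B a_m + Y_m` (`Y_m` = current occupancy). `B` interpolates from
  follow-the-majority (`B = 0`, taken as the limit since the urn weights
  vanish there) to independence (`B -> inf`);
- **wheel** — simultaneous placement: `n` spikes separated by an angle
  `theta` sit on a wheel spun by a uniform rotation over arcs whose lengths
  are the apriori weights. `theta = 0` herds; `theta = 2*pi/N` with equal
  arcs disperses everyone.

For `h != 1` a mechanism is embedded by a three-way participation split per
individual: sit at home directly (probability `(h-1)/(h+M-1)` when
`h > 1`), play the mechanism with the *uniform* internal apriori
(`M/(h+M-1)` when `h > 1`, everyone when `h = 1`, `Mh/(h+M-1)` when
`h < 1`), or move to a uniformly random non-home place
(`(M-1)(1-h)/(h+M-1)` when `h < 1`). Participants never react to
non-participants; the split composed with the uniform internal target
reproduces the territorial marginal exactly, which the tests check both
symbolically and by enumeration.

Open choices the source model leaves unspecified, fixed here:

- **Follow-the-majority ties** are broken proportionally to the apriori
  weights of the tied places (uniform tie-breaking is available as an
  option). This reduces to the plain apriori draw for the first mover and
  preserves faithfulness.
- **Wheel with a random participant subset**: spikes stay equally spaced by
  `theta` and are assigned to the participants in a uniformly random
  order, preserving exchangeability and faithfulness.
- **Arc layout**: places occupy consecutive half-open arcs in index order
  starting at position 0. Any fixed layout gives the same marginals; this
  one is canonical and testable.
- **Theta quantization**: `theta` is rounded to 3 decimal places in radians
  by default (configurable, disable with `theta_precision=None`). At the
  dispersal angle `2*pi/N` the unquantized wheel separates everyone forever
  and the evolutionary process cannot absorb; the rounded angle leaves a
  small incommensurability that produces occasional meetings.

### Group statistics

`enumerate_distribution` computes the exact place-labelled partition law by
summing over participation patterns, random-mover choices, and mechanism
outcomes; mover orderings are averaged exactly (for the urn via the
Dirichlet-multinomial form of the order-averaged occupancy law, for the
wheel by exact rotation-measure integration over the arc-boundary
breakpoints followed by averaging over spike assignments). The default cap
is `N <= 6`.

`group_size_distribution` is the scalable exact route. On the complete
graph with the uniform internal apriori the partition law is exchangeable
over individuals, so state-level quantities need only (i) the law of a
focal individual's group size and (ii) uniform sampling of co-members.
Per mechanism this requires two occupancy laws — participants on one fixed
place, and the mechanism-group size of a focal mover — which have closed or
cheaply integrable forms (binomial for independent movement, a point mass
for follow-the-majority, beta-binomial for the urn, breakpoint integration
for the wheel). The tests verify the reduction against the full
enumeration to ~1e-12 for every mechanism, including the wheel at `h != 1`.

Replacement weights follow: the self weight `w_s` is the probability of
being alone, the pair weight `w = d_N = (1 - w_s)/(N - 1)`, so the row
conservation `w_s + (N-1) w = 1` holds identically, and
`w* = (w_s - w)/w`. A process that never forms groups has `w = 0` and an
undefined `w*`; the code raises on it.

## Games and fitness

Public Goods: a cooperator pays `C`, shared as `V` among the *other* group
members; lone cooperators still pay. Hawk-Dove: hawks fight over `V`
(winner takes it, each losing hawk pays `C`), doves concede when hawks are
present and otherwise split `V`. Both games depend on the composition
`(a, b)` only.

State fitnesses at mutant count `k` average the focal payoff over the group
law with hypergeometric co-member types. Fast paths, each guarded by an
equivalence test against the enumeration average:

- Public Goods, any mechanism: `F_C = R - C + (k-1) V d_N`,
  `F_D = R + k V d_N`;
- Hawk-Dove, independent movement: dove `R + tau V`, hawk
  `R + omega V - nu C` with the closed coefficient functions
  `tau(h, N, k)`, `omega`, `nu` (note `omega + nu = 1`: a hawk either
  takes its expected reward share or pays its expected cost share). The
  power ratios inside are evaluated in log space so the infinite-population
  limit checks at `N = 1e4` do not overflow;
- infinite population at dove frequency `p`: dove
  `R + ((e^p - 1)/(e p)) V`, hawk
  `R + ((1 - e^{p-1})/(1-p)) V - ((e^{p-1} - p)/(1-p)) C`.

## Fixation

The mutant count is a birth-death chain; fixation from one mutant is the
standard ratio product, evaluated in log space. BDB gives ratio
`F_R/F_M`; BDD gives
`(N-k + (k+w*) F_R/F_M) / (k + (N-k+w*) F_M/F_R)`. The independent oracle
(`markov_fixation_oracle`) assembles the chain from the event probabilities
themselves — fitness-proportional or uniform birth, replacement through the
averaged weights — and solves the linear system; closed forms agree with it
to ~1e-15 relative across `N <= 10`, both games, both dynamics, all
mechanisms, `h` in {0.5, 1, 2, 10}.

Weak selection (`R` large): the cooperator's fixation is
`(1/N)(1 - (N-1)(V d_N + C)/(2R))` under BDB, with the extra factor
`(N+2w*)/(N+w*)` under BDD; the two coincide when `w* = 0` and the error
against the exact form decays as `R^-2`.

The dove neutrality condition solves `rho_dove = 1/N` for `C/V` by Brent's
method on a geometrically expanded bracket (residual tolerance 1e-12),
using the closed dove fixation at large `R` (default `1e4`). The
weak-selection series form of the condition is evaluated alongside under a
documented reading (Euler-Mascheroni `gamma`; generalized harmonic number
`H[n, a] = sum a^k/k` at `a = (h+N-1)/(h+N-2)`) and reported with its
discrepancy; the numeric root is authoritative. At `N = 10` the root is
~1.43 for `h` in {0.5, 1, 2} — above 1 yet below the classical pairwise
1.5–2 range, the multiplayer effect that leaves hawks worse off — while the
series value is ~1.11 near `h = 1`; the two agree only in order of
magnitude, so the series is treated as indicative.

The infinite-population equilibrium ratio
`V/C = e p (e^{p-1} - p) / ((1 - e^{p-1}) e p - (e^p - 1)(1 - p))` gives
0.688 at `p = 1/2` (so `C = 1.453 V`), verified against an independent
root solve of the fitness equality.

## Agent-based simulation

The simulator runs the one-shot process: per generation a movement
realization assigns realized payoffs as fitness, everyone returns home, a
second movement realization forms the replacement groups, and exactly one
birth-death event occurs (victim uniform in the reproducer's group under
BDB, inverse-fitness weighted under BDD; the parent replaces itself when
alone; the victim's vertex takes the reproducer's offspring). "Another
random member of the group" is read as excluding the parent when the group
has two or more members; including the parent is a switchable option.

Implementation notes: the inner loop is numba-compiled; the
replacement-round placement is sampled before the game round, and when it
leaves every individual alone the generation is a guaranteed no-op and the
game round is skipped (the two rounds are independent, so the law of the
process is unchanged — this matters for near-dispersal wheel runs whose
absorption takes ~2e4 generations). Replicates draw 31-bit substream seeds
by counter from the master seed, so each replicate is reproducible
independently of batch size. Runs not absorbed within `max_steps` (default
1e7) are excluded from the estimate and counted. Intervals are Wilson
score at 95%.

An *idealized* mode replaces realized payoffs with the state-dependent mean
fitnesses. Under BDB this makes the simulated mutant count an exact
realization of the analytic chain (the victim choice is uniform within the
group, and the group-averaged replacement weights match), so the estimate
can be checked against the closed form directly. Under BDD the realized
process weights victims by inverse fitness *within the realized group*,
whereas the analytic chain uses averaged weights; with large self-weights
these differ measurably — e.g. independent movement, `h = 100`, `N = 10`,
Hawk-Dove gives 0.0996 (simulated, 1e5 replicates) vs 0.0918 (averaged
chain) — so BDD simulations are compared with the analytics only
qualitatively. BDB shows no such gap (0.0950 vs 0.0955 in the same
setting).

## What the tests do and do not show

The simulated ordering experiments use the scaled-down study conditions
`N = M = 10`, `h = 1`, `R = 10`, `V = 2`, `C = 1`, 5e4 replicates (the
original analyses average 1e6 runs): herding minimizes the cooperator's
fixation and maximizes the dove's, independence the reverse, and the
near-dispersal wheel maximizes the cooperator. Interior Polya-urn points
(`B = 2` vs `B = 6`) differ by ~5e-4 in fixation probability — below
Monte-Carlo resolution at 5e4 replicates — so the interior trend is
asserted on the exact closed forms rather than on simulated point
estimates.

The synthetic study conditions are the model itself (there is no external
data): what passing tests show is internal consistency of the movement
laws, fitness averages, chain analytics and simulation protocol, plus the
qualitative herding/dispersal conclusions at one parameter set. They do
not probe non-complete graphs, unequal apriori targets across individuals,
history-dependent movement, mutation, or any empirical calibration of
`h`, `B`, `theta` to animal movement data.

## Numerical choices

- Exact-law tolerances: 1e-12 for faithfulness and worked distributions,
  1e-10 for fitness/fixation equivalences (observed agreement is ~1e-14).
- Monte-Carlo faithfulness checks use 4 standard errors.
- `B = 0` urn and `theta = 0` wheel are exact aliases of
  follow-the-majority; equality of the three laws is tested.
- Ratio products and power ratios in log space; linear solves via LAPACK on
  the (N-1)-state system.
- Degenerate inputs raise typed errors: always-alone processes (undefined
  `w*`, unreachable absorption), non-positive fitnesses (named state),
  vanishing equilibrium denominators, empty brackets in root searches.
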