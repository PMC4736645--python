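# Model and methods

## The model

`pglattice` simulates the evolution of a continuous cooperative trait —
the public-good production rate `p` — in a population of individuals
living on a square lattice with Moore connectivity (`k = 8`).  Each node
is empty or holds one individual.  An individual with trait `p`
(`0 ≤ p ≤ p_max`) emits `p` units of public good per Monte-Carlo step,
split in equal shares over its 3×3 neighbourhood; under *weak altruism*
the producer keeps one of the nine shares (`p/9` to self and to each
neighbour), under *strong altruism* the good goes only to the eight
neighbours (by default `p/8` each, conserving the total emitted; a
`discard9` option keeps `p/9` shares and discards the producer's own).

The benefit collected by individual *i* is

    B_i = b · (p_i + Σ_j p_j) / 9          (weak altruism)

summed over its occupied neighbours *j*; the cost is `C_i = c·p_i`, and
fitness is `f_i = max(0, B_i − C_i)`.  The good is not stored between
steps; benefits are recomputed from the current lattice.  Fitness
affects reproduction only, never death.

One Monte-Carlo step visits every node exactly once in a fresh uniform
random permutation:

* **Empty node** — the occupied neighbours run a replication lottery:
  competitor *i* wins with probability `f_i/f_tot · (1 − e^{−f_tot})`
  where `f_tot` is the summed fitness; with probability `e^{−f_tot}`
  nobody replicates.  The winner's offspring copies its trait, mutated
  with probability `μ` by a uniform draw from `[−δ/2, +δ/2]`, clipped
  (not reflected) to `[0, p_max]` — clipping preserves an atom of
  exactly-zero producers, which is where the selfish lineage settles.
* **Occupied node** — with probability `k_move` its content is swapped
  with a uniformly chosen adjacent node, then whatever occupies the
  visited node dies with probability `k_death`.

Events are applied immediately (asynchronous updating): later visits in
the same sweep see earlier births, deaths and moves.  One deliberate
exception: **offspring born during a sweep cannot themselves be chosen
as parents until the sweep ends.**  Without that rule, replication
chains propagate within a single sweep wherever fill probabilities
saturate (`1 − e^{−f_tot} ≈ 1`, which at `b = 10` is almost everywhere),
letting expansion fronts advance several nodes per step.  That
cascading regime behaves qualitatively differently from synchronous
updating — it flattens the trait-dependence of front speeds, reverses
the outcome of front competition between strains of different `p`, and
destabilises the high-cost travelling-wave regime on mid-sized
lattices — whereas the random-order and synchronous schemes are
supposed to be interchangeable for this model.  Gating newborn
eligibility (while letting newborns contribute public good and occupy
their node immediately) restores that equivalence at the expansion
front.  Two smaller scheme details: each node *index* is visited once
per sweep, so an individual swapped onto an already-visited node is not
revisited (it can thereby skip one death test); and the movement target
under no-flux boundaries is drawn uniformly from the 3–8 existing
neighbours.

## Parameters

| name      | meaning                                   | default | unit |
|-----------|-------------------------------------------|---------|------|
| `b`       | benefit per unit public good received     | 10      | –    |
| `c`       | cost per unit public good produced        | 4.5     | –    |
| `k_death` | per-step death probability                | 0.2     | 1/step |
| `k_move`  | per-step movement probability             | 0.02    | 1/step |
| `mu`      | mutation probability per replication      | 0.05    | –    |
| `delta`   | mutation kernel width                     | 0.1     | trait units |
| `p_max`   | production cap                            | 10      | trait units |
| `width`, `height` | lattice dimensions                | 128     | nodes |

The defaults are the study conditions of the cost-sweep experiments
(`c` is the swept variable; its default is the focal high-cost case).
Time is measured in Monte-Carlo steps; an individual's expected
lifetime is `1/k_death = 5` steps.

Weak altruism becomes individually costly when `c > b/9 ≈ 1.11`
(the producer's own share no longer repays the cost); the marginal
fitness of producing is `∂f/∂p = b/9 − c` wherever `f > 0`.

## Dynamical regimes

With `b = 10` the model shows three cost regimes, which the experiment
protocols probe:

* `c ≲ 1.5` — production evolves to the cap (kin-structured clusters
  plus direct self-benefit).
* `2 ≲ c ≲ 3` — production collapses to the minimum compatible with
  survival; the population persists at high density with low `p`.
* `c ≳ 3.5` — the regime the model targets is speciation into a
  high-producing cooperator lineage and a zero-producing selfish
  lineage that self-organise into travelling waves (cooperators at the
  front expanding into empty space, cheaters invading behind, empty
  wake), with a bimodal steady state whose mean *increases* with cost.
  **On the lattice sizes this package can run (≤256², single core),
  that steady state is not reached**: from any initial condition we
  tried (full occupancy, half occupancy, explicitly seeded wave bands)
  populations at `c = 4.5` go extinct within ~2·10³–4·10⁴ steps.  The
  mechanism is quantitative: at `b = 10` the lottery term
  `1 − e^{−f_tot}` is saturated almost everywhere, so the cooperator
  front advances at ≈1 node/step regardless of `p`, while selfish
  invasion runs at ≈0.1–0.2 nodes/step.  A wave band therefore inflates
  ~7× faster than it is consumed, outgrows any feasible domain, meets
  its own wake and is eaten.  The ingredients of the wave mechanism
  are still demonstrable in isolation — the strip assays show fast
  cooperator expansion into empty space, slow cost-accelerated selfish
  sweeps, wake clearance for exact zero-producers, and front/back
  selection in opposite directions — but the closed self-sustaining
  wave train would require domains far larger than the scaled tests.
  The corresponding regime tests in the acceptance suite are kept at
  their stated scales and fail there; this is recorded behaviour, not
  a bug.

## Experiment protocols

**Evolutionary runs / cost sweeps** start from full occupancy with all
individuals at `p = p_max` (a population of maximal producers) and run
≥100,000 steps; "steady state" statistics discard the first half of the
run as burn-in (a drift slope over the last quarter is reported but not
enforced).

**Strip assays** (`μ = 0`) shape the lattice into a 512×32 strip with
no-flux boundaries; the one-node boundary ring absorbs: individuals
moving or replicating into it are removed.  The first 8 interior
columns are seeded with the invading strain (for selfish invasion the
rest of the strip holds a homogeneous cooperator resident); the arrival
time is the first step at which an invader occupies the last interior
column, and the invasion rate is invaded length / arrival time.
Selfish sweep rates are low, strongly cost-dependent
(≈0.07/0.13/0.21 nodes/step at c = 3/4/5) and insensitive to the
residents' production; cooperator expansion saturates near 1 node/step
— its cost-dependence is clear (≈1.074/1.062/1.033) but its
p-dependence is resolvable only below p ≈ 4 (1.042 → 1.068 over
p = 1…4, flat above), because front fill probabilities are already
near 1.  Monotonicity claims are evaluated on replicate medians.

**Competition assays** seed two labelled blocks abreast (labels inherit
unchanged; `μ = 0`) and race them along a 2048×32 strip — front:
two cooperator strains expanding into empty space; back: two selfish
strains invading a cooperator resident.  The winner is the strain that
owns the advancing front (sole label within one strip-width of the
leading edge) when the wave arrives, or the survivor if its rival dies
out.  Front ownership is decided by an early scramble near the seeded
blocks and then locks in for the rest of the race; with the saturated
front speeds at these parameters the higher producer's advantage in
that scramble is real but modest (it wins a majority, not all, of
replicates), while the back assay is decisive for the lower producer
(its rival is usually cut off and goes extinct within a few hundred
steps).  The long front strip gives the lock-in time to express
itself; the back assay uses a 512-length strip because its decision is
local and early.

**Well-mixed / mixing controls** permute all node contents uniformly
before every step (the strongest reading of "mixing"; the lattice
machinery, replication lottery and demographic noise are unchanged —
no mean-field recursion).  `mix_from_t` switches from spatial to mixed
dynamics at a configurable step.

## Synthetic data and what tests show

All inputs are generated by the simulator itself from the parameters
above; there is no external data.  The test suite validates the engine
against closed-form oracles on enumerable 3×3 fixtures (lottery
probabilities, one-step event probabilities), checks structural
invariants (occupancy ≤ 1, trait bounds, conservation under movement,
histogram mass, seed-determinism, snapshot round-trips), and re-derives
the qualitative regime structure on scaled-down lattices (64²–256²,
10⁵ steps) rather than the full 2048² systems of the original study;
quantities that depend on lattice size (wave statistics, extinction
risk at high cost) are therefore checked only for their direction and
regime, not their large-lattice values.

## Numerical choices

* The Monte-Carlo sweep runs in a numba kernel over flat arrays with
  two incrementally maintained caches: the 3×3-block production sum
  (making a competitor's fitness O(1)) and the occupied-neighbour
  count (skipping the lottery scan in empty bulk).  Cache drift from
  float accumulation is ≤10⁻⁹ over 10⁵ sweeps and the caches are
  rebuilt from scratch at every driver entry.
* All randomness flows from a single seeded `numpy.random.Generator`
  (PCG64) shared by Python-level and compiled code; the per-sweep visit
  permutation is Fisher–Yates from identity using `floor(u·(i+1))`
  draws, so a sweep is a pure function of (world state, stream state)
  and a snapshot resume reproduces an uninterrupted run exactly.  The
  kernel draws one uniform per occupied node to decide move-vs-death
  for non-movers (conditionally identical to two independent Bernoulli
  trials); movers get an independent death draw.
* Histogram bins on `[0, p_max]` are left-closed, right-open, last bin
  closed.  The bimodality detector (50 bins by default) requires two
  candidate peaks separated by a ≥3-bin valley below 50% of the smaller
  peak, with ≥5% of the population on each side of the deepest valley
  bin — robust to mutation noise of width `δ = 0.1`.
* The cooperator/selfish classifier threshold defaults to `p* = 1.0`,
  well below the cooperator mode and inside the observed inter-mode
  valley of the bimodal high-cost distribution.
* `f_tot = 0` (all competitors clamped): the lottery returns "none"
  without consuming randomness.

## Known limitations

* Lattices ≥512² at ≥10⁵ steps are expensive in a single-core run;
  the shipped experiments are scaled down accordingly and the
  high-cost persistence claims are size-dependent.
* The mixing protocol and the strong-altruism share rule are model
  choices exposed as options (`mix_from_t`, `strong_share`); the
  original formulations of these controls are not fully specified in
  the source material available to us.
* No continuous-time (Gillespie) variant, no synchronous-update mode,
  and no automated segmentation of travelling waves (snapshots can be
  rendered and inspected; wave sizes are not measured).
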