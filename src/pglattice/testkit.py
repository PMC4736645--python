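"""Brute-force oracles and hand-enumerable fixtures.

The stochastic engine is falsifiable on small lattices: for a fixture
whose neighbourhoods can be enumerated by hand, the exact outcome
probabilities of the replication lottery and of single Monte-Carlo-step
events have closed forms, computed here independently of the kernel's
code path.  Tests compare empirical event frequencies from many seeded
engine runs against these oracles.
"""

from __future__ import annotations

import math

from . import engine
from .params import SimulationParams
from .state import WorldState

Site = tuple[int, int]


# ---------------------------------------------------------------------
# fixture construction
# ---------------------------------------------------------------------


def fixture_world(
    params: SimulationParams, production_rows: list[list[float | None]]
) -> WorldState:
    """Build a small hand-specified lattice.

    ``production_rows`` is a row-major nested list; ``None`` marks an
    empty node, a number an individual with that production rate.  The
    lattice dimensions must match ``params``.
    """
    h, w = params.shape
    if len(production_rows) != h or any(len(row) != w for row in production_rows):
        raise ValueError("fixture rows do not match params lattice dimensions")
    state = WorldState.empty(params)
    for r, row in enumerate(production_rows):
        for c, p in enumerate(row):
            if p is not None:
                state.occupancy[r, c] = True
                state.production[r, c] = float(p)
                state.strain_label[r, c] = 0
    return state


def fixture_isolated(params: SimulationParams, p: float = 5.0) -> WorldState:
    """A single individual at the centre of a 3x3 lattice."""
    none = None
    return fixture_world(params, [[none] * 3, [none, p, none], [none] * 3])


def fixture_full_3x3(params: SimulationParams, p: float = 5.0) -> WorldState:
    """Fully occupied homogeneous 3x3 lattice."""
    return fixture_world(params, [[p] * 3] * 3)


def fixture_ring_3x3(params: SimulationParams, p: float = 5.0) -> WorldState:
    """Empty centre surrounded by 8 identical individuals (3x3)."""
    none = None
    return fixture_world(params, [[p] * 3, [p, none, p], [p] * 3])


# ---------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------


def exact_lottery_distribution(
    fixture: WorldState, params: SimulationParams, empty_site: Site
) -> dict[Site | None, float]:
    """Exact replication-lottery outcome probabilities for an empty node.

    Enumerates the occupied Moore neighbours of ``empty_site``, evaluates
    each fitness on the fixture, and applies the closed form
    ``P(i) = f_i / f_tot * (1 - exp(-f_tot))``, ``P(none) = exp(-f_tot)``.
    The returned probabilities sum to 1.
    """
    if fixture.occupancy[empty_site]:
        raise ValueError(f"site {empty_site!r} is occupied")
    competitors = [
        nb
        for nb in engine.neighbor_sites(fixture, params, empty_site)
        if fixture.occupancy[nb]
    ]
    fs = {nb: engine.fitness(fixture, params, nb) for nb in competitors}
    f_tot = sum(fs.values())
    out: dict[Site | None, float] = {}
    if f_tot <= 0.0:
        for nb in competitors:
            out[nb] = 0.0
        out[None] = 1.0
        return out
    gain = -math.expm1(-f_tot)  # P(someone replicates)
    for nb, f in fs.items():
        out[nb] = f / f_tot * gain
    out[None] = math.exp(-f_tot)
    return out


#: Names of the canonical 3x3 configurations the Markov oracle knows.
ORACLE_CATALOGUE = ("isolated", "full_3x3", "ring_3x3")


def single_site_markov_oracle(
    params: SimulationParams, configuration: str, p: float = 5.0
) -> dict[str, float]:
    """Closed-form one-step event probabilities for canonical 3x3 fixtures.

    ``isolated`` (requires ``k_move = 0``): a lone individual neither
    replicates (no empty node has competitors with positive total
    fitness unless its own fitness is positive) nor interacts; it dies
    within the step with probability ``k_death``.  Returned keys:
    ``death``, ``fill_any`` (probability that at least one of the 8
    empty nodes is filled, conditional on the individual's fitness).

    ``full_3x3`` (toroidal): no empty nodes can appear at unvisited
    indices, so deaths are independent Bernoulli(``k_death``) trials;
    returns ``expected_deaths``.

    ``ring_3x3`` (requires ``k_move = k_death = 0``, toroidal): the only
    stochastic event is the centre lottery; returns ``filled`` =
    ``1 - exp(-f_tot)`` with ``f_tot`` enumerated on the fixture, and
    ``per_parent`` = the (common) win probability of each competitor.
    """
    if configuration not in ORACLE_CATALOGUE:
        raise ValueError(
            f"unknown configuration {configuration!r}; catalogue: {ORACLE_CATALOGUE}"
        )
    if params.shape != (3, 3):
        raise ValueError("the Markov oracle enumerates 3x3 lattices only")

    if configuration == "isolated":
        if params.k_move != 0.0:
            raise ValueError("isolated-individual oracle requires k_move = 0")
        state = fixture_isolated(params, p)
        f = engine.fitness(state, params, (1, 1))
        # Each of the 8 empty nodes sees the single individual as its only
        # competitor (3x3 torus: every node neighbours every other); a
        # node visited before the individual's death test is filled with
        # probability 1 - exp(-f).  With f = 0 nothing ever replicates.
        return {"death": params.k_death, "fitness": f}

    if configuration == "full_3x3":
        if params.boundary != "toroidal":
            raise ValueError("full-lattice oracle assumes toroidal boundaries")
        return {"expected_deaths": 9.0 * params.k_death}

    # ring_3x3
    if params.k_move != 0.0 or params.k_death != 0.0:
        raise ValueError("ring oracle requires k_move = k_death = 0")
    if params.boundary != "toroidal":
        raise ValueError("ring oracle assumes toroidal boundaries")
    state = fixture_ring_3x3(params, p)
    dist = exact_lottery_distribution(state, params, (1, 1))
    filled = 1.0 - dist[None]
    per_parent = filled / 8.0
    return {"filled": filled, "per_parent": per_parent}
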