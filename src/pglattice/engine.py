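"""Core lattice dynamics: fitness, the replication lottery, movement,
death, and the Monte-Carlo step loop.

Individuals sit on a square lattice with Moore connectivity (8
neighbours).  An individual producing public good at rate ``p`` shares
it with its neighbourhood; under weak altruism each of the 9 nodes of
the 3x3 block (self included) receives ``p/9``.  The benefit collected
by individual ``i`` is ``B_i = b * (p_i + sum_j p_j) / 9`` over its
occupied neighbours ``j``; it pays a cost ``C_i = c * p_i``; fitness is
``f_i = max(0, B_i - C_i)``.  The good is not accumulated over steps —
benefits are always computed fresh from the current lattice.

Sites are addressed as ``(row, col)`` tuples in the Python API.  The
step loop itself runs in a compiled kernel (see ``_kernels``); the
functions here define the per-event semantics on single sites and are
used directly by tests and small-scale analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels
from ._geometry import neighbor_table, neighbor_sites_rc
from .params import SimulationParams, N_SHARES
from .state import WorldState, NO_LABEL

Site = tuple[int, int]


def _check_site(state: WorldState, site: Site) -> None:
    r, c = site
    h, w = state.shape
    if not (0 <= r < h and 0 <= c < w):
        raise IndexError(f"site {site!r} outside {h}x{w} lattice")


def neighbor_sites(
    state: WorldState, params: SimulationParams, site: Site
) -> tuple[Site, ...]:
    """Moore neighbours of ``site``: all 8 with wrap-around on a toroidal
    lattice, the in-lattice subset under no-flux boundaries."""
    h, w = state.shape
    return neighbor_sites_rc(h, w, params.boundary, site)


def benefit(state: WorldState, params: SimulationParams, site: Site) -> float:
    """Benefit collected by the individual at ``site`` from the public
    good produced in its neighbourhood (and by itself, under weak
    altruism)."""
    _check_site(state, site)
    if not state.occupancy[site]:
        raise ValueError(f"site {site!r} is empty; benefit is defined for individuals")
    nbr_sum = 0.0
    for nb in neighbor_sites(state, params, site):
        if state.occupancy[nb]:
            nbr_sum += state.production[nb]
    p_own = float(state.production[site])
    if params.altruism == "weak":
        return params.b * (p_own + nbr_sum) / N_SHARES
    if params.strong_share == "split8":
        return params.b * nbr_sum / 8.0
    return params.b * nbr_sum / 9.0


def fitness(state: WorldState, params: SimulationParams, site: Site) -> float:
    """``f = max(0, B - c*p)``: benefit minus production cost, clamped at
    zero when costs exceed benefits."""
    _check_site(state, site)
    if not state.occupancy[site]:
        raise ValueError(f"site {site!r} is empty; fitness is defined for individuals")
    f = benefit(state, params, site) - params.c * float(state.production[site])
    return f if f > 0.0 else 0.0


def select_replicator(
    state: WorldState,
    params: SimulationParams,
    empty_site: Site,
    rng: np.random.Generator,
) -> Site | None:
    """Run the replication lottery for an empty node.

    The occupied Moore neighbours of ``empty_site`` compete; competitor
    ``i`` (fitness ``f_i``, total ``f_tot``) is returned with probability
    ``f_i / f_tot * (1 - exp(-f_tot))``; ``None`` is returned with the
    residual probability ``exp(-f_tot)`` — and with certainty when there
    are no competitors or every fitness is zero.
    """
    _check_site(state, empty_site)
    if state.occupancy[empty_site]:
        raise ValueError(f"site {empty_site!r} is occupied; the lottery needs an empty node")
    occ = state.occupancy
    competitors = [nb for nb in neighbor_sites(state, params, empty_site) if occ[nb]]
    if not competitors:
        return None
    fs = [fitness(state, params, nb) for nb in competitors]
    f_tot = sum(fs)
    if f_tot <= 0.0:
        return None
    u = rng.random()
    scale = -math.expm1(-f_tot) / f_tot
    acc = 0.0
    for nb, f in zip(competitors, fs):
        acc += f * scale
        if u < acc:
            return nb
    return None


def mutate_production(p: float, params: SimulationParams, rng: np.random.Generator) -> float:
    """Offspring production rate: unchanged with probability ``1 - mu``,
    otherwise perturbed by a uniform draw from ``[-delta/2, delta/2]``
    and clipped to ``[0, p_max]``."""
    if rng.random() < params.mu:
        p = p + (rng.random() - 0.5) * params.delta
        p = min(max(p, 0.0), params.p_max)
    return p


def apply_move(
    state: WorldState,
    params: SimulationParams,
    site: Site,
    rng: np.random.Generator,
) -> WorldState:
    """With probability ``k_move`` swap the contents of ``site`` with a
    uniformly chosen adjacent node (which may be empty or occupied).
    Under no-flux-absorbing boundaries, moving onto a boundary-ring node
    deletes the individual.  Mutates ``state`` in place."""
    _check_site(state, site)
    if not state.occupancy[site]:
        raise ValueError(f"site {site!r} is empty; movement acts on individuals")
    if rng.random() >= params.k_move:
        return state
    nbrs = neighbor_sites(state, params, site)
    target = nbrs[int(rng.random() * len(nbrs))]
    if _is_absorbing(state, params, target):
        _clear(state, site)
    else:
        for arr in (state.occupancy, state.production, state.strain_label):
            arr[site], arr[target] = arr[target], arr[site]
    return state


def apply_death(
    state: WorldState,
    params: SimulationParams,
    site: Site,
    rng: np.random.Generator,
) -> WorldState:
    """With probability ``k_death`` the node turns empty.  Death is
    fitness-independent.  Mutates ``state`` in place."""
    _check_site(state, site)
    if not state.occupancy[site]:
        raise ValueError(f"site {site!r} is empty; death acts on individuals")
    if rng.random() < params.k_death:
        _clear(state, site)
    return state


def _clear(state: WorldState, site: Site) -> None:
    state.occupancy[site] = False
    state.production[site] = 0.0
    state.strain_label[site] = NO_LABEL


def _is_absorbing(state: WorldState, params: SimulationParams, site: Site) -> bool:
    if params.boundary == "toroidal":
        return False
    r, c = site
    h, w = state.shape
    return r in (0, h - 1) or c in (0, w - 1)


# ---------------------------------------------------------------------
# step loop
# ---------------------------------------------------------------------


def _kernel_args(state: WorldState, params: SimulationParams):
    h, w = state.shape
    nbr, n_nbr, absorbing = neighbor_table(h, w, params.boundary)
    occ = state.occupancy.ravel()
    prod = state.production.ravel()
    label = state.strain_label.ravel()
    psum, nocc = _kernels.compute_caches(occ, prod, nbr, n_nbr)
    newborn = np.zeros(occ.shape[0], dtype=np.int8)
    mode = _kernels.mode_code(params.altruism, params.strong_share)
    return occ, prod, label, psum, nocc, newborn, nbr, n_nbr, absorbing, mode


def monte_carlo_step(
    state: WorldState, params: SimulationParams, rng: np.random.Generator
) -> WorldState:
    """Advance the lattice by one Monte-Carlo step.

    Every node is visited exactly once in a fresh uniform random
    permutation; events are applied immediately, so later visits see the
    partially updated lattice.  An individual swapped onto an
    already-visited node is not revisited within the step, and offspring
    born during the step do not reproduce before the next one.  Mutates
    ``state`` in place and increments ``state.t``.
    """
    occ, prod, label, psum, nocc, newborn, nbr, n_nbr, absorbing, mode = _kernel_args(state, params)
    perm = np.arange(occ.shape[0], dtype=np.int32)
    _kernels.run_steps(
        occ, prod, label, psum, nocc, newborn, nbr, n_nbr, absorbing, perm, 1,
        params.b, params.c, params.k_move, params.k_death,
        params.mu, params.delta, params.p_max, mode, rng,
    )
    state.t += 1
    return state


@dataclass(frozen=True)
class TrajectoryRecord:
    """Summary of the lattice at one sampling time."""

    t: int
    population_size: int
    mean_p: float  # NaN when the population is extinct
    histogram: np.ndarray  # counts over fixed-width bins on [0, p_max]


#: Default number of production-histogram bins in trajectory records.
DEFAULT_N_BINS = 50


def _record(state: WorldState, params: SimulationParams, n_bins: int) -> TrajectoryRecord:
    vals = state.production_values()
    edges = np.linspace(0.0, params.p_max, n_bins + 1)
    hist, _ = np.histogram(vals, bins=edges)
    mean = float(vals.mean()) if vals.size else float("nan")
    return TrajectoryRecord(
        t=state.t, population_size=int(vals.size), mean_p=mean, histogram=hist
    )


def run(
    params: SimulationParams,
    initial: WorldState,
    n_steps: int,
    sample_every: int = 100,
    rng: np.random.Generator | None = None,
    n_bins: int = DEFAULT_N_BINS,
) -> list[TrajectoryRecord]:
    """Run the Monte-Carlo dynamics for ``n_steps`` steps.

    ``initial`` is advanced in place.  Returns one
    :class:`TrajectoryRecord` for the initial state and one per sampling
    interval; terminates early (the extinction is visible as a final
    record with ``population_size == 0``) if the population dies out.
    Identical seeds yield identical trajectories.
    """
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    if sample_every < 1:
        raise ValueError("sample_every must be >= 1")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    records = [_record(initial, params, n_bins)]
    if n_steps == 0:
        return records
    occ, prod, label, psum, nocc, newborn, nbr, n_nbr, absorbing, mode = _kernel_args(initial, params)
    perm = np.arange(occ.shape[0], dtype=np.int32)
    done = 0
    while done < n_steps:
        chunk = min(sample_every, n_steps - done)
        pop, steps = _kernels.run_steps(
            occ, prod, label, psum, nocc, newborn, nbr, n_nbr, absorbing, perm, chunk,
            params.b, params.c, params.k_move, params.k_death,
            params.mu, params.delta, params.p_max, mode, rng,
        )
        done += steps
        initial.t += steps
        records.append(_record(initial, params, n_bins))
        if pop == 0:
            break
    return records
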