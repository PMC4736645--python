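"""Compiled Monte-Carlo update kernels.

The per-step update visits every node once in a fresh uniform random
permutation and applies events immediately (asynchronous updating):

* empty node: the occupied Moore neighbours compete for replication into
  it; competitor ``i`` wins with probability ``f_i / f_tot * (1 -
  exp(-f_tot))``, nobody replicates with the residual ``exp(-f_tot)``.
  The offspring copies the winner's production rate, mutated with
  probability ``mu`` by a uniform draw from ``[-delta/2, delta/2]`` and
  clipped to ``[0, p_max]``; it inherits the strain label unchanged.
  Offspring placed on an absorbing boundary node are removed immediately.
  Offspring born during the current sweep are present on the lattice
  (they contribute public good and block their node) but are not yet
  eligible to reproduce; they mature at the end of the step.  This keeps
  the random-order scheme equivalent to synchronous updating at the
  front of expanding populations, where within-step reproduction chains
  would otherwise let a wave advance several nodes per step.
* occupied node: with probability ``k_move`` its content is swapped with
  a uniformly chosen adjacent node (moving onto an absorbing node deletes
  the individual); afterwards, whatever then occupies the visited node
  dies with probability ``k_death``.

Fitness is ``f = max(0, B - c*p)`` where the benefit ``B`` is computed
from the producer sums of the current (partially updated) lattice.  To
make the empty-node lottery O(1) per competitor, the kernel maintains
two incremental caches: ``psum[s]`` = total production of the occupied
nodes in the 3x3 block centred on ``s`` (own node included), and
``nocc[s]`` = number of occupied neighbours of ``s`` (own node
excluded; lets the kernel skip the lottery scan in empty bulk).  Then

* weak altruism:            ``B = b * psum / 9``
* strong, split8 (default): ``B = b * (psum - p) / 8``
* strong, discard9:         ``B = b * (psum - p) / 9``

All randomness comes from the single ``numpy.random.Generator`` passed
in; numba shares its bit-generator state with Python-level draws, so a
seed fixes the whole trajectory.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .state import NO_LABEL

# altruism-mode codes for the kernels
MODE_WEAK = 0
MODE_STRONG_SPLIT8 = 1
MODE_STRONG_DISCARD9 = 2


def mode_code(altruism: str, strong_share: str) -> int:
    if altruism == "weak":
        return MODE_WEAK
    return MODE_STRONG_SPLIT8 if strong_share == "split8" else MODE_STRONG_DISCARD9


@njit(cache=True, inline="always")
def _fitness_at(psum_s, p_s, b, c, mode):
    if mode == MODE_WEAK:
        benefit = b * psum_s / 9.0
    elif mode == MODE_STRONG_SPLIT8:
        benefit = b * (psum_s - p_s) / 8.0
    else:
        benefit = b * (psum_s - p_s) / 9.0
    f = benefit - c * p_s
    return f if f > 0.0 else 0.0


@njit(cache=True, inline="always")
def _block_update(psum, nocc, nbr, n_nbr, s, dp, dn):
    """Record a production change ``dp`` (and occupancy change ``dn``)
    at site ``s`` in the neighbourhood caches."""
    psum[s] += dp
    for k in range(n_nbr[s]):
        j = nbr[s, k]
        psum[j] += dp
        nocc[j] += dn


@njit(cache=True, inline="always")
def _shuffle(rng, perm):
    # start from the identity so a step is a pure function of the
    # world state and the stream state (snapshot resume reproducibility)
    for i in range(perm.shape[0]):
        perm[i] = i
    for i in range(perm.shape[0] - 1, 0, -1):
        j = int(rng.random() * (i + 1))
        t = perm[i]
        perm[i] = perm[j]
        perm[j] = t


@njit(cache=True)
def compute_caches(occ, prod, nbr, n_nbr):
    """Recompute the 3x3-block production sums and the occupied-
    neighbour counts from scratch."""
    n = occ.shape[0]
    psum = np.zeros(n, dtype=np.float64)
    nocc = np.zeros(n, dtype=np.int8)
    for s in range(n):
        acc = prod[s] if occ[s] else 0.0
        cnt = 0
        for k in range(n_nbr[s]):
            j = nbr[s, k]
            if occ[j]:
                acc += prod[j]
                cnt += 1
        psum[s] = acc
        nocc[s] = cnt
    return psum, nocc


@njit(cache=True)
def run_steps(
    occ,
    prod,
    label,
    psum,
    nocc,
    newborn,
    nbr,
    n_nbr,
    absorbing,
    perm,
    n_steps,
    b,
    c,
    k_move,
    k_death,
    mu,
    delta,
    p_max,
    mode,
    rng,
):
    """Advance the lattice by up to ``n_steps`` Monte-Carlo steps in place.

    Returns ``(population, steps_done)``; stops after the step on which
    the population reaches zero.
    """
    n = occ.shape[0]
    pop = 0
    for s in range(n):
        if occ[s]:
            pop += 1
    # one uniform decides move-vs-death for non-movers: u < k_move moves,
    # u in [k_move, k_move + k_death*(1-k_move)) dies, conditionally
    # identical to two independent Bernoulli draws
    death_thresh = k_move + k_death * (1.0 - k_move)
    fs = np.empty(8, dtype=np.float64)
    for step in range(n_steps):
        _shuffle(rng, perm)
        for idx in range(n):
            s = perm[idx]
            if occ[s]:
                u = rng.random()
                # movement: swap content with a random adjacent node
                if u < k_move:
                    j = nbr[s, int(rng.random() * n_nbr[s])]
                    if absorbing[j]:
                        # moving into the boundary ring removes the individual
                        _block_update(psum, nocc, nbr, n_nbr, s, -prod[s], -1)
                        occ[s] = False
                        prod[s] = 0.0
                        label[s] = NO_LABEL
                        newborn[s] = 0
                        pop -= 1
                    elif occ[j]:
                        dp = prod[j] - prod[s]
                        if dp != 0.0:
                            _block_update(psum, nocc, nbr, n_nbr, s, dp, 0)
                            _block_update(psum, nocc, nbr, n_nbr, j, -dp, 0)
                        tp = prod[s]
                        prod[s] = prod[j]
                        prod[j] = tp
                        tl = label[s]
                        label[s] = label[j]
                        label[j] = tl
                        tb = newborn[s]
                        newborn[s] = newborn[j]
                        newborn[j] = tb
                    else:
                        p = prod[s]
                        _block_update(psum, nocc, nbr, n_nbr, s, -p, -1)
                        _block_update(psum, nocc, nbr, n_nbr, j, p, 1)
                        occ[s] = False
                        occ[j] = True
                        prod[j] = p
                        prod[s] = 0.0
                        label[j] = label[s]
                        label[s] = NO_LABEL
                        newborn[j] = newborn[s]
                        newborn[s] = 0
                    # death acts on whatever now occupies the visited node
                    if occ[s] and rng.random() < k_death:
                        _block_update(psum, nocc, nbr, n_nbr, s, -prod[s], -1)
                        occ[s] = False
                        prod[s] = 0.0
                        label[s] = NO_LABEL
                        newborn[s] = 0
                        pop -= 1
                elif u < death_thresh:
                    _block_update(psum, nocc, nbr, n_nbr, s, -prod[s], -1)
                    occ[s] = False
                    prod[s] = 0.0
                    label[s] = NO_LABEL
                    newborn[s] = 0
                    pop -= 1
            elif nocc[s] > 0:
                # replication lottery among occupied Moore neighbours
                f_tot = 0.0
                m = n_nbr[s]
                for k in range(m):
                    j = nbr[s, k]
                    if occ[j] and newborn[j] == 0:
                        f = _fitness_at(psum[j], prod[j], b, c, mode)
                    else:
                        f = 0.0
                    fs[k] = f
                    f_tot += f
                if f_tot > 0.0:
                    u = rng.random()
                    scale = (1.0 - math.exp(-f_tot)) / f_tot
                    acc = 0.0
                    winner = -1
                    for k in range(m):
                        acc += fs[k] * scale
                        if u < acc:
                            winner = nbr[s, k]
                            break
                    if winner >= 0:
                        p = prod[winner]
                        if rng.random() < mu:
                            p += (rng.random() - 0.5) * delta
                            if p < 0.0:
                                p = 0.0
                            elif p > p_max:
                                p = p_max
                        if not absorbing[s]:
                            occ[s] = True
                            prod[s] = p
                            label[s] = label[winner]
                            newborn[s] = 1
                            _block_update(psum, nocc, nbr, n_nbr, s, p, 1)
                            pop += 1
                        # else: offspring replicated into the boundary
                        # ring and is removed
        for s in range(n):
            newborn[s] = 0
        if pop == 0:
            return pop, step + 1
    return pop, n_steps
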