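"""Control variants: well-mixed dynamics and mixing perturbations.

Spatial self-organisation is the mechanism under study, so the package
ships the controls that destroy it.  "Mixing" is implemented as a full
uniform random permutation of all node contents applied once before
every Monte-Carlo step: the strongest form of the perturbation, which
guarantees random interactions while keeping the same replication
lottery and demographic stochasticity as the spatial system (no
mean-field recursion is involved).

Modes
-----
``spatial``
    Plain lattice dynamics (identity dispatch to the engine).
``well_mixed``
    Shuffle all node contents before every step, from t = 0.
``mix_from_t``
    Spatial dynamics until ``t = mix_start``, shuffled thereafter —
    the "destroy the evolved patterns mid-run" experiment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels, engine
from ._geometry import neighbor_table
from .params import SimulationParams
from .state import WorldState

MODES = ("spatial", "well_mixed", "mix_from_t")


@dataclass(frozen=True)
class VariantConfig:
    """Which dynamics variant to run, and when mixing starts."""

    mode: str = "spatial"
    mix_start: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode={self.mode!r}; expected one of {MODES}")
        if self.mix_start < 0:
            raise ValueError("mix_start must be >= 0")

    def mixing_active(self, t: int) -> bool:
        if self.mode == "well_mixed":
            return True
        if self.mode == "mix_from_t":
            return t >= self.mix_start
        return False


def shuffle_world(state: WorldState, rng: np.random.Generator) -> WorldState:
    """Uniformly permute the contents of all nodes, in place.

    The multiset of individuals (production rates, labels) is unchanged;
    only positions are randomised.  ``t`` is not advanced.
    """
    n = state.occupancy.size
    idx = rng.permutation(n)
    for arr in (state.occupancy, state.production, state.strain_label):
        flat = arr.ravel()
        flat[:] = flat[idx]
    return state


def step_with_variant(
    state: WorldState,
    params: SimulationParams,
    variant: VariantConfig,
    rng: np.random.Generator,
) -> WorldState:
    """One Monte-Carlo step under the given variant (shuffle-then-step
    when mixing is active at the current ``state.t``)."""
    if variant.mixing_active(state.t):
        shuffle_world(state, rng)
    return engine.monte_carlo_step(state, params, rng)


def run_with_variant(
    params: SimulationParams,
    initial: WorldState,
    variant: VariantConfig,
    n_steps: int,
    sample_every: int = 100,
    rng: np.random.Generator | None = None,
    n_bins: int = engine.DEFAULT_N_BINS,
) -> list[engine.TrajectoryRecord]:
    """Driver like :func:`pglattice.engine.run` but honouring a variant.

    ``spatial`` mode delegates to the engine driver unchanged (identical
    stream consumption, hence trajectory-identical at equal seeds, which
    also covers ``mix_from_t`` with ``mix_start >= n_steps``).
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if variant.mode == "spatial" or (
        variant.mode == "mix_from_t" and variant.mix_start >= initial.t + n_steps
    ):
        return engine.run(params, initial, n_steps, sample_every, rng, n_bins)
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")

    h, w = initial.shape
    nbr, n_nbr, absorbing = neighbor_table(h, w, params.boundary)
    occ = initial.occupancy.ravel()
    prod = initial.production.ravel()
    label = initial.strain_label.ravel()
    mode = _kernels.mode_code(params.altruism, params.strong_share)
    newborn = np.zeros(occ.shape[0], dtype=np.int8)
    perm = np.arange(occ.shape[0], dtype=np.int32)

    records = [engine._record(initial, params, n_bins)]
    since_sample = 0
    for _ in range(n_steps):
        if variant.mixing_active(initial.t):
            idx = rng.permutation(occ.shape[0])
            occ[:] = occ[idx]
            prod[:] = prod[idx]
            label[:] = label[idx]
        psum, nocc = _kernels.compute_caches(occ, prod, nbr, n_nbr)
        pop, _ = _kernels.run_steps(
            occ, prod, label, psum, nocc, newborn, nbr, n_nbr, absorbing, perm, 1,
            params.b, params.c, params.k_move, params.k_death,
            params.mu, params.delta, params.p_max, mode, rng,
        )
        initial.t += 1
        since_sample += 1
        if since_sample == sample_every or pop == 0:
            records.append(engine._record(initial, params, n_bins))
            since_sample = 0
        if pop == 0:
            break
    if since_sample:
        records.append(engine._record(initial, params, n_bins))
    return records
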