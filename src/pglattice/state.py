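"""Lattice world state and the random stream.

A :class:`WorldState` holds the per-node arrays of a simulation: boolean
occupancy, the production rate of the individual on each occupied node,
an optional integer strain label (used by the competition assays, where
it is inherited unchanged on replication), and the elapsed time in
Monte-Carlo steps.

All stochastic draws in a simulation come from a single
``numpy.random.Generator`` (the "random stream"): identical seed +
parameters + code version imply an identical trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import SimulationParams

#: Label value for empty nodes / unlabelled individuals.
NO_LABEL = -1


def make_rng(seed: int) -> np.random.Generator:
    """Create the single seeded random stream for a simulation."""
    return np.random.default_rng(seed)


@dataclass
class WorldState:
    """Lattice occupancy, per-individual production and strain labels.

    Arrays have shape ``(height, width)``; at most one individual per
    node; ``production`` is meaningful only where ``occupancy`` is True
    and is kept at 0 on empty nodes.
    """

    occupancy: np.ndarray  # bool, (h, w)
    production: np.ndarray  # float64, (h, w)
    strain_label: np.ndarray  # int32, (h, w); NO_LABEL where empty/untagged
    t: int = 0

    def __post_init__(self) -> None:
        if not (self.occupancy.shape == self.production.shape == self.strain_label.shape):
            raise ValueError("occupancy, production and strain_label shapes differ")

    # -- constructors -------------------------------------------------

    @classmethod
    def empty(cls, params: SimulationParams) -> "WorldState":
        h, w = params.shape
        return cls(
            occupancy=np.zeros((h, w), dtype=bool),
            production=np.zeros((h, w), dtype=np.float64),
            strain_label=np.full((h, w), NO_LABEL, dtype=np.int32),
        )

    @classmethod
    def filled(cls, params: SimulationParams, p: float, label: int = 0) -> "WorldState":
        """Fully occupied lattice, every individual at production ``p``."""
        state = cls.empty(params)
        state.occupancy[:] = True
        state.production[:] = p
        state.strain_label[:] = label
        return state

    @classmethod
    def random_fill(
        cls,
        params: SimulationParams,
        density: float,
        p: float,
        rng: np.random.Generator,
        label: int = 0,
    ) -> "WorldState":
        """Seed each node independently occupied with probability ``density``."""
        if not 0.0 <= density <= 1.0:
            raise ValueError("density must be in [0, 1]")
        state = cls.empty(params)
        occ = rng.random(params.shape) < density
        state.occupancy[:] = occ
        state.production[occ] = p
        state.strain_label[occ] = label
        return state

    # -- summaries ----------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.occupancy.shape

    def population_size(self) -> int:
        return int(self.occupancy.sum())

    def production_values(self) -> np.ndarray:
        """Production rates of all living individuals (1-D)."""
        return self.production[self.occupancy]

    def mean_production(self) -> float:
        vals = self.production_values()
        return float(vals.mean()) if vals.size else float("nan")

    def copy(self) -> "WorldState":
        return WorldState(
            occupancy=self.occupancy.copy(),
            production=self.production.copy(),
            strain_label=self.strain_label.copy(),
            t=self.t,
        )

    def equals(self, other: "WorldState") -> bool:
        """Field-for-field equality (exact, including production bits)."""
        return (
            self.t == other.t
            and self.shape == other.shape
            and bool(np.array_equal(self.occupancy, other.occupancy))
            and bool(np.array_equal(self.production, other.production))
            and bool(np.array_equal(self.strain_label, other.strain_label))
        )

    def check_invariants(self, params: SimulationParams) -> None:
        """Raise AssertionError if structural invariants are violated."""
        occ = self.occupancy
        assert np.all(self.production[~occ] == 0.0), "production non-zero on empty nodes"
        vals = self.production[occ]
        assert np.all(vals >= 0.0) and np.all(vals <= params.p_max), (
            "production outside [0, p_max]"
        )
        assert np.all(self.strain_label[~occ] == NO_LABEL), "label set on empty node"
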