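"""Model parameters and their validation.

The simulator models a population of public-good producers on a square
lattice with Moore connectivity (k = 8).  Each individual carries a
heritable production rate ``p`` in ``[0, p_max]``; the good it emits is
shared with its neighbourhood.  The parameters below are the complete set
of model constants; an instance of :class:`SimulationParams` plus a seed
fully determines a trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, asdict

#: Moore connectivity of the square lattice (8 surrounding nodes).
CONNECTIVITY = 8

#: Number of shares the produced good is split into under weak altruism
#: (the 8 neighbours plus the producer itself).
N_SHARES = CONNECTIVITY + 1

BOUNDARIES = ("toroidal", "no-flux-absorbing")
ALTRUISM_MODES = ("weak", "strong")
STRONG_SHARE_MODES = ("split8", "discard9")


@dataclass(frozen=True)
class SimulationParams:
    """All model constants and variant switches.

    Parameters
    ----------
    b :
        Benefit per unit of public good received (dimensionless).
    c :
        Fitness cost per unit of public good produced.
    k_death :
        Per-step probability that an occupied node becomes empty.
    k_move :
        Per-step probability that an individual swaps contents with a
        random adjacent node.
    mu :
        Probability that replication mutates the offspring's production
        rate.
    delta :
        Width of the mutation kernel: mutations add a uniform draw from
        ``[-delta/2, +delta/2]``.
    p_max :
        Cap on the production rate; offspring values are clipped to
        ``[0, p_max]``.
    width, height :
        Lattice dimensions in nodes (columns x rows).
    boundary :
        ``"toroidal"`` (wrap-around) or ``"no-flux-absorbing"`` (edges do
        not wrap; the one-node boundary ring absorbs: individuals moving
        or replicating into it are removed, as in the strip invasion
        assays).
    altruism :
        ``"weak"``: the producer receives a ``p/9`` share of its own good;
        ``"strong"``: the producer's good goes only to its neighbours.
    strong_share :
        How strong altruism splits the good.  ``"split8"`` (default):
        ``p/8`` to each of the 8 neighbours, conserving the total emitted;
        ``"discard9"``: ``p/9`` shares as in weak altruism but the
        producer's own share is discarded.
    seed :
        Seed of the single random stream driving the whole simulation.
    """

    b: float = 10.0
    c: float = 4.5
    k_death: float = 0.2
    k_move: float = 0.02
    mu: float = 0.05
    delta: float = 0.1
    p_max: float = 10.0
    width: int = 128
    height: int = 128
    boundary: str = "toroidal"
    altruism: str = "weak"
    strong_share: str = "split8"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("k_death", "k_move", "mu"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v!r} must be a probability in [0, 1]")
        for name in ("b", "c", "delta", "p_max"):
            v = getattr(self, name)
            if v < 0.0:
                raise ValueError(f"{name}={v!r} must be non-negative")
        for name in ("width", "height"):
            v = getattr(self, name)
            if not (isinstance(v, (int,)) and v >= 3):
                raise ValueError(
                    f"{name}={v!r}: lattice dimensions must be integers >= 3 "
                    "(the Moore neighbourhood degenerates below 3)"
                )
        if self.boundary not in BOUNDARIES:
            raise ValueError(f"boundary={self.boundary!r}; expected one of {BOUNDARIES}")
        if self.altruism not in ALTRUISM_MODES:
            raise ValueError(f"altruism={self.altruism!r}; expected one of {ALTRUISM_MODES}")
        if self.strong_share not in STRONG_SHARE_MODES:
            raise ValueError(
                f"strong_share={self.strong_share!r}; expected one of {STRONG_SHARE_MODES}"
            )

    @property
    def connectivity(self) -> int:
        return CONNECTIVITY

    @property
    def shape(self) -> tuple[int, int]:
        """Array shape ``(height, width)`` = (rows, columns)."""
        return (self.height, self.width)

    def with_(self, **kwargs) -> "SimulationParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationParams":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)
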