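"""Experiment protocols: evolutionary runs and cost sweeps on toroidal
lattices, and the mutation-free strip assays (invasion rates, front/back
competition).

The strip assays shape the lattice into a long narrow strip with
no-flux, absorbing boundaries (individuals moving or replicating into
the one-node boundary ring are removed), seed a population on one side
and record the Monte-Carlo time until it reaches the far side.  The
invasion rate is the invaded length divided by that arrival time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels, engine
from ._geometry import neighbor_table
from .analysis import ProductionHistogram
from .params import SimulationParams
from .state import WorldState

#: Strain labels used in the strip assays.
RESIDENT_LABEL = 0
INVADER_LABELS = (1, 2)


# ---------------------------------------------------------------------
# evolutionary runs & cost sweeps
# ---------------------------------------------------------------------


def evolutionary_run(
    params: SimulationParams,
    init_density: float = 1.0,
    init_p: float | None = None,
    n_steps: int = 100_000,
    sample_every: int = 100,
    rng: np.random.Generator | None = None,
    n_bins: int = engine.DEFAULT_N_BINS,
) -> tuple[list[engine.TrajectoryRecord], WorldState]:
    """Seed the lattice and run the evolutionary dynamics.

    The lattice is seeded uniformly at random at ``init_density`` with
    every individual producing ``init_p`` (default: the production cap —
    a population of highly producing individuals).  Returns the sampled
    trajectory and the final world state; terminates early on
    extinction.
    """
    if not 0.0 <= init_density <= 1.0:
        raise ValueError("init_density must be in [0, 1]")
    if init_p is None:
        init_p = params.p_max
    if not 0.0 <= init_p <= params.p_max:
        raise ValueError("init_p must be in [0, p_max]")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if init_density >= 1.0:
        state = WorldState.filled(params, init_p)
    else:
        state = WorldState.random_fill(params, init_density, init_p, rng)
    records = engine.run(params, state, n_steps, sample_every, rng, n_bins)
    return records, state


@dataclass(frozen=True)
class CostSweepResult:
    """Post-burn-in steady-state summary of one evolutionary run."""

    cost: float
    mean_p: float  # pooled over post-burn-in samples; NaN if extinct before burn-in
    histogram: ProductionHistogram  # pooled post-burn-in counts
    extinct: bool
    drift_slope: float  # mean_p drift per step over the last quarter (stationarity check)


def _pool_records(
    records: list[engine.TrajectoryRecord],
    burn_in_t: int,
    p_max: float,
    n_bins: int,
) -> tuple[float, ProductionHistogram, float]:
    post = [r for r in records if r.t >= burn_in_t and r.population_size > 0]
    edges = np.linspace(0.0, p_max, n_bins + 1)
    if not post:
        hist = ProductionHistogram(edges=edges, counts=np.zeros(n_bins, dtype=np.int64), t=-1)
        return float("nan"), hist, float("nan")
    weight = np.array([r.population_size for r in post], dtype=float)
    means = np.array([r.mean_p for r in post])
    mean_p = float((means * weight).sum() / weight.sum())
    counts = np.sum([r.histogram for r in post], axis=0)
    hist = ProductionHistogram(edges=edges, counts=counts, t=post[-1].t)
    # drift check over the last quarter of the run (reported, not enforced)
    tail = post[-max(2, len(post) // 4):]
    if len(tail) >= 2:
        ts = np.array([r.t for r in tail], dtype=float)
        slope = float(np.polyfit(ts, [r.mean_p for r in tail], 1)[0])
    else:
        slope = float("nan")
    return mean_p, hist, slope


def cost_sweep(
    base_params: SimulationParams,
    costs: list[float],
    n_steps: int = 100_000,
    burn_in: float = 0.5,
    sample_every: int = 200,
    rng: np.random.Generator | None = None,
    init_density: float = 1.0,
    init_p: float | None = None,
    n_bins: int = engine.DEFAULT_N_BINS,
) -> list[CostSweepResult]:
    """One evolutionary run per cost; report the post-burn-in pooled
    production distribution, its mean, and an extinction flag.

    ``burn_in`` is the fraction of ``n_steps`` discarded before pooling
    (default: the first half).
    """
    if not costs:
        raise ValueError("costs must be non-empty")
    if not 0.0 <= burn_in < 1.0:
        raise ValueError("burn_in must be a fraction in [0, 1)")
    if rng is None:
        rng = np.random.default_rng(base_params.seed)
    results = []
    for cost in costs:
        params = base_params.with_(c=float(cost))
        records, state = evolutionary_run(
            params, init_density, init_p, n_steps, sample_every, rng, n_bins
        )
        extinct = records[-1].population_size == 0
        mean_p, hist, slope = _pool_records(
            records, int(burn_in * n_steps), params.p_max, n_bins
        )
        results.append(CostSweepResult(float(cost), mean_p, hist, extinct, slope))
    return results


# ---------------------------------------------------------------------
# strip assays
# ---------------------------------------------------------------------


@dataclass(frozen=True)
class InvasionScenario:
    """Descriptor of a mutation-free strip invasion assay.

    ``cooperators_into_empty``: the invading strain is seeded on one
    side of an otherwise empty strip.  ``selfish_into_cooperators``: a
    homogeneous resident population of cooperators fills the strip and
    the invading strain replaces them in the seeded columns.
    """

    kind: str  # "cooperators_into_empty" | "selfish_into_cooperators"
    invader_p: float
    resident_p: float = 6.0  # unused for empty-space invasion
    strip_length: int = 512
    strip_width: int = 32
    c: float = 4.0
    b: float = 10.0
    seed_cols: int = 8

    def __post_init__(self) -> None:
        if self.kind not in ("cooperators_into_empty", "selfish_into_cooperators"):
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if self.strip_length <= self.strip_width:
            raise ValueError("strips must be long: strip_length > strip_width")
        if self.strip_width < 3 or self.strip_length < self.seed_cols + 4:
            raise ValueError("strip too small for seeding + detection")

    @property
    def detection_col(self) -> int:
        """Last interior column before the far absorbing ring."""
        return self.strip_length - 2

    @property
    def invaded_length(self) -> int:
        """Distance from the seeded region's edge to the detection column."""
        return self.detection_col - self.seed_cols


@dataclass(frozen=True)
class InvasionMeasurement:
    scenario: InvasionScenario
    arrival_time: int | None  # Monte-Carlo steps; None if never arrived
    invasion_rate: float  # nodes per step; 0 when flagged extinct
    extinct: bool = False


def strip_params(scenario: InvasionScenario, base: SimulationParams) -> SimulationParams:
    """Base parameters reshaped for the strip: no-flux absorbing
    boundaries, mutation off, scenario geometry and cost/benefit."""
    return base.with_(
        width=scenario.strip_length,
        height=scenario.strip_width,
        boundary="no-flux-absorbing",
        mu=0.0,
        c=scenario.c,
        b=scenario.b,
    )


def _build_strip(
    scenario: InvasionScenario, params: SimulationParams, split_ps: tuple[float, float] | None
) -> WorldState:
    """Seed the strip.  With ``split_ps`` the seeded block is split into
    two labelled half-width blocks abreast (competition assays);
    otherwise the whole block carries the invader strain (label 1)."""
    state = WorldState.empty(params)
    h, w = params.shape
    rows = slice(1, h - 1)
    if scenario.kind == "selfish_into_cooperators":
        state.occupancy[rows, 1 : w - 1] = True
        state.production[rows, 1 : w - 1] = scenario.resident_p
        state.strain_label[rows, 1 : w - 1] = RESIDENT_LABEL
    cols = slice(1, 1 + scenario.seed_cols)
    if split_ps is None:
        state.occupancy[rows, cols] = True
        state.production[rows, cols] = scenario.invader_p
        state.strain_label[rows, cols] = INVADER_LABELS[0]
    else:
        interior = np.arange(1, h - 1)
        half = len(interior) // 2
        for block_rows, lab, p in (
            (interior[:half], INVADER_LABELS[0], split_ps[0]),
            (interior[half:], INVADER_LABELS[1], split_ps[1]),
        ):
            state.occupancy[np.ix_(block_rows, np.arange(1, 1 + scenario.seed_cols))] = True
            state.production[np.ix_(block_rows, np.arange(1, 1 + scenario.seed_cols))] = p
            state.strain_label[np.ix_(block_rows, np.arange(1, 1 + scenario.seed_cols))] = lab
    return state


class _StripRunner:
    """Steps a strip world one Monte-Carlo step at a time, keeping the
    producer-sum cache alive between steps."""

    def __init__(self, state: WorldState, params: SimulationParams, rng):
        h, w = state.shape
        self.nbr, self.n_nbr, self.absorbing = neighbor_table(h, w, params.boundary)
        self.occ = state.occupancy.ravel()
        self.prod = state.production.ravel()
        self.label = state.strain_label.ravel()
        self.psum, self.nocc = _kernels.compute_caches(self.occ, self.prod, self.nbr, self.n_nbr)
        self.newborn = np.zeros(self.occ.shape[0], dtype=np.int8)
        self.mode = _kernels.mode_code(params.altruism, params.strong_share)
        self.perm = np.arange(self.occ.shape[0], dtype=np.int32)
        self.state = state
        self.params = params
        self.rng = rng

    def step(self, n: int = 1) -> int:
        p = self.params
        pop, steps = _kernels.run_steps(
            self.occ, self.prod, self.label, self.psum, self.nocc, self.newborn,
            self.nbr, self.n_nbr, self.absorbing, self.perm, n,
            p.b, p.c, p.k_move, p.k_death, p.mu, p.delta, p.p_max, self.mode, self.rng,
        )
        self.state.t += steps
        return pop


def invasion_assay(
    scenario: InvasionScenario,
    params: SimulationParams | None = None,
    rng: np.random.Generator | None = None,
    max_steps: int = 100_000,
) -> InvasionMeasurement:
    """Measure the invasion rate of a strain traversing the strip.

    Arrival is the first Monte-Carlo step at which any invader-strain
    individual occupies the detection column (the last interior column);
    the rate is the invaded length divided by the arrival time.  If the
    invading strain dies out first the rate is 0 and the measurement is
    flagged extinct.
    """
    base = params if params is not None else SimulationParams()
    sp = strip_params(scenario, base)
    if rng is None:
        rng = np.random.default_rng(sp.seed)
    state = _build_strip(scenario, sp, None)
    runner = _StripRunner(state, sp, rng)
    det = scenario.detection_col
    occ2 = state.occupancy
    lab2 = state.strain_label
    for _ in range(max_steps):
        runner.step(1)
        if np.any(occ2[:, det] & (lab2[:, det] == INVADER_LABELS[0])):
            t = state.t
            return InvasionMeasurement(scenario, t, scenario.invaded_length / t)
        if not np.any(lab2[state.occupancy] == INVADER_LABELS[0]):
            return InvasionMeasurement(scenario, None, 0.0, extinct=True)
    return InvasionMeasurement(scenario, None, 0.0, extinct=False)


@dataclass(frozen=True)
class CompetitionOutcome:
    """Result of a pairwise strip competition assay."""

    position: str  # "front" | "back"
    strain_ps: tuple[float, float]
    winner: int | None  # 1, 2, or None for coexistence at timeout
    t: int
    reason: str  # "front_fixation" | "rival_extinct" | "timeout"

    @property
    def winner_p(self) -> float | None:
        return None if self.winner is None else self.strain_ps[self.winner - 1]


def competition_assay(
    position: str,
    strain_ps: tuple[float, float],
    params: SimulationParams | None = None,
    rng: np.random.Generator | None = None,
    resident_p: float = 6.0,
    c: float = 4.0,
    b: float = 10.0,
    strip_length: int = 2048,
    strip_width: int = 32,
    seed_cols: int = 8,
    front_depth: int | None = None,
    max_steps: int = 30_000,
    check_every: int = 5,
) -> CompetitionOutcome:
    """Race two labelled strains seeded abreast on a strip.

    ``front``: two cooperator blocks expand into an empty strip — the
    assay probes selection at the front of a travelling wave.  ``back``:
    two selfish blocks invade a homogeneous resident cooperator
    population — selection in the back of a wave.  The winner is the
    strain that owns the advancing front (is the only invader label
    within ``front_depth`` columns of the leading edge) once the wave
    reaches the far detection column, or the survivor if its rival goes
    extinct first.  The long default strip (2048 nodes) gives the
    front-speed differences time to integrate into a decisive takeover.
    """
    if position not in ("front", "back"):
        raise ValueError("position must be 'front' or 'back'")
    kind = "cooperators_into_empty" if position == "front" else "selfish_into_cooperators"
    scenario = InvasionScenario(
        kind=kind,
        invader_p=strain_ps[0],
        resident_p=resident_p,
        strip_length=strip_length,
        strip_width=strip_width,
        c=c,
        b=b,
        seed_cols=seed_cols,
    )
    base = params if params is not None else SimulationParams()
    sp = strip_params(scenario, base)
    if rng is None:
        rng = np.random.default_rng(sp.seed)
    if front_depth is None:
        front_depth = strip_width
    state = _build_strip(scenario, sp, strain_ps)
    runner = _StripRunner(state, sp, rng)
    det = scenario.detection_col
    occ2, lab2 = state.occupancy, state.strain_label
    while state.t < max_steps:
        runner.step(check_every)
        inv_mask = occ2 & ((lab2 == 1) | (lab2 == 2))
        n1 = int(np.count_nonzero(occ2 & (lab2 == 1)))
        n2 = int(np.count_nonzero(occ2 & (lab2 == 2)))
        if n1 == 0 and n2 == 0:
            return CompetitionOutcome(position, strain_ps, None, state.t, "both_extinct")
        if n1 == 0 or n2 == 0:
            return CompetitionOutcome(
                position, strain_ps, 1 if n2 == 0 else 2, state.t, "rival_extinct"
            )
        cols = np.flatnonzero(inv_mask.any(axis=0))
        lead = int(cols.max())
        if lead >= det:
            region = inv_mask[:, max(0, lead - front_depth + 1) : lead + 1]
            labels = np.unique(lab2[:, max(0, lead - front_depth + 1) : lead + 1][region])
            if len(labels) == 1:
                return CompetitionOutcome(
                    position, strain_ps, int(labels[0]), state.t, "front_fixation"
                )
            return CompetitionOutcome(position, strain_ps, None, state.t, "mixed_front")
    return CompetitionOutcome(position, strain_ps, None, state.t, "timeout")
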