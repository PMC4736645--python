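"""Configuration, snapshots, rendering, CSV export and run manifests."""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .engine import TrajectoryRecord
from .params import SimulationParams
from .state import WorldState
from .variants import VariantConfig

SNAPSHOT_FORMAT = "pglattice-world"
SNAPSHOT_VERSION = 1


# ---------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------

_VARIANT_KEYS = {"mode", "mix_start"}


def load_config(path) -> tuple[SimulationParams, VariantConfig, dict]:
    """Read a YAML config file.

    Top-level keys are :class:`SimulationParams` fields (missing keys
    take the standard defaults: b=10, k_death=0.2, k_move=0.02, mu=0.05,
    delta=0.1, p_max=10), plus the variant keys ``mode``/``mix_start``
    and an optional free-form ``experiment:`` mapping, returned as a
    dict.  Unknown keys and out-of-range values raise ``ValueError``.
    """
    text = Path(path).read_text()
    raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path}: expected a mapping at top level")
    experiment = raw.pop("experiment", {}) or {}
    if not isinstance(experiment, dict):
        raise ValueError("'experiment' must be a mapping")
    variant_kwargs = {k: raw.pop(k) for k in list(raw) if k in _VARIANT_KEYS}
    params = SimulationParams.from_dict(raw)  # rejects unknown keys
    variant = VariantConfig(**variant_kwargs)
    return params, variant, experiment


# ---------------------------------------------------------------------
# snapshots
# ---------------------------------------------------------------------


def save_snapshot(
    state: WorldState, path, params: SimulationParams | None = None
) -> None:
    """Write a portable JSON snapshot of the world state.

    Production rates are serialised via ``repr``-style shortest
    round-trip floats, so ``load(save(s))`` equals ``s`` bit for bit.
    The parameter set (including the seed) is embedded when given.
    """
    h, w = state.shape
    doc = {
        "format": SNAPSHOT_FORMAT,
        "version": SNAPSHOT_VERSION,
        "height": h,
        "width": w,
        "t": state.t,
        "occupancy": state.occupancy.astype(int).tolist(),
        "production": state.production.tolist(),
        "strain_label": state.strain_label.tolist(),
    }
    if params is not None:
        doc["params"] = params.to_dict()
    Path(path).write_text(json.dumps(doc))


def load_snapshot(path) -> WorldState:
    """Read a snapshot written by :func:`save_snapshot`."""
    doc = _read_snapshot_doc(path)
    state = WorldState(
        occupancy=np.array(doc["occupancy"], dtype=bool),
        production=np.array(doc["production"], dtype=np.float64),
        strain_label=np.array(doc["strain_label"], dtype=np.int32),
        t=int(doc["t"]),
    )
    if state.shape != (doc["height"], doc["width"]):
        raise ValueError(f"snapshot {path}: array shapes disagree with header")
    return state


def load_snapshot_params(path) -> SimulationParams | None:
    """Parameter set embedded in a snapshot, if any."""
    doc = _read_snapshot_doc(path)
    return SimulationParams.from_dict(doc["params"]) if "params" in doc else None


def _read_snapshot_doc(path) -> dict:
    try:
        doc = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ValueError(f"cannot read snapshot {path}: {exc}") from exc
    if not isinstance(doc, dict) or doc.get("format") != SNAPSHOT_FORMAT:
        raise ValueError(f"{path} is not a {SNAPSHOT_FORMAT} snapshot")
    return doc


# ---------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------


def render_world(
    state: WorldState, path, p_max: float = 10.0, scale: int = 1, cmap: str = "viridis"
) -> None:
    """Write a PNG with one pixel block per node.

    Empty nodes are white; occupied nodes are coloured on a monotone
    colour scale in the production rate ``p`` over ``[0, p_max]``.
    """
    import matplotlib

    cm = matplotlib.colormaps[cmap]
    with np.errstate(invalid="ignore"):
        rgba = cm(np.clip(state.production / p_max if p_max > 0 else 0.0, 0.0, 1.0))
    rgba[~state.occupancy] = (1.0, 1.0, 1.0, 1.0)
    if scale > 1:
        rgba = np.repeat(np.repeat(rgba, scale, axis=0), scale, axis=1)
    import matplotlib.image

    matplotlib.image.imsave(str(path), rgba)


# ---------------------------------------------------------------------
# trajectory CSV
# ---------------------------------------------------------------------


def trajectory_to_frame(records: list[TrajectoryRecord]) -> pd.DataFrame:
    """Columns ``t``, ``population_size``, ``mean_p``, ``bin_0..bin_{k-1}``."""
    if not records:
        raise ValueError("no records")
    n_bins = len(records[0].histogram)
    rows = []
    for r in records:
        row = {"t": r.t, "population_size": r.population_size, "mean_p": r.mean_p}
        row.update({f"bin_{i}": int(r.histogram[i]) for i in range(n_bins)})
        rows.append(row)
    return pd.DataFrame(rows)


def save_trajectory(records: list[TrajectoryRecord], path) -> None:
    trajectory_to_frame(records).to_csv(path, index=False)


# ---------------------------------------------------------------------
# run manifests
# ---------------------------------------------------------------------


@dataclass(frozen=True)
class RunManifest:
    """Everything needed to re-execute a run bit-identically."""

    params: dict
    variant: dict
    seed: int
    code_version: str = _pkg_version
    start_step: int = 0
    end_step: int = 0
    outputs: tuple[str, ...] = ()

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def load(cls, path) -> "RunManifest":
        doc = json.loads(Path(path).read_text())
        doc["outputs"] = tuple(doc.get("outputs", ()))
        return cls(**doc)

    @classmethod
    def for_run(
        cls,
        params: SimulationParams,
        variant: VariantConfig,
        start_step: int,
        end_step: int,
        outputs=(),
    ) -> "RunManifest":
        return cls(
            params=params.to_dict(),
            variant=asdict(variant),
            seed=params.seed,
            start_step=start_step,
            end_step=end_step,
            outputs=tuple(str(o) for o in outputs),
        )
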