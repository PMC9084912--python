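"""Simulation driver: Monte Carlo loop, per-MCS model updates, track output.

One MCS performs ``width * height`` elementary copy attempts (compiled
kernel), after which the per-MCS model state advances: Act activities
decay, persistence target directions and smoothed movement directions blend
in the latest centroid displacement, and pseudopod state machines step.
Cell centroids (unwrapped across the periodic boundary) are recorded at the
configured interval once the equilibration phase has passed.

All randomness flows from one ``numpy.random.Generator``; a run is a pure
function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import kernel
from .analysis import TrackSet
from .config import SimulationConfig
from .core import CPMState, initialize_random_cells
from .persistence import act_decay
from .pseudopod import PseudopodEngine

__all__ = ["SimResult", "run_simulation"]

_PSEUDOPOD_MODELS = ("ariotti", "pseudopod-ext")


@dataclass
class SimResult:
    tracks: TrackSet
    state: CPMState
    config: SimulationConfig
    accepted: int = 0
    snapshots: list = field(default_factory=list)  # (mcs, owner copy [, actin])
    engine: PseudopodEngine | None = None


def _model_setup(config: SimulationConfig):
    m = config.model
    flags = kernel.pack_flags(
        persistence=(m == "persistence"),
        act=(m == "act"),
        actin=(m in _PSEUDOPOD_MODELS),
        pull=(m == "pseudopod-ext" and config.extension.pull_strength != 0),
        tip=(m == "pseudopod-ext" and config.extension.tip_bonus != 0),
        connectivity=config.connectivity,
    )
    params = kernel.pack_params(
        temperature=config.temperature,
        lambda_p=config.persistence.lambda_p,
        lambda_act=config.act.lambda_act,
        max_act=config.act.max_act,
        actin_bonus=config.pseudopod.neighboring_actin_bonus,
        pull_strength=config.extension.pull_strength,
        r_max=config.extension.r_max,
        tip_bonus=config.extension.tip_bonus,
    )
    return flags, params


def _blend_directions(vec: np.ndarray, delta: np.ndarray, decay_time: float,
                      alive: np.ndarray) -> None:
    """vec <- (1-dr) vec + dr * delta/|delta| for cells that moved."""
    dr = min(1.0 / decay_time, 1.0)
    norms = np.hypot(delta[:, 0], delta[:, 1])
    mask = alive & (norms > 0)
    if not np.any(mask):
        return
    unit = delta[mask] / norms[mask, None]
    vec[mask] = (1.0 - dr) * vec[mask] + dr * unit


def run_simulation(config: SimulationConfig,
                   seed: int | None = None,
                   on_mcs=None) -> SimResult:
    """Run a full simulation and return tracks plus final state.

    ``seed`` overrides ``config.seed``; one of the two must be set for a
    reproducible run (None falls back to OS entropy).  ``on_mcs``, if given,
    is called as ``on_mcs(mcs, state, engine)`` after every completed MCS
    (instrumentation hook; must not mutate the state).
    """
    config.validate()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    state = initialize_random_cells(config, rng)
    engine = None
    if config.model in _PSEUDOPOD_MODELS:
        engine = PseudopodEngine(state, config.pseudopod, config.extension)
    flags, params = _model_setup(config)
    w, h = state.width, state.height
    n_attempts = w * h
    use_act = config.model == "act"
    use_pers = config.model == "persistence"
    snapshots = []
    times: list[int] = []
    recorded: list[np.ndarray] = []  # centroids per recorded MCS
    prev_centroids = state.centroids()
    if config.equilibration_mcs == 0:
        times.append(0)
        recorded.append(prev_centroids.copy())
    accepted = 0
    for mcs in range(config.total_mcs):
        targets = rng.integers(0, n_attempts, size=n_attempts)
        nbrs = rng.integers(0, 8, size=n_attempts)
        urand = rng.random(n_attempts)
        accepted += kernel.run_mcs(
            state.owner, state.ctype, state.contact.j,
            state.area, state.target_area, state.lambda_area,
            state.sum_x, state.sum_y,
            state.act, state.target_dir, state.actin_owner,
            state.pod_vector, state.tips, state.tip_ok,
            params, flags, targets, nbrs, urand)
        if use_act:
            act_decay(state.act)
        centroids = state.centroids()
        alive = state.area > 0
        delta = centroids - prev_centroids
        delta[~alive] = 0.0
        if use_pers:
            _blend_directions(state.target_dir, delta,
                              config.persistence.decay_time, alive)
        if engine is not None:
            _blend_directions(state.move_dir, delta,
                              config.pseudopod.move_dir_decay_time, alive)
            engine.step(rng)
        prev_centroids = centroids
        if on_mcs is not None:
            on_mcs(mcs, state, engine)
        t = mcs + 1
        if (t >= config.equilibration_mcs
                and (t - config.equilibration_mcs) % config.track_interval == 0):
            times.append(t)
            recorded.append(centroids.copy())
        if (config.snapshot_interval
                and t % config.snapshot_interval == 0):
            snap = [t, state.owner.copy()]
            if engine is not None:
                snap.append(state.actin_owner.copy())
            snapshots.append(tuple(snap))
    # assemble tidy track table: one row per live cell per recorded MCS
    rows = []
    for t, cents in zip(times, recorded):
        live = np.flatnonzero(~np.isnan(cents[:, 0]))
        live = live[live > 0]
        rows.append(pd.DataFrame({
            "track_id": live, "t": float(t),
            "x": cents[live, 0], "y": cents[live, 1],
        }))
    df = (pd.concat(rows, ignore_index=True) if rows
          else pd.DataFrame(columns=["track_id", "t", "x", "y"]))
    tracks = TrackSet(df, window=(w, h))
    return SimResult(tracks=tracks, state=state, config=config,
                     accepted=accepted, snapshots=snapshots, engine=engine)
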