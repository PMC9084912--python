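"""Published persistence extensions: basic persistent motion and the Act model.

Basic persistence gives every cell a decaying target direction ``t`` built
from its recent centroid displacements; copy attempts moving a cell along
``t`` are favored with strength ``lambda_p`` (scaled by cell area, which for
a single cell type of near-constant area is simply a rescaling of
``lambda_p``).

The Act model stores a per-site protrusive activity: a freshly conquered
site receives ``max_act`` and the value decays by one each MCS.  Copies
from a high-activity neighborhood context into a lower-activity one are
energetically favored, creating the local positive feedback that produces
persistent motion.

These functions are the reference (oracle) forms of the terms the compiled
kernel applies during production runs.
"""

from __future__ import annotations

import math

import numpy as np

from .core import CPMState, CopyAttempt, MOORE_OFFSETS

__all__ = [
    "update_target_direction",
    "delta_h_basic_persistence",
    "act_on_successful_copy",
    "act_decay",
    "act_geometric_mean",
    "delta_h_act",
]


def update_target_direction(t_old, dx, decay_time: float):
    """Blend the previous target direction with the latest centroid shift.

    t_new = (1 - dr) t_old + dr dx/|dx| with dr = min(1/decay_time, 1).
    A zero displacement leaves the target direction unchanged (the
    continuous limit of the update; a zero vector cannot be normalized).
    """
    if decay_time < 1:
        raise ValueError("decay_time must be >= 1")
    t_old = np.asarray(t_old, dtype=float)
    dx = np.asarray(dx, dtype=float)
    norm = float(np.hypot(dx[0], dx[1]))
    if norm == 0.0:
        return t_old.copy()
    dr = min(1.0 / decay_time, 1.0)
    return (1.0 - dr) * t_old + dr * dx / norm


def delta_h_basic_persistence(state: CPMState, attempt: CopyAttempt,
                              lambda_p: float) -> float:
    """Sum over involved cells of -lambda_p * area * (s . t); medium -> 0."""
    dh = 0.0
    sx, sy = attempt.s
    for sigma in attempt.involved:
        if sigma == 0:
            continue
        t = state.target_dir[sigma]
        dh -= lambda_p * float(state.area[sigma]) * (sx * t[0] + sy * t[1])
    return dh


def act_on_successful_copy(state: CPMState, x: int, y: int,
                           max_act: float) -> None:
    """Assign maximum activity to a conquered site (0 if lost to medium)."""
    state.act[y, x] = max_act if state.owner[y, x] != 0 else 0.0


def act_decay(act: np.ndarray) -> None:
    """Once per MCS: decrement every positive activity, floor at zero."""
    np.subtract(act, 1.0, out=act, where=act > 0)
    np.maximum(act, 0.0, out=act)


def act_geometric_mean(state: CPMState, x: int, y: int) -> float:
    """Geometric mean of activities over the Moore neighborhood (including
    the central site, the original Act convention) restricted to sites
    sharing the central site's cell identifier; 0 for a medium site."""
    o = int(state.owner[y, x])
    if o == 0:
        return 0.0
    w, h = state.width, state.height
    values = []
    for dx, dy in list(MOORE_OFFSETS) + [(0, 0)]:
        xx, yy = (x + dx) % w, (y + dy) % h
        if state.owner[yy, xx] == o:
            values.append(float(state.act[yy, xx]))
    if any(v == 0.0 for v in values):
        return 0.0
    return math.exp(sum(math.log(v) for v in values) / len(values))


def delta_h_act(state: CPMState, attempt: CopyAttempt,
                lambda_act: float, max_act: float) -> float:
    """Activity term: -(lambda_act/max_act) * (GM(source) - GM(target)).

    Negative (favorable) when the source side sits in a more active
    context than the target side, so protrusion continues where the cell
    recently protruded.
    """
    xs, ys = attempt.source
    x, y = attempt.target
    gm_src = act_geometric_mean(state, xs, ys)
    gm_tgt = act_geometric_mean(state, x, y)
    return -(lambda_act / max_act) * (gm_src - gm_tgt)
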