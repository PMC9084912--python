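"""Explicit pseudopods: a finite state machine over actin-site chains.

Each cell owns a fixed number of pseudopods.  A pseudopod cycles through

    INIT -> GROWING -> RETRACTING -> INACTIVE -> INIT ...

INIT places the first actin site at the cell's rounded centroid (retrying
next MCS if that pixel is not currently owned by the cell) and draws a
growth direction from a von Mises distribution centered on the cell's
smoothed movement direction (concentration ``kappa_init``).  While GROWING,
each MCS the chain extends with probability ``p_ext`` by one Moore step in
a direction drawn from a von Mises centered on the current growth direction
(``kappa_cont``), discretized to the nearest of the 8 lattice steps; the
continuous growth direction is kept separately so repeated discretization
does not lock the chain onto a lattice axis.  Growth into a foreign cell is
a "touch" event handled by the configured touch behavior.  RETRACTING
removes one site per MCS with probability ``p_retr`` from the tip
(``backward``) or the origin (``forward``, treadmilling).  An emptied chain
goes INACTIVE, returning to INIT each MCS with probability
1/``time_between_extensions``.  The ``attach`` touch behavior adds a
TOUCHING state that falls into RETRACTING with probability ``p_touch_retr``
per MCS.

Coupling to the lattice dynamics: growth of the owning cell next to its own
actin receives an energy bonus, shrinkage next to its own actin is blocked
(infinite energy), pseudopods exert a pulling force along the vector sum of
their origin-to-tip vectors, and pseudopod tips near a cell-cell interface
act adhesively.  The reference forms of these energy terms live here; the
compiled kernel applies identical math during production runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import ExtensionParams, PseudopodParams
from .core import CPMState, CopyAttempt, MOORE_OFFSETS

__all__ = [
    "INIT", "GROWING", "RETRACTING", "INACTIVE", "TOUCHING",
    "Pseudopod", "PseudopodEngine",
    "sample_von_mises_direction", "discretize_direction",
    "pseudopod_vector_sum", "delta_h_actin_coupling",
    "delta_h_pulling", "delta_h_tip_adhesion", "handle_touch",
]

INIT = "INIT"
GROWING = "GROWING"
RETRACTING = "RETRACTING"
INACTIVE = "INACTIVE"
TOUCHING = "TOUCHING"


def sample_von_mises_direction(mean_direction, kappa: float,
                               rng: np.random.Generator):
    """Unit vector at a von Mises angle around ``mean_direction``.

    ``kappa = 0`` reduces to the uniform distribution on the circle; a zero
    mean direction is treated as uniform as well (no direction to center on).
    """
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    mx, my = float(mean_direction[0]), float(mean_direction[1])
    if mx == 0.0 and my == 0.0:
        kappa = 0.0
    mu = math.atan2(my, mx)
    ang = float(rng.vonmises(mu, kappa)) if kappa > 0 else float(
        rng.uniform(-math.pi, math.pi))
    return (math.cos(ang), math.sin(ang))


def discretize_direction(direction) -> tuple[int, int]:
    """Nearest of the 8 Moore steps to a continuous direction."""
    dx, dy = float(direction[0]), float(direction[1])
    best, best_dot = (1, 0), -2.0
    norm = math.hypot(dx, dy)
    if norm == 0:
        raise ValueError("cannot discretize a zero direction")
    dx, dy = dx / norm, dy / norm
    for ox, oy in MOORE_OFFSETS:
        n = math.hypot(ox, oy)
        dot = (ox * dx + oy * dy) / n
        if dot > best_dot:
            best_dot = dot
            best = (int(ox), int(oy))
    return best


@dataclass
class Pseudopod:
    """FSM state plus the ordered actin chain (origin first, tip last)."""

    state: str = INACTIVE
    chain: list[tuple[int, int]] = field(default_factory=list)
    growth_dir: tuple[float, float] = (1.0, 0.0)
    growth_timer: int = 0
    stall: int = 0

    @property
    def tip(self):
        return self.chain[-1] if self.chain else None

    @property
    def origin(self):
        return self.chain[0] if self.chain else None

    def vector(self, width: int, height: int) -> tuple[float, float]:
        """Origin-to-tip vector with periodic minimum image; empty -> (0,0)."""
        if len(self.chain) < 2:
            return (0.0, 0.0)
        ox, oy = self.chain[0]
        tx, ty = self.chain[-1]
        dx = float(tx - ox)
        dx -= width * round(dx / width)
        dy = float(ty - oy)
        dy -= height * round(dy / height)
        return (dx, dy)


def pseudopod_vector_sum(pods, width: int, height: int) -> tuple[float, float]:
    """Vector sum of origin-to-tip vectors over a cell's pseudopods."""
    fx = fy = 0.0
    for pod in pods:
        vx, vy = pod.vector(width, height)
        fx += vx
        fy += vy
    return (fx, fy)


def handle_touch(pod: Pseudopod, behavior: str, move_dir,
                 rng: np.random.Generator, ext: ExtensionParams,
                 width: int, height: int,
                 remove_actin=None) -> None:
    """React to a growth attempt into a neighboring cell (already rejected).

    nothing:  continue as before.
    retract:  enter RETRACTING.
    attach:   enter TOUCHING (per-MCS probability ``p_touch_retr`` of
              falling into RETRACTING handled by the engine step).
    poof-dir: if the pseudopod points laterally relative to the cell's
              movement direction (cos(alpha) < threshold) the whole chain is
              removed instantly and the pseudopod re-enters INIT.
    """
    if behavior == "nothing":
        return
    if behavior == "retract":
        pod.state = RETRACTING
        return
    if behavior == "attach":
        pod.state = TOUCHING
        return
    if behavior == "poof-dir":
        px, py = pod.vector(width, height)
        pn = math.hypot(px, py)
        mx, my = float(move_dir[0]), float(move_dir[1])
        mn = math.hypot(mx, my)
        if pn == 0.0 or mn == 0.0:
            return  # direction undefined; not considered lateral
        cos_alpha = (px * mx + py * my) / (pn * mn)
        if cos_alpha < ext.lateral_threshold:
            if remove_actin is not None:
                for site in pod.chain:
                    remove_actin(site)
            pod.chain.clear()
            pod.state = INIT
            pod.growth_timer = 0
            pod.stall = 0
        return
    raise ValueError(f"unknown touch behavior {behavior!r}")


class PseudopodEngine:
    """Owns all pseudopods of a simulation and advances them once per MCS."""

    def __init__(self, state: CPMState, params: PseudopodParams,
                 ext: ExtensionParams):
        self.state = state
        self.params = params
        self.ext = ext
        n = state.n_cells
        npod = params.n_pseudopods
        self.pods: list[list[Pseudopod]] = [
            [Pseudopod() for _ in range(npod)] for _ in range(n + 1)
        ]
        state.tips = np.zeros((n + 1, npod, 2))
        state.tip_ok = np.zeros((n + 1, npod), dtype=np.bool_)

    # -- actin occupancy ------------------------------------------------
    def _add_actin(self, sigma: int, site) -> None:
        x, y = site
        st = self.state
        st.actin_count[y, x] += 1
        st.actin_owner[y, x] = sigma

    def _remove_actin(self, site) -> None:
        x, y = site
        st = self.state
        st.actin_count[y, x] -= 1
        if st.actin_count[y, x] <= 0:
            st.actin_count[y, x] = 0
            st.actin_owner[y, x] = 0

    # -- FSM ------------------------------------------------------------
    def step(self, rng: np.random.Generator) -> None:
        """Advance every pseudopod of every live cell by one MCS."""
        st = self.state
        for sigma in range(1, st.n_cells + 1):
            if st.area[sigma] == 0:
                continue
            move = st.move_dir[sigma]
            for pod in self.pods[sigma]:
                self._step_pod(sigma, pod, move, rng)
        self.refresh_aggregates()

    def _step_pod(self, sigma: int, pod: Pseudopod, move,
                  rng: np.random.Generator) -> None:
        st = self.state
        p = self.params
        if pod.state == INACTIVE:
            if rng.random() < 1.0 / p.time_between_extensions:
                pod.state = INIT
            return
        if pod.state == INIT:
            cx, cy = st.centroid(sigma)
            x = int(round(cx)) % st.width
            y = int(round(cy)) % st.height
            if st.owner[y, x] == sigma:
                pod.chain = [(x, y)]
                self._add_actin(sigma, (x, y))
                pod.growth_dir = sample_von_mises_direction(move, p.kappa_init,
                                                            rng)
                pod.growth_timer = 0
                pod.stall = 0
                pod.state = GROWING
            return  # rounded centroid not owned: retry next MCS
        if pod.state == GROWING:
            pod.growth_timer += 1
            if pod.growth_timer > p.max_growth_time or pod.stall >= p.stall_limit:
                pod.state = RETRACTING
                return
            extended = False
            if rng.random() < p.p_ext:
                direction = sample_von_mises_direction(pod.growth_dir,
                                                       p.kappa_cont, rng)
                ox, oy = discretize_direction(direction)
                tx, ty = pod.tip
                nx, ny = (tx + ox) % st.width, (ty + oy) % st.height
                target_owner = int(st.owner[ny, nx])
                if target_owner == sigma:
                    pod.chain.append((nx, ny))
                    self._add_actin(sigma, (nx, ny))
                    norm = math.hypot(ox, oy)
                    pod.growth_dir = (ox / norm, oy / norm)
                    pod.stall = 0
                    extended = True
                elif target_owner != 0:
                    handle_touch(pod, self.ext.touch_behavior, move, rng,
                                 self.ext, st.width, st.height,
                                 remove_actin=self._remove_actin)
            if not extended:
                pod.stall += 1
            return
        if pod.state == TOUCHING:
            if rng.random() < self.ext.p_touch_retr:
                pod.state = RETRACTING
            return
        if pod.state == RETRACTING:
            if pod.chain and rng.random() < p.p_retr:
                if p.retraction_mode == "forward":
                    site = pod.chain.pop(0)
                else:
                    site = pod.chain.pop()
                self._remove_actin(site)
            if not pod.chain:
                pod.state = INACTIVE
            return

    def refresh_aggregates(self) -> None:
        """Rebuild per-cell tip positions and pseudopod vector sums (the
        quantities the kernel reads; chains only change between MCS)."""
        st = self.state
        st.tip_ok[:] = False
        for sigma in range(1, st.n_cells + 1):
            fx = fy = 0.0
            for ip, pod in enumerate(self.pods[sigma]):
                if pod.chain:
                    tx, ty = pod.tip
                    st.tips[sigma, ip, 0] = tx
                    st.tips[sigma, ip, 1] = ty
                    st.tip_ok[sigma, ip] = True
                vx, vy = pod.vector(st.width, st.height)
                fx += vx
                fy += vy
            st.pod_vector[sigma, 0] = fx
            st.pod_vector[sigma, 1] = fy


# -- reference energy terms (oracle forms of the kernel math) -----------

def delta_h_actin_coupling(state: CPMState, attempt: CopyAttempt,
                           actin_bonus: float) -> float:
    """Actin-lattice coupling for one attempt.

    Growth bonus: an actin site of the growing cell within the Moore
    neighborhood (including the center) of the target site contributes
    ``-actin_bonus`` (once).  Shrink block: an actin site of the shrinking
    cell within the same neighborhood returns +inf (attempt blocked).
    """
    x, y = attempt.target
    w, h = state.width, state.height
    bonus = 0.0
    for dx, dy in list(MOORE_OFFSETS) + [(0, 0)]:
        ao = int(state.actin_owner[(y + dy) % h, (x + dx) % w])
        if ao == 0:
            continue
        if ao == attempt.old_owner:
            return math.inf
        if ao == attempt.new_owner:
            bonus = -actin_bonus
    return bonus


def delta_h_pulling(state: CPMState, attempt: CopyAttempt,
                    pull_strength: float) -> float:
    """Pulling along the summed pseudopod vector: sum over involved cells of
    -F (s . f_sigma) / area_sigma."""
    sx, sy = attempt.s
    dh = 0.0
    for sigma in attempt.involved:
        if sigma == 0 or state.area[sigma] == 0:
            continue
        fx, fy = state.pod_vector[sigma]
        dh -= pull_strength * (sx * fx + sy * fy) / float(state.area[sigma])
    return dh


def _min_tip_dist2(state: CPMState, sigma: int, x: int, y: int) -> float:
    best = math.inf
    for ip in range(state.tips.shape[1]):
        if not state.tip_ok[sigma, ip]:
            continue
        dx = x - state.tips[sigma, ip, 0]
        dx -= state.width * round(dx / state.width)
        dy = y - state.tips[sigma, ip, 1]
        dy -= state.height * round(dy / state.height)
        best = min(best, dx * dx + dy * dy)
    return best


def delta_h_tip_adhesion(state: CPMState, attempt: CopyAttempt,
                         ext: ExtensionParams) -> float:
    """Adhesive pseudopod tips near a cell-cell interface.

    For each involved cell with a foreign cell in the Moore neighborhood of
    the site changing identity: no bonus if neither the cell's own nearest
    tip nor the foreign cells' nearest tip is within ``r_max`` of that site;
    ``-tip_bonus`` if exactly one is; ``-2 tip_bonus`` if both are.  The
    shrinking cell's term enters with opposite sign, so a growth that
    displaces another cell under symmetric tip coverage nets zero (tips
    cannot energetically "poke" into neighbors).
    """
    x, y = attempt.target
    w, h = state.width, state.height
    r2max = ext.r_max * ext.r_max

    def multiplier(sigma: int) -> int:
        foreign = set()
        for dx, dy in MOORE_OFFSETS:
            ou = int(state.owner[(y + dy) % h, (x + dx) % w])
            if ou != 0 and ou != sigma:
                foreign.add(ou)
        if not foreign:
            return 0
        r_fo2 = min(_min_tip_dist2(state, o, x, y) for o in foreign)
        r_own2 = _min_tip_dist2(state, sigma, x, y)
        return int(r_own2 <= r2max) + int(r_fo2 <= r2max)

    dh = 0.0
    if attempt.new_owner != 0:
        dh -= ext.tip_bonus * multiplier(attempt.new_owner)
    if attempt.old_owner != 0:
        dh += ext.tip_bonus * multiplier(attempt.old_owner)
    return dh
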