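"""Base Cellular Potts Model: lattice state, Hamiltonian, Metropolis rule.

A cell is the set of lattice sites carrying its identifier (sigma > 0;
sigma = 0 is medium).  The energy is

    H = sum_{Moore pairs, unlike sigma} J(tau, tau')
      + sum_cells lambda_V (v - V_target)^2

and a copy attempt (a site adopting a Moore neighbor's identifier) is
accepted with probability 1 if dH <= 0 and exp(-dH/T) otherwise.

The functions here are straightforward NumPy/Python reference
implementations used directly for small systems and as the oracle for the
compiled Monte Carlo kernel (:mod:`podcpm.kernel`) that production runs use.

Conventions: periodic boundaries; positions are (x, y) with x the column
index; the adhesion neighborhood is the same 8-site Moore neighborhood as
copy attempts, with each unordered pair counted once.  Centroids are
maintained as unwrapped running coordinate sums so that tracks have no
periodic jumps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import SimulationConfig

__all__ = [
    "MOORE_OFFSETS",
    "ContactEnergyTable",
    "CellRecord",
    "CopyAttempt",
    "CPMState",
    "acceptance_probability",
    "hamiltonian_total",
    "delta_h_base",
    "local_connectivity_ok",
    "attempt_copy",
    "initialize_random_cells",
]

# (dx, dy) offsets of the 8-site Moore neighborhood
MOORE_OFFSETS = np.array(
    [(-1, -1), (0, -1), (1, -1), (-1, 0), (1, 0), (-1, 1), (0, 1), (1, 1)],
    dtype=np.int64,
)
# offsets covering each unordered Moore pair exactly once
_HALF_OFFSETS = ((1, 0), (0, 1), (1, 1), (-1, 1))


class ContactEnergyTable:
    """Symmetric surface-energy table J(tau1, tau2), type 0 = medium."""

    def __init__(self, j: np.ndarray):
        j = np.asarray(j, dtype=np.float64)
        if j.ndim != 2 or j.shape[0] != j.shape[1]:
            raise ValueError("J must be a square matrix")
        if not np.allclose(j, j.T):
            raise ValueError("J must be symmetric")
        if not np.all(np.isfinite(j)):
            raise ValueError("J must be finite")
        self.j = j

    @classmethod
    def two_type(cls, j_cell_med: float, j_cell_cell: float) -> "ContactEnergyTable":
        """Medium (type 0) plus one cell type (type 1)."""
        return cls(np.array([[0.0, j_cell_med], [j_cell_med, j_cell_cell]]))

    def __call__(self, t1: int, t2: int) -> float:
        return float(self.j[t1, t2])


@dataclass
class CellRecord:
    """Per-cell bookkeeping (a read-only view assembled from state arrays)."""

    sigma: int
    ctype: int
    area: int
    target_area: float
    lambda_area: float
    centroid: tuple[float, float]          # unwrapped (x, y)
    movement_direction: tuple[float, float]


@dataclass
class CopyAttempt:
    """A proposed identifier copy from source site onto target site.

    ``s`` is the update direction: the unit vector from the source toward
    the target site.  ``involved`` is the (source owner, target owner) pair;
    owners always differ.
    """

    target: tuple[int, int]   # site v whose identity would change
    source: tuple[int, int]   # Moore neighbor v_n supplying the new identity
    new_owner: int            # sigma(source): the cell growing
    old_owner: int            # sigma(target): the cell shrinking
    s: tuple[float, float] = field(default=(0.0, 0.0))
    shape: tuple[int, int] | None = None  # (width, height) for periodic wrap

    def __post_init__(self):
        if self.new_owner == self.old_owner:
            raise ValueError("copy attempt requires differing owners")
        dx = self.target[0] - self.source[0]
        dy = self.target[1] - self.source[1]
        if self.shape is not None:
            w, h = self.shape
            dx -= w * round(dx / w)
            dy -= h * round(dy / h)
        if self.s == (0.0, 0.0):
            n = math.hypot(dx, dy)
            if n == 0:
                raise ValueError("target and source sites coincide")
            self.s = (dx / n, dy / n)

    @property
    def involved(self) -> tuple[int, int]:
        return (self.new_owner, self.old_owner)


class CPMState:
    """Lattice plus per-cell arrays; cell ids index the arrays directly."""

    def __init__(self, width: int, height: int, n_cells: int,
                 contact: ContactEnergyTable,
                 target_area: float, lambda_area: float):
        self.width = int(width)
        self.height = int(height)
        self.owner = np.zeros((height, width), dtype=np.int32)
        self.contact = contact
        n = int(n_cells)
        self.n_cells = n
        self.ctype = np.zeros(n + 1, dtype=np.int32)
        self.ctype[1:] = 1
        self.area = np.zeros(n + 1, dtype=np.int64)
        self.target_area = np.full(n + 1, float(target_area))
        self.target_area[0] = 0.0
        self.lambda_area = np.full(n + 1, float(lambda_area))
        self.lambda_area[0] = 0.0
        # unwrapped coordinate sums: centroid = sum / area
        self.sum_x = np.zeros(n + 1)
        self.sum_y = np.zeros(n + 1)
        # smoothed recent-movement direction (pseudopod models) and
        # persistence target direction
        self.move_dir = np.zeros((n + 1, 2))
        self.target_dir = np.zeros((n + 1, 2))
        # Act activity field and actin occupancy (pseudopod chains)
        self.act = np.zeros((height, width))
        self.actin_owner = np.zeros((height, width), dtype=np.int32)
        self.actin_count = np.zeros((height, width), dtype=np.int32)
        # pseudopod aggregates, refreshed each MCS by the engine
        self.pod_vector = np.zeros((n + 1, 2))
        self.tips = np.zeros((n + 1, 1, 2))
        self.tip_ok = np.zeros((n + 1, 1), dtype=np.bool_)

    # -- bookkeeping ----------------------------------------------------
    def centroid(self, sigma: int) -> tuple[float, float]:
        a = self.area[sigma]
        if a == 0:
            raise ValueError(f"cell {sigma} has no sites")
        return (self.sum_x[sigma] / a, self.sum_y[sigma] / a)

    def centroids(self) -> np.ndarray:
        """(n_cells+1, 2) unwrapped centroids; dead cells are NaN."""
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.stack([self.sum_x, self.sum_y], axis=1) / self.area[:, None]
        out[self.area == 0] = np.nan
        return out

    def cell(self, sigma: int) -> CellRecord:
        return CellRecord(
            sigma=sigma,
            ctype=int(self.ctype[sigma]),
            area=int(self.area[sigma]),
            target_area=float(self.target_area[sigma]),
            lambda_area=float(self.lambda_area[sigma]),
            centroid=self.centroid(sigma),
            movement_direction=tuple(self.move_dir[sigma]),
        )

    def add_site(self, sigma: int, x: int, y: int) -> None:
        """Assign site to ``sigma`` updating area and unwrapped centroid sums."""
        old = int(self.owner[y, x])
        if old == sigma:
            return
        if old != 0:
            self._remove_from_sums(old, x, y)
            self.area[old] -= 1
        self.owner[y, x] = sigma
        if sigma != 0:
            self._add_to_sums(sigma, x, y)
            self.area[sigma] += 1
        else:
            self.act[y, x] = 0.0

    def _add_to_sums(self, sigma: int, x: int, y: int) -> None:
        a = self.area[sigma]
        if a > 0:
            mx = self.sum_x[sigma] / a
            my = self.sum_y[sigma] / a
            x = x + self.width * round((mx - x) / self.width)
            y = y + self.height * round((my - y) / self.height)
        self.sum_x[sigma] += x
        self.sum_y[sigma] += y

    def _remove_from_sums(self, sigma: int, x: int, y: int) -> None:
        a = self.area[sigma]
        mx = self.sum_x[sigma] / a
        my = self.sum_y[sigma] / a
        x = x + self.width * round((mx - x) / self.width)
        y = y + self.height * round((my - y) / self.height)
        self.sum_x[sigma] -= x
        self.sum_y[sigma] -= y
        if a == 1:
            self.sum_x[sigma] = 0.0
            self.sum_y[sigma] = 0.0

    def check_consistency(self) -> None:
        """Raise if areas or ownership bookkeeping drifted (test helper)."""
        counts = np.bincount(self.owner.ravel(), minlength=self.n_cells + 1)
        if np.any(self.owner > self.n_cells) or np.any(self.owner < 0):
            raise AssertionError("unknown cell id on lattice")
        if not np.array_equal(counts[1:], self.area[1:]):
            raise AssertionError("area bookkeeping inconsistent with lattice")
        total = counts.sum()
        if total != self.width * self.height:
            raise AssertionError("site conservation violated")


def acceptance_probability(delta_h: float, temperature: float) -> float:
    """Metropolis acceptance: 1 for dH <= 0, exp(-dH/T) otherwise."""
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    if delta_h <= 0:
        return 1.0
    if math.isinf(delta_h):
        return 0.0
    return math.exp(-delta_h / temperature)


def hamiltonian_total(state: CPMState) -> float:
    """Full energy: adhesion over unordered unlike Moore pairs + area term."""
    owner = state.owner
    types = state.ctype[owner]
    j = state.contact.j
    adhesion = 0.0
    for dx, dy in _HALF_OFFSETS:
        shifted_owner = np.roll(owner, shift=(-dy, -dx), axis=(0, 1))
        shifted_types = np.roll(types, shift=(-dy, -dx), axis=(0, 1))
        unlike = owner != shifted_owner
        adhesion += j[types[unlike], shifted_types[unlike]].sum()
    area_term = float(
        np.sum(state.lambda_area[1:] * (state.area[1:] - state.target_area[1:]) ** 2)
    )
    return adhesion + area_term


def delta_h_base(state: CPMState, attempt: CopyAttempt) -> float:
    """Adhesion + area energy change of a copy attempt, computed locally."""
    x, y = attempt.target
    new, old = attempt.new_owner, attempt.old_owner
    j = state.contact.j
    ctype = state.ctype
    owner = state.owner
    w, h = state.width, state.height
    d_adh = 0.0
    for dx, dy in MOORE_OFFSETS:
        ou = int(owner[(y + dy) % h, (x + dx) % w])
        if ou != old:
            d_adh -= j[ctype[old], ctype[ou]]
        if ou != new:
            d_adh += j[ctype[new], ctype[ou]]
    d_area = 0.0
    for sigma, gain in ((new, 1), (old, -1)):
        if sigma != 0:
            v = state.area[sigma]
            t = state.target_area[sigma]
            lam = state.lambda_area[sigma]
            d_area += lam * ((v + gain - t) ** 2 - (v - t) ** 2)
    return float(d_adh + d_area)


def local_connectivity_ok(owner: np.ndarray, x: int, y: int, losing: int) -> bool:
    """Local test that removing site (x, y) keeps ``losing`` locally connected.

    Considers only the losing cell's sites within the Moore neighborhood of
    the removed site and checks they form a single Moore-connected component.
    A cell losing its last site passes (the cell simply vanishes).
    """
    h, w = owner.shape
    members = []
    for dx, dy in MOORE_OFFSETS:
        if owner[(y + dy) % h, (x + dx) % w] == losing:
            members.append((int(dx), int(dy)))
    if not members:
        return True
    # flood fill among the ring sites with Moore adjacency
    seen = {members[0]}
    stack = [members[0]]
    cells = set(members)
    while stack:
        cx, cy = stack.pop()
        for nx, ny in cells - seen:
            if abs(nx - cx) <= 1 and abs(ny - cy) <= 1:
                seen.add((nx, ny))
                stack.append((nx, ny))
    return len(seen) == len(members)


def attempt_copy(state: CPMState, rng: np.random.Generator,
                 temperature: float,
                 extensions: list | None = None,
                 connectivity: bool = False,
                 act_max: float | None = None) -> bool:
    """One elementary Metropolis copy attempt (reference implementation).

    Draws a uniform target site and a uniform Moore neighbor as source;
    identical-owner pairs are discarded (returns False without counting as a
    rejection in any statistic).  ``extensions`` is a list of callables
    ``f(state, attempt) -> energy`` whose returns are added to the base dH;
    any +inf contribution blocks the attempt.  Production runs use the
    compiled kernel in :mod:`podcpm.kernel`, which implements the same rule.
    """
    w, h = state.width, state.height
    idx = int(rng.integers(0, w * h))
    x, y = idx % w, idx // w
    k = int(rng.integers(0, 8))
    dx, dy = MOORE_OFFSETS[k]
    xs, ys = (x + dx) % w, (y + dy) % h
    new = int(state.owner[ys, xs])
    old = int(state.owner[y, x])
    if new == old:
        return False
    norm = math.hypot(dx, dy)
    attempt = CopyAttempt(target=(x, y), source=(xs, ys),
                          new_owner=new, old_owner=old,
                          s=(-dx / norm, -dy / norm))
    if connectivity and old != 0:
        if not local_connectivity_ok(state.owner, x, y, old):
            return False
    dh = delta_h_base(state, attempt)
    for ext in extensions or ():
        term = ext(state, attempt)
        if math.isinf(term):
            return False
        dh += term
    if rng.random() >= acceptance_probability(dh, temperature):
        return False
    state.add_site(new, x, y)
    if act_max is not None:
        state.act[y, x] = act_max if new != 0 else 0.0
    return True


def initialize_random_cells(config: SimulationConfig,
                            rng: np.random.Generator) -> CPMState:
    """Place each cell as a distinct random single site; growth toward the
    target area happens during the early Monte Carlo steps."""
    config.validate()
    n = config.n_cells
    w, h = config.width, config.height
    if n > w * h:
        raise ValueError("cell count exceeds lattice capacity")
    contact = ContactEnergyTable.two_type(config.contact.j_cell_med,
                                          config.contact.j_cell_cell)
    state = CPMState(w, h, n, contact,
                     config.contact.target_area, config.contact.lambda_area)
    sites = rng.choice(w * h, size=n, replace=False)
    for sigma, idx in enumerate(sites, start=1):
        x, y = int(idx % w), int(idx // w)
        state.add_site(sigma, x, y)
    return state
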