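"""Seeded synthetic tracks and point patterns with known ground truth.

These generators provide inputs for the statistics suite whose expected
outcomes are analytically known: Brownian walks (DAC ~ 0 beyond lag 0),
persistent random walks with a prescribed persistence time, streaming
tracks sharing a common drift, and point patterns that are completely
spatially random, clustered (parent-offspring) or hard-core (minimum
distance).  All generators are pure functions of their spec: the same seed
produces identical output.

Persistent random walk mapping.  The walk moves at fixed speed and turns by
a von Mises(0, kappa) angle each step, so consecutive step directions
satisfy E[cos(theta_{n} - theta_0)] = R^n with R = I1(kappa)/I0(kappa) (the
mean resultant length of the turning distribution).  Matching R^n =
exp(-n dt / tau_p) gives R = exp(-dt/tau_p), and ``kappa_for_persistence_time``
inverts the Bessel ratio numerically.  The DAC of such tracks therefore
decays exponentially with time constant tau_p and persistent fraction 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import i0e, i1e

from .analysis import Track, TrackSet

__all__ = [
    "FixtureSpec", "generate", "kappa_for_persistence_time",
    "generate_brownian_tracks", "generate_prw_tracks",
    "generate_streaming_tracks", "generate_point_pattern",
]


@dataclass
class FixtureSpec:
    """Declarative description of a synthetic fixture."""

    kind: str                   # brownian | prw | streaming | point-csr |
                                # point-clustered | point-hardcore
    seed: int
    n: int = 100                # tracks or points
    steps: int = 200
    step_size: float = 1.0
    dt: float = 1.0
    tau_p: float = 10.0         # prw
    drift_fraction: float = 0.5  # streaming
    drift_direction: tuple | None = None
    n_clusters: int = 10        # clustered
    cluster_sd: float = 10.0
    core_distance: float = 20.0  # hardcore
    window: tuple = (1000.0, 1000.0)

    def __post_init__(self):
        if self.n <= 0 or self.steps <= 0:
            raise ValueError("counts must be positive")
        if self.seed is None:
            raise ValueError("a seed is mandatory")


def generate(spec: FixtureSpec):
    kind = spec.kind
    rng = np.random.default_rng(spec.seed)
    if kind == "brownian":
        return generate_brownian_tracks(spec, rng)
    if kind == "prw":
        return generate_prw_tracks(spec, rng)
    if kind == "streaming":
        return generate_streaming_tracks(spec, rng)
    if kind.startswith("point-"):
        return generate_point_pattern(spec, rng)
    raise ValueError(f"unknown fixture kind {kind!r}")


def _start_positions(spec: FixtureSpec, rng) -> np.ndarray:
    w, h = spec.window
    return rng.uniform((0, 0), (w, h), size=(spec.n, 2))


def _tracks_from_angles(spec: FixtureSpec, angles: np.ndarray,
                        starts: np.ndarray,
                        drift: np.ndarray | None = None) -> TrackSet:
    steps = spec.step_size * np.stack([np.cos(angles), np.sin(angles)], axis=-1)
    if drift is not None:
        steps = (1.0 - spec.drift_fraction) * steps + spec.drift_fraction * drift
    pos = np.concatenate(
        [starts[:, None, :], starts[:, None, :] + np.cumsum(steps, axis=1)],
        axis=1)
    t = np.arange(spec.steps + 1) * spec.dt
    tracks = [Track(i, t, pos[i]) for i in range(spec.n)]
    return TrackSet.from_tracks(tracks, window=spec.window)


def generate_brownian_tracks(spec: FixtureSpec,
                             rng: np.random.Generator | None = None
                             ) -> TrackSet:
    """Fixed-length steps in i.i.d. uniformly random directions."""
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    angles = rng.uniform(-math.pi, math.pi, size=(spec.n, spec.steps))
    return _tracks_from_angles(spec, angles, _start_positions(spec, rng))


def kappa_for_persistence_time(tau_p: float, dt: float = 1.0) -> float:
    """Von Mises concentration giving direction-correlation time ``tau_p``.

    Solves I1(kappa)/I0(kappa) = exp(-dt/tau_p).  The exponentially scaled
    Bessel functions keep the ratio stable for large kappa.
    """
    if tau_p <= 0:
        raise ValueError("tau_p must be > 0")
    target = math.exp(-dt / tau_p)

    def f(kappa):
        return i1e(kappa) / i0e(kappa) - target

    lo, hi = 1e-12, 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e12:
            raise ValueError("tau_p too large to resolve kappa")
    return float(brentq(f, lo, hi, xtol=1e-12, rtol=1e-12))


def generate_prw_tracks(spec: FixtureSpec,
                        rng: np.random.Generator | None = None) -> TrackSet:
    """Fixed-speed persistent random walk with von Mises turning angles whose
    concentration is chosen so the DAC decays with time constant ``tau_p``."""
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    kappa = kappa_for_persistence_time(spec.tau_p, spec.dt)
    turns = rng.vonmises(0.0, kappa, size=(spec.n, spec.steps))
    turns[:, 0] = rng.uniform(-math.pi, math.pi, size=spec.n)  # random heading
    angles = np.cumsum(turns, axis=1)
    return _tracks_from_angles(spec, angles, _start_positions(spec, rng))


def generate_streaming_tracks(spec: FixtureSpec,
                              rng: np.random.Generator | None = None
                              ) -> TrackSet:
    """Each step blends a shared constant drift vector (weight
    ``drift_fraction``) with a private uniformly-directed step."""
    if not 0.0 <= spec.drift_fraction <= 1.0:
        raise ValueError("drift fraction must be in [0, 1]")
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    if spec.drift_direction is None:
        ang = rng.uniform(-math.pi, math.pi)
        drift_dir = np.array([math.cos(ang), math.sin(ang)])
    else:
        d = np.asarray(spec.drift_direction, dtype=float)
        drift_dir = d / np.linalg.norm(d)
    drift = spec.step_size * drift_dir
    angles = rng.uniform(-math.pi, math.pi, size=(spec.n, spec.steps))
    return _tracks_from_angles(spec, angles, _start_positions(spec, rng),
                               drift=drift)


def generate_point_pattern(spec: FixtureSpec,
                           rng: np.random.Generator | None = None
                           ) -> np.ndarray:
    """Point pattern in a rectangular window.

    point-csr: homogeneous Poisson (uniform, fixed n).
    point-clustered: ``n_clusters`` uniform parents with Gaussian offspring
    (sd ``cluster_sd``), n points total.
    point-hardcore: sequential rejection of points closer than
    ``core_distance`` to an accepted point; raises if the window saturates.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    w, h = spec.window
    if w <= 0 or h <= 0:
        raise ValueError("window area must be positive")
    if spec.kind == "point-csr":
        return rng.uniform((0, 0), (w, h), size=(spec.n, 2))
    if spec.kind == "point-clustered":
        parents = rng.uniform((0, 0), (w, h), size=(spec.n_clusters, 2))
        assignment = rng.integers(0, spec.n_clusters, size=spec.n)
        pts = parents[assignment] + rng.normal(0.0, spec.cluster_sd,
                                               size=(spec.n, 2))
        return np.mod(pts, (w, h))  # wrap to keep all offspring in the window
    if spec.kind == "point-hardcore":
        pts = np.empty((spec.n, 2))
        placed = 0
        attempts = 0
        max_attempts = 1000 * spec.n
        core2 = spec.core_distance ** 2
        while placed < spec.n:
            if attempts >= max_attempts:
                raise RuntimeError(
                    "hard-core saturation: cannot place requested points")
            p = rng.uniform((0, 0), (w, h))
            attempts += 1
            if placed:
                d2 = np.sum((pts[:placed] - p) ** 2, axis=1)
                if d2.min() < core2:
                    continue
            pts[placed] = p
            placed += 1
        return pts
    raise ValueError(f"unknown point pattern kind {spec.kind!r}")
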