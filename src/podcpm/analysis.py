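"""Cell-track and point-pattern statistics.

Implements the quantification suite used to characterize migration:
instantaneous speeds, directional autocorrelation (DAC) with exponential
decay fit (persistent fraction ``phi`` and persistence time ``tau_p``),
pairwise migration-angle curves (streaming), frame-wise drift correction,
polar histograms, Ripley's K/L with isotropic edge correction, confinement
ratio, and Fisher-z averaging of Pearson correlations across replicates.

Tracks are time-ordered (t, x, y) samples per track id; times are minutes
for experimental data and MCS for simulations.  All statistics skip
zero-length steps (their direction is undefined).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr, spearmanr

__all__ = [
    "Track", "TrackSet", "DACCurve", "DACFit", "RipleyCurve",
    "WellSummary", "CorrelationMatrix",
    "instantaneous_speed", "directional_autocorrelation", "fit_dac",
    "pairwise_angle_by_distance", "drift_correct", "polar_histogram",
    "ripley_k", "ripley_L", "confinement_ratio", "fisher_average",
    "build_correlogram", "mean_squared_displacement",
]

CORR_LABELS = ("density", "speed", "tau_p")


@dataclass
class Track:
    """One cell's trajectory: strictly increasing times, (x, y) positions."""

    track_id: int
    t: np.ndarray
    xy: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float)
        if self.t.ndim != 1 or self.xy.shape != (self.t.size, 2):
            raise ValueError("track needs matching 1D times and (n, 2) positions")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("track times must be strictly increasing")

    def __len__(self):
        return self.t.size

    @property
    def steps(self) -> np.ndarray:
        return np.diff(self.xy, axis=0)


class TrackSet:
    """A collection of tracks with a common sampling interval.

    Backed by a tidy DataFrame (``track_id, t, x, y`` plus optional metadata
    columns such as ``well`` and ``replicate``).
    """

    def __init__(self, df: pd.DataFrame, unit_scale: float = 1.0,
                 window=None):
        required = {"track_id", "t", "x", "y"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"track table missing columns: {sorted(missing)}")
        self.df = df.sort_values(["track_id", "t"], kind="stable").reset_index(
            drop=True)
        self.unit_scale = unit_scale
        self.window = window
        self._tracks: dict[int, Track] | None = None

    @classmethod
    def from_tracks(cls, tracks: list[Track], **kw) -> "TrackSet":
        frames = [
            pd.DataFrame({"track_id": tr.track_id, "t": tr.t,
                          "x": tr.xy[:, 0], "y": tr.xy[:, 1]})
            for tr in tracks
        ]
        df = (pd.concat(frames, ignore_index=True) if frames
              else pd.DataFrame(columns=["track_id", "t", "x", "y"]))
        return cls(df, **kw)

    def tracks(self) -> dict[int, Track]:
        if self._tracks is None:
            self._tracks = {
                int(tid): Track(int(tid), g["t"].to_numpy(),
                                g[["x", "y"]].to_numpy())
                for tid, g in self.df.groupby("track_id", sort=True)
            }
        return self._tracks

    def __len__(self):
        return len(self.tracks())

    @property
    def dt(self) -> float:
        """Median sampling interval across all tracks."""
        diffs = self.df.groupby("track_id")["t"].diff().dropna()
        if diffs.empty:
            raise ValueError("need at least one step to infer sampling interval")
        return float(diffs.median())

    def frame_times(self) -> np.ndarray:
        return np.sort(self.df["t"].unique())


@dataclass
class DACCurve:
    """Directional autocorrelation: mean step-direction dot product per lag."""

    lag: np.ndarray       # time units (multiples of dt), lag 0 included
    value: np.ndarray
    n_pairs: np.ndarray


@dataclass
class DACFit:
    """Exponential fit DAC(tau) ~ phi * exp(-tau / tau_p)."""

    phi: float
    tau_p: float
    ok: bool
    message: str = ""
    rmse: float = float("nan")


@dataclass
class RipleyCurve:
    r: np.ndarray
    k: np.ndarray
    l: np.ndarray
    r_minus_l: np.ndarray
    n_points: int
    correction: str = "isotropic"


@dataclass
class WellSummary:
    """Per-well/per-run migration summary used for correlograms."""

    well: str
    replicate: str
    density: float          # cells per unit area
    speed: float            # mean instantaneous speed
    phi: float
    tau_p: float


@dataclass
class CorrelationMatrix:
    """Fisher-averaged Pearson correlations between density, speed, tau_p."""

    labels: tuple = CORR_LABELS
    matrix: np.ndarray = field(default_factory=lambda: np.eye(3))
    per_replicate: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)

    def __getitem__(self, pair):
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.matrix[i, j])


# ---------------------------------------------------------------------------
# speeds and displacement


def instantaneous_speed(track: Track, subtrack_length: float | None = None
                        ) -> np.ndarray:
    """Speed series of one track.

    With ``subtrack_length=None``: per-frame displacement divided by the
    frame interval (the experimental convention).  With a length (same time
    units as ``t``): net displacement over non-overlapping subtracks of that
    duration divided by the elapsed time (the simulation convention, which
    suppresses centroid jitter).
    """
    if len(track) < 2:
        raise ValueError("track too short for a speed estimate")
    if subtrack_length is None:
        d = np.linalg.norm(track.steps, axis=1)
        return d / np.diff(track.t)
    dt = float(np.median(np.diff(track.t)))
    k = max(1, int(round(subtrack_length / dt)))
    n = len(track)
    if n - 1 < k:
        raise ValueError("track too short for one subtrack")
    starts = np.arange(0, n - k, k)
    ends = starts + k
    disp = np.linalg.norm(track.xy[ends] - track.xy[starts], axis=1)
    return disp / (track.t[ends] - track.t[starts])


def mean_squared_displacement(trackset: TrackSet, max_lag: int) -> np.ndarray:
    """MSD per lag (in sample units), averaged over tracks and time offsets."""
    sums = np.zeros(max_lag + 1)
    counts = np.zeros(max_lag + 1, dtype=np.int64)
    for tr in trackset.tracks().values():
        xy = tr.xy
        n = len(tr)
        for lag in range(1, min(max_lag, n - 1) + 1):
            d = xy[lag:] - xy[:-lag]
            sums[lag] += np.einsum("ij,ij->", d, d)
            counts[lag] += d.shape[0]
    with np.errstate(invalid="ignore"):
        out = sums / counts
    out[0] = 0.0
    return out


# ---------------------------------------------------------------------------
# directional autocorrelation


def _unit_steps(track: Track) -> np.ndarray:
    """Normalized step directions; zero-length steps become NaN rows."""
    steps = track.steps
    norms = np.linalg.norm(steps, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        units = steps / norms[:, None]
    units[norms == 0] = np.nan
    return units


def directional_autocorrelation(trackset: TrackSet, max_lag: int,
                                per_cell: bool = False) -> DACCurve:
    """Mean dot product of normalized step directions separated by ``n``
    sampling intervals, averaged over all cells and time offsets.

    DAC(0) = 1 by construction.  Zero-length steps are skipped.  With
    ``per_cell=True`` each cell's own lag average is computed first and then
    averaged across cells (equal cell weight instead of equal pair weight).
    Lags without any valid pair are omitted.
    """
    dt = trackset.dt
    sums = np.zeros(max_lag + 1)
    counts = np.zeros(max_lag + 1, dtype=np.int64)
    cell_curves = []
    for tr in trackset.tracks().values():
        units = _unit_steps(tr)
        m = units.shape[0]
        if m < 1:
            continue
        track_sums = np.zeros(max_lag + 1)
        track_counts = np.zeros(max_lag + 1, dtype=np.int64)
        valid = ~np.isnan(units[:, 0])
        track_sums[0] = valid.sum()
        track_counts[0] = valid.sum()
        for lag in range(1, min(max_lag, m - 1) + 1):
            dots = np.einsum("ij,ij->i", units[:-lag], units[lag:])
            good = ~np.isnan(dots)
            track_sums[lag] = dots[good].sum()
            track_counts[lag] = good.sum()
        sums += track_sums
        counts += track_counts
        with np.errstate(invalid="ignore"):
            cell_curves.append(track_sums / track_counts)
    if per_cell:
        stacked = np.vstack(cell_curves)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            value = np.nanmean(stacked, axis=0)
        counts = np.sum(~np.isnan(stacked), axis=0)
    else:
        with np.errstate(invalid="ignore"):
            value = sums / counts
    keep = counts > 0
    value = value[keep]
    lags = np.arange(max_lag + 1)[keep] * dt
    if lags.size and lags[0] == 0:
        value[0] = 1.0  # exact by definition
    return DACCurve(lag=lags, value=value, n_pairs=counts[keep])


def fit_dac(curve: DACCurve, tau_max: float | None = None) -> DACFit:
    """Least-squares fit of ``phi * exp(-tau/tau_p)`` to the DAC at lags > 0.

    ``phi`` is bounded to [0, 1] and ``tau_p`` to (0, tau_max] with
    ``tau_max`` defaulting to 10x the largest lag.  Fits pinned at a bound
    or failing to converge are returned flagged (``ok=False``) rather than
    raising; such estimates should be interpreted cautiously.
    """
    mask = curve.lag > 0
    lags = curve.lag[mask]
    vals = curve.value[mask]
    if lags.size < 3:
        return DACFit(float("nan"), float("nan"), False, "fewer than 3 lags")
    if tau_max is None:
        tau_max = 10.0 * float(lags.max())
    phi0 = float(np.clip(vals[0], 1e-3, 1.0))
    below = lags[vals < phi0 / math.e]
    tau0 = float(below[0]) if below.size else float(lags.max()) / 2.0
    tau0 = min(max(tau0, 1e-6), tau_max)

    def model(tau, phi, tau_p):
        return phi * np.exp(-tau / tau_p)

    try:
        popt, _ = curve_fit(model, lags, vals, p0=(phi0, tau0),
                            bounds=([0.0, 1e-9], [1.0, tau_max]),
                            maxfev=10000)
    except (RuntimeError, ValueError) as exc:
        return DACFit(float("nan"), float("nan"), False, f"fit failed: {exc}")
    phi, tau_p = float(popt[0]), float(popt[1])
    rmse = float(np.sqrt(np.mean((model(lags, phi, tau_p) - vals) ** 2)))
    message = ""
    ok = True
    if tau_p >= 0.999 * tau_max:
        ok = False
        message = "tau_p pinned at upper bound"
    elif tau_p <= 1e-8:
        ok = False
        message = "tau_p pinned at lower bound"
    return DACFit(phi, tau_p, ok, message, rmse)


# ---------------------------------------------------------------------------
# streaming: pairwise angles, drift, polar histograms


def _frame_steps(trackset: TrackSet):
    """Per frame-time: starting positions and step vectors of all tracks
    stepping from that frame to their next sample."""
    out = {}
    for tr in trackset.tracks().values():
        steps = tr.steps
        for i in range(len(tr) - 1):
            out.setdefault(tr.t[i], []).append(
                (tr.track_id, tr.xy[i], steps[i]))
    return out


def pairwise_angle_by_distance(trackset: TrackSet, frame=None,
                               bin_width: float = 5.0,
                               max_distance: float | None = None,
                               min_pairs: int = 20) -> pd.DataFrame:
    """Mean angle (degrees, in [0, 180]) between the migration directions of
    all unordered cell pairs, binned by the distance between their positions.

    Uniformly random directions give 90 degrees per bin; streaming shows up
    as sub-90 angles at short distances.  Bins with fewer than ``min_pairs``
    pairs are suppressed.  ``frame=None`` aggregates over all frames.
    """
    frames = _frame_steps(trackset)
    if frame is not None:
        if frame not in frames:
            raise ValueError(f"no steps start at frame {frame!r}")
        frames = {frame: frames[frame]}
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    for entries in frames.values():
        moving = [(p, s) for (_tid, p, s) in entries
                  if s[0] != 0.0 or s[1] != 0.0]
        if len(moving) < 2:
            continue
        pos = np.array([p for p, _ in moving])
        dirs = np.array([s for _, s in moving])
        dirs = dirs / np.linalg.norm(dirs, axis=1)[:, None]
        dist = pdist(pos)
        cosang = np.clip(squareform(dirs @ dirs.T, checks=False), -1.0, 1.0)
        ang = np.degrees(np.arccos(cosang))
        if max_distance is not None:
            keep = dist <= max_distance
            dist, ang = dist[keep], ang[keep]
        bins = (dist // bin_width).astype(int)
        for b, a in zip(bins, ang):
            sums[b] = sums.get(b, 0.0) + a
            counts[b] = counts.get(b, 0) + 1
    rows = [
        {"distance": (b + 0.5) * bin_width, "mean_angle": sums[b] / counts[b],
         "n_pairs": counts[b]}
        for b in sorted(sums)
        if counts[b] >= min_pairs
    ]
    return pd.DataFrame(rows, columns=["distance", "mean_angle", "n_pairs"])


def drift_correct(trackset: TrackSet) -> TrackSet:
    """Subtract the per-frame mean displacement (over all cells stepping in
    that frame) from every displacement and rebuild positions cumulatively.

    Removes rigid large-scale drift (e.g., stage drift or a global stream);
    applying the correction twice equals applying it once.
    """
    frames = _frame_steps(trackset)
    mean_step = {
        t: np.mean([s for (_tid, _p, s) in entries], axis=0)
        for t, entries in frames.items()
    }
    new_tracks = []
    for tr in trackset.tracks().values():
        steps = tr.steps.copy()
        for i in range(len(tr) - 1):
            steps[i] -= mean_step[tr.t[i]]
        xy = np.vstack([tr.xy[0], tr.xy[0] + np.cumsum(steps, axis=0)])
        new_tracks.append(Track(tr.track_id, tr.t.copy(), xy))
    return TrackSet.from_tracks(new_tracks, unit_scale=trackset.unit_scale,
                                window=trackset.window)


def polar_histogram(directions, n_bins: int = 16) -> np.ndarray:
    """Counts of step directions per angular bin over [-pi, pi).

    Zero-length directions are excluded (undefined angle); the counts sum to
    the number of nonzero input directions.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    directions = np.asarray(directions, dtype=float).reshape(-1, 2)
    if directions.size == 0:
        return np.zeros(n_bins, dtype=np.int64)
    norms = np.linalg.norm(directions, axis=1)
    directions = directions[norms > 0]
    angles = np.arctan2(directions[:, 1], directions[:, 0])
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    counts, _ = np.histogram(angles, bins=edges)
    return counts.astype(np.int64)


# ---------------------------------------------------------------------------
# Ripley K / L


def _normalize_window(window):
    if len(window) == 2:
        return (0.0, float(window[0]), 0.0, float(window[1]))
    if len(window) == 4:
        return tuple(float(v) for v in window)
    raise ValueError("window must be (width, height) or (xmin, xmax, ymin, ymax)")


def _isotropic_weights(points: np.ndarray, dmat: np.ndarray, window):
    """Ripley isotropic edge-correction weights for each ordered pair (i, j):
    the reciprocal of the fraction of the circle centered at point i with
    radius d(i, j) that lies inside the rectangular window."""
    xmin, xmax, ymin, ymax = window
    x = points[:, 0][:, None]
    y = points[:, 1][:, None]
    d = dmat
    with np.errstate(invalid="ignore", divide="ignore"):
        edges = np.zeros_like(d)
        dists = (x - xmin, xmax - x, y - ymin, ymax - y)
        for e in dists:
            ratio = np.clip(e / d, -1.0, 1.0)
            edges += 2.0 * np.arccos(ratio) * (e < d)
        corners = np.zeros_like(d)
        for a in dists[:2]:
            for b in dists[2:]:
                term = (np.arccos(np.clip(a / d, -1.0, 1.0))
                        + np.arccos(np.clip(b / d, -1.0, 1.0)) - np.pi / 2.0)
                corners += np.maximum(term, 0.0)
        exterior = edges - corners
        w = 2.0 * np.pi / (2.0 * np.pi - exterior)
    np.fill_diagonal(w, 0.0)
    return w


def ripley_k(points, window, r_grid) -> np.ndarray:
    """Ripley's K with isotropic edge correction in a rectangular window."""
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    n = points.shape[0]
    if n < 10:
        raise ValueError("need at least 10 points for Ripley statistics")
    window = _normalize_window(window)
    xmin, xmax, ymin, ymax = window
    r_grid = np.asarray(r_grid, dtype=float)
    rmax_valid = min(xmax - xmin, ymax - ymin) / 2.0
    if r_grid.max() >= rmax_valid:
        raise ValueError(
            f"r values must stay below half the shorter window side "
            f"({rmax_valid:g}) for the isotropic correction")
    area = (xmax - xmin) * (ymax - ymin)
    dmat = squareform(pdist(points))
    w = _isotropic_weights(points, dmat, window)
    k = np.empty_like(r_grid)
    for i, r in enumerate(r_grid):
        k[i] = w[(dmat <= r) & (dmat > 0)].sum()
    k *= area / (n * (n - 1))
    return k


def ripley_L(points, window, r_grid) -> RipleyCurve:
    """L(r) = sqrt(K(r)/pi); the returned ``r_minus_l`` is r - L(r), which is
    0 under complete spatial randomness, negative for clustering and
    positive for dispersion."""
    r_grid = np.asarray(r_grid, dtype=float)
    k = ripley_k(points, window, r_grid)
    l = np.sqrt(k / np.pi)
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    return RipleyCurve(r=r_grid, k=k, l=l, r_minus_l=r_grid - l,
                       n_points=points.shape[0])


# ---------------------------------------------------------------------------
# scalar summaries and correlograms


def confinement_ratio(track: Track) -> float:
    """Net displacement over total path length, in [0, 1].

    Biased downward for longer random tracks, which is why persistence is
    quantified by the DAC fit instead; kept for comparison.  A zero path
    length is undefined and returns NaN.
    """
    if len(track) < 2:
        raise ValueError("track too short")
    path = float(np.linalg.norm(track.steps, axis=1).sum())
    if path == 0.0:
        return float("nan")
    net = float(np.linalg.norm(track.xy[-1] - track.xy[0]))
    return net / path


def fisher_average(correlations) -> float:
    """tanh of the mean artanh: the Fisher-z average of Pearson correlations.

    Entries with |r| = 1 (infinite z) are excluded with a warning.
    """
    rs = np.asarray(correlations, dtype=float)
    rs = rs[~np.isnan(rs)]
    keep = np.abs(rs) < 1.0
    if not np.all(keep):
        warnings.warn("excluding correlations with |r| = 1 from Fisher average")
        rs = rs[keep]
    if rs.size == 0:
        return float("nan")
    return float(np.tanh(np.mean(np.arctanh(rs))))


def build_correlogram(summaries) -> CorrelationMatrix:
    """Pairwise Pearson correlations between density, speed and tau_p per
    replicate, Fisher-averaged across replicates.

    ``summaries``: list of :class:`WellSummary` or an equivalent DataFrame
    with columns replicate, density, speed, tau_p (>= 3 wells per replicate).
    Constant columns yield flagged NaN entries.
    """
    if isinstance(summaries, pd.DataFrame):
        df = summaries
    else:
        df = pd.DataFrame([s.__dict__ for s in summaries])
    flags: list[str] = []
    per_rep: dict = {}
    for rep, g in df.groupby("replicate"):
        if len(g) < 3:
            flags.append(f"replicate {rep!r}: fewer than 3 wells, skipped")
            continue
        cols = [g["density"].to_numpy(), g["speed"].to_numpy(),
                g["tau_p"].to_numpy()]
        m = np.eye(3)
        for i in range(3):
            for j in range(i + 1, 3):
                a, b = cols[i], cols[j]
                if np.std(a) == 0 or np.std(b) == 0:
                    m[i, j] = m[j, i] = np.nan
                    flags.append(
                        f"replicate {rep!r}: constant column in "
                        f"({CORR_LABELS[i]}, {CORR_LABELS[j]})")
                else:
                    m[i, j] = m[j, i] = pearsonr(a, b)[0]
        per_rep[rep] = m
    if not per_rep:
        raise ValueError("no replicate with >= 3 wells")
    out = np.eye(3)
    for i in range(3):
        for j in range(i + 1, 3):
            vals = np.array([m[i, j] for m in per_rep.values()])
            vals = vals[~np.isnan(vals)]
            if vals.size == 0:
                r = float("nan")
            elif np.ptp(vals) == 0.0:
                r = float(vals[0])  # identical replicates (incl. |r| = 1)
            else:
                r = fisher_average(vals)
            out[i, j] = out[j, i] = r
    return CorrelationMatrix(matrix=out, per_replicate=per_rep, flags=flags)


def density_spearman(summaries, var: str = "speed"):
    """Spearman correlation of observed density with another summary column
    over pooled wells (sign tests for density sweeps)."""
    if isinstance(summaries, pd.DataFrame):
        df = summaries
    else:
        df = pd.DataFrame([s.__dict__ for s in summaries])
    rho, p = spearmanr(df["density"], df[var])
    return float(rho), float(p)
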