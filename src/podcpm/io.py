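"""Track, point-pattern and snapshot I/O.

Tracks travel as CSV with header ``track_id,t,x,y`` (optional ``well`` and
``replicate`` metadata columns); point patterns as ``x,y`` CSV; label
snapshots as 16-bit TIFF images of the site-owner matrix (optional second
channel with actin occupancy), with a plain-text matrix alternative.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .analysis import TrackSet

__all__ = [
    "read_tracks", "write_tracks", "read_points", "write_points",
    "write_snapshot", "write_snapshot_text",
]

_REQUIRED = ["track_id", "t", "x", "y"]


def read_tracks(path) -> TrackSet:
    """Read a track CSV; rows are sorted by (track, time) with a warning if
    they were out of order. Raises on missing columns or non-numeric cells."""
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"track CSV missing columns: {missing}")
    for col in ("t", "x", "y"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    sorted_df = df.sort_values(["track_id", "t"], kind="stable")
    if not np.array_equal(sorted_df.index.to_numpy(), df.index.to_numpy()):
        warnings.warn("track rows were not sorted by (track_id, t); sorting")
    return TrackSet(sorted_df.reset_index(drop=True))


def write_tracks(trackset: TrackSet, path) -> None:
    """Write tracks as CSV, lossless to 6 decimal places on round trip."""
    df = trackset.df.copy()
    df.to_csv(path, index=False, float_format="%.6f")


def read_points(path) -> np.ndarray:
    df = pd.read_csv(path)
    if not {"x", "y"} <= set(df.columns):
        raise ValueError("point CSV needs columns x,y")
    return df[["x", "y"]].to_numpy(dtype=float)


def write_points(points: np.ndarray, path) -> None:
    pd.DataFrame(np.asarray(points), columns=["x", "y"]).to_csv(
        path, index=False, float_format="%.6f")


def write_snapshot(path, owner: np.ndarray,
                   actin_owner: np.ndarray | None = None) -> None:
    """Write a label image: cell id per pixel as 16-bit TIFF; when actin
    occupancy is given, a 2-channel stack (labels, actin owner)."""
    import tifffile

    owner16 = owner.astype(np.uint16)
    if actin_owner is None:
        tifffile.imwrite(path, owner16)
    else:
        stack = np.stack([owner16, actin_owner.astype(np.uint16)])
        tifffile.imwrite(path, stack)


def write_snapshot_text(path, owner: np.ndarray) -> None:
    np.savetxt(path, owner, fmt="%d")
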