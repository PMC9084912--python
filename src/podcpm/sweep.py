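"""Density sweeps: repeat simulations over cell counts and summarize.

For each (cell count, seed replicate) the sweep runs a simulation, discards
the equilibration phase (already excluded from recorded tracks), measures
the mean instantaneous speed from 50-MCS subtracks, fits the persistence
time from the directional autocorrelation, and takes the observed density
as the time-averaged number of live cells divided by the lattice area.
Seeds act as replicates: Pearson correlations between density, speed and
persistence time are computed per seed across cell counts and
Fisher-averaged into a correlogram.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .analysis import (CorrelationMatrix, WellSummary, build_correlogram,
                       directional_autocorrelation, fit_dac,
                       instantaneous_speed)
from .config import SimulationConfig
from .sim import SimResult, run_simulation

__all__ = ["SweepSpec", "summarize_run", "run_density_sweep"]

log = logging.getLogger("podcpm.sweep")

SPEED_SUBTRACK_MCS = 50.0


@dataclass
class SweepSpec:
    cell_counts: list
    seeds: list
    config: SimulationConfig
    max_lag: int = 250          # DAC lags (in sampling intervals) for the fit
    out_dir: str | None = None

    def __post_init__(self):
        if len(self.cell_counts) < 2:
            raise ValueError("need >= 2 cell counts for correlation output")
        if not self.seeds:
            raise ValueError("need at least one seed")


def summarize_run(result: SimResult, max_lag: int = 250,
                  well: str = "well", replicate: str = "rep") -> WellSummary:
    """Reduce one simulation to (density, speed, phi, tau_p)."""
    cfg = result.config
    tracks = result.tracks
    speeds = []
    for tr in tracks.tracks().values():
        if len(tr) * tracks.dt > SPEED_SUBTRACK_MCS:
            speeds.extend(instantaneous_speed(tr, SPEED_SUBTRACK_MCS))
    speed = float(np.mean(speeds)) if speeds else float("nan")
    dac = directional_autocorrelation(tracks, max_lag)
    fit = fit_dac(dac)
    # observed density: time-averaged live-cell count per lattice site
    per_time = tracks.df.groupby("t")["track_id"].count()
    density = float(per_time.mean()) / (cfg.width * cfg.height)
    return WellSummary(well=well, replicate=replicate, density=density,
                       speed=speed, phi=fit.phi, tau_p=fit.tau_p)


def run_density_sweep(spec: SweepSpec):
    """Run the sweep; returns (summary DataFrame, CorrelationMatrix).

    Individual run failures are logged and skipped; the sweep continues.
    A correlogram needs >= 3 cell counts per seed (Pearson over wells);
    with fewer, the matrix is returned as None and flagged in the log.
    """
    rows = []
    for seed in spec.seeds:
        for count in spec.cell_counts:
            cfg = spec.config.copy(n_cells=int(count))
            try:
                result = run_simulation(cfg, seed=int(seed))
                summary = summarize_run(result, max_lag=spec.max_lag,
                                        well=f"n{count}", replicate=f"s{seed}")
            except Exception:
                log.exception("sweep run failed (n=%s seed=%s); continuing",
                              count, seed)
                continue
            rows.append(summary)
            log.info("n=%s seed=%s density=%.5f speed=%.4f tau_p=%.1f",
                     count, seed, summary.density, summary.speed,
                     summary.tau_p)
    df = pd.DataFrame([s.__dict__ for s in rows])
    corr: CorrelationMatrix | None = None
    if len(spec.cell_counts) >= 3:
        try:
            corr = build_correlogram(df)
        except ValueError as exc:
            log.warning("correlogram undefined: %s", exc)
    else:
        log.warning("correlogram undefined: fewer than 3 cell counts")
    return df, corr
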