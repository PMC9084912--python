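"""Calibrated per-model parameter presets.

Temperature, surface energies and model strengths are calibration choices:
they were tuned once so each model variant reproduces its characteristic
qualitative migration behavior at desk scale (150x150 lattice, target area
250 sites, cell counts 10-60), and are shipped as the package's reference
conditions.  They are not measured quantities.  The same presets back the
example config files under ``configs/``.

Qualitative behaviors the presets are calibrated to:

* ``base``            -- Brownian single-cell motion (no persistence).
* ``persistence``     -- speed rises with density (cells merge and move
                         through each other in the low cell-cell surface
                         energy regime).
* ``act``             -- speed falls with density (crowding obstructs the
                         activity-driven protrusion).
* ``ariotti``         -- explicit pseudopods; speed falls with density
                         (pseudopods obstruct each other).
* ``pseudopod-ext``   -- pseudopods with tip adhesion + pulling + CIL-style
                         poof-dir touch behavior; speed and persistence both
                         rise with density (collectively migrating clusters
                         free cells that are stuck at the high cell-medium
                         surface energy when sparse).
"""

from __future__ import annotations

from .config import SimulationConfig

__all__ = ["preset_config", "PRESET_MODELS"]

PRESET_MODELS = ("base", "persistence", "act", "ariotti", "pseudopod-ext")


def preset_config(model: str, **overrides) -> SimulationConfig:
    """Reference configuration for one model variant.

    Keyword overrides are applied to the top-level config (width, height,
    n_cells, total_mcs, ...).
    """
    if model not in PRESET_MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {PRESET_MODELS}")
    cfg = SimulationConfig(model=model)
    cfg.temperature = 20.0
    cfg.contact.j_cell_med = 20.0
    cfg.contact.j_cell_cell = 30.0
    cfg.contact.lambda_area = 25.0
    cfg.contact.target_area = 250.0
    if model == "persistence":
        cfg.persistence.lambda_p = 0.3
        cfg.persistence.decay_time = 2.0
        cfg.contact.j_cell_cell = 16.0   # merging regime
    elif model == "act":
        cfg.act.lambda_act = 100.0
        cfg.act.max_act = 40.0
        cfg.contact.j_cell_cell = 60.0   # collisions arrest protrusion
    elif model in ("ariotti", "pseudopod-ext"):
        cfg.pseudopod.neighboring_actin_bonus = 100.0
        cfg.pseudopod.kappa_init = 3.0
        cfg.pseudopod.kappa_cont = 8.0
        cfg.pseudopod.max_growth_time = 60.0
        cfg.pseudopod.time_between_extensions = 20.0
        cfg.pseudopod.n_pseudopods = 3
        if model == "pseudopod-ext":
            cfg.contact.j_cell_med = 50.0  # sparse cells are stuck
            cfg.extension.pull_strength = 400.0
            cfg.extension.tip_bonus = 60.0
            cfg.extension.r_max = 3.0
            cfg.extension.touch_behavior = "poof-dir"
    for key, value in overrides.items():
        setattr(cfg, key, value)
    cfg.validate()
    return cfg
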