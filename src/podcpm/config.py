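"""Simulation configuration: typed parameter blocks and a flat key-value file format.

Config files are plain text, one ``key = value`` per line, ``#`` starts a
comment.  Keys are hyphenated (``pull-strength = 10``).  Unknown keys raise
with a suggestion for the nearest valid key.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass, field, replace

__all__ = [
    "ContactParams",
    "PersistenceParams",
    "ActParams",
    "PseudopodParams",
    "ExtensionParams",
    "SimulationConfig",
    "ConfigError",
    "read_config",
    "write_config",
]

MODELS = ("base", "persistence", "act", "ariotti", "pseudopod-ext")
TOUCH_BEHAVIORS = ("nothing", "retract", "attach", "poof-dir")
RETRACTION_MODES = ("backward", "forward")


class ConfigError(ValueError):
    """Raised for malformed or inconsistent configuration input."""


@dataclass
class ContactParams:
    """Surface energies and elastic area constraint.

    ``j_cell_med`` / ``j_cell_cell`` are energies per unlike Moore neighbor
    pair (pairs counted once).  Values shipped in example configs are
    calibration choices, not measured quantities.
    """

    j_cell_med: float = 20.0
    j_cell_cell: float = 30.0
    lambda_area: float = 25.0     # energy / site^2
    target_area: float = 250.0    # sites; ~20 um cell at ~2 um/px


@dataclass
class PersistenceParams:
    """Basic persistence: cells carry a decaying target direction."""

    lambda_p: float = 0.1        # energy per site (multiplied by cell area)
    decay_time: float = 20.0     # MCS


@dataclass
class ActParams:
    """Act model: per-site protrusive activity with linear decay."""

    lambda_act: float = 160.0
    max_act: float = 40.0        # MCS of memory


@dataclass
class PseudopodParams:
    """Finite-state-machine pseudopods (explicit actin chains)."""

    p_ext: float = 0.3
    p_retr: float = 0.3
    kappa_init: float = 3.0          # init-dir-strength
    kappa_cont: float = 8.0          # cont-dir-strength
    max_growth_time: float = 60.0    # MCS
    stall_limit: int = 20            # MCS without extension before retracting
    time_between_extensions: float = 20.0  # MCS; INACTIVE->INIT prob is 1/this
    retraction_mode: str = "backward"
    neighboring_actin_bonus: float = 60.0  # energy
    n_pseudopods: int = 3
    move_dir_decay_time: float = 10.0  # MCS; smoothing of the cell movement direction


@dataclass
class ExtensionParams:
    """Tip adhesion, pulling force and touch behavior of pseudopods."""

    pull_strength: float = 0.0       # F; energy (divided by cell area in dH)
    tip_bonus: float = 0.0           # E_tip-bonus; energy
    r_max: float = 3.0               # max-distance-for-tip-bonus; lattice units
    touch_behavior: str = "nothing"
    p_touch_retr: float = 0.1
    lateral_threshold: float = 0.85  # cos(alpha) below which a touch is lateral


@dataclass
class SimulationConfig:
    width: int = 150
    height: int = 150
    n_cells: int = 30
    total_mcs: int = 5000
    equilibration_mcs: int = 1000
    track_interval: int = 1
    snapshot_interval: int = 0       # 0 disables snapshots
    temperature: float = 20.0
    connectivity: bool = False
    model: str = "base"
    seed: int | None = None
    contact: ContactParams = field(default_factory=ContactParams)
    persistence: PersistenceParams = field(default_factory=PersistenceParams)
    act: ActParams = field(default_factory=ActParams)
    pseudopod: PseudopodParams = field(default_factory=PseudopodParams)
    extension: ExtensionParams = field(default_factory=ExtensionParams)

    def validate(self) -> None:
        if self.temperature <= 0:
            raise ConfigError("temperature must be > 0")
        if self.width < 1 or self.height < 1:
            raise ConfigError("lattice dimensions must be positive")
        if self.n_cells < 0 or self.n_cells > self.width * self.height:
            raise ConfigError("cell count must be in [0, width*height]")
        if not (self.total_mcs > self.equilibration_mcs >= 0):
            raise ConfigError("total MCS must exceed equilibration MCS (>= 0)")
        if self.model not in MODELS:
            raise ConfigError(f"model must be one of {MODELS}")
        if self.extension.touch_behavior not in TOUCH_BEHAVIORS:
            raise ConfigError(f"touch-behavior must be one of {TOUCH_BEHAVIORS}")
        if self.pseudopod.retraction_mode not in RETRACTION_MODES:
            raise ConfigError(f"retraction-mode must be one of {RETRACTION_MODES}")
        for p in (self.pseudopod.p_ext, self.pseudopod.p_retr,
                  self.extension.p_touch_retr):
            if not 0.0 <= p <= 1.0:
                raise ConfigError("probabilities must lie in [0, 1]")
        if self.extension.r_max <= 0:
            raise ConfigError("max-distance-for-tip-bonus must be > 0")
        if self.pseudopod.n_pseudopods < 1:
            raise ConfigError("n-pseudopods must be >= 1")

    def copy(self, **updates) -> "SimulationConfig":
        return replace(self, **updates)


# flat key -> (block attribute on SimulationConfig or None, field name, type)
_KEYMAP: dict[str, tuple[str | None, str, type]] = {
    "lattice-width": (None, "width", int),
    "lattice-height": (None, "height", int),
    "cell-count": (None, "n_cells", int),
    "total-mcs": (None, "total_mcs", int),
    "equilibration-mcs": (None, "equilibration_mcs", int),
    "track-interval": (None, "track_interval", int),
    "snapshot-interval": (None, "snapshot_interval", int),
    "temperature": (None, "temperature", float),
    "connectivity-constraint": (None, "connectivity", bool),
    "model": (None, "model", str),
    "seed": (None, "seed", int),
    "j-cell-med": ("contact", "j_cell_med", float),
    "j-cell-cell": ("contact", "j_cell_cell", float),
    "lambda-area": ("contact", "lambda_area", float),
    "target-area": ("contact", "target_area", float),
    "lambda-persistence": ("persistence", "lambda_p", float),
    "decay-time": ("persistence", "decay_time", float),
    "lambda-act": ("act", "lambda_act", float),
    "max-act": ("act", "max_act", float),
    "p-ext": ("pseudopod", "p_ext", float),
    "p-retr": ("pseudopod", "p_retr", float),
    "init-dir-strength": ("pseudopod", "kappa_init", float),
    "cont-dir-strength": ("pseudopod", "kappa_cont", float),
    "max-growth-time": ("pseudopod", "max_growth_time", float),
    "stall-limit": ("pseudopod", "stall_limit", int),
    "time-between-extensions": ("pseudopod", "time_between_extensions", float),
    "retraction-mode": ("pseudopod", "retraction_mode", str),
    "neighboring-actin-bonus": ("pseudopod", "neighboring_actin_bonus", float),
    "n-pseudopods": ("pseudopod", "n_pseudopods", int),
    "move-dir-decay-time": ("pseudopod", "move_dir_decay_time", float),
    "pull-strength": ("extension", "pull_strength", float),
    "tip-bonus": ("extension", "tip_bonus", float),
    "max-distance-for-tip-bonus": ("extension", "r_max", float),
    "touch-behavior": ("extension", "touch_behavior", str),
    "p-touch-retr": ("extension", "p_touch_retr", float),
    "lateral-threshold": ("extension", "lateral_threshold", float),
}


def _parse_value(raw: str, typ: type, key: str, lineno: int):
    raw = raw.strip()
    try:
        if typ is bool:
            low = raw.lower()
            if low in ("true", "on", "yes", "1"):
                return True
            if low in ("false", "off", "no", "0"):
                return False
            raise ValueError(raw)
        return typ(raw)
    except ValueError as exc:
        raise ConfigError(
            f"line {lineno}: cannot parse value {raw!r} for key {key!r} as {typ.__name__}"
        ) from exc


def read_config(path, overrides: dict | None = None) -> SimulationConfig:
    """Parse a flat ``key = value`` config file into a :class:`SimulationConfig`.

    Keys absent from the file keep their documented defaults.  Unknown keys
    raise a :class:`ConfigError` naming the closest valid key.
    """
    cfg = SimulationConfig()
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.readlines()
    items: dict[str, object] = {}
    for lineno, line in enumerate(lines, start=1):
        text = line.split("#", 1)[0].strip()
        if not text:
            continue
        if "=" not in text:
            raise ConfigError(f"line {lineno}: expected 'key = value', got {text!r}")
        key, raw = (part.strip() for part in text.split("=", 1))
        if key not in _KEYMAP:
            hint = difflib.get_close_matches(key, _KEYMAP, n=1)
            suffix = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ConfigError(f"line {lineno}: unknown key {key!r}{suffix}")
        block, name, typ = _KEYMAP[key]
        items[key] = (block, name, _parse_value(raw, typ, key, lineno))
    if overrides:
        for key, value in overrides.items():
            if key not in _KEYMAP:
                raise ConfigError(f"unknown override key {key!r}")
            block, name, typ = _KEYMAP[key]
            items[key] = (block, name, value)
    for block, name, value in items.values():
        target = cfg if block is None else getattr(cfg, block)
        setattr(target, name, value)
    cfg.validate()
    return cfg


def write_config(cfg: SimulationConfig, path) -> None:
    """Write the fully resolved configuration (provenance record for runs)."""
    lines = []
    for key, (block, name, _typ) in _KEYMAP.items():
        target = cfg if block is None else getattr(cfg, block)
        value = getattr(target, name)
        if value is None:
            continue
        lines.append(f"{key} = {value}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
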