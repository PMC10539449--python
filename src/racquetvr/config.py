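"""Run configuration: schema, defaults and YAML loading.

Every pipeline threshold defaults to the task's stated value: 10 Hz motion
smoothing, 15 Hz gaze smoothing, 3 deg dispersion, 100 ms minimum fixation,
0.1 s bounce window, 100 ms gap / 20% missing exclusion rules, alpha 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

__all__ = ["RunConfig", "load_config"]

SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    master_seed: int = 1
    n_per_group: int = 22
    sequence_id: int = 1
    group_presets: dict = field(
        default_factory=lambda: {"ASD": "asd_like", "NT": "nt_like"})
    # pipeline thresholds (task defaults)
    motion_cutoff_hz: float = 10.0
    gaze_cutoff_hz: float = 15.0
    dispersion_max_deg: float = 3.0
    min_fix_duration_s: float = 0.100
    bounce_window_s: float = 0.100
    gap_max_s: float = 0.100
    missing_max_frac: float = 0.20
    foreswing_v_thresh: float = 0.2
    rom_mode: str = "facing_vs_displacement"
    # stats options
    alpha: float = 0.05
    bf_scale: float = 0.707
    schema_version: int = SCHEMA_VERSION

    def validate(self) -> None:
        from .agent import PRESETS

        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.sequence_id not in (1, 2, 3):
            raise ValueError("sequence_id must be in {1, 2, 3}")
        if set(self.group_presets) != {"ASD", "NT"}:
            raise ValueError("group_presets must map exactly ASD and NT")
        for name in self.group_presets.values():
            if name not in PRESETS:
                raise ValueError(f"unknown preset '{name}' (have {sorted(PRESETS)})")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        for fieldname in ("motion_cutoff_hz", "gaze_cutoff_hz",
                          "dispersion_max_deg", "min_fix_duration_s",
                          "gap_max_s"):
            if getattr(self, fieldname) <= 0:
                raise ValueError(f"{fieldname} must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path=None, **overrides) -> RunConfig:
    """Load a YAML config (missing file fields fall back to defaults)."""
    data = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        version = data.pop("schema_version", SCHEMA_VERSION)
        if version != SCHEMA_VERSION:
            raise ValueError(f"unsupported config schema_version {version}")
    data.update(overrides)
    unknown = set(data) - {f for f in RunConfig.__dataclass_fields__}
    if unknown:
        raise ValueError(f"unknown config fields: {sorted(unknown)}")
    cfg = RunConfig(**data)
    cfg.validate()
    return cfg
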