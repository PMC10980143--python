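"""Run configuration: YAML loading with strict keys and seed fan-out."""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

_SECTION_KEYS: dict[str, set[str]] = {
    "data": {"input", "annotations", "fs_target", "window_s", "standardize"},
    "augment": {"p_apply", "permutation_segment_len", "warp_knots",
                "warp_max_stretch", "scale_low", "scale_high"},
    "model": {"channels", "strides", "feature_dim", "input_length",
              "stem_kernel", "stem_stride", "preset"},
    "ssl": {"method", "n_epochs", "batch_size", "lr", "freeze_encoder",
            "projection_dim", "temperature", "head_nonlinear"},
    "finetune": {"lr", "max_epochs", "patience", "batch_size", "threshold",
                 "val_fraction", "test_fraction", "k_folds", "seeds"},
    "dailyliving": {"sd_threshold", "min_nonwear_minutes", "min_wear_hours",
                    "n_days"},
    "stats": {"alpha", "correction", "covariates"},
    "simulate": {"subjects", "days", "duration_s", "gait_fraction",
                 "arm_swing_amplitude", "tremor_amplitude", "fs",
                 "daily_walking_minutes"},
}
_GLOBAL_KEYS = {"seed", "out_dir"}


class ConfigError(ValueError):
    """Raised on unknown keys or malformed run configuration."""


@dataclass
class RunConfig:
    """Nested per-stage option sections plus the global seed."""

    seed: int = 0
    out_dir: str = "."
    sections: dict[str, dict] = field(default_factory=dict)

    def section(self, name: str) -> dict:
        return dict(self.sections.get(name, {}))

    def stage_seed(self, stage: str) -> int:
        return derive_seed(self.seed, stage)

    def resolved(self) -> dict:
        return {"seed": self.seed, "out_dir": self.out_dir, **self.sections}


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed so stages can be rerun independently."""
    return (int(global_seed) * 1000003 + zlib.crc32(stage.encode())) % (2 ** 31)


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    unknown = set(raw) - set(_SECTION_KEYS) - _GLOBAL_KEYS
    if unknown:
        raise ConfigError(f"{path}: unknown top-level key(s) {sorted(unknown)}")
    sections = {}
    for name, allowed in _SECTION_KEYS.items():
        sec = raw.get(name, {})
        if not isinstance(sec, dict):
            raise ConfigError(f"{path}: section {name!r} must be a mapping")
        bad = set(sec) - allowed
        if bad:
            raise ConfigError(f"{path}: unknown key(s) {sorted(bad)} in section {name!r}")
        if sec:
            sections[name] = sec
    return RunConfig(
        seed=int(raw.get("seed", 0)),
        out_dir=str(raw.get("out_dir", ".")),
        sections=sections,
    )


def write_resolved(cfg: RunConfig, path: str | Path) -> None:
    """Write the fully resolved configuration next to a run's outputs."""
    Path(path).write_text(yaml.safe_dump(cfg.resolved(), sort_keys=True))
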