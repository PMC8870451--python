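"""Run configuration: YAML loading with strict key validation.

Defaults equal the published analysis parameters (2.8 / 3 / 6 Å shells,
3.5 Å / 30 deg H-bonds, lambda 0.3, eps_in 8, sigma 0.7, 0.15 M,
1.8 points/Å, 90% identity, 500 bootstraps).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

ALL_STAGES = ("simulate", "shells", "rotamers", "hbonds", "amd", "pb", "phylo")

_DEFAULTS: dict[str, dict[str, Any]] = {
    "analysis": {
        "first_shell_protein": 2.8,
        "first_shell_water": 3.0,
        "second_shell": 6.0,
        "bridge_water": 3.0,
        "hbond_dist": 3.5,
        "hbond_angle_dev": 30.0,
        "rotamer_filter_window": 50.0,
    },
    "site": {
        "n_replicas": 3,
        "n_frames": 100,
        "frame_interval": 1.0,
        "noise_sd": 0.02,
        "water_count": 4,
        "first_fraction": 0.6,
        "second_fraction": 0.2,
    },
    "amd": {
        "n_frames": 2000,
        "dt": 0.1,
        "dihedral_mean": 500.0,
        "dihedral_sd": 10.0,
        "potential_mean": -50000.0,
        "potential_sd": 100.0,
        "window": [20.0, 120.0],
        "lambda_factor": 0.3,
        "n_atoms": 10000,
    },
    "pb": {
        "eps_in": 8.0,
        "eps_out": 80.0,
        "sigma": 0.7,
        "ionic_strength": 0.15,
        "scale": 1.8,
        "fill_ratio": 0.7,
        "grid_points": 41,
        "dielectric_model": "gaussian",
    },
    "phylo": {
        "n_leaves": 8,
        "sequence_length": 120,
        "branch_length": 0.15,
        "identity_threshold": 0.90,
        "n_bootstrap": 500,
        "distance_correction": "none",
    },
}


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class RunConfig:
    seed: int
    output_dir: Path
    stages: tuple[str, ...]
    analysis: dict[str, Any]
    site: dict[str, Any]
    amd: dict[str, Any]
    pb: dict[str, Any]
    phylo: dict[str, Any]

    def as_dict(self) -> dict[str, Any]:
        return {
            "seed": self.seed,
            "output_dir": str(self.output_dir),
            "stages": list(self.stages),
            "analysis": dict(self.analysis),
            "site": dict(self.site),
            "amd": dict(self.amd),
            "pb": dict(self.pb),
            "phylo": dict(self.phylo),
        }


def _merge_section(name: str, user: Mapping[str, Any] | None) -> dict[str, Any]:
    merged = dict(_DEFAULTS[name])
    if user:
        for key, value in user.items():
            if key not in merged:
                raise ConfigError(f"unknown key {name}.{key!r}")
            merged[key] = value
    return merged


def load_config(source: str | Path | Mapping[str, Any]) -> RunConfig:
    """Load and validate a run configuration from YAML or a mapping."""
    if isinstance(source, (str, Path)):
        raw = yaml.safe_load(Path(source).read_text())
    else:
        raw = dict(source)
    if raw is None:
        raw = {}
    if not isinstance(raw, Mapping):
        raise ConfigError("configuration must be a mapping")
    allowed_top = {"seed", "output_dir", "stages", *_DEFAULTS}
    for key in raw:
        if key not in allowed_top:
            raise ConfigError(f"unknown key {key!r}")
    if "seed" not in raw:
        raise ConfigError("seed is required (seeds must be explicit)")
    stages = tuple(raw.get("stages", ALL_STAGES))
    for stage in stages:
        if stage not in ALL_STAGES:
            raise ConfigError(f"unknown stage {stage!r}; expected one of {ALL_STAGES}")
    return RunConfig(
        seed=int(raw["seed"]),
        output_dir=Path(raw.get("output_dir", "ionbind_out")),
        stages=stages,
        analysis=_merge_section("analysis", raw.get("analysis")),
        site=_merge_section("site", raw.get("site")),
        amd=_merge_section("amd", raw.get("amd")),
        pb=_merge_section("pb", raw.get("pb")),
        phylo=_merge_section("phylo", raw.get("phylo")),
    )
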