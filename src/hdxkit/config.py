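"""Declarative run configuration (YAML/JSON) shared by CLI commands."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """All validation problems of a config, reported at once."""


@dataclass
class RunConfig:
    # input
    input_path: str = ""
    time_unit: str = "s"
    mapping_path: str | None = None
    # comparison
    state_a: str = ""
    state_b: str = ""
    # back-exchange
    backexchange_method: str = "none"        # none | experimental_maxD | plateau_maxD
    maxd_file: str | None = None
    # pH normalization
    ph_reference: float | None = None
    ph_per_state: dict = field(default_factory=dict)
    # empirical calibration
    empirical_enabled: bool = False
    empirical_reference_state: str = ""
    empirical_reference_protein: str = "REFERENCE"
    # fitting
    max_nexp: int = 1
    window: tuple[float, float] | None = None
    plateau_fraction: float = 0.99
    log_time: bool = False
    # significance
    metric: str = "uptake_area"
    distribution: str = "per_replicate"
    threshold: str = "sd_ci"
    confidence: float = 0.95
    alpha: float = 0.05
    outlier: str = "none"
    n_samples_s: int = 100
    bootstrap_b: int = 10_000
    seed: int = 0
    # protection factors
    pf_enabled: bool = False
    pf_ph: float = 7.0
    pf_temperature: float = 293.0
    ln_pf_max: float = 10.0
    # output
    output_dir: str = "hdxkit_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        if cfg.window is not None:
            cfg.window = tuple(cfg.window)
        return cfg

    def validate(self, known_states: set[str] | None = None) -> None:
        """Collect every problem and raise once with field paths."""
        errors = []
        if not 0.5 < self.confidence < 1:
            errors.append(f"confidence: {self.confidence} outside (0.5, 1)")
        if not 0 < self.alpha < 0.5:
            errors.append(f"alpha: {self.alpha} outside (0, 0.5)")
        if self.time_unit not in ("ms", "s", "min"):
            errors.append(f"time_unit: {self.time_unit!r} not one of ms/s/min")
        if self.backexchange_method not in ("none", "experimental_maxD",
                                            "plateau_maxD"):
            errors.append(f"backexchange_method: {self.backexchange_method!r}")
        if self.distribution not in ("per_replicate", "random", "bootstrap"):
            errors.append(f"distribution: {self.distribution!r}")
        if self.threshold not in ("sd_ci", "pairwise_ci", "bootstrap_ci"):
            errors.append(f"threshold: {self.threshold!r}")
        if self.outlier not in ("none", "mean", "median", "quartiles",
                                "grubbs", "gesd"):
            errors.append(f"outlier: {self.outlier!r}")
        if self.metric not in ("uptake", "uptake_area", "k_obs", "pf"):
            errors.append(f"metric: {self.metric!r}")
        if self.max_nexp < 1:
            errors.append(f"max_nexp: {self.max_nexp} must be >= 1")
        if self.window is not None and not self.window[0] < self.window[1]:
            errors.append(f"window: {self.window} not increasing")
        if known_states is not None:
            for label, state in (("state_a", self.state_a),
                                 ("state_b", self.state_b)):
                if state and state not in known_states:
                    errors.append(
                        f"{label}: {state!r} not among input states "
                        f"{sorted(known_states)}")
            for state in self.ph_per_state:
                if state not in known_states:
                    errors.append(f"ph_per_state: unknown state {state!r}")
        if errors:
            raise ConfigError("invalid configuration:\n  " + "\n  ".join(errors))

    def manifest(self) -> dict:
        from . import __version__
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return {
            "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
            "seed": self.seed,
            "hdxkit_version": __version__,
        }
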