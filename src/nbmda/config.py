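"""Run configuration: defaults, config-file parsing, flag precedence.

A flat YAML document of dotted keys configures every tunable; resolution
precedence is built-in defaults < config file < command-line flags.  The
resolved configuration is embedded in every report so a run can be
reproduced exactly from its own output.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = ["RunConfig", "load_config", "ConfigError", "VALID_KEYS"]


class ConfigError(ValueError):
    """Unknown configuration key or out-of-range value."""


@dataclass
class RunConfig:
    """All tunables with their conventional defaults."""

    k: int = 3
    vote_threshold: int | None = None
    delta: float = 0.5
    gamma_prime_m: float = 1.0
    gamma_prime_d: float = 1.0
    folds: int = 5
    repeats: int = 100
    seed: int = 0
    similarity_mode: str = "dynamic"

    def validate(self) -> "RunConfig":
        if self.k < 1:
            raise ConfigError(f"knn.k must be >= 1, got {self.k}")
        if self.vote_threshold is not None and not 1 <= self.vote_threshold <= self.k:
            raise ConfigError(
                f"knn.vote_threshold must lie in [1, k={self.k}], got {self.vote_threshold}"
            )
        if not 0 < self.delta <= 1:
            raise ConfigError(f"semantic.delta must be in (0, 1], got {self.delta}")
        if self.gamma_prime_m <= 0:
            raise ConfigError("kernel.gamma_prime_m must be positive")
        if self.gamma_prime_d <= 0:
            raise ConfigError("kernel.gamma_prime_d must be positive")
        if self.folds < 2:
            raise ConfigError(f"cv.folds must be >= 2, got {self.folds}")
        if self.repeats < 1:
            raise ConfigError(f"cv.repeats must be >= 1, got {self.repeats}")
        if self.similarity_mode not in ("dynamic", "static"):
            raise ConfigError(
                f"cv.similarity_mode must be 'dynamic' or 'static', got {self.similarity_mode!r}"
            )
        return self

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


#: dotted config-file key -> RunConfig field
VALID_KEYS = {
    "knn.k": "k",
    "knn.vote_threshold": "vote_threshold",
    "semantic.delta": "delta",
    "kernel.gamma_prime_m": "gamma_prime_m",
    "kernel.gamma_prime_d": "gamma_prime_d",
    "cv.folds": "folds",
    "cv.repeats": "repeats",
    "cv.seed": "seed",
    "cv.similarity_mode": "similarity_mode",
}


def load_config(
    path: str | Path | None = None,
    overrides: Mapping[str, Any] | None = None,
) -> RunConfig:
    """Resolve a RunConfig from defaults, an optional file, and flag overrides.

    ``overrides`` maps RunConfig field names to values (``None`` entries are
    ignored, letting CLI flags default to "not given").
    """
    values: dict[str, Any] = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: expected a flat key/value document")
        for key, val in raw.items():
            if key not in VALID_KEYS:
                raise ConfigError(
                    f"{path}: unknown config key {key!r}; valid keys: "
                    + ", ".join(sorted(VALID_KEYS))
                )
            values[VALID_KEYS[key]] = val
    for name, val in (overrides or {}).items():
        if val is not None:
            values[name] = val
    return RunConfig(**values).validate()
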