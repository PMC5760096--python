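"""Run configuration: defaults, presets, YAML loading and validation."""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["RunConfig", "ConfigError", "load_config", "PRESETS"]


class ConfigError(ValueError):
    """Configuration file failed validation."""


@dataclass
class RunConfig:
    """All tunables of the identification pipeline.

    ``restarts`` is the number of outer random restarts of the Hill/ARX
    search and ``inner_combos`` the number of (n, K) combinations scored per
    restart; the full-scale values are 500 and 200 (the ``full`` preset),
    with a ``fast`` preset (20/50) for exploratory and benchmark runs.
    ``iv_cycles`` repeats the refine-and-re-recover step within each restart
    so the combination scoring uses a recovery produced under an
    increasingly apt transform; the full-scale preset keeps a single cycle
    and relies on restart volume instead.
    ``hankel_width`` ("auto" -> floor((N+1)/3)) is the column count c of the
    Hankel-like matrices.  ``recovery_noise`` is the assumed
    measurement-noise SD on the normalized scale; the signal recovery
    accepts the smallest rank that reproduces the observations to that RMS
    (0 demands an exact structured completion).
    ``cutoff_fraction`` defines the gain cutoff for
    the time constant; 1/sqrt(2) is the -3 dB point.  ``freq_convention`` is
    "substitution" (z -> i*omega) or "discrete" (z -> exp(i*omega*dt)).
    """

    dt: float | str = "auto"
    hankel_width: int | str = "auto"
    restarts: int = 500
    inner_combos: int = 200
    iv_cycles: int = 2
    tol: float = 1e-9
    max_iter: int = 300
    m_max: int = 3
    recovery_noise: float = 0.0
    cutoff_fraction: float = 1.0 / math.sqrt(2.0)
    freq_convention: str = "substitution"
    seed: int = 0
    conditions: list[str] = field(default_factory=list)
    candidates: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.restarts < 1 or self.inner_combos < 1:
            raise ConfigError("restarts and inner_combos must be >= 1")
        if self.freq_convention not in ("substitution", "discrete"):
            raise ConfigError(
                f"freq_convention must be 'substitution' or 'discrete', "
                f"got {self.freq_convention!r}"
            )
        if not (0 < self.cutoff_fraction < 1):
            raise ConfigError("cutoff_fraction must be in (0, 1)")
        if self.dt != "auto" and not (isinstance(self.dt, (int, float)) and self.dt > 0):
            raise ConfigError("dt must be 'auto' or a positive number")
        if self.hankel_width != "auto" and not (
            isinstance(self.hankel_width, int) and self.hankel_width >= 2
        ):
            raise ConfigError("hankel_width must be 'auto' or an integer >= 2")

    def hankel_c(self, n_steps: int) -> int:
        if self.hankel_width == "auto":
            return max(2, min(n_steps - 1, (n_steps + 1) // 3))
        return int(self.hankel_width)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


PRESETS = {
    "full": {"restarts": 500, "inner_combos": 200, "iv_cycles": 1},
    "fast": {"restarts": 20, "inner_combos": 50, "tol": 1e-6, "max_iter": 120},
}

_FIELD_TYPES = {
    "dt": (int, float, str),
    "hankel_width": (int, str),
    "restarts": (int,),
    "inner_combos": (int,),
    "iv_cycles": (int,),
    "tol": (int, float),
    "max_iter": (int,),
    "m_max": (int,),
    "recovery_noise": (int, float),
    "cutoff_fraction": (int, float),
    "freq_convention": (str,),
    "seed": (int,),
    "conditions": (list,),
    "candidates": (dict,),
}


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML config; unknown keys are rejected.

    A top-level ``preset: full|fast`` key expands to the corresponding
    restart counts before explicit keys are applied.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    preset = raw.pop("preset", None)
    merged: dict = {}
    if preset is not None:
        if preset not in PRESETS:
            raise ConfigError(
                f"unknown preset {preset!r}; choose from {sorted(PRESETS)}"
            )
        merged.update(PRESETS[preset])
    unknown = set(raw) - set(_FIELD_TYPES)
    if unknown:
        raise ConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    for key, val in raw.items():
        if not isinstance(val, _FIELD_TYPES[key]) or isinstance(val, bool):
            raise ConfigError(
                f"config key {key!r} has wrong type {type(val).__name__}"
            )
        merged[key] = val
    if "candidates" in merged:
        cand = merged["candidates"]
        for out, pool in cand.items():
            if not isinstance(pool, list) or not all(isinstance(x, str) for x in pool):
                raise ConfigError(f"candidates[{out!r}] must be a list of molecule names")
            if out in pool:
                raise ConfigError(f"output {out!r} cannot be its own candidate input")
    return RunConfig(**merged)
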