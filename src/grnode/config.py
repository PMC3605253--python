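"""Inference configuration.

All tunable settings of the heuristic live in :class:`InferenceConfig`.
Configurations can be round-tripped through a flat ``key: value`` text file;
the dotted key aliases (``interpolation.k_per_interval`` etc.) are accepted on
input and used on output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

from .errors import ConfigError

__all__ = ["InferenceConfig"]


@dataclass
class InferenceConfig:
    """Settings controlling pre-processing, fitting and structure search.

    Parameters
    ----------
    allowed_error:
        Per-time-series error threshold (weight-normalised mean squared
        deviation).  While a sub-model's error exceeds it, the structure is
        extended.  Smaller values yield denser networks.
    max_connections:
        Maximum number of incoming connections per sub-model beyond the
        mandatory self-regulation.
    max_order:
        Maximum integrator-chain order per sub-model.
    k_per_interval:
        Number of artificial (cubic-spline) points inserted per measured
        interval.
    weight_measured, weight_interpolated:
        Weights w(t_k) of measured resp. interpolated points in regression and
        objective.
    growing_threshold:
        Relative improvement required to accept an added connection or a
        raised order: J_new <= (1 - growing_threshold) * J_old.
    pruning_threshold:
        Relative worsening tolerated when removing a connection:
        J_new <= (1 + pruning_threshold) * J_old.
    coeff_bound:
        Box bound for all coefficients: [-coeff_bound, coeff_bound].
    diag_upper:
        Upper bound of the diagonal (self-regulation) coefficient; strictly
        negative to keep every sub-model stable.
    max_iter, gtol:
        Iteration cap and projected-gradient tolerance of the bounded
        quasi-Newton optimiser.
    prior_lambda:
        Penalty weight of flexible prior knowledge (used when the prior object
        does not carry its own value).
    sigmoid, sigmoid_gain:
        Optional saturating non-linearity wrapping each sub-model's linear
        combination.
    rtol, atol:
        Tolerances for the stiffness-tolerant initial-value solver.
    seed:
        Seed recorded with every run; inference itself is deterministic, the
        seed drives data generation and resampling only.
    refit_included:
        Re-optimise already-included sub-models when later genes are added.
        Disabled by default (and untested territory): the heuristic freezes
        accepted sub-models.
    """

    allowed_error: float = 0.005
    max_connections: int = 4
    max_order: int = 3
    k_per_interval: int = 3
    weight_measured: float = 1.0
    weight_interpolated: float = 0.25
    growing_threshold: float = 0.05
    pruning_threshold: float = 0.05
    coeff_bound: float = 50.0
    diag_upper: float = -1e-3
    max_iter: int = 200
    gtol: float = 1e-8
    prior_lambda: float = 0.1
    sigmoid: bool = False
    sigmoid_gain: float = 1.0
    rtol: float = 1e-6
    atol: float = 1e-8
    seed: int = 0
    refit_included: bool = False

    # dotted aliases used in config files
    _ALIASES = {
        "allowedError": "allowed_error",
        "maxConnections": "max_connections",
        "maxOrder": "max_order",
        "interpolation.k_per_interval": "k_per_interval",
        "weights.measured": "weight_measured",
        "weights.interpolated": "weight_interpolated",
        "prior.lambda": "prior_lambda",
    }

    def validate(self) -> "InferenceConfig":
        if not self.allowed_error > 0:
            raise ConfigError("allowedError must be > 0")
        if self.max_order < 1:
            raise ConfigError("maxOrder must be >= 1")
        if self.max_connections < 0:
            raise ConfigError("maxConnections must be >= 0")
        if self.k_per_interval < 0:
            raise ConfigError("interpolation.k_per_interval must be >= 0")
        if self.weight_measured < self.weight_interpolated:
            raise ConfigError("measured weight must be >= interpolated weight")
        if min(self.weight_measured, self.weight_interpolated) < 0:
            raise ConfigError("weights must be non-negative")
        if not (0 <= self.growing_threshold < 1):
            raise ConfigError("growing_threshold must lie in [0, 1)")
        if self.pruning_threshold < 0:
            raise ConfigError("pruning_threshold must be >= 0")
        if self.diag_upper >= 0:
            raise ConfigError("diag_upper must be strictly negative")
        if self.coeff_bound <= 0:
            raise ConfigError("coeff_bound must be positive")
        if self.prior_lambda < 0:
            raise ConfigError("prior.lambda must be >= 0")
        if not isinstance(self.seed, int):
            raise ConfigError("seed must be an integer")
        return self

    # ------------------------------------------------------------------ I/O
    def to_text(self) -> str:
        """Serialise as flat ``key: value`` lines (dotted names where defined)."""
        inv = {v: k for k, v in self._ALIASES.items()}
        lines = []
        for f in dataclasses.fields(self):
            key = inv.get(f.name, f.name)
            lines.append(f"{key}: {getattr(self, f.name)}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "InferenceConfig":
        values: dict = {}
        fields = {f.name: f for f in dataclasses.fields(cls)}
        for lineno, raw in enumerate(text.splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if ":" not in line:
                raise ConfigError(f"line {lineno}: expected 'key: value', got {raw!r}")
            key, _, val = line.partition(":")
            key = cls._ALIASES.get(key.strip(), key.strip())
            if key not in fields:
                raise ConfigError(f"line {lineno}: unknown setting {key!r}")
            values[key] = _coerce(val.strip(), fields[key].type, key)
        return cls(**values).validate()

    @classmethod
    def from_file(cls, path) -> "InferenceConfig":
        return cls.from_text(Path(path).read_text())

    def replace(self, **kwargs) -> "InferenceConfig":
        return dataclasses.replace(self, **kwargs)


def _coerce(value: str, typ, key: str):
    typ = {"int": int, "float": float, "bool": bool, "str": str}.get(str(typ), typ)
    if typ is bool:
        low = value.lower()
        if low in ("true", "1", "yes", "on"):
            return True
        if low in ("false", "0", "no", "off"):
            return False
        raise ConfigError(f"{key}: cannot parse boolean from {value!r}")
    try:
        return typ(value)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{key}: cannot parse {value!r}") from exc
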