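"""Structured configuration for reproducible simulate/analyze pipelines.

A protocol config is a YAML mapping with four optional sections::

    model:               # ModelParameters overrides, keys as in the dataclass
      g_pfc: 0.4
      mix: 0.1
    sessions:            # ordered list; preset name or explicit rule
      - preset: initial_learning
      - name: my_reversal
        reward_action1: 0.0
        reward_action2: 1.0
        n_trials: 500
        impaired: false
    agents: 100
    seed: 1
    analysis:
      n_reps: 1000
      hazard: 0.004975124378109453
      pseudocount: 1.0

Unspecified keys fall back to the canonical defaults (published parameter
table, standard session battery).  Unknown keys are rejected by name.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Union

import yaml

from .core import ModelParameters
from . import sessions as S

__all__ = ["AnalysisSettings", "ProtocolConfig", "ConfigError",
           "load_config", "save_config"]

_PRESETS = {
    "initial_learning": S.initial_learning,
    "devaluation": S.devaluation,
    "reward_reversal": S.reward_reversal,
    "punished_outcome": S.punished_outcome,
    "reward_reversal_pfc_impaired": S.reward_reversal_impaired,
    "punished_outcome_pfc_impaired": S.punished_outcome_impaired,
}


class ConfigError(ValueError):
    """Raised for unknown keys, malformed files, or out-of-range values."""


@dataclass
class AnalysisSettings:
    n_reps: int = 1000
    hazard: float = 1.0 / 201.0
    pseudocount: float = 1.0

    def validate(self) -> None:
        if self.n_reps < 2:
            raise ConfigError("analysis.n_reps must be at least 2")
        if not 0.0 < self.hazard < 1.0:
            raise ConfigError("analysis.hazard must lie in (0, 1)")
        if self.pseudocount <= 0:
            raise ConfigError("analysis.pseudocount must be positive")


@dataclass
class ProtocolConfig:
    params: ModelParameters = field(default_factory=ModelParameters)
    sessions: List[S.SessionSpec] = field(
        default_factory=S.default_protocol)
    n_agents: int = 100
    root_seed: int = 1
    analysis: AnalysisSettings = field(default_factory=AnalysisSettings)

    def to_dict(self) -> dict:
        return {
            "model": self.params.to_dict(),
            "sessions": [dataclasses.asdict(s) for s in self.sessions],
            "agents": self.n_agents,
            "seed": self.root_seed,
            "analysis": dataclasses.asdict(self.analysis),
        }


def _session_from_entry(entry, idx: int) -> S.SessionSpec:
    if isinstance(entry, str):
        entry = {"preset": entry}
    if not isinstance(entry, dict):
        raise ConfigError(f"sessions[{idx}] must be a mapping or preset name")
    entry = dict(entry)
    preset = entry.pop("preset", None)
    if preset is not None:
        if preset not in _PRESETS:
            raise ConfigError(
                f"sessions[{idx}]: unknown preset {preset!r}; "
                f"choose from {sorted(_PRESETS)}")
        spec = _PRESETS[preset]()
        allowed = {"n_trials", "impaired"}
        bad = set(entry) - allowed
        if bad:
            raise ConfigError(
                f"sessions[{idx}]: unknown key {sorted(bad)[0]!r}")
        if entry:
            spec = dataclasses.replace(spec, **entry)
        return spec
    allowed = {"name", "reward_action1", "reward_action2",
               "n_trials", "impaired"}
    bad = set(entry) - allowed
    if bad:
        raise ConfigError(f"sessions[{idx}]: unknown key {sorted(bad)[0]!r}")
    missing = {"name", "reward_action1", "reward_action2",
               "n_trials"} - set(entry)
    if missing:
        raise ConfigError(
            f"sessions[{idx}]: missing key {sorted(missing)[0]!r}")
    try:
        return S.SessionSpec(**entry)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"sessions[{idx}]: {exc}") from exc


def _config_from_mapping(raw: dict, source: str) -> ProtocolConfig:
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{source}: top level must be a mapping")
    raw = dict(raw)
    known = {"model", "sessions", "agents", "seed", "analysis"}
    bad = set(raw) - known
    if bad:
        raise ConfigError(f"{source}: unknown key {sorted(bad)[0]!r}")

    model_raw = raw.get("model") or {}
    if not isinstance(model_raw, dict):
        raise ConfigError("model section must be a mapping")
    valid_fields = {f.name for f in dataclasses.fields(ModelParameters)}
    bad = set(model_raw) - valid_fields
    if bad:
        raise ConfigError(f"model: unknown key {sorted(bad)[0]!r}")
    try:
        params = ModelParameters(**model_raw)
    except ValueError as exc:
        raise ConfigError(f"model: {exc}") from exc

    sessions_raw = raw.get("sessions")
    if sessions_raw is None:
        specs = S.default_protocol()
    else:
        if not isinstance(sessions_raw, list) or not sessions_raw:
            raise ConfigError("sessions must be a non-empty list")
        specs = [_session_from_entry(e, i) for i, e in enumerate(sessions_raw)]

    analysis_raw = raw.get("analysis") or {}
    bad = set(analysis_raw) - {f.name for f in
                               dataclasses.fields(AnalysisSettings)}
    if bad:
        raise ConfigError(f"analysis: unknown key {sorted(bad)[0]!r}")
    analysis = AnalysisSettings(**analysis_raw)
    analysis.validate()

    n_agents = int(raw.get("agents", 100))
    if n_agents < 1:
        raise ConfigError("agents must be at least 1")
    root_seed = int(raw.get("seed", 1))
    return ProtocolConfig(params=params, sessions=specs, n_agents=n_agents,
                          root_seed=root_seed, analysis=analysis)


def load_config(path: Union[str, Path]) -> ProtocolConfig:
    """Parse and validate a YAML protocol config; defaults fill the gaps."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: malformed YAML ({exc})") from exc
    return _config_from_mapping(raw, str(path))


def save_config(config: ProtocolConfig, path: Union[str, Path]) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
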