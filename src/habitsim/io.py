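"""Session-log file I/O and deterministic test fixtures.

A session log is written as a CSV (one row per trial, 9 significant digits)
plus a JSON sidecar ``<name>.json`` carrying the session spec, the seed
entropy, the inherited initial weights, and the model parameters — enough
to re-run or extend the session exactly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .core import ModelParameters, PlasticWeights
from .sessions import LOG_COLUMNS, SessionLog, SessionSpec
from .config import ProtocolConfig, AnalysisSettings
from . import sessions as S

__all__ = ["SchemaError", "write_session_log", "read_session_log",
           "make_fixture", "FIXTURE_KINDS"]

_FLOAT_FMT = "%.9g"


class SchemaError(ValueError):
    """A log file does not match the expected column schema."""


def _sidecar_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(csv_path.suffix + ".json")


def write_session_log(log: SessionLog, path: Union[str, Path],
                      params: ModelParameters = None) -> None:
    """Write CSV + JSON sidecar; round-trips through read_session_log."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    log.table[LOG_COLUMNS].to_csv(path, index=False, float_format=_FLOAT_FMT)
    sidecar = {
        "spec": dataclasses.asdict(log.spec),
        "seed_entropy": int(log.seed_entropy),
        "initial_weights": [float(f"{v:.9g}") for v in log.initial_weights],
    }
    if params is not None:
        sidecar["params"] = params.to_dict()
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def read_session_log(path: Union[str, Path]) -> SessionLog:
    """Read a session log written by :func:`write_session_log`."""
    path = Path(path)
    table = pd.read_csv(path)
    missing = [c for c in LOG_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"{path}: missing column {missing[0]!r}")
    side = _sidecar_path(path)
    if not side.exists():
        raise SchemaError(f"{path}: sidecar {side.name} not found")
    meta = json.loads(side.read_text())
    spec = SessionSpec(**meta["spec"])
    if len(table) != spec.n_trials:
        raise SchemaError(
            f"{path}: {len(table)} rows but spec declares {spec.n_trials}")
    return SessionLog(spec=spec, seed_entropy=meta["seed_entropy"],
                      initial_weights=np.asarray(meta["initial_weights"]),
                      table=table)


FIXTURE_KINDS = ("symmetric", "trained-agent-weights", "mini-protocol")


def make_fixture(kind: str, seed: int = 0):
    """Small deterministic inputs for fast tests.

    - ``"symmetric"``: unbiased weights, all equal to w0 = 1.
    - ``"trained-agent-weights"``: a constructed weight set biased toward
      channel 1 in both compartments (pmc_d1[1] > w0 > pmc_d2[1]), with
      small seed-dependent jitter.
    - ``"mini-protocol"``: a 5-agent, 20-trial-session ProtocolConfig with
      50 analysis repeats.
    """
    rs = np.random.RandomState(np.uint32(seed))
    if kind == "symmetric":
        return PlasticWeights.initial()
    if kind == "trained-agent-weights":
        jitter = rs.uniform(0.0, 0.02, 8)
        w = PlasticWeights.initial()
        w.pfc_d1[:] = [1.30 + jitter[0], 0.75 + jitter[1]]
        w.pfc_d2[:] = [0.75 + jitter[2], 1.25 + jitter[3]]
        w.pmc_d1[:] = [1.40 + jitter[4], 1.00 + jitter[5]]
        w.pmc_d2[:] = [0.70 + jitter[6], 1.00 + jitter[7]]
        return w
    if kind == "mini-protocol":
        specs = [dataclasses.replace(s, n_trials=20)
                 for s in S.default_protocol()]
        return ProtocolConfig(
            params=ModelParameters(), sessions=specs, n_agents=5,
            root_seed=int(rs.randint(0, 2**31 - 1)),
            analysis=AnalysisSettings(n_reps=50))
    raise ValueError(f"unknown fixture kind {kind!r}; "
                     f"choose from {FIXTURE_KINDS}")
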