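"""Plain-text serialization of traces, protocols and fit results.

A trace is stored as a two-column CSV ``(time_s, current_uA)`` next to a
JSON sidecar carrying the seed, sample rate, protocol, ligand and cascade
parameters, so any stored trace can be re-analyzed or regenerated.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .params import CascadeParams, LigandKinetics
from .protocol import PerfusionProtocol, ProtocolStep
from .simulate import SimulatedTrace


def protocol_to_dict(protocol: PerfusionProtocol) -> dict:
    return {
        "steps": [dataclasses.asdict(s) for s in protocol.steps],
        "antagonist_steps": [dataclasses.asdict(s)
                             for s in protocol.antagonist_steps],
        "total_duration": protocol.total_duration,
    }


def protocol_from_dict(data: dict) -> PerfusionProtocol:
    return PerfusionProtocol(
        steps=tuple(ProtocolStep(**s) for s in data["steps"]),
        antagonist_steps=tuple(ProtocolStep(**s)
                               for s in data.get("antagonist_steps", [])),
        total_duration=float(data["total_duration"]))


def write_trace(trace: SimulatedTrace, path: str | Path) -> tuple[Path, Path]:
    """Write ``<path>.csv`` (time_s, current_uA) and ``<path>.json`` sidecar."""
    base = Path(path)
    csv_path = base.with_suffix(".csv")
    json_path = base.with_suffix(".json")
    pd.DataFrame({"time_s": trace.time, "current_uA": trace.current}
                 ).to_csv(csv_path, index=False, float_format="%.9g")
    sidecar = {
        "seed": trace.seed,
        "sample_rate": trace.params.sample_rate,
        "params": dataclasses.asdict(trace.params),
        "protocol": protocol_to_dict(trace.protocol),
        "ligand": dataclasses.asdict(trace.ligand) if trace.ligand else None,
        "antagonist": (dataclasses.asdict(trace.antagonist)
                       if trace.antagonist else None),
    }
    json_path.write_text(json.dumps(sidecar, indent=1, sort_keys=True) + "\n")
    return csv_path, json_path


def read_trace(path: str | Path) -> SimulatedTrace:
    """Read a trace written by :func:`write_trace`."""
    base = Path(path)
    frame = pd.read_csv(base.with_suffix(".csv"))
    sidecar = json.loads(base.with_suffix(".json").read_text())
    ligand = (LigandKinetics(**sidecar["ligand"])
              if sidecar.get("ligand") else None)
    antagonist = (LigandKinetics(**sidecar["antagonist"])
                  if sidecar.get("antagonist") else None)
    return SimulatedTrace(
        time=frame["time_s"].to_numpy(),
        current=frame["current_uA"].to_numpy(),
        seed=sidecar.get("seed"),
        protocol=protocol_from_dict(sidecar["protocol"]),
        params=CascadeParams(**sidecar["params"]),
        ligand=ligand, antagonist=antagonist)


def load_yaml(path: str | Path) -> dict:
    with open(path) as handle:
        return yaml.safe_load(handle)


def dump_json(data, path: str | Path) -> Path:
    """Write deterministic, sorted-key JSON (round-trips numpy scalars)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_plain(data), indent=1, sort_keys=True) + "\n")
    return path


def _plain(obj):
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return [_plain(v) for v in obj.tolist()]
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _plain(dataclasses.asdict(obj))
    return obj
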