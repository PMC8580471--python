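"""Configuration, trajectory and table serialization."""

from __future__ import annotations

import dataclasses
import json
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .network import FibreNetwork
from .params import ModelParameters


def load_config(path) -> ModelParameters:
    """Load a YAML/JSON key-value config in bench units (see
    ModelParameters.from_config for the key list)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} did not parse to a mapping")
    return ModelParameters.from_config(cfg)


def write_xyz(path, network: FibreNetwork, comment: str = "") -> None:
    """Extended XYZ frame in nanometres; the atom label is the fibre id."""
    p = network.positions * 1e9
    box = network.box_lengths * 1e9
    with open(path, "w") as fh:
        fh.write(f"{network.n_nodes}\n")
        fh.write(f"box_nm={box[0]:.6g},{box[1]:.6g},{box[2]:.6g} "
                 f"time_s={network.time:.9g} "
                 f"nodes_per_fibre={network.nodes_per_fibre} {comment}\n")
        for f in range(network.n_fibres):
            for m in range(network.nodes_per_fibre):
                x, y, z = p[f, m]
                fh.write(f"F{f} {x:.6f} {y:.6f} {z:.6f}\n")


def read_xyz(path) -> FibreNetwork:
    with open(path) as fh:
        n = int(fh.readline())
        header = fh.readline().split()
        meta = dict(kv.split("=", 1) for kv in header if "=" in kv)
        box = np.array([float(v) for v in meta["box_nm"].split(",")]) * 1e-9
        npf = int(meta.get("nodes_per_fibre", 22))
        rows = [fh.readline().split()[1:4] for _ in range(n)]
    pos = np.array(rows, dtype=float).reshape(-1, npf, 3) * 1e-9
    return FibreNetwork(positions=pos, box_lengths=box,
                        time=float(meta.get("time_s", 0.0)))


@dataclass
class RunManifest:
    """Traceability record: every output file maps to a config + seed."""

    config: dict
    seeds: list
    outputs: dict = field(default_factory=dict)
    code_version: str = "fibrinbd-0.1.0"
    wall_time_s: float = 0.0
    created: str = field(default_factory=lambda: _time.strftime("%Y-%m-%dT%H:%M:%S"))

    def dump(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def load(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def params_to_config(params: ModelParameters) -> dict:
    """Bench-unit config dict round-trippable through from_config."""
    return {
        "a_nm": params.a * 1e9,
        "r0S_nm": params.r0_S * 1e9,
        "kS": params.k_S, "kB": params.k_B, "kT": params.k_T,
        "kA": params.k_A, "kR": params.k_R,
        "mu_mPa_s": params.mu * 1e3,
        "T": params.temperature,
        "dt_ns": params.dt * 1e9,
        "seed": params.seed,
        "n_fibres": params.n_fibres,
        "nodes_per_fibre": params.nodes_per_fibre,
        "box_nm": [L * 1e9 for L in params.box],
        "concentration_mg_ml": params.concentration,
        "aggregation_mode": params.aggregation_mode,
    }


def save_config(path, params: ModelParameters) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params_to_config(params), fh, sort_keys=False)
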