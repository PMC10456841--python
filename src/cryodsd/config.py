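"""YAML run configuration: circuit description, protocol block, rate model.

Schema (all keys optional unless noted)::

    circuit:                  # required for circuit runs
      inputs: [x1, x2]
      gates:
        - id: g1
          inputs: [x1, x2]    # external inputs or upstream gate ids
          threshold_nM: 40    # 0 -> OR, >0 -> AND
          layer: 1
      reporters: [g1]
      default_conc_nM: 50
    protocol:
      anion: SO4              # SO4 | Ac | Cl | NO3
      n_cycles: 8
      t_freeze_s: 60
      T_freeze_C: -196
      t_thaw_s: 300
      T_thaw_C: 37
      eutectic_window_s: 60
      dose: 1.0               # optional per-cycle dose override
    rate_model:
      k_ref: 5.3e3            # /M/s at 4-nt toehold
      fold_per_nt: 10
      saturation_len: 6
    buffer:                   # provenance only, not used by the kinetics
      mg_mM: 12.5
      conc_nM: 50
      pH: 8.0
    seed: 1

Units are explicit in key suffixes: concentrations nM, durations seconds,
temperatures Celsius.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import yaml

from .circuit import CircuitSpec, GateSpec
from .freezethaw import DEFAULT_ANIONS, AnionParams, CycleSchedule
from .kinetics import RateModel

__all__ = ["RunConfig", "load_config", "circuit_from_dict", "circuit_to_dict"]


def circuit_from_dict(d: dict) -> CircuitSpec:
    gates = [
        GateSpec(
            g["id"],
            tuple(g["inputs"]),
            float(g.get("threshold_nM", 0.0)),
            int(g.get("layer", 1)),
        )
        for g in d.get("gates", [])
    ]
    return CircuitSpec(
        gates,
        list(d.get("inputs", [])),
        list(d.get("reporters", [])),
        float(d.get("default_conc_nM", 50.0)),
    )


def circuit_to_dict(spec: CircuitSpec) -> dict:
    return {
        "inputs": list(spec.external_inputs),
        "gates": [
            {
                "id": g.gate_id,
                "inputs": list(g.input_refs),
                "threshold_nM": g.threshold_conc,
                "layer": g.layer_index,
            }
            for g in spec.gates
        ],
        "reporters": list(spec.reporter_outputs),
        "default_conc_nM": spec.default_conc,
    }


@dataclass
class RunConfig:
    """Parsed run configuration with resolved domain objects."""

    circuit: CircuitSpec | None = None
    schedule: CycleSchedule = field(default_factory=CycleSchedule)
    anion: AnionParams = field(default_factory=lambda: DEFAULT_ANIONS["SO4"])
    n_cycles: int = 8
    rate_model: RateModel = field(default_factory=RateModel)
    buffer: dict = field(default_factory=lambda: {"mg_mM": 12.5, "conc_nM": 50.0,
                                                  "pH": 8.0})
    seed: int = 0


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}

    cfg = RunConfig()
    if "circuit" in raw:
        cfg.circuit = circuit_from_dict(raw["circuit"])

    proto = raw.get("protocol", {})
    cfg.schedule = CycleSchedule(
        t_freeze=float(proto.get("t_freeze_s", 60.0)),
        T_freeze=float(proto.get("T_freeze_C", -196.0)),
        t_thaw=float(proto.get("t_thaw_s", 300.0)),
        T_thaw=float(proto.get("T_thaw_C", 37.0)),
        eutectic_window=proto.get("eutectic_window_s"),
    )
    cfg.n_cycles = int(proto.get("n_cycles", 8))
    anion_name = proto.get("anion", "SO4")
    if anion_name not in DEFAULT_ANIONS:
        raise ValueError(
            f"unknown anion {anion_name!r}; known: {sorted(DEFAULT_ANIONS)}"
        )
    anion = DEFAULT_ANIONS[anion_name]
    if "dose" in proto:
        anion = replace(anion, dose=float(proto["dose"]))
    cfg.anion = anion

    rm = raw.get("rate_model", {})
    cfg.rate_model = RateModel(
        k_ref=float(rm.get("k_ref", 5.3e3)),
        fold_per_nt=float(rm.get("fold_per_nt", 10.0)),
        saturation_len=int(rm.get("saturation_len", 6)),
    )
    if "buffer" in raw:
        cfg.buffer = dict(raw["buffer"])
    cfg.seed = int(raw.get("seed", 0))
    return cfg
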