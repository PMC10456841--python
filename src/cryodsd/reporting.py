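"""Output normalization, ON/OFF classification, and comparison statistics.

Fluorescence readouts are normalized to relative output concentration
(baseline -> 0, plateau maximum -> 1) and classified ON at or above 0.4.
Fold speedups are the ratio of the printed isothermal completion time of a
reference system to the freeze-thaw protocol duration; the printed
completion times enter as configuration constants, not fitted quantities.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .circuit import CircuitSpec, compile_circuit
from .freezethaw import CycleSchedule, protocol_duration
from .kinetics import RateModel, build_crn, simulate_circuit

__all__ = [
    "CalibrationTable",
    "OutputCall",
    "ON_THRESHOLD",
    "normalize",
    "plateau_max",
    "classify",
    "average_rate",
    "speedup",
    "boolean_oracle",
    "truth_table_report",
    "evaluate_truth_table",
]

#: normalized-output classification threshold (ON at or above)
ON_THRESHOLD = 0.4


@dataclass(frozen=True)
class CalibrationTable:
    """Printed isothermal (25 C) completion times per reference system, hours."""

    hours: dict[str, float] = field(
        default_factory=lambda: {
            "basic_4nt": 20.0,
            "or_gate": 4.0,
            "and_gate": 16.0,
            "and_or": 10.0,
            "or_and_or": 12.0,
            "network8": 36.0,
        }
    )

    def __post_init__(self) -> None:
        for k, v in self.hours.items():
            if v <= 0:
                raise ValueError(f"calibration entry {k!r} must be > 0 h")

    def __getitem__(self, system: str) -> float:
        try:
            return self.hours[system]
        except KeyError:
            raise KeyError(
                f"unknown system {system!r}; known: {sorted(self.hours)}"
            ) from None


@dataclass(frozen=True)
class OutputCall:
    """One classified circuit output."""

    signal: str
    value: float
    state: str
    threshold: float = ON_THRESHOLD


def normalize(raw, baseline: float, max_level: float) -> np.ndarray:
    """Affine map of raw fluorescence to relative output concentration."""
    if max_level <= baseline:
        raise ValueError("max_level must exceed baseline")
    return (np.asarray(raw, dtype=float) - baseline) / (max_level - baseline)


def plateau_max(series, n: int = 5) -> float:
    """Maximum level from the mean of the last n plateau points."""
    arr = np.asarray(series, dtype=float)
    if arr.size < n:
        raise ValueError(f"need at least {n} points for a plateau estimate")
    return float(arr[-n:].mean())


def classify(value: float, threshold: float = ON_THRESHOLD) -> str:
    """ON at or above the threshold (a value exactly at threshold is ON)."""
    if not np.isfinite(value):
        raise ValueError("value must be finite")
    return "ON" if value >= threshold else "OFF"


def average_rate(
    output_fraction: float,
    n_cycles: int | None = None,
    elapsed_h: float | None = None,
) -> float:
    """Output fraction per cycle (cycling mode) or per hour (isothermal mode)."""
    if (n_cycles is None) == (elapsed_h is None):
        raise ValueError("give exactly one of n_cycles or elapsed_h")
    denom = n_cycles if n_cycles is not None else elapsed_h
    if denom is None or denom <= 0:
        raise ValueError("denominator must be > 0")
    return output_fraction / denom


def speedup(
    system: str,
    n_cycles: int,
    schedule: CycleSchedule | None = None,
    table: CalibrationTable | None = None,
    rounded: bool = True,
) -> float:
    """Fold speedup of n freeze-thaw cycles over isothermal operation.

    Ratio of the system's printed 25 C completion time to the protocol
    duration, rounded to the nearest integer for reporting.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    table = table or CalibrationTable()
    hours = table[system]
    protocol_h = protocol_duration(n_cycles, schedule) / 3600.0
    fold = hours / protocol_h
    return float(round(fold)) if rounded else fold


def boolean_oracle(spec: CircuitSpec, inputs: dict[str, int]) -> dict[str, int]:
    """Evaluate the circuit's Boolean semantics by topological propagation.

    Zero-threshold gates compute OR, positive-threshold gates AND.  Returns
    the truth value of every reporter output.
    """
    values = {name: int(bool(inputs.get(name, 0))) for name in spec.external_inputs}
    remaining = list(spec.gates)
    while remaining:
        progressed = False
        for gate in list(remaining):
            a, b = gate.input_refs
            if a in values and b in values:
                if gate.threshold_conc == 0:
                    values[gate.gate_id] = values[a] | values[b]
                else:
                    values[gate.gate_id] = values[a] & values[b]
                remaining.remove(gate)
                progressed = True
        if not progressed:
            raise ValueError("circuit wiring is not acyclic/resolvable")
    return {out: values[out] for out in spec.reporter_outputs}


def truth_table_report(
    spec: CircuitSpec,
    results: dict[tuple[int, ...], dict[str, float]],
    threshold: float = ON_THRESHOLD,
) -> pd.DataFrame:
    """Normalize simulated endpoints per output and classify each combination.

    ``results`` maps every binary input combination (ordered as
    ``spec.external_inputs``) to the raw final readout of each reporter
    output.  Outputs are normalized together across combinations (baseline =
    minimum, maximum level = maximum), as parallel experiments of one circuit
    are.  Raises if any combination is missing.
    """
    names = spec.external_inputs
    combos = list(itertools.product((0, 1), repeat=len(names)))
    missing = [c for c in combos if tuple(c) not in results]
    if missing:
        raise ValueError(f"missing input combinations: {missing}")

    rows = []
    for out in spec.reporter_outputs:
        raw = np.array([results[c][out] for c in combos])
        lo, hi = raw.min(), raw.max()
        norm = normalize(raw, lo, hi) if hi > lo + 1e-12 else np.zeros_like(raw)
        for combo, r, v in zip(combos, raw, norm):
            expected = boolean_oracle(spec, dict(zip(names, combo)))[out]
            rows.append(
                {
                    **{f"in_{n}": x for n, x in zip(names, combo)},
                    "output": out,
                    "raw_nM": r,
                    "value": v,
                    "state": classify(v, threshold),
                    "expected": "ON" if expected else "OFF",
                }
            )
    df = pd.DataFrame(rows)
    df["correct"] = df["state"] == df["expected"]
    return df


def evaluate_truth_table(
    spec: CircuitSpec,
    t_end_s: float,
    model: RateModel | None = None,
    threshold: float = ON_THRESHOLD,
    report_duration: float = 1800.0,
) -> pd.DataFrame:
    """Simulate every input combination to ``t_end_s`` and report the calls.

    Inputs are present at the circuit's operating concentration when 1 and
    absent when 0; reporters are added after operation (endpoint reporting).
    """
    compiled = compile_circuit(spec)
    crn = build_crn(compiled, model)
    names = spec.external_inputs
    results: dict[tuple[int, ...], dict[str, float]] = {}
    for combo in itertools.product((0, 1), repeat=len(names)):
        conc = {n: spec.default_conc * bit for n, bit in zip(names, combo)}
        _trace, finals = simulate_circuit(
            crn, t_end_s, conc, reporter_timing="after",
            report_duration=report_duration,
        )
        results[combo] = finals
    return truth_table_report(spec, results, threshold)
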