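"""Compile declarative threshold-logic circuit descriptions into molecule inventories.

A gate in this architecture is a two-input threshold unit built from six
prepared DNA complexes: two weight complexes ``W1``/``W2`` that hold the
signal-conversion capacity for each input, two switch strands ``Sw1``/``Sw2``
that activate the weights by hybridization, one transmit complex ``Sd`` that
sums the intermediate species released by both inputs, and one threshold
complex ``Th`` that absorbs transmitted signal with a fast (long-toehold)
reaction.  The logic function is selected purely by the threshold
concentration: 0 nM gives OR (any input's signal survives), a concentration
between one and two input-equivalents (40 nM at the 50 nM operating
concentration) gives AND.

Terminal outputs additionally receive one fluorophore/quencher reporter
complex, so a single gate with one reporter is seven molecules excluding
inputs, a two-gate cascade thirteen, a three-gate cascade nineteen.

The compiler is purely structural: it emits the species inventory and wiring
and knows nothing about rate constants (see :mod:`cryodsd.kinetics`).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "CircuitError",
    "GateSpec",
    "CircuitSpec",
    "Species",
    "CompiledCircuit",
    "logic_mode",
    "compile_gate",
    "compile_circuit",
    "build_network",
    "species_table",
    "read_species_table",
]

#: default operating concentration for prepared complexes, nM
DEFAULT_CONC_NM = 50.0
#: toehold length used by gate-level displacement/transmit reactions, nt
GATE_TOEHOLD_NT = 5
#: toehold length of switch, threshold and reporter complexes, nt
LONG_TOEHOLD_NT = 8

ROLES = (
    "weight",
    "switch",
    "transmit",
    "threshold",
    "reporter",
    "input",
    "intermediate",
    "output",
)


class CircuitError(ValueError):
    """Structural problem in a circuit description (wiring, counts, signs)."""


@dataclass(frozen=True)
class GateSpec:
    """One two-input threshold gate.

    ``input_refs`` name either external inputs or upstream gate ids; the
    gate's own ``gate_id`` doubles as the name of its output signal.
    ``threshold_conc`` (nM) selects the logic mode: 0 = OR, >0 = AND.
    """

    gate_id: str
    input_refs: tuple[str, str]
    threshold_conc: float = 0.0
    layer_index: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "input_refs", tuple(self.input_refs))


def _check_gate(gate: GateSpec) -> None:
    if len(gate.input_refs) != 2:
        raise CircuitError(
            f"gate {gate.gate_id!r} must have exactly 2 input_refs, "
            f"got {len(gate.input_refs)}"
        )
    if gate.threshold_conc < 0:
        raise CircuitError(
            f"gate {gate.gate_id!r}: threshold_conc must be >= 0 nM, "
            f"got {gate.threshold_conc}"
        )
    if gate.layer_index < 1:
        raise CircuitError(f"gate {gate.gate_id!r}: layer_index must be >= 1")


def logic_mode(gate: GateSpec) -> str:
    """Return ``"OR"`` or ``"AND"`` according to the threshold concentration.

    A zero-concentration threshold complex absorbs nothing, so any single
    input drives the output (OR); a positive threshold absorbs one input's
    worth of signal and only the sum of both inputs exceeds it (AND).
    """
    _check_gate(gate)
    return "OR" if gate.threshold_conc == 0 else "AND"


@dataclass(frozen=True)
class Species:
    """One prepared complex or strand in the molecule inventory."""

    name: str
    role: str
    toehold_len: int
    initial_conc: float  # nM
    is_input: bool = False

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise CircuitError(f"unknown species role {self.role!r}")
        if self.initial_conc < 0:
            raise CircuitError(f"{self.name}: initial_conc must be >= 0 nM")
        if not 0 <= self.toehold_len <= 8:
            raise CircuitError(f"{self.name}: toehold_len must be in [0, 8] nt")


@dataclass
class CircuitSpec:
    """Declarative description of a circuit: gates, inputs, reporters."""

    gates: list[GateSpec]
    external_inputs: list[str]
    reporter_outputs: list[str]
    default_conc: float = DEFAULT_CONC_NM


@dataclass
class CompiledCircuit:
    """Molecule inventory produced by :func:`compile_circuit`.

    ``molecule_count`` counts prepared (non-input) molecules only and always
    equals ``6 * n_gates + n_reporters``.
    """

    species: list[Species]
    gate_membership: dict[str, list[str]]
    molecule_count: int
    spec: CircuitSpec = field(repr=False, default=None)

    def species_by_name(self) -> dict[str, Species]:
        return {s.name: s for s in self.species}


def compile_gate(gate: GateSpec, default_conc: float = DEFAULT_CONC_NM) -> list[Species]:
    """Emit the six prepared species of one gate.

    Two weights and two switches at the operating concentration, one transmit
    complex sized to carry the *sum* of both weights (2x the operating
    concentration), and one threshold complex at the gate's threshold
    concentration.  A threshold species is emitted even at 0 nM so that the
    molecule inventory is uniform across logic modes.
    """
    _check_gate(gate)
    g = gate.gate_id
    return [
        Species(f"{g}.W1", "weight", GATE_TOEHOLD_NT, default_conc),
        Species(f"{g}.W2", "weight", GATE_TOEHOLD_NT, default_conc),
        Species(f"{g}.Sw1", "switch", LONG_TOEHOLD_NT, default_conc),
        Species(f"{g}.Sw2", "switch", LONG_TOEHOLD_NT, default_conc),
        Species(f"{g}.Sd", "transmit", GATE_TOEHOLD_NT, 2 * default_conc),
        Species(f"{g}.Th", "threshold", LONG_TOEHOLD_NT, gate.threshold_conc),
    ]


def wiring_graph(spec: CircuitSpec) -> "nx.DiGraph":
    """Signal-flow graph: external inputs and gates as nodes, refs as edges."""
    g = nx.DiGraph()
    g.add_nodes_from(spec.external_inputs, kind="input")
    for gate in spec.gates:
        g.add_node(gate.gate_id, kind="gate")
    for gate in spec.gates:
        for ref in gate.input_refs:
            g.add_edge(ref, gate.gate_id)
    return g


def compile_circuit(spec: CircuitSpec) -> CompiledCircuit:
    """Compile a :class:`CircuitSpec` into its full molecule inventory.

    Raises :class:`CircuitError` on cyclic wiring, dangling signal references,
    duplicate gate ids, reporters attached to non-terminal or non-gate
    signals, or malformed gates.
    """
    gate_ids = [g.gate_id for g in spec.gates]
    if len(set(gate_ids)) != len(gate_ids):
        raise CircuitError("duplicate gate ids")
    if set(gate_ids) & set(spec.external_inputs):
        raise CircuitError("gate ids must not collide with external input names")
    known = set(gate_ids) | set(spec.external_inputs)
    for gate in spec.gates:
        _check_gate(gate)
        for ref in gate.input_refs:
            if ref not in known:
                raise CircuitError(
                    f"gate {gate.gate_id!r}: dangling signal reference {ref!r}"
                )

    graph = wiring_graph(spec)
    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        raise CircuitError(f"cyclic wiring: {cycle}")

    internal = {ref for g in spec.gates for ref in g.input_refs}
    for out in spec.reporter_outputs:
        if out not in gate_ids:
            raise CircuitError(f"reporter output {out!r} is not produced by a gate")
        if out in internal:
            raise CircuitError(f"reporter output {out!r} also feeds a downstream gate")
    if len(set(spec.reporter_outputs)) != len(spec.reporter_outputs):
        raise CircuitError("duplicate reporter outputs")

    species: list[Species] = []
    membership: dict[str, list[str]] = {}
    for name in spec.external_inputs:
        species.append(Species(name, "input", GATE_TOEHOLD_NT, 0.0, is_input=True))
    for gate in spec.gates:
        gate_species = compile_gate(gate, spec.default_conc)
        membership[gate.gate_id] = [s.name for s in gate_species]
        species.extend(gate_species)
    for out in spec.reporter_outputs:
        species.append(Species(f"R_{out}", "reporter", LONG_TOEHOLD_NT, spec.default_conc))
        membership[out].append(f"R_{out}")

    count = sum(1 for s in species if not s.is_input)
    assert count == 6 * len(spec.gates) + len(spec.reporter_outputs)
    return CompiledCircuit(species, membership, count, spec)


def build_network(
    weights,
    patterns,
    thresholds=None,
    default_conc: float = DEFAULT_CONC_NM,
) -> CircuitSpec:
    """Compile a weighted-sum + threshold classifier network into a CircuitSpec.

    Parameters
    ----------
    weights
        Non-negative integer matrix, shape ``(n_pixels, n_outputs)``.  A weight
        of *w* is realized as *w* copies of the pixel's signal feeding the
        output's adder tree (copy counts of weight complexes).
    patterns
        Iterable of binary grids; pixels map to presence/absence of input
        species.  Used to fix the pixel count and validate binariness.
    thresholds
        Integer decision threshold per output, in units of active weighted
        inputs.  Defaults to each output's total weight (exact template
        match).  The root gate of each adder tree carries the threshold as a
        concentration, ``(t - 0.5) * default_conc``, so the Boolean decision
        boundary falls between t-1 and t matched inputs.

    Each output ``y_k`` is the terminal reporter signal of a binary tree of
    two-input zero-threshold (adder) gates over the weighted pixel signals.
    """
    w = np.asarray(weights)
    if w.size == 0:
        raise CircuitError("weights must be non-empty")
    if w.ndim != 2:
        raise CircuitError("weights must be a 2-D matrix (pixels x outputs)")
    if not np.issubdtype(w.dtype, np.integer):
        if not np.all(w == np.floor(w)):
            raise CircuitError("weights must be integers")
        w = w.astype(int)
    if (w < 0).any():
        raise CircuitError("weights must be non-negative")

    pats = [np.asarray(p) for p in patterns]
    for p in pats:
        if not np.isin(p, (0, 1)).all():
            raise CircuitError("patterns must be binary (0/1) grids")
        if p.size != w.shape[0]:
            raise CircuitError(
                f"pattern size {p.size} does not match weight rows {w.shape[0]}"
            )

    n_pixels, n_outputs = w.shape
    pixel_ids = [f"px{i}" for i in range(n_pixels)]
    if thresholds is None:
        thresholds = w.sum(axis=0)
    thresholds = np.asarray(thresholds, dtype=float)

    gates: list[GateSpec] = []
    reporters: list[str] = []
    need_bias = False
    for k in range(n_outputs):
        leaves: list[str] = []
        for i in range(n_pixels):
            leaves.extend([pixel_ids[i]] * int(w[i, k]))
        if not leaves:
            raise CircuitError(f"output {k} has no positive weights")
        root_id = f"y{k + 1}"
        th_conc = max(0.0, (thresholds[k] - 0.5) * default_conc)
        if len(leaves) == 1:
            need_bias = True
            leaves.append("bias0")
        layer, stage = 1, 0
        nodes = leaves
        while len(nodes) > 1:
            nxt: list[str] = []
            for j in range(0, len(nodes) - 1, 2):
                is_root = len(nodes) == 2
                gid = root_id if is_root else f"{root_id}_s{stage}"
                stage += 1
                gates.append(
                    GateSpec(
                        gid,
                        (nodes[j], nodes[j + 1]),
                        th_conc if is_root else 0.0,
                        layer,
                    )
                )
                nxt.append(gid)
            if len(nodes) % 2:
                nxt.append(nodes[-1])
            nodes = nxt
            layer += 1
        reporters.append(root_id)

    inputs = pixel_ids + (["bias0"] if need_bias else [])
    return CircuitSpec(gates, inputs, reporters, default_conc)


def species_table(compiled: CompiledCircuit) -> pd.DataFrame:
    """Compiled inventory as a table (name, role, toehold_len, conc_nM, is_input)."""
    return pd.DataFrame(
        {
            "name": [s.name for s in compiled.species],
            "role": [s.role for s in compiled.species],
            "toehold_len": [s.toehold_len for s in compiled.species],
            "conc_nM": [s.initial_conc for s in compiled.species],
            "is_input": [int(s.is_input) for s in compiled.species],
        }
    )


def read_species_table(path_or_buf) -> list[Species]:
    """Re-import a species table written by :func:`species_table` (TSV)."""
    if isinstance(path_or_buf, str) and "\t" in path_or_buf:
        path_or_buf = io.StringIO(path_or_buf)
    df = pd.read_csv(path_or_buf, sep="\t")
    return [
        Species(r["name"], r["role"], int(r["toehold_len"]), float(r["conc_nM"]),
                bool(r["is_input"]))
        for _, r in df.iterrows()
    ]
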