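"""Structural tests for the circuit compiler."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cryodsd import (
    CircuitError,
    CircuitSpec,
    GateSpec,
    Species,
    build_network,
    compile_circuit,
    compile_gate,
    fixture_circuit,
    logic_mode,
    species_table,
    read_species_table,
)


class TestGateCompilation:
    def test_gate_emits_six_species_with_expected_roles(self):
        species = compile_gate(GateSpec("g", ("a", "b"), 40.0))
        assert len(species) == 6
        roles = sorted(s.role for s in species)
        assert roles == ["switch", "switch", "threshold", "transmit",
                         "weight", "weight"]

    @pytest.mark.parametrize("th,mode", [(0.0, "OR"), (40.0, "AND"), (1e-6, "AND")])
    def test_logic_mode_from_threshold_concentration(self, th, mode):
        assert logic_mode(GateSpec("g", ("a", "b"), th)) == mode

    def test_or_gate_threshold_species_emitted_at_zero(self):
        species = compile_gate(GateSpec("g", ("a", "b"), 0.0))
        th = [s for s in species if s.role == "threshold"]
        assert len(th) == 1 and th[0].initial_conc == 0.0

    def test_and_gate_threshold_species_carries_threshold(self):
        species = compile_gate(GateSpec("g", ("a", "b"), 40.0))
        th = [s for s in species if s.role == "threshold"]
        assert th[0].initial_conc == 40.0

    def test_transmit_capacity_covers_sum_of_weights(self):
        species = {s.name: s for s in compile_gate(GateSpec("g", ("a", "b")), 50.0)}
        weights = sum(s.initial_conc for s in species.values() if s.role == "weight")
        assert species["g.Sd"].initial_conc == weights

    def test_one_input_gate_rejected(self):
        with pytest.raises(CircuitError, match="exactly 2"):
            compile_gate(GateSpec("g", ("a",)))

    def test_negative_threshold_rejected(self):
        with pytest.raises(CircuitError, match="threshold"):
            logic_mode(GateSpec("g", ("a", "b"), -1.0))


class TestCircuitCompilation:
    @pytest.mark.parametrize(
        "name,count",
        [("or", 7), ("and", 7), ("and_or", 13), ("or_and_or", 19)],
    )
    def test_benchmark_molecule_counts(self, name, count):
        """Single gate = 7 molecules (with reporter), 2-gate cascade = 13,
        3-gate cascade = 19, inputs excluded."""
        assert compile_circuit(fixture_circuit(name)).molecule_count == count

    def test_inputs_excluded_from_molecule_count(self):
        compiled = compile_circuit(fixture_circuit("or"))
        assert sum(s.is_input for s in compiled.species) == 2
        assert len(compiled.species) == compiled.molecule_count + 2

    def test_compilation_is_deterministic(self):
        a = compile_circuit(fixture_circuit("or_and_or"))
        b = compile_circuit(fixture_circuit("or_and_or"))
        assert a.species == b.species
        assert a.gate_membership == b.gate_membership

    def test_cyclic_wiring_rejected(self):
        spec = CircuitSpec(
            [GateSpec("g1", ("g2", "x1")), GateSpec("g2", ("g1", "x1"))],
            ["x1"], [],
        )
        with pytest.raises(CircuitError, match="cyclic"):
            compile_circuit(spec)

    def test_dangling_signal_rejected(self):
        spec = CircuitSpec([GateSpec("g1", ("x1", "nope"))], ["x1"], ["g1"])
        with pytest.raises(CircuitError, match="dangling"):
            compile_circuit(spec)

    def test_reporter_on_internal_signal_rejected(self):
        spec = CircuitSpec(
            [GateSpec("g1", ("x1", "x2")), GateSpec("g2", ("g1", "x2"))],
            ["x1", "x2"], ["g1", "g2"],
        )
        with pytest.raises(CircuitError, match="feeds a downstream gate"):
            compile_circuit(spec)

    def test_reporter_must_be_gate_output(self):
        spec = CircuitSpec([GateSpec("g1", ("x1", "x2"))], ["x1", "x2"], ["x1"])
        with pytest.raises(CircuitError, match="not produced by a gate"):
            compile_circuit(spec)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.data())
    def test_molecule_count_formula_on_random_dags(self, data):
        """molecule_count == 6 * n_gates + n_reporters for arbitrary DAGs."""
        n_gates = data.draw(st.integers(1, 5))
        n_inputs = data.draw(st.integers(2, 4))
        inputs = [f"x{i}" for i in range(n_inputs)]
        gates = []
        for i in range(n_gates):
            pool = inputs + [g.gate_id for g in gates]
            refs = (data.draw(st.sampled_from(pool)), data.draw(st.sampled_from(pool)))
            th = data.draw(st.sampled_from([0.0, 40.0]))
            gates.append(GateSpec(f"g{i}", refs, th, 1))
        used = {r for g in gates for r in g.input_refs}
        reporters = [g.gate_id for g in gates if g.gate_id not in used]
        compiled = compile_circuit(CircuitSpec(gates, inputs, reporters))
        assert compiled.molecule_count == 6 * n_gates + len(reporters)


class TestSpeciesInvariants:
    def test_negative_concentration_rejected(self):
        with pytest.raises(CircuitError):
            Species("s", "weight", 5, -1.0)

    def test_toehold_out_of_range_rejected(self):
        with pytest.raises(CircuitError):
            Species("s", "weight", 9, 1.0)

    def test_unknown_role_rejected(self):
        with pytest.raises(CircuitError, match="role"):
            Species("s", "glue", 5, 1.0)


class TestNetworkBuilder:
    def test_toy_two_class_network(self):
        w = np.array([[1, 0], [1, 0], [0, 1], [0, 1]])
        spec = build_network(w, [np.array([[1, 1], [0, 0]])])
        assert spec.reporter_outputs == ["y1", "y2"]
        compile_circuit(spec)  # structurally valid

    def test_eight_pattern_network_has_eight_reporters(self):
        from cryodsd import make_patterns, pattern_weights

        patterns = make_patterns(seed=0)
        w, t = pattern_weights(patterns)
        spec = build_network(w, patterns, t)
        assert spec.reporter_outputs == [f"y{i}" for i in range(1, 9)]
        compiled = compile_circuit(spec)
        assert compiled.molecule_count == 6 * len(spec.gates) + 8

    def test_non_binary_pattern_rejected(self):
        w = np.ones((4, 1), dtype=int)
        bad = np.array([[0, 1], [2, 0]])
        with pytest.raises(CircuitError, match="binary"):
            build_network(w, [bad])

    def test_negative_weight_rejected(self):
        with pytest.raises(CircuitError, match="non-negative"):
            build_network(np.array([[-1], [1]]), [np.array([1, 1])])

    def test_root_gate_carries_threshold(self):
        w = np.array([[1], [1], [1]])
        spec = build_network(w, [np.array([1, 1, 1])], thresholds=[3])
        root = {g.gate_id: g for g in spec.gates}["y1"]
        assert root.threshold_conc == pytest.approx(2.5 * 50.0)


class TestSpeciesTableRoundTrip:
    def test_export_reimport_identical(self, tmp_path):
        compiled = compile_circuit(fixture_circuit("and_or"))
        path = tmp_path / "species.tsv"
        species_table(compiled).to_csv(path, sep="\t", index=False)
        assert read_species_table(str(path)) == compiled.species
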