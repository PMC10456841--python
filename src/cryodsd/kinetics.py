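"""Mass-action reaction networks for strand-displacement circuits.

Toehold-mediated strand displacement is modelled as an effective irreversible
bimolecular reaction whose rate constant grows ~10-fold per toehold
nucleotide until it saturates.  The reference point is calibrated from the
observed behaviour of the basic 4-nt-toehold reaction at 50 nM: an
equal-concentration irreversible second-order reaction reaches 95 %
conversion at t95 = 19/(k C0), so k(4) = 19/(C0 * 20 h) = 5.3e3 /M/s.

The kinetic scheme instantiated per compiled gate:

==================  =============================================  =========
template            reaction                                       toehold
==================  =============================================  =========
switching           Sw_i + W_i -> W_i*                             8 nt
displacement        input_i + W_i* -> I   (shared intermediate)    5 nt
transmit            I + Sd -> sig                                  5 nt
threshold_absorb    sig + Th -> (inert)                            8 nt
report              sig + R -> F          (fluorescent product)    8 nt
==================  =============================================  =========

The threshold runs at the long-toehold rate, ten-fold faster than transmit,
so it preferentially absorbs impinging signal until stoichiometrically
exhausted.  Because reporter and threshold share the same fast rate, faithful
thresholding requires the reporter to be added *after* operation (as in the
wet protocol); :func:`simulate_circuit` therefore defaults to endpoint
reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.linalg import null_space

from .circuit import CompiledCircuit, GATE_TOEHOLD_NT, LONG_TOEHOLD_NT

__all__ = [
    "RateModel",
    "Reaction",
    "CRN",
    "Trace",
    "SimulationError",
    "toehold_rate",
    "basic_reaction_crn",
    "build_crn",
    "simulate_isothermal",
    "simulate_circuit",
    "completion_time",
    "CompletionResult",
    "conserved_moieties",
    "max_conservation_drift",
]

#: convert a bimolecular rate constant from /M/s to /nM/s
_M_TO_NM = 1e-9


@dataclass(frozen=True)
class RateModel:
    """Toehold-length dependence of the displacement rate constant.

    ``k_ref`` is the bimolecular rate constant at a 4-nt toehold (per molar
    per second); each extra nucleotide multiplies the rate by ``fold_per_nt``
    up to ``saturation_len``, beyond which the rate is constant.
    """

    k_ref: float = 5.3e3
    fold_per_nt: float = 10.0
    saturation_len: int = 6

    def __post_init__(self) -> None:
        if self.k_ref <= 0:
            raise ValueError("k_ref must be > 0")
        if self.fold_per_nt <= 1:
            raise ValueError("fold_per_nt must be > 1")
        if self.saturation_len < 4:
            raise ValueError("saturation_len must be >= 4")


def toehold_rate(m: int, model: RateModel | None = None) -> float:
    """Bimolecular displacement rate constant (/M/s) for an m-nt toehold.

    ``k(m) = k_ref * fold_per_nt**(min(m, saturation_len) - 4)``; strictly
    increasing below saturation, constant above.
    """
    model = model or RateModel()
    if m <= 0:
        raise ValueError(f"toehold length must be > 0 nt, got {m}")
    if m > 8:
        raise ValueError(f"toehold length must be <= 8 nt, got {m}")
    return model.k_ref * model.fold_per_nt ** (min(m, model.saturation_len) - 4)


@dataclass(frozen=True)
class Reaction:
    """One irreversible mass-action reaction (1-2 reactants)."""

    reactants: tuple[str, ...]
    products: tuple[str, ...]
    rate_const: float  # /nM/s if bimolecular, /s if unimolecular
    template: str

    def __post_init__(self) -> None:
        if not 1 <= len(self.reactants) <= 2:
            raise ValueError("reactions must have 1 or 2 reactants")
        if self.rate_const <= 0:
            raise ValueError("rate_const must be > 0")

    @property
    def bimolecular(self) -> bool:
        return len(self.reactants) == 2


@dataclass
class CRN:
    """A chemical reaction network: species with initial nM and reactions.

    ``outputs`` names the species whose summed concentration measures circuit
    progress (the released-output moiety); ``output_ref_nM`` is the
    concentration at which that sum equals full conversion.  ``reporters``
    maps each reported signal to its ``(R, F)`` reporter/fluorescent-product
    species so reporters can be withheld until after operation.
    """

    init: dict[str, float]
    reactions: list[Reaction]
    outputs: list[str] = field(default_factory=list)
    output_ref_nM: float = 50.0
    reporters: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for rxn in self.reactions:
            for name in (*rxn.reactants, *rxn.products):
                if name not in self.init:
                    raise ValueError(f"reaction references undeclared species {name!r}")
        for name, conc in self.init.items():
            if conc < 0:
                raise ValueError(f"{name}: negative initial concentration")

    @property
    def species(self) -> list[str]:
        return list(self.init)

    def stoichiometry(self) -> np.ndarray:
        """Net stoichiometric matrix, shape (n_species, n_reactions)."""
        idx = {s: i for i, s in enumerate(self.init)}
        n = np.zeros((len(idx), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for r in rxn.reactants:
                n[idx[r], j] -= 1
            for p in rxn.products:
                n[idx[p], j] += 1
        return n

    def y0(self, overrides: dict[str, float] | None = None) -> np.ndarray:
        concs = dict(self.init)
        if overrides:
            for name, c in overrides.items():
                if name not in concs:
                    raise ValueError(f"unknown species {name!r}")
                concs[name] = c
        return np.array(list(concs.values()), dtype=float)


@dataclass
class Trace:
    """Concentration time courses (nM) on a time grid (s)."""

    times: np.ndarray
    conc: np.ndarray  # (n_times, n_species)
    species: list[str]
    segments: list[tuple[float, float, float]] = field(default_factory=list)
    # (t_start, t_end, temperature_C) per integration segment

    def series(self, name: str) -> np.ndarray:
        return self.conc[:, self.species.index(name)]

    def conversion(self, outputs: list[str], ref_nM: float) -> np.ndarray:
        cols = [self.species.index(s) for s in outputs]
        return self.conc[:, cols].sum(axis=1) / ref_nM

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.conc, columns=self.species)
        df.insert(0, "time_s", self.times)
        temp = np.full(len(self.times), np.nan)
        for t0, t1, tc in self.segments:
            temp[(self.times >= t0) & (self.times <= t1)] = tc
        df["temperature_C"] = temp
        return df

    @staticmethod
    def concat(traces: list["Trace"]) -> "Trace":
        first = traces[0]
        return Trace(
            np.concatenate([t.times for t in traces]),
            np.vstack([t.conc for t in traces]),
            first.species,
            [seg for t in traces for seg in t.segments],
        )


class SimulationError(RuntimeError):
    """ODE integration failed to converge."""


def _integrate(
    crn: CRN,
    y0: np.ndarray,
    t0: float,
    t1: float,
    *,
    bimol_scale: float = 1.0,
    temperature_C: float = 25.0,
    n_points: int = 500,
    rtol: float = 1e-8,
    atol: float = 1e-8,
) -> Trace:
    names = crn.species
    idx = {s: i for i, s in enumerate(names)}
    stoich = crn.stoichiometry()
    r0 = np.array([idx[r.reactants[0]] for r in crn.reactions])
    r1 = np.array(
        [idx[r.reactants[1]] if r.bimolecular else -1 for r in crn.reactions]
    )
    ks = np.array(
        [
            r.rate_const * (bimol_scale if r.bimolecular else 1.0)
            for r in crn.reactions
        ]
    )
    bim = r1 >= 0

    def rhs(_t, y):
        rates = ks * y[r0]
        rates[bim] *= y[r1[bim]]
        return stoich @ rates

    t_eval = np.linspace(t0, t1, max(n_points, 2))
    sol = solve_ivp(
        rhs, (t0, t1), y0, method="LSODA", t_eval=t_eval, rtol=rtol, atol=atol
    )
    if not sol.success:
        raise SimulationError(f"ODE solver failed on [{t0}, {t1}] s: {sol.message}")
    return Trace(sol.t, sol.y.T, names, [(t0, t1, temperature_C)])


def simulate_isothermal(
    crn: CRN,
    t_end: float,
    *,
    temperature_C: float = 25.0,
    input_conc: dict[str, float] | None = None,
    n_points: int = 600,
    rtol: float = 1e-8,
    atol: float = 1e-8,
) -> Trace:
    """Deterministically integrate the CRN at a fixed temperature.

    All temperature effects are absorbed elsewhere (freeze-episode boost);
    the annotation is recorded in the trace but does not alter rates.
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    y0 = crn.y0(input_conc)
    return _integrate(
        crn, y0, 0.0, t_end,
        temperature_C=temperature_C, n_points=n_points, rtol=rtol, atol=atol,
    )


def simulate_circuit(
    crn: CRN,
    t_end: float,
    input_conc: dict[str, float] | None = None,
    *,
    reporter_timing: str = "after",
    report_duration: float = 1800.0,
    temperature_C: float = 25.0,
    rtol: float = 1e-8,
    atol: float = 1e-8,
) -> tuple[Trace, dict[str, float]]:
    """Run a circuit CRN and return (trace, final fluorescence per reporter).

    ``reporter_timing="after"`` (default) withholds every reporter complex
    during operation and adds it for a short reporting phase at the end,
    mirroring the wet protocol; ``"during"`` keeps reporters present
    throughout.
    """
    if reporter_timing not in ("after", "during"):
        raise ValueError("reporter_timing must be 'after' or 'during'")
    overrides = dict(input_conc or {})
    withheld = {}
    if reporter_timing == "after":
        for _sig, (r_name, _f) in crn.reporters.items():
            withheld[r_name] = crn.init[r_name]
            overrides[r_name] = 0.0
    y0 = crn.y0(overrides)
    trace = _integrate(
        crn, y0, 0.0, t_end, temperature_C=temperature_C, rtol=rtol, atol=atol
    )
    if withheld:
        y1 = trace.conc[-1].copy()
        for r_name, conc in withheld.items():
            y1[crn.species.index(r_name)] = conc
        tail = _integrate(
            crn, y1, t_end, t_end + report_duration,
            temperature_C=temperature_C, rtol=rtol, atol=atol,
        )
        trace = Trace.concat([trace, tail])
    finals = {
        sig: float(trace.series(f_name)[-1])
        for sig, (_r, f_name) in crn.reporters.items()
    }
    return trace, finals


class CompletionResult(NamedTuple):
    """Outcome of a completion-time query; ``time_s`` is None if not reached."""

    time_s: float | None
    reached: bool
    max_fraction: float


def completion_time(
    trace: Trace,
    fraction: float,
    outputs: list[str] | None = None,
    ref_nM: float | None = None,
    crn: CRN | None = None,
) -> CompletionResult:
    """First time the normalized output reaches ``fraction`` (linear interp).

    ``outputs``/``ref_nM`` default to the CRN's declared output moiety and
    reference concentration when ``crn`` is given.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if outputs is None or ref_nM is None:
        if crn is None:
            raise ValueError("provide outputs and ref_nM, or a CRN")
        outputs = outputs or crn.outputs
        ref_nM = ref_nM or crn.output_ref_nM
    conv = trace.conversion(outputs, ref_nM)
    max_frac = float(conv.max())
    above = np.nonzero(conv >= fraction)[0]
    if len(above) == 0:
        return CompletionResult(None, False, max_frac)
    i = int(above[0])
    if i == 0:
        return CompletionResult(float(trace.times[0]), True, max_frac)
    t0, t1 = trace.times[i - 1], trace.times[i]
    c0, c1 = conv[i - 1], conv[i]
    t = t0 if c1 == c0 else t0 + (fraction - c0) * (t1 - t0) / (c1 - c0)
    return CompletionResult(float(t), True, max_frac)


def basic_reaction_crn(
    toehold_len: int = 4,
    conc_nM: float = 50.0,
    model: RateModel | None = None,
    with_reporter: bool = True,
    reporter_conc_nM: float | None = None,
) -> CRN:
    """The basic displacement reaction: input X + substrate C -> Out (+ report).

    An input strand invades a partially double-stranded substrate via an
    m-nt toehold and releases the output strand; a fluorophore/quencher
    reporter with an 8-nt toehold stoichiometrically converts Out to a
    fluorescent product F.
    """
    model = model or RateModel()
    k_m = toehold_rate(toehold_len, model) * _M_TO_NM
    init = {"X": conc_nM, "C": conc_nM, "Out": 0.0, "Cw": 0.0}
    reactions = [Reaction(("X", "C"), ("Out", "Cw"), k_m, "displacement")]
    reporters: dict[str, tuple[str, str]] = {}
    outputs = ["Out"]
    if with_reporter:
        k8 = toehold_rate(8, model) * _M_TO_NM
        init.update(
            {"R": reporter_conc_nM if reporter_conc_nM is not None else conc_nM,
             "F": 0.0}
        )
        reactions.append(Reaction(("Out", "R"), ("F",), k8, "report"))
        reporters["basic"] = ("R", "F")
        outputs = ["Out", "F"]
    return CRN(init, reactions, outputs, conc_nM, reporters)


def build_crn(
    compiled: CompiledCircuit,
    model: RateModel | None = None,
    gate_toehold: int = GATE_TOEHOLD_NT,
) -> CRN:
    """Instantiate the per-gate reaction templates for a compiled circuit.

    Each gate contributes 2 switching + 2 displacement + 1 transmit +
    1 threshold reaction (both displacement branches release the same
    intermediate, which the transmit complex sums); each reporter adds one
    report reaction.  Upstream transmitted signal species act directly as
    downstream inputs.
    """
    model = model or RateModel()
    spec = compiled.spec
    if spec is None:
        raise ValueError("compiled circuit lacks its CircuitSpec (wiring unknown)")
    k_gate = toehold_rate(gate_toehold, model) * _M_TO_NM
    k_long = toehold_rate(LONG_TOEHOLD_NT, model) * _M_TO_NM

    by_name = compiled.species_by_name()
    for s in compiled.species:
        if s.role not in ("weight", "switch", "transmit", "threshold",
                          "reporter", "input"):
            raise ValueError(f"species {s.name!r}: unknown role {s.role!r} in CRN")

    init = {s.name: s.initial_conc for s in compiled.species}
    reactions: list[Reaction] = []
    reporters: dict[str, tuple[str, str]] = {}
    gate_ids = {g.gate_id for g in spec.gates}

    def signal_species(ref: str) -> str:
        return f"sig_{ref}" if ref in gate_ids else ref

    for gate in spec.gates:
        g = gate.gate_id
        for part in (f"{g}.W1a", f"{g}.W2a", f"{g}.I", f"sig_{g}", f"{g}.abs"):
            init[part] = 0.0
        reactions.append(
            Reaction((f"{g}.Sw1", f"{g}.W1"), (f"{g}.W1a",), k_long, "switching")
        )
        reactions.append(
            Reaction((f"{g}.Sw2", f"{g}.W2"), (f"{g}.W2a",), k_long, "switching")
        )
        a, b = (signal_species(r) for r in gate.input_refs)
        reactions.append(Reaction((a, f"{g}.W1a"), (f"{g}.I",), k_gate, "displacement"))
        reactions.append(Reaction((b, f"{g}.W2a"), (f"{g}.I",), k_gate, "displacement"))
        reactions.append(
            Reaction((f"{g}.I", f"{g}.Sd"), (f"sig_{g}",), k_gate, "transmit")
        )
        reactions.append(
            Reaction((f"sig_{g}", f"{g}.Th"), (f"{g}.abs",), k_long, "threshold_absorb")
        )

    outputs: list[str] = []
    for out in spec.reporter_outputs:
        f_name = f"F_{out}"
        init[f_name] = 0.0
        reactions.append(
            Reaction((f"sig_{out}", f"R_{out}"), (f_name,), k_long, "report")
        )
        reporters[out] = (f"R_{out}", f_name)
        outputs.extend([f"sig_{out}", f_name])

    _ = by_name  # validated above
    return CRN(init, reactions, outputs, spec.default_conc, reporters)


def conserved_moieties(crn: CRN) -> np.ndarray:
    """Orthonormal basis of conservation laws (left null space of stoichiometry)."""
    return null_space(crn.stoichiometry().T)


def max_conservation_drift(trace: Trace, crn: CRN) -> float:
    """Largest relative drift of any conserved linear combination over a trace."""
    basis = conserved_moieties(crn)
    if basis.size == 0:
        return 0.0
    totals = trace.conc @ basis  # (n_times, n_laws)
    drift = 0.0
    for j in range(totals.shape[1]):
        col = totals[:, j]
        scale = np.abs(col).max()
        if scale < 1e-9:
            continue
        drift = max(drift, float((col.max() - col.min()) / scale))
    return drift
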