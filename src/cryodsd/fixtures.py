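"""Deterministic toy inputs: the four benchmark circuits and digit patterns.

The circuit fixtures are the four architectures used throughout the package:
a single OR gate, a single AND gate (40 nM threshold), a two-layer AND-OR
cascade and a three-layer OR-AND-OR cascade, all at the 50 nM operating
concentration.

The pattern fixtures stand in for the handwritten-digit inputs of the
network-scale demonstration: eight 12x12 binary grids, one per digit 1-8,
drawn from a coarse stroke font and jittered with seed-controlled extra
pixels.  The companion weight matrix uses each pattern as its own template
(weights = pattern pixels, threshold = pixel count), so under weighted-sum +
threshold semantics each fixture pattern activates exactly its own output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .circuit import CircuitSpec, GateSpec, build_network

__all__ = [
    "Fixture",
    "fixture_circuit",
    "fixture_circuits",
    "make_patterns",
    "pattern_weights",
    "classify_pattern",
    "generate_fixtures",
]

# 3x5 stroke font for digits 1-8 (rows of 3 columns)
_FONT = {
    1: ["010", "110", "010", "010", "111"],
    2: ["111", "001", "111", "100", "111"],
    3: ["111", "001", "111", "001", "111"],
    4: ["101", "101", "111", "001", "001"],
    5: ["111", "100", "111", "001", "111"],
    6: ["111", "100", "111", "101", "111"],
    7: ["111", "001", "010", "010", "010"],
    8: ["111", "101", "111", "101", "111"],
}


@dataclass
class Fixture:
    """A named, regenerable toy input."""

    name: str
    circuit: CircuitSpec | None = None
    patterns: list[np.ndarray] | None = None
    weights: np.ndarray | None = None
    thresholds: np.ndarray | None = None
    params: dict | None = None


def fixture_circuit(name: str, default_conc: float = 50.0) -> CircuitSpec:
    """One of the benchmark circuits: 'or', 'and', 'and_or', 'or_and_or'."""
    th = 0.8 * default_conc  # 40 nM at the 50 nM operating concentration
    if name == "or":
        gates = [GateSpec("g1", ("x1", "x2"), 0.0, 1)]
        return CircuitSpec(gates, ["x1", "x2"], ["g1"], default_conc)
    if name == "and":
        gates = [GateSpec("g1", ("x1", "x2"), th, 1)]
        return CircuitSpec(gates, ["x1", "x2"], ["g1"], default_conc)
    if name == "and_or":
        gates = [
            GateSpec("g1", ("x1", "x2"), th, 1),
            GateSpec("g2", ("g1", "x3"), 0.0, 2),
        ]
        return CircuitSpec(gates, ["x1", "x2", "x3"], ["g2"], default_conc)
    if name == "or_and_or":
        gates = [
            GateSpec("g1", ("x1", "x2"), 0.0, 1),
            GateSpec("g2", ("g1", "x3"), th, 2),
            GateSpec("g3", ("g2", "x4"), 0.0, 3),
        ]
        return CircuitSpec(gates, ["x1", "x2", "x3", "x4"], ["g3"], default_conc)
    raise ValueError(f"unknown fixture circuit {name!r}")


def fixture_circuits(default_conc: float = 50.0) -> dict[str, CircuitSpec]:
    return {
        name: fixture_circuit(name, default_conc)
        for name in ("or", "and", "and_or", "or_and_or")
    }


def _glyph(digit: int, size: int = 12) -> np.ndarray:
    """Upscale the 3x5 font to a centred size x size grid."""
    rows = _FONT[digit]
    grid = np.zeros((size, size), dtype=int)
    sy, sx = 2, 3  # vertical x2, horizontal x3 -> 10 x 9 glyph
    oy, ox = (size - 5 * sy) // 2, (size - 3 * sx) // 2
    for r, row in enumerate(rows):
        for c, ch in enumerate(row):
            if ch == "1":
                grid[oy + r * sy : oy + (r + 1) * sy,
                     ox + c * sx : ox + (c + 1) * sx] = 1
    return grid


def make_patterns(
    seed: int = 0, size: int = 12, jitter_pixels: int = 6, max_tries: int = 100
) -> list[np.ndarray]:
    """Eight binary size x size digit patterns, jittered per seed.

    Extra pixels are flipped on at seeded random blank positions; the set is
    resampled until no pattern's pixels are a subset of another's, so
    template-matching weights classify each pattern uniquely.
    """
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        patterns = []
        for digit in range(1, 9):
            grid = _glyph(digit, size)
            blanks = np.flatnonzero(grid == 0)
            extra = rng.choice(blanks, size=jitter_pixels, replace=False)
            grid.flat[extra] = 1
            patterns.append(grid)
        if _uniquely_classifiable(patterns):
            return patterns
    raise RuntimeError("could not generate uniquely classifiable patterns")


def _uniquely_classifiable(patterns: list[np.ndarray]) -> bool:
    flats = [p.ravel() for p in patterns]
    for k, pk in enumerate(flats):
        for j, pj in enumerate(flats):
            if j != k and (pk & pj).sum() >= pk.sum():
                return False  # pattern k contained in pattern j
    return True


def pattern_weights(patterns: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Template-matching weight matrix and thresholds for a pattern set.

    weights[:, k] = pattern k's pixels; thresholds[k] = pattern k's pixel
    count, so output k fires iff the input contains every template pixel.
    """
    w = np.stack([p.ravel() for p in patterns], axis=1).astype(int)
    return w, w.sum(axis=0)


def classify_pattern(
    weights: np.ndarray, thresholds: np.ndarray, pattern: np.ndarray
) -> list[int]:
    """Boolean weighted-sum oracle: indices of outputs whose weighted input
    sum reaches the threshold."""
    x = np.asarray(pattern).ravel()
    if not np.isin(x, (0, 1)).all():
        raise ValueError("pattern must be binary")
    sums = x @ np.asarray(weights)
    return [int(k) for k in np.flatnonzero(sums >= np.asarray(thresholds))]


def generate_fixtures(seed: int = 0) -> dict[str, Fixture]:
    """All fixtures: the four benchmark circuits plus the 8-pattern network."""
    out = {
        name: Fixture(name, circuit=spec, params={"default_conc": 50.0})
        for name, spec in fixture_circuits().items()
    }
    patterns = make_patterns(seed)
    weights, thresholds = pattern_weights(patterns)
    out["network8"] = Fixture(
        "network8",
        circuit=build_network(weights, patterns, thresholds),
        patterns=patterns,
        weights=weights,
        thresholds=thresholds,
        params={"seed": seed, "size": 12},
    )
    return out
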