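"""Three-letter-code DNA domain design.

Designed (top) strands use only A, T and C, so G and C never co-occur in the
same strand and G-mediated secondary structure is avoided; G-containing
bottom strands are obtained as reverse complements, never designed directly.
Domains are rejection-sampled against run-length limits (at most three
consecutive A's or T's, at most two consecutive C's, i.e. runs of fewer than
four A/T and fewer than three C), a 30-70 % C-content band, and a pairwise
orthogonality screen bounding the longest shared or complementary stretch
between accepted domains.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

__all__ = [
    "DesignConstraints",
    "DomainSeq",
    "generate_domain",
    "validate_domain",
    "screen_library",
    "longest_common_substring",
    "longest_complementary_stretch",
    "write_fasta",
]


@dataclass(frozen=True)
class DesignConstraints:
    """Per-domain composition rules for three-letter-code design."""

    alphabet: str = "ATC"
    max_run_a: int = 3
    max_run_t: int = 3
    max_run_c: int = 2
    c_fraction_range: tuple[float, float] = (0.30, 0.70)

    def __post_init__(self) -> None:
        if min(self.max_run_a, self.max_run_t, self.max_run_c) < 1:
            raise ValueError("run-length maxima must be >= 1")
        lo, hi = self.c_fraction_range
        if not 0 <= lo <= hi <= 1:
            raise ValueError("c_fraction_range must be within [0, 1]")


@dataclass(frozen=True)
class DomainSeq:
    """A designed domain: identifier, length and bases."""

    domain_id: str
    bases: str

    @property
    def length(self) -> int:
        return len(self.bases)


def validate_domain(
    seq: DomainSeq | str, constraints: DesignConstraints | None = None
) -> tuple[bool, list[str]]:
    """Check every design rule; returns (passes, list of violations)."""
    constraints = constraints or DesignConstraints()
    bases = seq.bases if isinstance(seq, DomainSeq) else seq
    if not bases:
        raise ValueError("empty sequence")
    violations: list[str] = []
    bad = set(bases) - set(constraints.alphabet)
    if bad:
        violations.append(f"alphabet: disallowed bases {sorted(bad)}")
    for base, limit in (
        ("A", constraints.max_run_a),
        ("T", constraints.max_run_t),
        ("C", constraints.max_run_c),
    ):
        if re.search(base * (limit + 1), bases):
            violations.append(f"run: more than {limit} consecutive {base}")
    lo, hi = constraints.c_fraction_range
    frac = bases.count("C") / len(bases)
    if not lo <= frac <= hi:
        violations.append(f"c_fraction: {frac:.2f} outside [{lo}, {hi}]")
    return (not violations, violations)


def generate_domain(
    length: int,
    constraints: DesignConstraints | None = None,
    seed: int = 0,
    domain_id: str | None = None,
    max_attempts: int = 100_000,
) -> DomainSeq:
    """Rejection-sample one domain satisfying all constraints (deterministic
    per seed)."""
    constraints = constraints or DesignConstraints()
    if length < 4:
        raise ValueError("length must be >= 4 so the C-fraction band is attainable")
    rng = np.random.default_rng(seed)
    letters = np.array(list(constraints.alphabet))
    for _ in range(max_attempts):
        bases = "".join(rng.choice(letters, size=length))
        ok, _violations = validate_domain(bases, constraints)
        if ok:
            return DomainSeq(domain_id or f"d{seed}", bases)
    raise RuntimeError(
        f"no valid domain of length {length} found in {max_attempts} attempts"
    )


def longest_common_substring(a: str, b: str) -> int:
    """Length of the longest exact substring shared by two sequences (DP)."""
    best = 0
    prev = [0] * (len(b) + 1)
    for ca in a:
        cur = [0] * (len(b) + 1)
        for j, cb in enumerate(b, start=1):
            if ca == cb:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best:
                    best = cur[j]
        prev = cur
    return best


def _revcomp(s: str) -> str:
    return str(Seq(s).reverse_complement())


def longest_complementary_stretch(a: str, b: str) -> int:
    """Longest contiguous stretch of a that is Watson-Crick complementary to
    a stretch of b (antiparallel)."""
    return longest_common_substring(a, _revcomp(b))


def _orthogonal(a: str, b: str, limit: int) -> bool:
    return (
        longest_common_substring(a, b) <= limit
        and longest_complementary_stretch(a, b) <= limit
    )


def screen_library(
    n_domains: int,
    length: int,
    constraints: DesignConstraints | None = None,
    orthogonality_limit: int = 6,
    seed: int = 0,
    max_attempts: int = 100_000,
) -> list[DomainSeq]:
    """Generate and screen a library of mutually orthogonal domains.

    Candidates are drawn from one seeded stream; each must pass
    :func:`validate_domain` and keep its longest shared and complementary
    stretch with every accepted domain at or below ``orthogonality_limit``.
    If the attempt budget runs out a partial library is returned with a
    warning.
    """
    if n_domains < 1:
        raise ValueError("n_domains must be >= 1")
    constraints = constraints or DesignConstraints()
    rng = np.random.default_rng(seed)
    letters = np.array(list(constraints.alphabet))
    accepted: list[DomainSeq] = []
    for _ in range(max_attempts):
        if len(accepted) == n_domains:
            break
        bases = "".join(rng.choice(letters, size=length))
        ok, _v = validate_domain(bases, constraints)
        if not ok:
            continue
        if all(_orthogonal(bases, d.bases, orthogonality_limit) for d in accepted):
            accepted.append(DomainSeq(f"d{len(accepted)}", bases))
    if len(accepted) < n_domains:
        warnings.warn(
            f"orthogonality screen yielded only {len(accepted)}/{n_domains} "
            f"domains within {max_attempts} attempts",
            stacklevel=2,
        )
    return accepted


def write_fasta(domains: list[DomainSeq], path, include_complements: bool = True) -> None:
    """Write designed domains (and their reverse complements) as FASTA."""
    records = [
        SeqRecord(Seq(d.bases), id=d.domain_id, description="") for d in domains
    ]
    if include_complements:
        records += [
            SeqRecord(Seq(_revcomp(d.bases)), id=f"{d.domain_id}_rc",
                      description="reverse complement")
            for d in domains
        ]
    SeqIO.write(records, path, "fasta")
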