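"""Domain-level DNA sequence generation and validation.

Composition rules for strand-displacement circuits: long single-base runs
are banned (at most four A, four T or three C in a row), output strands
use a three-letter {A, C, T} alphabet to suppress secondary structure, and
gate strands keep their GC content between 30% and 70%.  Cross-talk is
screened pairwise: two sequences in a pool must not share a contiguous
stretch longer than 35% of the domain length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import GenerationError, InputError

_NUCLEOTIDES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class SequenceConstraintSet:
    max_a_run: int = 4
    max_t_run: int = 4
    max_c_run: int = 3
    max_g_run: int = 3  # symmetric with C (G runs form quadruplexes)
    output_strand_alphabet: tuple[str, ...] = ("A", "C", "T")
    gate_gc_range: tuple[float, float] = (0.30, 0.70)
    max_pairwise_shared_fraction: float = 0.35

    def __post_init__(self):
        for run in (self.max_a_run, self.max_t_run, self.max_c_run):
            if run < 1:
                raise InputError("run-length limits must be >= 1")
        lo, hi = self.gate_gc_range
        if not (0 <= lo <= hi <= 1):
            raise InputError("GC bounds must satisfy 0 <= lo <= hi <= 1")
        if not (0 < self.max_pairwise_shared_fraction < 1):
            raise InputError("shared fraction must lie in (0, 1)")


@dataclass
class ValidationReport:
    sequence: str
    role: str
    violations: list[tuple[str, tuple[int, int]]] = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return not self.violations


def _runs(seq: str):
    start = 0
    for i in range(1, len(seq) + 1):
        if i == len(seq) or seq[i] != seq[start]:
            yield seq[start], start, i - 1
            start = i


def validate_sequence(
    seq: str,
    role: str = "generic",
    constraints: SequenceConstraintSet | None = None,
) -> ValidationReport:
    """Apply all composition rules; violation spans are 1-based inclusive."""
    c = constraints or SequenceConstraintSet()
    if not seq:
        raise InputError("empty sequence")
    seq = seq.upper()
    if set(seq) - set(_NUCLEOTIDES):
        raise InputError(f"non-ACGT characters in sequence {seq!r}")
    if role not in ("output", "gate", "generic"):
        raise InputError(f"unknown sequence role {role!r}")
    report = ValidationReport(sequence=seq, role=role)
    limits = {
        "A": c.max_a_run,
        "T": c.max_t_run,
        "C": c.max_c_run,
        "G": c.max_g_run,
    }
    for base, start, end in _runs(seq):
        if end - start + 1 > limits[base]:
            report.violations.append(
                (f"run of {base} longer than {limits[base]}", (start + 1, end + 1))
            )
    if role == "output":
        for i, base in enumerate(seq):
            if base not in c.output_strand_alphabet:
                report.violations.append(
                    (f"base {base} outside output alphabet", (i + 1, i + 1))
                )
    if role == "gate":
        gc = sum(1 for b in seq if b in "GC") / len(seq)
        lo, hi = c.gate_gc_range
        if not (lo <= gc <= hi):
            report.violations.append(
                (f"GC content {gc:.2f} outside [{lo:.2f}, {hi:.2f}]",
                 (1, len(seq)))
            )
    return report


def longest_common_substring(a: str, b: str) -> int:
    """Length of the longest shared contiguous stretch (dynamic program)."""
    if not a or not b:
        return 0
    prev = [0] * (len(b) + 1)
    best = 0
    for i in range(1, len(a) + 1):
        cur = [0] * (len(b) + 1)
        ai = a[i - 1]
        for j in range(1, len(b) + 1):
            if ai == b[j - 1]:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best:
                    best = cur[j]
        prev = cur
    return best


def check_pool_orthogonality(
    pool: Sequence[str],
    domain_length: int,
    constraints: SequenceConstraintSet | None = None,
) -> list[tuple[int, int]]:
    """Pairs (i, j) sharing a contiguous stretch > 35% of domain_length."""
    if not pool:
        raise InputError("empty sequence pool")
    c = constraints or SequenceConstraintSet()
    limit = c.max_pairwise_shared_fraction * domain_length
    flagged = []
    for i in range(len(pool)):
        for j in range(i + 1, len(pool)):
            if longest_common_substring(pool[i].upper(), pool[j].upper()) > limit:
                flagged.append((i, j))
    return flagged


def generate_domain(
    length: int,
    role: str = "generic",
    constraints: SequenceConstraintSet | None = None,
    pool: Sequence[str] = (),
    seed: int = 0,
    max_attempts: int = 10000,
) -> str:
    """Seeded rejection sampling of one domain sequence.

    The returned sequence passes :func:`validate_sequence` and is
    orthogonal (35% rule) to every sequence already in ``pool``.
    """
    if length < 4:
        raise InputError("domains shorter than 4 nt are not supported")
    c = constraints or SequenceConstraintSet()
    rng = np.random.default_rng(seed)
    alphabet = (
        c.output_strand_alphabet if role == "output" else _NUCLEOTIDES
    )
    limit = c.max_pairwise_shared_fraction * length
    for _ in range(max_attempts):
        seq = "".join(rng.choice(alphabet, size=length))
        if not validate_sequence(seq, role, c).valid:
            continue
        if any(
            longest_common_substring(seq, p.upper()) > limit for p in pool
        ):
            continue
        return seq
    raise GenerationError(
        f"no valid {role} domain of length {length} found in "
        f"{max_attempts} attempts; relax the constraints or shrink the pool"
    )


def primer_tm_estimate(seq: str) -> float:
    """Advisory Wallace-rule melting temperature (deg C).

    A length/GC heuristic only — no nearest-neighbor thermodynamics; used
    to flag primers far from the 55 degC ligation target.
    """
    if not seq:
        raise InputError("empty sequence")
    seq = seq.upper()
    at = sum(1 for b in seq if b in "AT")
    gc = len(seq) - at
    if len(seq) < 14:
        return 2.0 * at + 4.0 * gc
    return 64.9 + 41.0 * (gc - 16.4) / len(seq)
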