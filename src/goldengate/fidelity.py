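"""Ligation-fidelity rules for 4-nt overhang (fusion-site) sets.

High-fidelity one-pot assembly requires that no two junction overhangs in a
set can cross-anneal.  The design rule enforced here restricts the middle
dinucleotide (positions 2-3, 1-based, reading the overhang 5'->3') to a
single use per set.  The rationale is a practical failure mode: enzyme
preparations carry trace exonuclease activity that can remove the 5'-most
base (position 1) of an extension, after which the remaining 3 bases may
anneal to a non-partner end.  In-register annealing of a single-trimmed end
with a non-partner's mating strand requires the two overhangs to share
either positions 2-4 or positions 1-3 — both of which include the middle
dinucleotide, so middle uniqueness eliminates every such hazard.  Since any
middle dinucleotide can appear only once, at most 16 overhangs (one per
dinucleotide) can coexist.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

from .seqcore import GoldenGateError, SequenceAlphabetError, revcomp

__all__ = [
    "FidelityReport",
    "FidelityError",
    "check_overhang_set",
    "max_set_size",
]

_BASES = "ACGT"


class FidelityError(GoldenGateError):
    """Raised on malformed overhangs or unknown constraint ids."""


@dataclass
class FidelityReport:
    """Outcome of :func:`check_overhang_set`; empty report == set passes."""

    duplicates: list = field(default_factory=list)
    palindromes: list = field(default_factory=list)
    cross_pairs: list = field(default_factory=list)
    middle_reuse: list = field(default_factory=list)
    trim_hazards: list = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not (self.duplicates or self.palindromes or self.cross_pairs
                    or self.middle_reuse or self.trim_hazards)

    def summary(self) -> str:
        if self.passed:
            return "overhang set passes all fidelity rules"
        lines = []
        if self.duplicates:
            lines.append("duplicates: " + ", ".join(self.duplicates))
        if self.palindromes:
            lines.append("self-complementary: " + ", ".join(self.palindromes))
        for a, b in self.cross_pairs:
            lines.append(f"cross-complementary junctions: {a} / {b}")
        for mid, members in self.middle_reuse:
            lines.append(f"middle dinucleotide {mid} reused by " + ", ".join(members))
        for trimmed, partner in self.trim_hazards:
            lines.append(f"trim hazard: {trimmed} (trimmed) anneals to {partner}")
        return "; ".join(lines)

    def to_dict(self) -> dict:
        return {
            "passed": self.passed,
            "duplicates": self.duplicates,
            "palindromes": self.palindromes,
            "cross_pairs": [list(p) for p in self.cross_pairs],
            "middle_reuse": [[m, list(o)] for m, o in self.middle_reuse],
            "trim_hazards": [list(p) for p in self.trim_hazards],
        }


def _validate(overhangs) -> list:
    out = []
    for o in overhangs:
        if not isinstance(o, str):
            raise FidelityError(f"overhang must be a string, got {o!r}")
        s = o.upper()
        if len(s) != 4 or set(s) - set(_BASES):
            raise SequenceAlphabetError(f"malformed overhang {o!r} (need 4 nt of ACGT)")
        out.append(s)
    return out


def check_overhang_set(overhangs) -> FidelityReport:
    """Audit a 4-nt overhang set against all fidelity rules.

    Reported categories:

    * ``duplicates`` — literal repeats;
    * ``palindromes`` — self-complementary overhangs (their two strand forms
      are identical, so such an end ligates to itself);
    * ``cross_pairs`` — one overhang is the reverse complement of another,
      making the two junctions fully interchangeable;
    * ``middle_reuse`` — a middle dinucleotide (positions 2-3) used by more
      than one overhang;
    * ``trim_hazards`` — after exonucleolytic loss of the position-1 base,
      the remaining 3-mer anneals perfectly (in register) to the mating
      strand of a different junction, i.e. the two overhangs share positions
      2-4 or positions 1-3.

    The report content is order-invariant with respect to the input.
    """
    ohs = _validate(overhangs)
    order = sorted(set(ohs))
    report = FidelityReport()

    seen = {}
    for o in ohs:
        seen[o] = seen.get(o, 0) + 1
    report.duplicates = sorted(o for o, c in seen.items() if c > 1)
    report.palindromes = [o for o in order if o == revcomp(o)]
    report.cross_pairs = [
        (a, b)
        for i, a in enumerate(order)
        for b in order[i:]
        if revcomp(a) == b and a != b
    ]

    by_middle = {}
    for o in order:
        by_middle.setdefault(o[1:3], []).append(o)
    report.middle_reuse = sorted(
        (mid, members) for mid, members in by_middle.items() if len(members) > 1
    )

    hazards = set()
    for a in order:
        for b in order:
            if a == b:
                continue
            if a[1:4] == b[1:4]:        # trimmed a-form vs b's mating strand
                hazards.add((a[1:4], b))
            if a[0:3] == b[0:3]:        # trimmed mating form of a vs b-form
                hazards.add((revcomp(a)[1:4], b))
    report.trim_hazards = sorted(hazards)
    return report


def max_set_size(constraint: str = "unique_middle", allowed_middles=None):
    """Maximum overhang-set size under a fidelity constraint, with a witness.

    For ``unique_middle`` the answer is found by enumeration over all 256
    4-mers: overhangs are grouped by middle dinucleotide and one per group is
    taken (lexicographically smallest), which is maximal because each set
    member consumes its middle exactly once.  ``allowed_middles`` restricts
    the admissible middles (e.g. ``{"AT"}`` gives size 1).

    Returns ``(size, witness_set)``.
    """
    if constraint != "unique_middle":
        raise FidelityError(f"unknown constraint id {constraint!r}")
    if allowed_middles is not None:
        allowed = {m.upper() for m in allowed_middles}
        for m in allowed:
            _validate([m + m])  # 2-nt check by padding to 4
    groups = {}
    for tup in product(_BASES, repeat=4):
        o = "".join(tup)
        mid = o[1:3]
        if allowed_middles is not None and mid not in allowed:
            continue
        groups.setdefault(mid, []).append(o)
    witness = sorted(min(members) for members in groups.values())
    return len(groups), witness
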