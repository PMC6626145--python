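"""Core sequence primitives shared by every other module.

A :class:`DnaMolecule` is a fully double-stranded, annotated piece of DNA —
linear or circular — represented by its top strand.  Coordinates are 0-based,
half-open, on the top strand; circular arithmetic is modulo length.  The
alphabet is strictly ``{A, C, G, T}``: lower case is upper-cased on input and
``U`` is rejected rather than converted, so RNA input fails loudly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from Bio.Seq import Seq

__all__ = [
    "GoldenGateError",
    "SequenceAlphabetError",
    "FrameError",
    "Feature",
    "Overhang",
    "DnaMolecule",
    "revcomp",
    "translate",
]


class GoldenGateError(Exception):
    """Base class for all errors raised by this package."""


class SequenceAlphabetError(GoldenGateError, ValueError):
    """Sequence contains characters outside {A, C, G, T}."""


class FrameError(GoldenGateError, ValueError):
    """Coding sequence length is not a multiple of three."""


_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID = frozenset("ACGT")

FEATURE_KINDS = (
    "selection_marker",
    "counter_selection",
    "origin",
    "cds",
    "part_payload",
    "misc",
)


def _clean(seq: str) -> str:
    s = seq.upper()
    bad = set(s) - _VALID
    if bad:
        if "U" in bad:
            raise SequenceAlphabetError(
                "sequence contains 'U' — RNA input is rejected, not converted"
            )
        raise SequenceAlphabetError(f"non-nucleotide characters: {sorted(bad)}")
    return s


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string. ``revcomp(revcomp(s)) == s``."""
    return _clean(seq).translate(_COMPLEMENT)[::-1]


def translate(cds: str, codon_table: int = 1) -> str:
    """Translate an in-frame CDS; stops rendered as ``*``.

    Raises :class:`FrameError` if the length is not divisible by 3.
    """
    s = _clean(cds)
    if len(s) % 3:
        raise FrameError(f"CDS length {len(s)} not divisible by 3")
    return str(Seq(s).translate(table=codon_table))


@dataclass
class Feature:
    """An annotated interval on the top strand of a molecule.

    ``start``/``end`` are 0-based half-open; on circular molecules ``start``
    may exceed ``end`` to denote an origin-spanning feature.
    """

    label: str
    kind: str = "misc"
    start: int = 0
    end: int = 0
    strand: int = 1
    qualifiers: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in FEATURE_KINDS:
            self.kind = "misc"
        if self.strand not in (1, -1):
            raise ValueError(f"strand must be +1/-1, got {self.strand}")

    def shifted(self, offset: int) -> "Feature":
        return replace(self, start=self.start + offset, end=self.end + offset)


@dataclass(frozen=True)
class Overhang:
    """A single-stranded extension at a fragment end.

    ``seq`` is recorded 5'->3' in its top-strand-equivalent form; an empty
    ``seq`` means a blunt end.  Extensions longer than 4 nt never occur in
    this system (4 nt for BsaI-class junctions, 3 nt for SapI, 0 for MlyI).
    """

    seq: str = ""
    polarity: str = "five_prime"

    def __post_init__(self):
        object.__setattr__(self, "seq", _clean(self.seq) if self.seq else "")
        if self.polarity not in ("five_prime", "three_prime"):
            raise ValueError(f"bad polarity {self.polarity!r}")
        if len(self.seq) > 4:
            raise ValueError(f"overhang longer than 4 nt: {self.seq}")

    @property
    def is_blunt(self) -> bool:
        return self.seq == ""

    @classmethod
    def blunt(cls) -> "Overhang":
        return cls("", "five_prime")


@dataclass
class DnaMolecule:
    """Annotated double-stranded DNA, linear or circular."""

    id: str
    seq: str
    topology: str = "linear"
    features: list = field(default_factory=list)

    def __post_init__(self):
        self.seq = _clean(self.seq)
        if not self.seq:
            raise SequenceAlphabetError("empty sequence")
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"topology must be linear|circular, got {self.topology!r}")
        n = len(self.seq)
        for f in self.features:
            if self.topology == "linear":
                if not (0 <= f.start < f.end <= n):
                    raise ValueError(
                        f"feature {f.label!r} interval [{f.start},{f.end}) "
                        f"out of bounds for linear length {n}"
                    )
            else:
                if not (0 <= f.start < n and 0 < f.end <= n):
                    raise ValueError(
                        f"feature {f.label!r} interval [{f.start},{f.end}) "
                        f"out of bounds for circular length {n}"
                    )

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def is_circular(self) -> bool:
        return self.topology == "circular"

    def subseq(self, start: int, end: int) -> str:
        """Top-strand slice; on circular molecules coordinates wrap."""
        n = len(self.seq)
        if self.is_circular:
            start %= n
            end = end % n or (n if end else 0)
            if end > start:
                return self.seq[start:end]
            return self.seq[start:] + self.seq[:end]
        if not (0 <= start <= end <= n):
            raise ValueError(f"slice [{start},{end}) out of bounds (length {n})")
        return self.seq[start:end]

    def rotated(self, k: int) -> "DnaMolecule":
        """Rotate a circular molecule so old coordinate ``k`` becomes 0."""
        if not self.is_circular:
            raise ValueError("only circular molecules can be rotated")
        n = len(self.seq)
        k %= n
        feats = []
        for f in self.features:
            s = (f.start - k) % n
            e = (f.end - k) % n or n
            feats.append(replace(f, start=s, end=e))
        return DnaMolecule(self.id, self.seq[k:] + self.seq[:k], "circular", feats)

    def reverse_complement(self) -> "DnaMolecule":
        n = len(self.seq)
        feats = []
        for f in self.features:
            s, e = f.start, f.end
            if e < s:  # origin-spanning
                e += n
            ns, ne = n - e, n - s
            if self.is_circular:
                ns %= n
                ne = ne % n or n
            feats.append(replace(f, start=ns, end=ne, strand=-f.strand))
        return DnaMolecule(self.id + "_rc", revcomp(self.seq), self.topology, feats)

    def canonical_form(self) -> str:
        """Rotation- and strand-invariant canonical string for circles.

        For linear molecules the strand-invariant min(seq, revcomp) is used.
        """
        if not self.is_circular:
            return min(self.seq, revcomp(self.seq))
        best = None
        for s in (self.seq, revcomp(self.seq)):
            doubled = s + s
            for i in range(len(s)):
                cand = doubled[i : i + len(s)]
                if best is None or cand < best:
                    best = cand
        return best
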