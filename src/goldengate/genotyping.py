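"""Restriction-site-loss genotyping of genome edits.

A PCR amplicon spanning a nuclease target site is digested with an enzyme
(here typically MlyI, a blunt cutter) whose site overlaps the expected cut
position.  Unedited alleles are cleaved into fragments; alleles carrying
indels that destroy the site resist digestion and run as a full-length band
on a gel.  Resistant alleles are then described by global pairwise alignment
against the wild type.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align

from .enzymes import StickyFragment, digest, get_enzyme, locate_sites
from .seqcore import DnaMolecule, GoldenGateError

__all__ = [
    "AssayDesignError",
    "NotComparableError",
    "IndelCall",
    "AssayResult",
    "call_indel",
    "site_loss_assay",
]

FLANK_IDENTITY = 10     # nt of end identity required before alignment
COMIGRATION_TOL = 0.05  # fragment lengths within 5% are flagged as one band

# global alignment, match +1 / mismatch -1, gap of length k costs 4 + k
_MATCH, _MISMATCH, _GAP_OPEN, _GAP_EXTEND = 1.0, -1.0, -4.0, -1.0


class AssayDesignError(GoldenGateError):
    """The wild-type amplicon lacks a site for the assay enzyme."""


class NotComparableError(GoldenGateError):
    """Allele and wild type do not share enough flanking identity."""


@dataclass(frozen=True)
class IndelCall:
    """One alignment event: type, size and wild-type start coordinate."""

    type: str        # insertion | deletion | substitution | none
    size: int
    position: int = None


@dataclass
class AssayResult:
    """Digestion outcome for one allele amplicon."""

    allele_id: str
    status: str                       # "cut" | "resistant"
    fragment_lengths: list
    indel_calls: list = field(default_factory=list)
    comigrating: list = field(default_factory=list)  # (len, len) close pairs
    cut_position: int = None          # wild-type top-strand cut coordinate

    @property
    def indel_call(self) -> IndelCall:
        """Primary event (largest; ties to the leftmost), with its position
        reported relative to the wild-type cut site."""
        if not self.indel_calls:
            return IndelCall("none", 0, None)
        c = max(self.indel_calls, key=lambda c: (c.size, -(c.position or 0)))
        if self.cut_position is None or c.position is None:
            return c
        return IndelCall(c.type, c.size, c.position - self.cut_position)


def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = _MATCH
    al.mismatch_score = _MISMATCH
    # Biopython charges open on the first gap base; a k-gap then costs
    # 5 + (k-1) = 4 + k, the intended affine cost
    al.open_gap_score = _GAP_OPEN + _GAP_EXTEND
    al.extend_gap_score = _GAP_EXTEND
    return al


def _events_from_alignment(aln, wt: str, allele: str):
    """Convert aligned blocks into (type, size, wt_position) events."""
    events = []
    wt_aln, al_aln = aln[0], aln[1]
    wpos = 0
    i = 0
    while i < len(wt_aln):
        a, b = wt_aln[i], al_aln[i]
        if a == "-" or b == "-":
            kind = "insertion" if a == "-" else "deletion"
            j = i
            size = 0
            inserted = []
            while j < len(wt_aln) and (wt_aln[j] == "-" if kind == "insertion"
                                       else al_aln[j] == "-"):
                if kind == "insertion":
                    inserted.append(al_aln[j])
                size += 1
                j += 1
            events.append([kind, size, wpos, "".join(inserted)])
            if kind == "deletion":
                wpos += size
            i = j
        elif a != b:
            j = i
            while j < len(wt_aln) and wt_aln[j] != "-" and al_aln[j] != "-" \
                    and wt_aln[j] != al_aln[j]:
                j += 1
            events.append(["substitution", j - i, wpos, ""])
            wpos += j - i
            i = j
        else:
            wpos += 1
            i += 1
    return events


def _left_align(events, wt: str):
    """Shift gaps leftward over repeated context (standard indel
    normalisation), so tied-score alignments give a deterministic call."""
    out = []
    for kind, size, pos, inserted in events:
        if kind == "deletion":
            while pos > 0 and wt[pos - 1] == wt[pos + size - 1]:
                pos -= 1
        elif kind == "insertion":
            while pos > 0 and inserted and wt[pos - 1] == inserted[-1]:
                inserted = wt[pos - 1] + inserted[:-1]
                pos -= 1
        out.append(IndelCall(kind, size, pos))
    return out


def call_indel(wt: str, allele: str) -> list:
    """Describe an allele relative to wild type by global alignment.

    Both sequences must share at least 10 nt of identity at each end.
    Returns a list of :class:`IndelCall`; identical sequences give
    ``[IndelCall("none", 0, None)]``.  Gap placement ties are resolved
    leftmost.
    """
    wt, allele = wt.upper(), allele.upper()
    k = FLANK_IDENTITY
    if len(wt) < 2 * k or len(allele) < 2 * k \
            or wt[:k] != allele[:k] or wt[-k:] != allele[-k:]:
        raise NotComparableError(
            f"not comparable: sequences do not share {k} nt identity at both ends"
        )
    if wt == allele:
        return [IndelCall("none", 0, None)]
    aln = _aligner().align(wt, allele)[0]
    events = _events_from_alignment(aln, wt, allele)
    return _left_align(events, wt)


def site_loss_assay(wt_amplicon: DnaMolecule, alleles, enzyme,
                    enzymes: dict = None) -> list:
    """Digest each allele amplicon; classify, predict bands, call indels.

    The wild type must contain at least one site (assay-design check) and is
    reported first as the reference.  An allele is resistant iff it retains
    zero sites; fragment lengths are reported sorted for gel comparison,
    with near-comigrating bands (within 5% length) flagged.
    """
    enz = get_enzyme(enzyme, enzymes)
    wt_sites = locate_sites(wt_amplicon, enz)
    if not wt_sites:
        raise AssayDesignError(
            f"assay design error: wild-type amplicon {wt_amplicon.id!r} has "
            f"no {enz.name} site"
        )
    results = []
    for mol in [wt_amplicon] + list(alleles):
        frags = digest(mol, enz, enzymes)
        cut = bool(locate_sites(mol, enz))
        if cut and frags and isinstance(frags[0], StickyFragment):
            lengths = sorted((len(f) for f in frags), reverse=True)
        else:
            lengths = [len(mol.seq)]
        comig = [
            (a, b)
            for i, a in enumerate(lengths)
            for b in lengths[i + 1:]
            if a != b and (a - b) / a <= COMIGRATION_TOL
        ]
        if mol is wt_amplicon:
            calls = []
        else:
            calls = [c for c in call_indel(wt_amplicon.seq, mol.seq)
                     if c.type != "none"]
        results.append(AssayResult(mol.id, "cut" if cut else "resistant",
                                   lengths, calls, comig,
                                   cut_position=wt_sites[0].cut_top_pos))
    return results
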