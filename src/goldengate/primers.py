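"""Entry-primer and mutagenesis-primer design, plus virtual PCR.

An entry primer stacks two nested type IIS modules in front of the template
homology: the entry enzyme's site (cutting onto a directional entry
overhang used for cloning into the universal acceptor backbone) and the
level-2 enzyme's site (cutting onto the 4-nt fusion site that will define
the part's position in later assembly)::

    5'-[pad][entry site][spacer][entry overhang][level-2 site][spacer]
       [fusion site][homology]-3'

Spacer lengths follow each enzyme's cut geometry so the cut lands exactly on
the intended overhang (BpiI needs 2 nt, BsaI/Esp3I 1 nt).  Melting
temperatures use the Wallace rule, 2(A+T) + 4(G+C) — deterministic and
parameter-free; a nearest-neighbour model is a documented extension point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .enzymes import get_enzyme, locate_sites
from .grammar import FusionSiteTable, PositionSpec
from .seqcore import DnaMolecule, GoldenGateError, revcomp

__all__ = [
    "PrimerError",
    "PrimerDesign",
    "tm",
    "design_entry_primers",
    "design_mutagenesis_primers",
    "simulate_pcr",
    "simulate_site_directed_mutagenesis",
]

HOMOLOGY_FLOOR = 18
HOMOLOGY_CEIL = 30
TM_MIN, TM_MAX = 52.0, 60.0
DEFAULT_PAD = "TT"
MUTAGENESIS_OVERLAP = 15


class PrimerError(GoldenGateError):
    """Primer design cannot satisfy its constraints."""


@dataclass
class PrimerDesign:
    """A primer with its labelled segment structure (5'->3')."""

    name: str
    segments: list                      # ordered (label, seq) pairs
    tm_homology: float = 0.0
    warnings: list = field(default_factory=list)

    @property
    def full_seq(self) -> str:
        return "".join(seq for _lab, seq in self.segments)

    @property
    def homology(self) -> str:
        for lab, seq in self.segments:
            if lab == "homology":
                return seq
        return ""

    @property
    def homology_len(self) -> int:
        return len(self.homology)

    def segment(self, label: str) -> str:
        for lab, seq in self.segments:
            if lab == label:
                return seq
        raise KeyError(label)


def tm(seq: str) -> float:
    """Wallace-rule melting temperature: 2(A+T) + 4(G+C) degrees C."""
    if not seq:
        raise PrimerError("cannot compute Tm of an empty sequence")
    s = seq.upper()
    return 2.0 * (s.count("A") + s.count("T")) + 4.0 * (s.count("G") + s.count("C"))


def _grow_homology(template: str, anchor: int, leftward: bool,
                   tm_min: float, tm_max: float):
    """Pick a homology arm anchored at ``anchor``, grown 18 -> 30 nt until
    its Tm enters the window.

    ``leftward`` arms end at the anchor, rightward arms start there.  If the
    window cannot be reached the closest achievable arm is returned with a
    warning.
    """
    warnings = []
    best = None
    for ln in range(HOMOLOGY_FLOOR, HOMOLOGY_CEIL + 1):
        if leftward:
            if anchor - ln < 0:
                break
            arm = template[anchor - ln: anchor]
        else:
            if anchor + ln > len(template):
                break
            arm = template[anchor: anchor + ln]
        best = arm
        t = tm(arm)
        if t >= tm_min:
            if t > tm_max:
                warnings.append(
                    f"Tm window unreachable; closest achievable {t:.0f} C"
                )
            return arm, t, warnings
    if best is None:
        raise PrimerError("template shorter than the minimum homology arm")
    warnings.append(f"Tm window unreachable; closest achievable {tm(best):.0f} C")
    return best, tm(best), warnings


_SPACER_BASES = "ACGT"


def _entry_primer(name, template_arm_seq, arm_tm, arm_warnings, entry_enz,
                  level2_enz, entry_overhang, fusion_site, pad):
    """Assemble one entry primer, choosing spacers that add no stray sites."""
    entry_spacer_len = entry_enz.cut_top
    level2_spacer_len = level2_enz.cut_top
    for s1 in _spacers(entry_spacer_len):
        for s2 in _spacers(level2_spacer_len):
            segments = [
                ("pad", pad),
                ("entry_enzyme_site", entry_enz.recognition),
                ("entry_spacer", s1),
                ("entry_overhang", entry_overhang),
                ("level2_enzyme_site", level2_enz.recognition),
                ("level2_spacer", s2),
                ("fusion_site", fusion_site),
                ("homology", template_arm_seq),
            ]
            design = PrimerDesign(name, segments, arm_tm, list(arm_warnings))
            probe = DnaMolecule("probe", design.full_seq, "linear")
            if (len(locate_sites(probe, entry_enz)) == 1
                    and len(locate_sites(probe, level2_enz)) == 1):
                return design
    raise PrimerError(f"could not choose spacers free of stray sites for {name}")


def _spacers(n):
    if n == 0:
        yield ""
        return
    from itertools import product
    for tup in product(_SPACER_BASES, repeat=n):
        yield "".join(tup)


def design_entry_primers(template: DnaMolecule, position: PositionSpec,
                         grammar: FusionSiteTable, tm_min: float = TM_MIN,
                         tm_max: float = TM_MAX, entry_enzyme: str = None,
                         pad: str = DEFAULT_PAD, enzymes: dict = None):
    """Design the forward/reverse primer pair that amplifies ``template`` in
    full and stages it for directional entry cloning at ``position``.

    The template must already be free of the entry and level-2 enzymes'
    sites; otherwise a :class:`PrimerError` lists the hits and advises
    domestication first.
    """
    entry_enz = get_enzyme(entry_enzyme or grammar.enzymes["entry"], enzymes)
    level2_enz = get_enzyme(grammar.enzymes["level2"], enzymes)
    offenders = []
    for enz in (entry_enz, level2_enz):
        offenders += [(enz.name, h.recog_start) for h in locate_sites(template, enz)]
    if offenders:
        raise PrimerError(
            "domesticate first: template contains "
            + ", ".join(f"{n} site at {p}" for n, p in offenders)
        )
    if position.level != "LI->LII":
        raise PrimerError("entry primers stage parts for LI->LII positions")
    fs_left = grammar.overhang("LI->LII", position.left)
    fs_right = grammar.overhang("LI->LII", position.right)
    entry_left, entry_right = grammar.entry

    fwd_arm, fwd_tm, fwd_warn = _grow_homology(template.seq, 0, False, tm_min, tm_max)
    rev_arm_top, rev_tm, rev_warn = _grow_homology(template.seq, len(template.seq),
                                                   True, tm_min, tm_max)

    fwd = _entry_primer(f"{template.id}_{position}_F", fwd_arm, fwd_tm, fwd_warn,
                        entry_enz, level2_enz, entry_left, fs_left, pad)
    rev = _entry_primer(f"{template.id}_{position}_R", revcomp(rev_arm_top),
                        rev_tm, rev_warn, entry_enz, level2_enz,
                        revcomp(entry_right), revcomp(fs_right), pad)
    return fwd, rev


def design_mutagenesis_primers(template: DnaMolecule, edit, tm_min: float = TM_MIN,
                               tm_max: float = TM_MAX,
                               overlap: int = MUTAGENESIS_OVERLAP):
    """Design an overlapping primer pair carrying a silent edit.

    Both primers contain the edited base(s) inside an overlap of at least
    ``overlap`` nt centred on the edit; each primer's 3' homology arm is
    grown until its Wallace Tm enters the window.  Raises
    :class:`PrimerError` if the edit sits too close to a template end for
    the arms to fit.
    """
    n = len(template.seq)
    s, e = edit.position, edit.end
    if template.seq[s:e] != edit.before:
        raise PrimerError(f"edit does not match template at [{s},{e})")
    edited = template.seq[:s] + edit.after + template.seq[e:]
    center = (s + e) // 2
    half = max(overlap, e - s + 2) // 2
    o_start, o_end = center - half, center + half + 1
    if o_start < 0 or o_end > n:
        raise PrimerError("edit too close to the template end for the overlap")
    if template.is_circular:
        raise PrimerError("mutagenesis primers are designed on the linearised "
                          "top strand; rotate the molecule first")

    fwd_arm, fwd_tm, fwd_warn = _grow_homology(edited, o_end, False, tm_min, tm_max)
    rev_arm, rev_tm, rev_warn = _grow_homology(edited, o_start, True, tm_min, tm_max)

    overlap_seq = edited[o_start:o_end]
    fwd = PrimerDesign(
        f"{template.id}_mut_F",
        [("overlap", overlap_seq), ("homology", fwd_arm)],
        fwd_tm, fwd_warn,
    )
    rev = PrimerDesign(
        f"{template.id}_mut_R",
        [("overlap", revcomp(overlap_seq)), ("homology", revcomp(rev_arm))],
        rev_tm, rev_warn,
    )
    return fwd, rev


def _find_arm(hay: str, arm: str, what: str) -> int:
    i = hay.find(arm)
    if i == -1 or hay.find(arm, i + 1) != -1:
        raise PrimerError(f"{what} arm does not anneal uniquely")
    return i


def simulate_pcr(template: DnaMolecule, fwd: PrimerDesign, rev: PrimerDesign,
                 product_id: str = None) -> DnaMolecule:
    """Exact-annealing virtual PCR.

    Each primer's homology segment must match the template (forward) or its
    reverse complement (reverse) uniquely; the product is the template
    between and including the annealing footprints, with both primer tails
    appended.
    """
    top = template.seq
    f_arm, r_arm = fwd.homology, rev.homology
    fi = _find_arm(top, f_arm, "forward")
    r_arm_top = revcomp(r_arm)
    ri = _find_arm(top, r_arm_top, "reverse")
    if ri + len(r_arm_top) <= fi + len(f_arm) and not template.is_circular:
        raise PrimerError("primer pair does not amplify a forward product")
    core = top[fi + len(f_arm): ri]
    seq = fwd.full_seq + core + revcomp(rev.full_seq)
    return DnaMolecule(product_id or f"{template.id}_amplicon", seq, "linear")


def simulate_site_directed_mutagenesis(template: DnaMolecule,
                                       fwd: PrimerDesign, rev: PrimerDesign,
                                       product_id: str = None) -> DnaMolecule:
    """Virtual whole-plasmid mutagenesis with an overlapping primer pair.

    The 3' homology arms anneal exactly; the overlap (carrying the edit)
    replaces the corresponding template region.  Returns the re-circularised
    product.
    """
    top = template.seq
    fi = _find_arm(top, fwd.homology, "forward")       # right arm start
    overlap_top = fwd.segment("overlap")
    rev_arm_top = revcomp(rev.homology)
    ri = _find_arm(top, rev_arm_top, "reverse")        # left arm start
    o_start = ri + len(rev_arm_top)                    # overlap replaces [o_start, fi)
    if fi - o_start != len(overlap_top):
        raise PrimerError("primer arms do not flank a region matching the overlap")
    seq = top[:o_start] + overlap_top + top[fi:]
    return DnaMolecule(product_id or f"{template.id}_sdm", seq, template.topology)
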