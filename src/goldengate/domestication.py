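"""Part domestication: removing internal type IIS sites by silent mutation.

Parts entering the platform must be cleared of the assembly enzymes' sites
(by default BsaI, BpiI and ideally Esp3I), otherwise they are cut during
assembly.  Inside a CDS a recognition site can be destroyed by a synonymous
codon substitution; the planner picks, per site, the substitution that
changes the fewest bases (ties broken by the lexicographically smallest
replacement codon), destroys the match on both strands, and creates no new
forbidden site within a +/-10 nt window — wide enough to cover the longest
shipped recognition sequence (7 nt) on either strand.  Sites outside any
CDS are never auto-edited; the landing-pad route exists precisely so such
parts can enter the system without touching their sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from Bio.Data import CodonTable

from .enzymes import SiteHit, get_enzyme, locate_sites
from .seqcore import DnaMolecule, FrameError, GoldenGateError, translate

__all__ = [
    "DomesticationError",
    "UndomesticableSiteError",
    "AnnotatedHit",
    "SilentEdit",
    "scan_forbidden",
    "propose_silent_edits",
    "apply_edits",
    "domesticate",
]

NEW_SITE_WINDOW = 10  # nt each side rescanned after a candidate edit


class DomesticationError(GoldenGateError):
    """Edit planning or application failed."""


class UndomesticableSiteError(DomesticationError):
    """No synonymous substitution destroys the site."""


@dataclass(frozen=True)
class AnnotatedHit:
    """A forbidden site annotated with its coding context (if any)."""

    hit: SiteHit
    cds: object = None          # overlapping cds Feature or None
    frame: int = None           # recognition start phase within its codon

    @property
    def coding(self) -> bool:
        return self.cds is not None


@dataclass
class SilentEdit:
    """A synonymous substitution destroying one forbidden site."""

    position: int               # molecule/CDS coordinate of the edited codon
    before: str                 # original codon(s)
    after: str                  # replacement codon(s)
    destroyed_site: SiteHit = None
    protein_unchanged: bool = True
    new_sites_created: list = field(default_factory=list)

    def __post_init__(self):
        if self.before == self.after:
            raise DomesticationError("edit changes no bases")
        if len(self.before) != len(self.after) or len(self.before) % 3:
            raise DomesticationError("edits must substitute whole codons")

    @property
    def end(self) -> int:
        return self.position + len(self.before)

    @property
    def changed_bases(self) -> int:
        return sum(a != b for a, b in zip(self.before, self.after))


def _synonyms(table_id: int = 1) -> dict:
    """codon -> sorted list of synonymous codons (codon itself excluded)."""
    tab = CodonTable.unambiguous_dna_by_id[table_id]
    by_aa = {}
    for codon, aa in tab.forward_table.items():
        by_aa.setdefault(aa, []).append(codon)
    for stop in tab.stop_codons:
        by_aa.setdefault("*", []).append(stop)
    out = {}
    for codons in by_aa.values():
        for c in codons:
            out[c] = sorted(x for x in codons if x != c)
    return out


def scan_forbidden(mol: DnaMolecule, enzyme_names, enzymes: dict = None) -> list:
    """All forbidden-enzyme sites, each annotated with CDS overlap and frame.

    A hit overlapping an annotated ``cds`` feature carries that feature and
    the phase of the recognition start within its codon; other hits are
    non-coding.
    """
    out = []
    cds_feats = [f for f in mol.features if f.kind == "cds"]
    for name in enzyme_names:
        enz = get_enzyme(name, enzymes)
        for hit in locate_sites(mol, enz):
            ann = AnnotatedHit(hit)
            for f in cds_feats:
                if hit.recog_start < f.end and hit.recog_end > f.start:
                    if f.strand == 1:
                        frame = (hit.recog_start - f.start) % 3
                    else:
                        frame = (f.end - hit.recog_end) % 3
                    ann = AnnotatedHit(hit, f, frame)
                    break
            out.append(ann)
    out.sort(key=lambda a: (a.hit.recog_start, a.hit.enzyme))
    return out


def _window_hits(seq: str, lo: int, hi: int, enzyme_objs) -> list:
    """Forbidden hits whose recognition intersects [lo, hi) in a plain string."""
    mol = DnaMolecule("w", seq, "linear")
    found = []
    for enz in enzyme_objs:
        for h in locate_sites(mol, enz):
            if h.recog_start < hi and h.recog_end > lo:
                found.append(h)
    return found


def propose_silent_edits(cds: str, hits, enzyme_names=("BsaI", "BpiI", "Esp3I"),
                         codon_table: int = 1, enzymes: dict = None) -> list:
    """Plan one minimal synonymous edit per forbidden site inside a CDS.

    ``cds`` is the in-frame top-strand coding sequence; ``hits`` are
    :class:`SiteHit` (or :class:`AnnotatedHit`) with coordinates on ``cds``.
    Each returned edit substitutes a single codon, destroys its site on both
    strands and creates no new forbidden site within ``NEW_SITE_WINDOW`` nt.
    """
    if len(cds) % 3:
        raise FrameError(f"CDS length {len(cds)} not divisible by 3")
    cds = cds.upper()
    syn = _synonyms(codon_table)
    enzyme_objs = [get_enzyme(n, enzymes) for n in enzyme_names]
    edits = []
    work = cds
    for item in hits:
        hit = item.hit if isinstance(item, AnnotatedHit) else item
        s, e = hit.recog_start, hit.recog_end
        if not (0 <= s < e <= len(cds)):
            raise DomesticationError(
                f"manual intervention required: site at [{s},{e}) lies outside "
                "the CDS — consider a landing-pad (lacZ/ccdB) route instead"
            )
        codon_lo, codon_hi = s // 3, (e + 2) // 3
        lo = max(0, s - NEW_SITE_WINDOW)
        hi = min(len(work), e + NEW_SITE_WINDOW)
        baseline = {
            (h.enzyme, h.strand, h.recog_start)
            for h in _window_hits(work, lo, hi, enzyme_objs)
            if not (h.recog_start < e and h.recog_end > s)
        }
        candidates = []
        for ci in range(codon_lo, codon_hi):
            before = work[ci * 3: ci * 3 + 3]
            for alt in syn.get(before, []):
                trial = work[: ci * 3] + alt + work[ci * 3 + 3:]
                local = _window_hits(trial, lo, hi, enzyme_objs)
                # the targeted site must be gone ...
                if any(h.recog_start < e and h.recog_end > s for h in local):
                    continue
                # ... and nothing new created (pre-existing hits may remain)
                if {(h.enzyme, h.strand, h.recog_start) for h in local} - baseline:
                    continue
                changes = sum(a != b for a, b in zip(before, alt))
                candidates.append((changes, alt, ci, before))
        if not candidates:
            span = ", ".join(work[ci * 3: ci * 3 + 3]
                             for ci in range(codon_lo, codon_hi))
            raise UndomesticableSiteError(
                f"no synonymous option destroys the {hit.enzyme} site at "
                f"[{s},{e}); constrained codons: {span}"
            )
        changes, alt, ci, before = min(candidates)
        work = work[: ci * 3] + alt + work[ci * 3 + 3:]
        edits.append(SilentEdit(position=ci * 3, before=before, after=alt,
                                destroyed_site=hit))
    assert translate(work, codon_table) == translate(cds, codon_table)
    return edits


def apply_edits(mol: DnaMolecule, edits, enzyme_names=("BsaI", "BpiI", "Esp3I"),
                offset: int = 0, enzymes: dict = None):
    """Apply non-overlapping edits to a molecule; verify the outcome.

    ``offset`` translates CDS-relative edit coordinates to molecule
    coordinates.  Returns ``(edited_molecule, log)`` where the log is a list
    of human-readable strings.  After editing, the targeted enzymes must
    find no site and every annotated CDS must translate unchanged.
    """
    spans = sorted(((e.position + offset, e.end + offset, e) for e in edits),
                   key=lambda t: (t[0], t[1]))
    for (s1, e1, _), (s2, e2, _) in zip(spans, spans[1:]):
        if s2 < e1:
            raise DomesticationError(
                f"overlapping edits at [{s1},{e1}) and [{s2},{e2})"
            )
    seq = mol.seq
    log = []
    for s, e, edit in spans:
        if seq[s:e] != edit.before:
            raise DomesticationError(
                f"edit mismatch at {s}: molecule has {seq[s:e]}, "
                f"edit expects {edit.before}"
            )
        seq = seq[:s] + edit.after + seq[e:]
        log.append(f"{s}: {edit.before} -> {edit.after} "
                   f"(destroys {edit.destroyed_site.enzyme if edit.destroyed_site else '?'} site)")
    out = DnaMolecule(mol.id + "_dom" if edits else mol.id, seq, mol.topology,
                      [replace(f) for f in mol.features])
    if edits:
        remaining = scan_forbidden(out, enzyme_names, enzymes)
        targeted = {get_enzyme(n, enzymes).name for n in enzyme_names}
        leftover = [a for a in remaining if a.hit.enzyme in targeted]
        if leftover:
            raise DomesticationError(
                f"{len(leftover)} forbidden site(s) remain after editing"
            )
    for f in out.features:
        if f.kind == "cds" and f.strand == 1 and (f.end - f.start) % 3 == 0:
            if translate(out.seq[f.start:f.end]) != translate(mol.seq[f.start:f.end]):
                raise DomesticationError(
                    f"edit altered the protein of CDS {f.label!r}"
                )
    return out, log


def domesticate(mol: DnaMolecule, enzyme_names=("BsaI", "BpiI", "Esp3I"),
                codon_table: int = 1, enzymes: dict = None):
    """End-to-end pipeline: scan, plan silent edits for coding hits, apply.

    Raises :class:`DomesticationError` if any forbidden site lies outside an
    annotated plus-strand CDS (those need the landing-pad route).
    Returns ``(edited_molecule, edits, log)``.
    """
    annotated = scan_forbidden(mol, enzyme_names, enzymes)
    if not annotated:
        return mol, [], []
    all_edits = []
    by_cds = {}
    for ann in annotated:
        if not ann.coding or ann.cds.strand != 1:
            raise DomesticationError(
                f"manual intervention required: {ann.hit.enzyme} site at "
                f"{ann.hit.recog_start} is not inside a plus-strand CDS — "
                "consider a landing-pad (lacZ/ccdB) route"
            )
        by_cds.setdefault((ann.cds.start, ann.cds.end), []).append(ann)
    for (start, end), anns in by_cds.items():
        cds_seq = mol.seq[start:end]
        rebased = [
            SiteHit(a.hit.enzyme, a.hit.strand, a.hit.recog_start - start,
                    a.hit.recog_end - start, a.hit.cut_top_pos - start,
                    a.hit.cut_bottom_pos - start)
            for a in anns
        ]
        edits = propose_silent_edits(cds_seq, rebased, enzyme_names,
                                     codon_table, enzymes)
        all_edits.extend(replace(e, position=e.position + start) for e in edits)
    out, log = apply_edits(mol, all_edits, enzyme_names, offset=0, enzymes=enzymes)
    return out, all_edits, log
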