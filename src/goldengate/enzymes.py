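"""Restriction enzyme definitions and the digestion engine.

Type IIS enzymes recognise a non-palindromic sequence and cut at a fixed
offset *outside* it, leaving a programmable single-stranded extension — the
property Golden Gate cloning exploits.  The shipped definition file also
contains a handful of ordinary palindromic (type IIP) enzymes used only as a
linearization panel; they cut inside their site (negative offsets).

Cut offsets are measured in nucleotides from the 3' end of the top-strand
recognition sequence to the cut on each strand.  For a +strand site with
recognition interval ``[s, e)``::

    top-strand cut     at  e + cut_top
    bottom-strand cut  at  e + cut_bottom

``cut_bottom - cut_top > 0`` yields a 5' extension of that length,
``== 0`` a blunt cut, ``< 0`` a 3' extension.  Minus-strand sites mirror
these offsets leftward: top cut at ``s - cut_bottom``, bottom cut at
``s - cut_top``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources

from .seqcore import DnaMolecule, GoldenGateError, Overhang, revcomp

__all__ = [
    "TypeIISEnzyme",
    "SiteHit",
    "StickyFragment",
    "DigestError",
    "UnknownEnzymeError",
    "load_enzymes",
    "default_enzymes",
    "get_enzyme",
    "locate_sites",
    "digest",
    "find_unique_cutters",
]


class DigestError(GoldenGateError):
    """Digestion cannot proceed (colliding cuts, cut off a linear end, ...)."""


class UnknownEnzymeError(GoldenGateError, KeyError):
    """Enzyme name absent from the definition set."""


@dataclass(frozen=True)
class TypeIISEnzyme:
    """Recognition pattern plus asymmetric cut offsets."""

    name: str
    recognition: str
    cut_top: int
    cut_bottom: int

    @property
    def overhang_length(self) -> int:
        """Signed extension length: positive = 5' extension, 0 = blunt."""
        return self.cut_bottom - self.cut_top

    @property
    def is_palindromic(self) -> bool:
        return self.recognition == revcomp(self.recognition)

    @property
    def is_type_iis(self) -> bool:
        # type IIS: cuts fall outside the recognition interval
        return min(self.cut_top, self.cut_bottom) >= 0


@dataclass(frozen=True)
class SiteHit:
    """One recognition match with its absolute cut coordinates.

    Coordinates are top-strand, possibly extending past the sequence end for
    sites near a circle's origin (callers take them modulo length).
    """

    enzyme: str
    strand: int
    recog_start: int
    recog_end: int
    cut_top_pos: int
    cut_bottom_pos: int


@dataclass
class StickyFragment:
    """A duplex core with typed single-stranded extensions at each end.

    ``seq`` is the top strand between consecutive top-strand cuts, so a 5'
    left extension appears as a prefix of ``seq`` while the right extension's
    bases live on the mating strand and are recorded top-strand-equivalently
    in ``right_overhang``.  Summing ``len(seq)`` over the fragments of one
    digest therefore conserves nucleotide count exactly.
    """

    seq: str
    left_overhang: Overhang
    right_overhang: Overhang
    source: tuple = ("", (0, 0))
    features: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.seq)

    def as_molecule(self, mol_id: str = None) -> DnaMolecule:
        return DnaMolecule(mol_id or f"{self.source[0]}_frag", self.seq, "linear",
                           [replace(f) for f in self.features])


def load_enzymes(path=None) -> dict:
    """Load enzyme definitions (name -> TypeIISEnzyme) from a JSON file.

    Without a path, the shipped definition set is loaded.  The file is a JSON
    list of ``{name, recognition, cut_top, cut_bottom}`` and is
    user-extensible.
    """
    if path is None:
        text = resources.files("goldengate.data").joinpath("enzymes.json").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    out = {}
    for entry in json.loads(text):
        enz = TypeIISEnzyme(entry["name"], entry["recognition"].upper(),
                            int(entry["cut_top"]), int(entry["cut_bottom"]))
        out[enz.name] = enz
    return out


_DEFAULTS = None


def default_enzymes() -> dict:
    global _DEFAULTS
    if _DEFAULTS is None:
        _DEFAULTS = load_enzymes()
    return _DEFAULTS


def get_enzyme(name, enzymes: dict = None) -> TypeIISEnzyme:
    if isinstance(name, TypeIISEnzyme):
        return name
    db = enzymes if enzymes is not None else default_enzymes()
    try:
        return db[name]
    except KeyError:
        raise UnknownEnzymeError(f"enzyme {name!r} not defined") from None


def _scan(seq: str, pattern: str, circular: bool):
    """Yield start positions (0..len-1) of ``pattern`` on the top strand."""
    n, k = len(seq), len(pattern)
    hay = seq + seq[: k - 1] if circular else seq
    i = hay.find(pattern)
    while i != -1:
        if i < n:
            yield i
        i = hay.find(pattern, i + 1)


def locate_sites(mol: DnaMolecule, enzyme, enzymes: dict = None) -> list:
    """Find all recognition sites on both strands, sorted by position.

    Circular molecules are scanned across the origin.  For palindromic
    enzymes each physical site is reported once (+ strand).
    """
    enz = get_enzyme(enzyme, enzymes)
    hits = []
    for s in _scan(mol.seq, enz.recognition, mol.is_circular):
        e = s + len(enz.recognition)
        hits.append(SiteHit(enz.name, 1, s, e,
                            e + enz.cut_top, e + enz.cut_bottom))
    if not enz.is_palindromic:
        rc = revcomp(enz.recognition)
        for s in _scan(mol.seq, rc, mol.is_circular):
            e = s + len(rc)
            hits.append(SiteHit(enz.name, -1, s, e,
                                s - enz.cut_bottom, s - enz.cut_top))
    hits.sort(key=lambda h: (h.recog_start, h.strand))
    return hits


def digest(mol: DnaMolecule, enzyme, enzymes: dict = None) -> list:
    """Complete digest: all sites cut simultaneously.

    Returns a list of :class:`StickyFragment` — a linear input with *n* sites
    gives *n*+1 fragments, a circular input *n*.  A molecule with no sites is
    returned unchanged as ``[mol]``.  Overlapping staggered cut windows raise
    :class:`DigestError` naming both sites.
    """
    enz = get_enzyme(enzyme, enzymes)
    hits = locate_sites(mol, enz)
    if not hits:
        return [mol]
    n = len(mol.seq)

    # (top_cut, bottom_cut, hit) in unrolled top coordinates: the staggered
    # window keeps its true span and its low end lies in [0, n)
    cuts = []
    for h in hits:
        t, b = h.cut_top_pos, h.cut_bottom_pos
        if mol.is_circular:
            span = b - t
            t %= n
            b = t + span
            if b < 0:
                t, b = t + n, b + n
        else:
            if min(t, b) < 0 or max(t, b) > n:
                raise DigestError(
                    f"{h.enzyme} site at {h.recog_start} cuts beyond the end "
                    f"of linear molecule {mol.id!r}"
                )
        cuts.append((t, b, h))
    cuts.sort(key=lambda c: (min(c[0], c[1]), max(c[0], c[1])))

    def _collide(c1, c2, offset=0):
        hi1 = max(c1[0], c1[1])
        lo2 = min(c2[0], c2[1]) + offset
        if lo2 < hi1 and not (c1[0] == c1[1] == lo2):
            raise DigestError(
                f"colliding cuts: {c1[2].enzyme} site at {c1[2].recog_start} "
                f"and {c2[2].enzyme} site at {c2[2].recog_start} overlap on "
                f"{mol.id!r}"
            )

    for c1, c2 in zip(cuts, cuts[1:]):
        _collide(c1, c2)
    if mol.is_circular and len(cuts) > 1:
        _collide(cuts[-1], cuts[0], offset=n)

    def overhang_for(t, b):
        if t == b:
            return Overhang.blunt()
        lo, hi = min(t, b), max(t, b)
        seq = mol.subseq(lo % n, hi % n) if mol.is_circular else mol.seq[lo:hi]
        return Overhang(seq, "five_prime" if b > t else "three_prime")

    frags = []
    if mol.is_circular:
        for i, (t, b, h) in enumerate(cuts):
            t2, b2, h2 = cuts[(i + 1) % len(cuts)]
            end = t2 if i + 1 < len(cuts) else t2 + n
            if end <= t:
                end += n
            seq = (mol.seq * 2)[t % n: t % n + (end - t)]
            frags.append(StickyFragment(seq, overhang_for(t, b),
                                        overhang_for(t2, b2),
                                        (mol.id, (t % n, end % n)),
                                        _features_in(mol, t % n, t % n + (end - t))))
    else:
        bounds = [(0, 0, None)] + cuts + [(n, n, None)]
        for (t, b, h), (t2, b2, h2) in zip(bounds, bounds[1:]):
            left = Overhang.blunt() if h is None else overhang_for(t, b)
            right = Overhang.blunt() if h2 is None else overhang_for(t2, b2)
            frags.append(StickyFragment(mol.seq[t:t2], left, right,
                                        (mol.id, (t, t2)),
                                        _features_in(mol, t, t2)))
    return frags


def _features_in(mol: DnaMolecule, start: int, end: int) -> list:
    """Features wholly contained in the unrolled top interval [start, end).

    Features severed by a cut are dropped (they have been destroyed).
    """
    n = len(mol.seq)
    out = []
    for f in mol.features:
        fs, fe = f.start, f.end
        if fe <= fs:  # origin-spanning feature on a circle
            fe += n
        shifts = (0, n, -n) if mol.is_circular else (0,)
        for shift in shifts:
            if start <= fs + shift and fe + shift <= end:
                out.append(replace(f, start=fs + shift - start,
                                   end=fe + shift - start))
                break
    return out


def find_unique_cutters(mol: DnaMolecule, candidates: list, enzymes: dict = None) -> list:
    """Names among ``candidates`` with exactly one site in ``mol``.

    Used to pick linearization enzymes ahead of in-vitro transcription.
    """
    out = []
    for name in candidates:
        enz = get_enzyme(name, enzymes)  # raises UnknownEnzymeError
        if len(locate_sites(mol, enz)) == 1:
            out.append(enz.name)
    return out
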