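"""Part registry, GenBank/FASTA I/O and the synthetic fixture kit.

The fixture kit builds, from a seed and a fusion-site table alone, every
molecule class the platform manipulates: universal entry backbones (with a
counter-selection stuffer between the directional entry junctions), entry
(LI) part plasmids for each position span including dummies and a lacZ-style
landing pad, level-2 backbones for the five transcription-unit slots, and a
level-3 backbone — so the complete LI -> LII -> LIII chain can be exercised
with no external data.  All filler sequence is scrubbed of every assembly
enzyme's recognition pattern, then each finished molecule is checked for the
exact expected site counts (regenerating fillers on the rare chance a
junction concatenation recreated a site), so generation is deterministic in
the seed.
"""

from __future__ import annotations

import json
import os
import random
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, CompoundLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .enzymes import get_enzyme, locate_sites, revcomp
from .grammar import FusionSiteTable, default_grammar
from .seqcore import DnaMolecule, Feature, GoldenGateError

__all__ = [
    "RegistryError",
    "PartRecord",
    "FixtureKit",
    "read_genbank",
    "write_genbank",
    "read_fasta",
    "write_fasta",
    "generate_fixture_kit",
    "save_registry",
    "load_registry",
    "validate_registry",
]

ASSEMBLY_ENZYMES = ("BsaI", "BpiI", "Esp3I", "SapI", "AarI", "MlyI")
LINEARIZATION_PANEL = ("EcoRI", "HindIII", "XbaI", "PstI", "SphI", "NotI")

_KIND_TO_GB = {
    "cds": "CDS",
    "origin": "rep_origin",
    "selection_marker": "misc_feature",
    "counter_selection": "misc_feature",
    "part_payload": "misc_feature",
    "misc": "misc_feature",
}
_GB_TO_KIND = {"CDS": "cds", "rep_origin": "origin"}


class RegistryError(GoldenGateError):
    """Registry inconsistency or I/O failure."""


@dataclass
class PartRecord:
    """Registry entry: which molecule provides which part or backbone."""

    id: str
    level: str                 # LI | LII | LIII | backbone
    position: str              # span like "A-B"/"1-2", or backbone slot name
    molecule_id: str
    notes: str = ""


# ---------------------------------------------------------------------------
# standard-format I/O


def write_genbank(mol: DnaMolecule, path) -> None:
    """Write a molecule as a GenBank flat file (topology on the LOCUS line)."""
    rec = SeqRecord(Seq(mol.seq), id=mol.id, name=mol.id[:16],
                    description="", annotations={
                        "molecule_type": "DNA",
                        "topology": mol.topology,
                        "data_file_division": "SYN",
                    })
    n = len(mol.seq)
    for f in mol.features:
        strand = f.strand
        if f.end <= f.start:  # origin-spanning on a circle
            loc = CompoundLocation([FeatureLocation(f.start, n, strand),
                                    FeatureLocation(0, f.end, strand)])
        else:
            loc = FeatureLocation(f.start, f.end, strand)
        quals = {"label": [f.label], "gg_kind": [f.kind]}
        for k, v in f.qualifiers.items():
            quals[k] = [str(v)]
        rec.features.append(SeqFeature(loc, type=_KIND_TO_GB.get(f.kind, "misc_feature"),
                                       qualifiers=quals))
    SeqIO.write([rec], str(path), "genbank")


def read_genbank(path) -> DnaMolecule:
    """Read a GenBank flat file into a molecule.

    Sequence/topology/features used by this system round-trip losslessly;
    unknown feature keys are preserved as ``misc``.  Degenerate bases are
    rejected at parse time.
    """
    try:
        rec = SeqIO.read(str(path), "genbank")
    except ValueError as exc:
        raise RegistryError(f"malformed GenBank file {path}: {exc}") from exc
    topology = rec.annotations.get("topology", "linear")
    n = len(rec.seq)
    feats = []
    for sf in rec.features:
        if sf.type == "source":
            continue
        kind = sf.qualifiers.get("gg_kind", [None])[0] \
            or _GB_TO_KIND.get(sf.type, "misc")
        label = sf.qualifiers.get("label",
                                  sf.qualifiers.get("gene",
                                                    sf.qualifiers.get("note", [sf.type])))[0]
        loc = sf.location
        parts = getattr(loc, "parts", [loc])
        if len(parts) == 2 and int(parts[0].end) == n and int(parts[1].start) == 0:
            start, end = int(parts[0].start), int(parts[1].end)  # wraps origin
        else:
            start, end = int(loc.start), int(loc.end)
        quals = {k: v[0] for k, v in sf.qualifiers.items()
                 if k not in ("label", "gg_kind") and v}
        feats.append(Feature(label, kind, start, end,
                             1 if (loc.strand or 1) >= 0 else -1, quals))
    return DnaMolecule(rec.id if rec.id not in ("", "<unknown id>") else rec.name,
                       str(rec.seq), topology, feats)


def write_fasta(mols, path) -> None:
    recs = [SeqRecord(Seq(m.seq), id=m.id, description="") for m in mols]
    SeqIO.write(recs, str(path), "fasta")


def read_fasta(path) -> list:
    return [DnaMolecule(r.id, str(r.seq), "linear")
            for r in SeqIO.parse(str(path), "fasta")]


# ---------------------------------------------------------------------------
# fixture generation


def _forbidden_patterns(extra=()):
    pats = []
    for name in tuple(ASSEMBLY_ENZYMES) + tuple(LINEARIZATION_PANEL) + tuple(extra):
        rec = get_enzyme(name).recognition
        pats.append(rec)
        if rec != revcomp(rec):
            pats.append(revcomp(rec))
    return pats


def _clean_random(rng: random.Random, n: int, patterns) -> str:
    """Random sequence of length n free of all patterns (both strands)."""
    seq = "".join(rng.choice("ACGT") for _ in range(n))
    for _round in range(200):
        hit = None
        for pat in patterns:
            i = seq.find(pat)
            if i != -1:
                hit = (i, pat)
                break
        if hit is None:
            return seq
        i, pat = hit
        j = i + rng.randrange(len(pat))
        seq = seq[:j] + rng.choice([b for b in "ACGT" if b != seq[j]]) + seq[j + 1:]
    raise RegistryError("could not scrub filler sequence of forbidden sites")


class _Builder:
    """Accumulates (segment, feature) layout for one synthetic molecule."""

    def __init__(self):
        self.chunks = []
        self.features = []

    def add(self, seq, label=None, kind="misc", strand=1, **quals):
        start = sum(len(c) for c in self.chunks)
        self.chunks.append(seq)
        if label is not None:
            self.features.append(Feature(label, kind, start, start + len(seq),
                                         strand, quals))
        return self

    def molecule(self, mol_id, topology="circular") -> DnaMolecule:
        return DnaMolecule(mol_id, "".join(self.chunks), topology, self.features)


@dataclass
class FixtureKit:
    """Deterministic synthetic registry covering the full assembly chain."""

    grammar: FusionSiteTable
    seed: int
    molecules: dict = field(default_factory=dict)
    records: list = field(default_factory=list)

    def add(self, mol: DnaMolecule, level: str, position: str, notes: str = ""):
        if mol.id in self.molecules:
            raise RegistryError(f"duplicate registry id {mol.id!r}")
        self.molecules[mol.id] = mol
        self.records.append(PartRecord(mol.id, level, position, mol.id, notes))

    def __getitem__(self, mol_id) -> DnaMolecule:
        return self.molecules[mol_id]

    def li_part(self, left: str, right: str) -> DnaMolecule:
        return self[f"li-{left.lower()}{right.lower()}"]

    def dummy(self, left: str, right: str) -> DnaMolecule:
        return self[f"li-dmy-{left.lower()}{right.lower()}"]

    @property
    def dummies(self) -> dict:
        labels = self.grammar.labels("LI->LII")
        out = {}
        for a, b in zip(labels, labels[1:]):
            mol_id = f"li-dmy-{a.lower()}{b.lower()}"
            if mol_id in self.molecules:
                out[(a, b)] = self.molecules[mol_id]
        return out

    def lii_backbone(self, left: str, right: str) -> DnaMolecule:
        return self[f"lii-bb-{left}{right}"]


def _expect_counts(mol, expected) -> bool:
    return all(len(locate_sites(mol, enz)) == cnt for enz, cnt in expected.items())


def _retry(build_fn, rng, expected, tries=100) -> DnaMolecule:
    for _ in range(tries):
        mol = build_fn(rng)
        if _expect_counts(mol, expected):
            return mol
    raise RegistryError(f"could not build clean fixture {mol.id!r}")


def generate_fixture_kit(seed: int, grammar: FusionSiteTable = None) -> FixtureKit:
    """Build the complete synthetic molecule registry (deterministic in seed)."""
    table = grammar or default_grammar()
    rng = random.Random(seed)
    kit = FixtureKit(table, seed)
    pats = _forbidden_patterns()
    eL, eR = table.entry
    sp2 = "CA"   # 2-nt spacer matching BpiI's cut offset
    sp1 = "A"    # 1-nt spacer matching BsaI/Esp3I's cut offset
    BSA = get_enzyme("BsaI").recognition
    BPI = get_enzyme("BpiI").recognition
    ESP = get_enzyme("Esp3I").recognition

    def entry_backbone(rng_, entry_enzyme, mol_id):
        enz = get_enzyme(entry_enzyme)
        sp = "CA"[: enz.cut_top]  # spacer sized to the enzyme's cut offset
        b = _Builder()
        b.add(_clean_random(rng_, 220, pats), "backbone-core", "misc")
        b.add(_clean_random(rng_, 60, pats), "ori", "origin")
        b.add(_clean_random(rng_, 90, pats), "GmR", "selection_marker",
              marker="gentamicin")
        b.add(eL)
        b.add(sp + revcomp(enz.recognition))
        b.add(_clean_random(rng_, 120, pats), "ccdB", "counter_selection",
              counter="ccdB")
        b.add(enz.recognition + sp)
        b.add(eR)
        return b.molecule(mol_id)

    for enzname, name in (("BpiI", "p-entry-bpi"), ("Esp3I", "p-entry-esp3i")):
        expected = {e: 0 for e in ASSEMBLY_ENZYMES}
        expected[enzname] = 2
        kit.add(_retry(lambda r, z=enzname, m=name: entry_backbone(r, z, m),
                       rng, expected),
                "backbone", "entry", f"universal acceptor ({enzname})")

    labels2 = table.labels("LI->LII")
    payload_names = {
        ("A", "B"): "promoter", ("B", "C"): "n-tag", ("C", "D"): "orf",
        ("D", "E"): "c-tag", ("E", "F"): "terminator", ("F", "G"): "extra",
    }

    def li_plasmid(rng_, mol_id, core_builder, extra_expected=None):
        def build(r):
            b = _Builder()
            b.add(_clean_random(r, 180, pats), "backbone-core", "misc")
            b.add(_clean_random(r, 60, pats), "ori", "origin")
            b.add(_clean_random(r, 90, pats), "GmR", "selection_marker",
                  marker="gentamicin")
            b.add(eL)
            b.add(BSA + sp1)
            core_builder(r, b)
            b.add(sp1 + revcomp(BSA))
            b.add(eR)
            return b.molecule(mol_id)
        expected = {e: 0 for e in ASSEMBLY_ENZYMES}
        expected["BsaI"] = 2
        if extra_expected:
            expected.update(extra_expected)
        return _retry(build, rng_, expected)

    for (a, b2), payload in payload_names.items():
        fsL, fsR = table.level2[a], table.level2[b2]
        if payload == "orf":
            def core(r, bld, fsL=fsL, fsR=fsR):
                bld.add(fsL)
                cds = _scrub_cds(r, 24, pats)
                bld.add(cds, "orf", "cds")
                bld.add(fsR)
        else:
            def core(r, bld, fsL=fsL, fsR=fsR, payload=payload):
                bld.add(fsL)
                bld.add(_clean_random(r, 66, pats), payload, "part_payload")
                bld.add(fsR)
        kit.add(li_plasmid(rng, f"li-{a.lower()}{b2.lower()}", core),
                "LI", f"{a}-{b2}", f"{payload} part")

    for a, b2 in zip(labels2, labels2[1:]):
        fsL, fsR = table.level2[a], table.level2[b2]

        def dmy_core(r, bld, fsL=fsL, fsR=fsR, a=a, b2=b2):
            bld.add(fsL)
            bld.add(_clean_random(r, 30, pats), f"DMY-{a}{b2}", "part_payload")
            bld.add(fsR)
        kit.add(li_plasmid(rng, f"li-dmy-{a.lower()}{b2.lower()}", dmy_core),
                "LI", f"{a}-{b2}", "dummy filler part")

    # landing pad: A-B part whose payload is a lacZ stuffer flanked by
    # inward Esp3I sites releasing the directional entry overhangs
    fsA, fsB = table.level2["A"], table.level2["B"]

    def pad_core(r, bld):
        bld.add(fsA)
        bld.add(eL)
        bld.add(sp1 + revcomp(ESP))
        bld.add(_clean_random(r, 80, pats), "lacZ", "counter_selection",
                counter="lacZ")
        bld.add(ESP + sp1)
        bld.add(eR)
        bld.add(fsB)
    kit.add(li_plasmid(rng, "li-pad-lacz-ab", pad_core,
                       extra_expected={"Esp3I": 2}),
            "LI", "A-B", "lacZ landing pad (Esp3I re-entry)")

    # level-2 backbones for each transcription-unit slot, with the
    # linearization panel inserted once each into the core
    labels3 = table.labels("LII->LIII")
    fsG = table.level2[labels2[-1]]
    fs1 = table.level2[labels2[0]]
    panel_sites = [get_enzyme(n).recognition for n in LINEARIZATION_PANEL]

    def lii_backbone(rng_, mol_id, o_left, o_right):
        def build(r):
            b = _Builder()
            b.add(_clean_random(r, 150, pats), "backbone-core", "misc")
            for name, site in zip(LINEARIZATION_PANEL, panel_sites):
                b.add(_clean_random(r, 8, pats))
                b.add(site, f"{name}-site", "misc")
            b.add(_clean_random(r, 40, pats), "oriT", "misc")
            b.add(_clean_random(r, 60, pats), "ori", "origin")
            b.add(_clean_random(r, 90, pats), "SpR", "selection_marker",
                  marker="spectinomycin")
            b.add(BPI + sp2)
            b.add(o_left)
            b.add(_clean_random(r, 10, pats))
            b.add(fs1)
            b.add(sp1 + revcomp(BSA))
            b.add(_clean_random(r, 120, pats), "ccdB", "counter_selection",
                  counter="ccdB")
            b.add(BSA + sp1)
            b.add(fsG)
            b.add(_clean_random(r, 10, pats))
            b.add(o_right)
            b.add(sp2 + revcomp(BPI))
            return b.molecule(mol_id)
        expected = {e: 0 for e in ASSEMBLY_ENZYMES}
        expected.update({"BsaI": 2, "BpiI": 2})
        expected.update({n: 1 for n in LINEARIZATION_PANEL})
        return _retry(build, rng_, expected)

    for j, k in zip(labels3, labels3[1:]):
        o_l, o_r = table.level3[j], table.level3[k]
        kit.add(lii_backbone(rng, f"lii-bb-{j}{k}", o_l, o_r),
                "backbone", f"{j}-{k}", "transcription-unit slot backbone")

    # level-3 backbone
    o_first, o_last = table.level3[labels3[0]], table.level3[labels3[-1]]

    def liii_backbone(r):
        b = _Builder()
        b.add(_clean_random(r, 200, pats), "backbone-core", "misc")
        b.add(_clean_random(r, 60, pats), "ori", "origin")
        b.add(_clean_random(r, 90, pats), "KanR", "selection_marker",
              marker="kanamycin")
        b.add(o_first)
        b.add(sp2 + revcomp(BPI))
        b.add(_clean_random(r, 120, pats), "ccdB", "counter_selection",
              counter="ccdB")
        b.add(BPI + sp2)
        b.add(o_last)
        return b.molecule("liii-bb")
    expected = {e: 0 for e in ASSEMBLY_ENZYMES}
    expected["BpiI"] = 2
    kit.add(_retry(liii_backbone, rng, expected), "backbone", "LIII",
            "multi-unit backbone")

    # a CDS template carrying one deliberate internal BsaI site, for
    # domestication exercises (GGT-CTC sits on a Gly/Leu codon boundary)
    def dom_template(r):
        b = _Builder()
        head = "ATG" + "".join(r.choice(_CODONS_NO_STOP) for _ in range(8))
        tail = "".join(r.choice(_CODONS_NO_STOP) for _ in range(8)) + "TAA"
        cds = head + "GGTCTC" + tail
        b.add(cds, "orf", "cds")
        return b.molecule("cds-with-bsai", "linear")
    expected = {e: 0 for e in ASSEMBLY_ENZYMES}
    expected["BsaI"] = 1
    kit.add(_retry(dom_template, rng, expected), "template", "C-D",
            "domestication exercise template (internal BsaI site)")

    # wild-type genotyping amplicon with one central MlyI site
    def amplicon(r):
        b = _Builder()
        b.add(_clean_random(r, 55, pats))
        b.add("GAGTC", "target-site", "misc")
        b.add(_clean_random(r, 60, pats))
        return b.molecule("wt-amplicon", "linear")
    expected = {e: 0 for e in ASSEMBLY_ENZYMES}
    expected["MlyI"] = 1
    kit.add(_retry(amplicon, rng, expected), "template", "amplicon",
            "site-loss genotyping reference")

    return kit


_CODONS_NO_STOP = sorted(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
)


def _scrub_cds(rng, n_codons, patterns) -> str:
    """An ATG...stop CDS whose codons avoid the forbidden patterns."""
    for _ in range(200):
        cds = "ATG" + "".join(rng.choice(_CODONS_NO_STOP)
                              for _ in range(n_codons)) + "TAA"
        if not any(p in cds for p in patterns):
            return cds
    raise RegistryError("could not build a clean CDS")


# ---------------------------------------------------------------------------
# registry persistence and validation


def save_registry(kit: FixtureKit, directory) -> None:
    """One JSON index plus per-molecule GenBank files (human-diffable)."""
    os.makedirs(directory, exist_ok=True)
    index = {
        "seed": kit.seed,
        "records": [vars(r) for r in kit.records],
    }
    with open(os.path.join(directory, "index.json"), "w") as fh:
        json.dump(index, fh, indent=2)
    for mol in kit.molecules.values():
        write_genbank(mol, os.path.join(directory, f"{mol.id}.gb"))


def load_registry(directory, grammar: FusionSiteTable = None) -> FixtureKit:
    with open(os.path.join(directory, "index.json")) as fh:
        index = json.load(fh)
    kit = FixtureKit(grammar or default_grammar(), index.get("seed", 0))
    for rec in index["records"]:
        mol = read_genbank(os.path.join(directory, f"{rec['molecule_id']}.gb"))
        kit.add(mol, rec["level"], rec["position"], rec.get("notes", ""))
    return kit


def validate_registry(kit: FixtureKit) -> list:
    """Cross-check declared vs inferred positions for every LI part record.

    Returns a list of problem strings (empty == registry consistent).
    """
    from .grammar import infer_position

    problems = []
    for rec in kit.records:
        if rec.level != "LI" or "-" not in rec.position:
            continue
        left, right = rec.position.split("-")
        if left not in kit.grammar.labels("LI->LII"):
            continue
        try:
            spec, _frag = infer_position(kit.molecules[rec.molecule_id],
                                         kit.grammar, "LI->LII")
        except GoldenGateError as exc:
            problems.append(f"{rec.id}: {exc}")
            continue
        if (spec.left, spec.right) != (left, right):
            problems.append(
                f"{rec.id}: declared {rec.position}, inferred {spec}"
            )
    return problems
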