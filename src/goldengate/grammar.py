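"""The hierarchical position grammar: fusion-site tables and position inference.

Entry-level (LI) parts are flanked by level-2 enzyme sites that release them
with two 4-nt fusion sites; the pair of fusion sites *is* the part's
position.  The level-2 junction chain A..G defines six part slots (promoter
A-B, N-tag B-C, ORF C-D, C-tag D-E, terminator E-F, extra F-G); the level-3
chain 1..6 defines five transcription-unit slots.  Fusion-site sequences are
entirely config-driven: the shipped default table is a documented toy set
that passes every fidelity rule, and users can substitute the table of any
real system.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

from .enzymes import StickyFragment, digest, get_enzyme, locate_sites
from .fidelity import check_overhang_set
from .seqcore import DnaMolecule, GoldenGateError

__all__ = [
    "GrammarError",
    "AmbiguousReleaseError",
    "UnknownJunctionError",
    "FusionSiteTable",
    "PositionSpec",
    "load_grammar",
    "default_grammar",
    "infer_position",
]

LEVELS = ("LI->LII", "LII->LIII")


class GrammarError(GoldenGateError):
    """Malformed or fidelity-violating fusion-site table."""


class AmbiguousReleaseError(GoldenGateError):
    """Digestion did not release exactly one candidate insert."""


class UnknownJunctionError(GoldenGateError):
    """A released overhang is not a junction of the table."""


@dataclass(frozen=True)
class PositionSpec:
    """A contiguous [left, right) span of junction labels at one level."""

    level: str
    left: str
    right: str

    def __post_init__(self):
        if self.level not in LEVELS:
            raise GrammarError(f"level must be one of {LEVELS}, got {self.level!r}")

    def __str__(self):
        return f"{self.left}-{self.right}"


@dataclass
class FusionSiteTable:
    """Ordered junction-label -> overhang maps for each assembly level."""

    level2: dict
    level3: dict
    entry: tuple
    enzymes: dict

    def __post_init__(self):
        self.entry = tuple(self.entry)
        for name, mapping in (("level2", self.level2), ("level3", self.level3),
                              ("entry", dict(zip(("L", "R"), self.entry)))):
            report = check_overhang_set(list(mapping.values()))
            if not report.passed:
                raise GrammarError(f"{name} junction set fails fidelity rules: "
                                   f"{report.summary()}")
        for key in ("entry", "level2", "level3"):
            if key not in self.enzymes:
                raise GrammarError(f"missing enzyme assignment for {key!r}")

    def labels(self, level: str) -> list:
        return list(self.level2 if level == "LI->LII" else self.level3)

    def junctions(self, level: str) -> dict:
        return dict(self.level2 if level == "LI->LII" else self.level3)

    def enzyme_for(self, level: str) -> str:
        return self.enzymes["level2"] if level == "LI->LII" else self.enzymes["level3"]

    def slots(self, level: str) -> int:
        """Number of single-span part slots the junction chain admits."""
        return len(self.labels(level)) - 1

    def overhang(self, level: str, label: str) -> str:
        try:
            return self.junctions(level)[label]
        except KeyError:
            raise UnknownJunctionError(f"no junction {label!r} at level {level}") from None

    def label_of(self, level: str, overhang: str) -> str:
        for lab, o in self.junctions(level).items():
            if o == overhang.upper():
                return lab
        raise UnknownJunctionError(
            f"overhang {overhang!r} is not a {level} junction of this table"
        )

    def span(self, level: str, left: str, right: str) -> PositionSpec:
        labels = self.labels(level)
        if left not in labels or right not in labels:
            raise UnknownJunctionError(f"unknown junction label {left!r} or {right!r}")
        if labels.index(left) >= labels.index(right):
            raise GrammarError(f"span {left}-{right} is empty or reversed")
        return PositionSpec(level, left, right)


def load_grammar(path=None) -> FusionSiteTable:
    """Load and validate a fusion-site table from a JSON config.

    Config shape: ``{"level2": {"A": "XXXX", ...}, "level3": {...},
    "entry": [l, r], "enzymes": {"entry": ..., "level2": ..., "level3": ...}}``.
    Validation failures carry fidelity-rule diagnostics naming the offending
    junctions.
    """
    if path is None:
        text = resources.files("goldengate.data").joinpath("default_grammar.json").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    cfg = json.loads(text)
    try:
        table = FusionSiteTable(
            level2={k: v.upper() for k, v in cfg["level2"].items()},
            level3={k: v.upper() for k, v in cfg["level3"].items()},
            entry=tuple(v.upper() for v in cfg["entry"]),
            enzymes=dict(cfg["enzymes"]),
        )
    except KeyError as exc:
        raise GrammarError(f"grammar config missing key {exc}") from None
    return table


_DEFAULT = None


def default_grammar() -> FusionSiteTable:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = load_grammar()
    return _DEFAULT


def infer_position(mol: DnaMolecule, table: FusionSiteTable, level: str,
                   enzymes: dict = None):
    """Infer the label span of the part a molecule releases at ``level``.

    The molecule is digested with the level's enzyme; exactly one fragment
    must lack internal sites and carry two table junctions as overhangs.
    Returns ``(PositionSpec, released_fragment)``.
    """
    if level not in LEVELS:
        raise GrammarError(f"level must be one of {LEVELS}, got {level!r}")
    enz = get_enzyme(table.enzyme_for(level), enzymes)
    frags = digest(mol, enz)
    candidates = [
        f for f in frags
        if isinstance(f, StickyFragment)
        and len(f.left_overhang.seq) == 4
        and len(f.right_overhang.seq) == 4
        and not locate_sites(f.as_molecule(), enz)
    ]
    if len(candidates) != 1:
        raise AmbiguousReleaseError(
            f"{mol.id!r}: expected exactly one released insert at level "
            f"{level}, found {len(candidates)}"
        )
    frag = candidates[0]
    left = table.label_of(level, frag.left_overhang.seq)
    right = table.label_of(level, frag.right_overhang.seq)
    return table.span(level, left, right), frag
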