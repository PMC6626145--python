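"""One-pot cut-ligation simulation.

The defining behaviour of Golden Gate assembly is its steady state: the
reaction cycles between digestion and ligation, and only circular products
that have lost every recognition site of the reaction enzyme escape
re-cutting and accumulate.  The simulation therefore digests every input,
builds a directed compatibility graph between sticky fragments (X -> Y iff
X's right overhang anneals, full-length and exactly, to Y's left overhang),
enumerates simple cycles up to a size bound, materialises each cycle as a
circular molecule, and keeps only those without residual sites.  Linear
products and blunt joins are discarded: transformation selects circles and
the platform uses sticky junctions only.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .enzymes import StickyFragment, digest, get_enzyme, locate_sites
from .grammar import FusionSiteTable, PositionSpec
from .seqcore import DnaMolecule, GoldenGateError

__all__ = [
    "AssemblyError",
    "CutLigationReaction",
    "AssemblyProduct",
    "AssemblyResult",
    "simulate_cut_ligation",
    "apply_selection",
    "plan_assembly",
    "verify_expected",
]

MAX_FRAGMENTS_PER_PRODUCT = 12  # backbone + 6 parts + headroom
_CYCLE_CAP = 10000


class AssemblyError(GoldenGateError):
    """Ill-posed reaction (position conflicts, incomplete tiling, ...)."""


@dataclass
class CutLigationReaction:
    """A one-pot reaction: input molecules plus the reaction enzyme."""

    inputs: list
    enzyme: object  # name or TypeIISEnzyme
    grammar: FusionSiteTable = None
    max_fragments_per_product: int = MAX_FRAGMENTS_PER_PRODUCT

    def __post_init__(self):
        if self.max_fragments_per_product < 2:
            raise AssemblyError("max_fragments_per_product must be >= 2")


@dataclass
class AssemblyProduct:
    """A circular ligation product and its ordered part composition."""

    molecule: DnaMolecule
    composition: list            # ordered (source molecule id, fragment span)
    viable: bool = None          # set by apply_selection
    selection_notes: str = ""

    @property
    def source_ids(self) -> list:
        return [sid for sid, _span in self.composition]


class AssemblyResult(list):
    """Product list with reaction metadata (`truncated` enumeration flag)."""

    def __init__(self, products=(), truncated=False):
        super().__init__(products)
        self.truncated = truncated


def _fragment_pool(rxn: CutLigationReaction, enzymes=None) -> list:
    enz = get_enzyme(rxn.enzyme, enzymes)
    pool = []
    for mol in rxn.inputs:
        for frag in digest(mol, enz, enzymes):
            if isinstance(frag, StickyFragment):
                pool.append(frag)
            # uncut molecules cannot participate: circles are closed and
            # blunt-ended linears are excluded by the sticky-only rule
    return pool


def simulate_cut_ligation(rxn: CutLigationReaction, enzymes: dict = None,
                          require_no_residual_sites: bool = True) -> AssemblyResult:
    """Enumerate circular products of a one-pot cut-ligation.

    Each product uses any physical fragment at most once (simple-cycle rule,
    which also excludes concatemers); products are deduplicated by a
    rotation- and strand-invariant canonical form and returned in canonical
    order.  ``require_no_residual_sites=False`` disables the steady-state
    filter — useful for digest-then-religate round trips.
    """
    enz = get_enzyme(rxn.enzyme, enzymes)
    pool = _fragment_pool(rxn, enzymes)
    graph = nx.DiGraph()
    graph.add_nodes_from(range(len(pool)))
    for i, x in enumerate(pool):
        if x.right_overhang.is_blunt or x.right_overhang.polarity != "five_prime":
            continue
        for j, y in enumerate(pool):
            if y.left_overhang.is_blunt or y.left_overhang.polarity != "five_prime":
                continue
            if x.right_overhang.seq == y.left_overhang.seq:
                graph.add_edge(i, j)

    bound = rxn.max_fragments_per_product
    truncated = False
    cycles = []
    for k, cycle in enumerate(nx.simple_cycles(graph, length_bound=bound + 1)):
        if len(cycle) > bound or k >= _CYCLE_CAP:
            truncated = True
            continue
        cycles.append(cycle)

    products = {}
    counter = 0
    for cycle in cycles:
        # rotate so the composition starts deterministically
        pivot = min(range(len(cycle)), key=lambda i: (pool[cycle[i]].source, i))
        cycle = cycle[pivot:] + cycle[:pivot]
        seq = "".join(pool[i].seq for i in cycle)
        feats = []
        offset = 0
        for i in cycle:
            feats.extend(f.shifted(offset) for f in pool[i].features)
            offset += len(pool[i].seq)
        counter += 1
        mol = DnaMolecule(f"product_{counter}", seq, "circular", feats)
        if require_no_residual_sites and locate_sites(mol, enz, enzymes):
            continue
        key = mol.canonical_form()
        if key in products:
            continue
        products[key] = AssemblyProduct(
            molecule=mol,
            composition=[pool[i].source for i in cycle],
            selection_notes=f"{len(cycle)} fragments; "
                            f"{len(locate_sites(mol, enz, enzymes))} residual "
                            f"{enz.name} sites",
        )
    ordered = [products[k] for k in sorted(products)]
    for i, p in enumerate(ordered, 1):
        p.molecule.id = f"product_{i}"
    return AssemblyResult(ordered, truncated=truncated)


def apply_selection(products, marker: str):
    """Mark products viable iff they carry the antibiotic marker and no
    counter-selection (toxin) cassette.

    Mirrors plating an assembly on selective medium: the backbone donates the
    marker, a retained stuffer's counter-selection cassette kills the host.
    """
    out = []
    for p in products:
        has_marker = any(
            f.kind == "selection_marker"
            and f.qualifiers.get("marker", f.label) == marker
            for f in p.molecule.features
        )
        counters = [f for f in p.molecule.features if f.kind == "counter_selection"]
        p.viable = has_marker and not counters
        notes = [p.selection_notes] if p.selection_notes else []
        notes.append(f"marker {marker} {'present' if has_marker else 'absent'}")
        notes.append("counter-selection " +
                     (f"present ({', '.join(f.label for f in counters)})"
                      if counters else "absent"))
        p.selection_notes = "; ".join(notes)
        out.append(p)
    if isinstance(products, AssemblyResult):
        return AssemblyResult(out, products.truncated)
    return out


def _tile_spans(parts, table: FusionSiteTable, level: str, autofill: bool,
                dummies=None):
    """Order part spans along the junction chain, filling gaps with dummies."""
    labels = table.labels(level)
    idx = {lab: i for i, lab in enumerate(labels)}
    taken = [None] * (len(labels) - 1)
    for mol, spec in parts:
        lo, hi = idx[spec.left], idx[spec.right]
        for k in range(lo, hi):
            if taken[k] is not None:
                raise AssemblyError(
                    f"position conflict: {mol.id!r} and {taken[k].id!r} both "
                    f"claim junction span {labels[k]}-{labels[k + 1]}"
                )
            taken[k] = mol
    ordered = []
    k = 0
    missing = []
    while k < len(taken):
        if taken[k] is not None:
            mol = taken[k]
            while k < len(taken) and taken[k] is mol:
                k += 1
            ordered.append(mol)
        else:
            span = (labels[k], labels[k + 1])
            if autofill and dummies and span in dummies:
                ordered.append(dummies[span])
            else:
                missing.append(f"{span[0]}-{span[1]}")
            k += 1
    if missing:
        raise AssemblyError(
            "incomplete tiling: no part or dummy for junction span(s) "
            + ", ".join(missing)
        )
    return ordered


def plan_assembly(parts, backbone: DnaMolecule, grammar: FusionSiteTable,
                  autofill_dummies: bool = False, dummies: dict = None,
                  level: str = "LI->LII"):
    """Plan a one-level assembly and predict its unique composition.

    ``parts`` is a list of ``(molecule, PositionSpec)``; ``dummies`` maps
    single-junction spans ``(left, right)`` to filler part molecules used
    when ``autofill_dummies`` is set.  Returns ``(CutLigationReaction,
    expected_composition)`` where the expected composition is the ordered
    list of source molecule ids, backbone first.
    """
    for _mol, spec in parts:
        if spec.level != level:
            raise AssemblyError(f"part position {spec} is not at level {level}")
    ordered = _tile_spans(parts, grammar, level, autofill_dummies, dummies)
    rxn = CutLigationReaction(
        inputs=[backbone] + ordered,
        enzyme=grammar.enzyme_for(level),
        grammar=grammar,
    )
    expected = [backbone.id] + [m.id for m in ordered]
    return rxn, expected


def verify_expected(result, expected, rxn: CutLigationReaction = None,
                    enzymes: dict = None) -> tuple:
    """Check that exactly one viable product matches the expected composition.

    Returns ``(ok, diagnostic)``.  The composition comparison is insensitive
    to rotation of the circular product.  Passing the reaction lets the
    zero-product diagnostic name the junction that failed to mate.
    """
    viable = [p for p in result if p.viable is not False]
    if len(viable) == 0:
        return False, "no viable product: " + _unmatched_note(result, rxn, enzymes)
    if len(viable) > 1:
        listing = "; ".join(",".join(p.source_ids) for p in viable)
        return False, f"{len(viable)} viable products: {listing}"
    got = viable[0].source_ids
    exp = list(expected)
    if len(got) == len(exp) and any(
        got[k:] + got[:k] == exp for k in range(len(got))
    ):
        return True, "pass"
    return False, f"wrong composition: expected {exp}, got {got}"


def _unmatched_note(result, rxn: CutLigationReaction = None,
                    enzymes: dict = None) -> str:
    if isinstance(result, AssemblyResult) and result.truncated:
        return "cycle enumeration truncated"
    if rxn is not None and rxn.grammar is not None:
        enz = get_enzyme(rxn.enzyme, enzymes)
        # only fragments free of internal sites can appear in a product
        pool = [f for f in _fragment_pool(rxn, enzymes)
                if not locate_sites(f.as_molecule(), enz)]
        rights = {f.right_overhang.seq for f in pool}
        lefts = {f.left_overhang.seq for f in pool}
        bad = []
        for level in ("LI->LII", "LII->LIII"):
            for label, ovh in rxn.grammar.junctions(level).items():
                if (ovh in rights) != (ovh in lefts):
                    bad.append(label)
        if bad:
            return "junction " + ", ".join(sorted(set(bad))) + " unmatched"
    return "no circular junction path closed (check junction overhangs)"
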