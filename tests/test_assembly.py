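from itertools import permutations

import pytest

import goldengate as gg
from conftest import random_molecule

SP = "A"
BSA = "GGTCTC"
BSA_RC = "GAGACC"


def part_plasmid(mol_id, left, right, core):
    """Circular plasmid whose BsaI digest releases left+core (right overhang)."""
    seq = ("T" * 25 + BSA + SP + left + core + right + SP + BSA_RC + "T" * 25)
    return gg.DnaMolecule(mol_id, seq, "circular")


def backbone_plasmid(mol_id, first, last, marker="spectinomycin"):
    """Backbone with a ccdB stuffer between ``first`` and ``last`` junctions."""
    feats = [gg.Feature("marker", "selection_marker", 5, 20, 1,
                        {"marker": marker}),
             gg.Feature("ccdB", "counter_selection", 36, 60)]
    seq = ("G" * 30 + first + SP + BSA_RC + "C" * 30 + BSA + SP + last)
    return gg.DnaMolecule(mol_id, seq, "circular", feats)


def brute_force_cycles(frags, max_len=8):
    """Exhaustive oracle: all distinct circular fragment orderings."""
    found = set()
    idx = range(len(frags))
    for k in range(1, min(max_len, len(frags)) + 1):
        for perm in permutations(idx, k):
            ok = all(
                frags[perm[i]].right_overhang.seq
                == frags[perm[(i + 1) % k]].left_overhang.seq
                and frags[perm[i]].right_overhang.seq
                for i in range(k)
            )
            if ok:
                seq = "".join(frags[i].seq for i in perm)
                found.add(gg.DnaMolecule("x", seq, "circular").canonical_form())
    return found


def test_backbone_plus_three_parts_yields_single_ordered_product(table):
    A, B, C, G = (table.level2[x] for x in "ABCG")
    inputs = [
        backbone_plasmid("bb", A, G),
        part_plasmid("pAB", A, B, "AAACCC"),
        part_plasmid("pBC", B, C, "CCCAAA"),
        part_plasmid("pCG", C, G, "ACACAC"),
    ]
    rxn = gg.CutLigationReaction(inputs, "BsaI", grammar=table)
    products = gg.simulate_cut_ligation(rxn)
    assert len(products) == 1
    p = products[0]
    assert [s for s, _ in p.composition] == ["bb", "pAB", "pBC", "pCG"]
    assert gg.locate_sites(p.molecule, "BsaI") == []
    # oracle: exhaustive enumeration over all fragment orderings finds the
    # same site-free circles
    frags = [f for m in inputs for f in gg.digest(m, "BsaI")]
    sitefree = {
        c for c in brute_force_cycles(frags)
        if not gg.locate_sites(gg.DnaMolecule("c", c, "circular"), "BsaI")
    }
    assert sitefree == {p.molecule.canonical_form()}


def test_unmatched_overhangs_give_no_product(table):
    a = part_plasmid("a", "GGAG", "TACT", "AAAACC")
    b = part_plasmid("b", "AATG", "GCTT", "CCAAAA")
    rxn = gg.CutLigationReaction([a, b], "BsaI")
    assert list(gg.simulate_cut_ligation(rxn)) == []


def test_digest_religate_recovers_input_when_filter_disabled(table):
    plasmid = part_plasmid("p", "GGAG", "TACT", "ACGTACGTAA")
    rxn = gg.CutLigationReaction([plasmid], "BsaI")
    products = gg.simulate_cut_ligation(rxn, require_no_residual_sites=False)
    forms = {p.molecule.canonical_form() for p in products}
    assert plasmid.canonical_form() in forms


def test_selection_logic(table, kit, six_parts):
    bb = kit.lii_backbone("1", "2")
    rxn = gg.CutLigationReaction([bb] + six_parts, "BsaI", grammar=table)
    products = gg.simulate_cut_ligation(rxn)
    products = gg.apply_selection(products, "spectinomycin")
    viable = [p for p in products if p.viable]
    assert len(viable) == 1
    # the stuffer (and its ccdB) is gone from the correct product
    assert not any(f.kind == "counter_selection"
                   for f in viable[0].molecule.features)
    # re-circularised backbone retaining the ccdB stuffer is non-viable
    relig = gg.simulate_cut_ligation(
        gg.CutLigationReaction([bb], "BsaI"), require_no_residual_sites=False)
    bad = gg.apply_selection(relig, "spectinomycin")
    assert all(p.viable is False
               for p in bad
               if any(f.kind == "counter_selection" for f in p.molecule.features))
    # part-only circle lacking the marker is non-viable
    part_only = gg.apply_selection(
        [gg.AssemblyProduct(gg.DnaMolecule("c", "ACGT" * 10, "circular"), [])],
        "spectinomycin")
    assert part_only[0].viable is False


def test_plan_assembly_autofills_dummies(kit, table):
    parts = [(kit.li_part("A", "B"), table.span("LI->LII", "A", "B")),
             (kit.li_part("C", "D"), table.span("LI->LII", "C", "D")),
             (kit.li_part("E", "F"), table.span("LI->LII", "E", "F"))]
    rxn, expected = gg.plan_assembly(parts, kit.lii_backbone("1", "2"), table,
                                     autofill_dummies=True, dummies=kit.dummies)
    assert expected == ["lii-bb-12", "li-ab", "li-dmy-bc", "li-cd",
                        "li-dmy-de", "li-ef", "li-dmy-fg"]
    products = gg.apply_selection(gg.simulate_cut_ligation(rxn), "spectinomycin")
    ok, diag = gg.verify_expected(products, expected, rxn)
    assert ok, diag


def test_plan_assembly_detects_conflicts_and_gaps(kit, table):
    dup = [(kit.li_part("C", "D"), table.span("LI->LII", "C", "D")),
           (kit.li_part("C", "D"), table.span("LI->LII", "C", "D"))]
    with pytest.raises(gg.AssemblyError, match="position conflict"):
        gg.plan_assembly(dup, kit.lii_backbone("1", "2"), table)
    sparse = [(kit.li_part("A", "B"), table.span("LI->LII", "A", "B"))]
    with pytest.raises(gg.AssemblyError, match="incomplete tiling"):
        gg.plan_assembly(sparse, kit.lii_backbone("1", "2"), table,
                         autofill_dummies=False)


def test_verify_expected_names_unmatched_junction(kit, table, six_parts):
    # mutate the A junction of the A-B part so the chain cannot close
    pab = six_parts[0]
    i = pab.seq.find(BSA) + len(BSA) + 1  # the A fusion site follows the spacer
    assert pab.seq[i:i + 4] == table.level2["A"]
    mutated_seq = pab.seq[:i] + "TTTT" + pab.seq[i + 4:]
    mutated = gg.DnaMolecule("li-ab", mutated_seq, "circular")
    rxn = gg.CutLigationReaction([kit.lii_backbone("1", "2"), mutated]
                                 + six_parts[1:], "BsaI", grammar=table)
    products = gg.apply_selection(gg.simulate_cut_ligation(rxn), "spectinomycin")
    ok, diag = gg.verify_expected(products,
                                  ["lii-bb-12"] + [p.id for p in six_parts], rxn)
    assert not ok
    assert "junction A" in diag


def test_two_competing_parts_report_multiple_products(kit, table, six_parts):
    # a second, distinct part claiming the same A-B span: both assemblies form
    extra = part_plasmid("li-ab2", table.level2["A"], table.level2["B"],
                         "ACACACACAC")
    rxn = gg.CutLigationReaction([kit.lii_backbone("1", "2"), extra]
                                 + six_parts, "BsaI", grammar=table)
    products = gg.apply_selection(gg.simulate_cut_ligation(rxn), "spectinomycin")
    viable = [p for p in products if p.viable]
    ok, diag = gg.verify_expected(viable, ["lii-bb-12"] + [p.id for p in six_parts])
    assert not ok and "2 viable" in diag


def test_identical_fragment_copies_collapse_to_one_product(kit, table, six_parts):
    # a sequence-identical duplicate part yields an indistinguishable circle,
    # so the deduplicated product list is unchanged
    extra = gg.DnaMolecule("li-ab2", kit.li_part("A", "B").seq, "circular",
                           kit.li_part("A", "B").features)
    rxn = gg.CutLigationReaction([kit.lii_backbone("1", "2"), extra]
                                 + six_parts, "BsaI", grammar=table)
    products = gg.apply_selection(gg.simulate_cut_ligation(rxn), "spectinomycin")
    assert len([p for p in products if p.viable]) == 1


def test_hierarchy_closure_five_units_into_liii(kit, table, lii_plasmids):
    rxn = gg.CutLigationReaction(lii_plasmids + [kit["liii-bb"]], "BpiI",
                                 grammar=table)
    products = gg.apply_selection(gg.simulate_cut_ligation(rxn), "kanamycin")
    viable = [p for p in products if p.viable]
    assert len(viable) == 1
    assert len(viable[0].composition) == 6  # five transcription units + backbone
    assert gg.locate_sites(viable[0].molecule, "BpiI") == []


def test_enzyme_orthogonality_of_assembled_lii(lii_plasmids):
    lii = lii_plasmids[0]
    assert gg.locate_sites(lii, "BsaI") == []
    assert len(gg.locate_sites(lii, "BpiI")) == 2


def test_product_list_deterministic_across_input_orderings(kit, table, six_parts):
    inputs = [kit.lii_backbone("1", "2")] + six_parts
    base = None
    for perm in (inputs, inputs[::-1], inputs[3:] + inputs[:3]):
        rxn = gg.CutLigationReaction(list(perm), "BsaI", grammar=table)
        forms = [p.molecule.canonical_form()
                 for p in gg.simulate_cut_ligation(rxn)]
        if base is None:
            base = forms
        assert forms == base


def test_esp3i_landing_pad_two_step_replacement(kit, table, six_parts):
    """A lacZ landing pad in an assembled LII is replaced by a new part via a
    second, Esp3I cut-ligation — no mutagenesis of the incoming part needed."""
    pad = kit["li-pad-lacz-ab"]
    rxn = gg.CutLigationReaction([kit.lii_backbone("1", "2"), pad]
                                 + six_parts[1:], "BsaI", grammar=table)
    products = gg.apply_selection(gg.simulate_cut_ligation(rxn), "spectinomycin")
    with_pad = [p for p in products
                if any(f.label == "lacZ" for f in p.molecule.features)]
    assert len(with_pad) == 1
    lii_pad = with_pad[0].molecule
    assert len(gg.locate_sites(lii_pad, "Esp3I")) == 2
    # incoming insert staged with the directional entry overhangs
    eL, eR = table.entry
    insert = gg.DnaMolecule(
        "new-part",
        "T" * 12 + "CGTCTC" + "A" + eL + "ACGTACGTACGT" + eR + "A" + "GAGACG" + "T" * 12,
    )
    rxn2 = gg.CutLigationReaction([lii_pad, insert], "Esp3I", grammar=table)
    out = gg.apply_selection(gg.simulate_cut_ligation(rxn2), "spectinomycin")
    good = [p for p in out if p.viable]
    assert len(good) == 1
    assert "ACGTACGTACGT" in good[0].molecule.seq * 2
    assert not any(f.label == "lacZ" for f in good[0].molecule.features)


def test_random_circular_digest_religation_round_trip(rng):
    for _ in range(40):
        mol = random_molecule(rng, "BsaI", circular=True, n_sites=2)
        if not gg.locate_sites(mol, "BsaI"):
            continue
        rxn = gg.CutLigationReaction([mol], "BsaI")
        products = gg.simulate_cut_ligation(rxn, require_no_residual_sites=False)
        assert mol.canonical_form() in {p.molecule.canonical_form()
                                        for p in products}
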