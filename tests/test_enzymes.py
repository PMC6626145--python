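import pytest

import goldengate as gg
from conftest import random_molecule


def test_locate_plus_strand_site():
    m = gg.DnaMolecule("m", "TTTGGTCTCAAATGCCCCCC")
    hits = gg.locate_sites(m, "BsaI")
    assert len(hits) == 1
    h = hits[0]
    assert (h.strand, h.recog_start, h.recog_end) == (1, 3, 9)
    # type IIS: the cut window lies outside the recognition interval
    assert h.cut_top_pos >= h.recog_end


def test_locate_no_site():
    assert gg.locate_sites(gg.DnaMolecule("m", "AAAAAAAA"), "BsaI") == []


def test_locate_minus_strand_site():
    m = gg.DnaMolecule("m", "TTTTTGAGACCTTTT")
    hits = gg.locate_sites(m, "BsaI")
    assert len(hits) == 1 and hits[0].strand == -1


def test_locate_spanning_circular_origin():
    seq = "CTCAAATG" + "C" * 30 + "GGT"  # GGTCTC wraps the origin
    m = gg.DnaMolecule("m", seq, "circular")
    hits = gg.locate_sites(m, "BsaI")
    assert len(hits) == 1 and hits[0].recog_start == 38


def test_palindromic_sites_counted_once():
    m = gg.DnaMolecule("m", "TTTGAATTCTTT")
    assert len(gg.locate_sites(m, "EcoRI")) == 1


def test_digest_linear_releases_programmed_overhang():
    m = gg.DnaMolecule("m", "TTTGGTCTCAAATGCCCCCC")
    up, down = gg.digest(m, "BsaI")
    assert down.left_overhang.seq == "AATG"
    assert down.left_overhang.polarity == "five_prime"
    assert down.seq.startswith("AATG")
    assert up.right_overhang.seq == "AATG"
    assert len(up.seq) + len(down.seq) == len(m.seq)


def test_digest_no_sites_is_identity():
    m = gg.DnaMolecule("m", "AAAACCCCGGGG")
    assert gg.digest(m, "BsaI") == [m]


def test_digest_circular_single_site_fragment_religates():
    m = gg.DnaMolecule("m", "GGTCTCAAATG" + "C" * 30, "circular")
    (frag,) = gg.digest(m, "BsaI")
    assert frag.left_overhang.seq == frag.right_overhang.seq == "AATG"
    assert len(frag.seq) == len(m.seq)
    religated = gg.DnaMolecule("r", frag.seq, "circular")
    assert religated.canonical_form() == m.canonical_form()


@pytest.mark.parametrize("name,length", [
    ("BsaI", 4), ("BpiI", 4), ("Esp3I", 4), ("AarI", 4), ("SapI", 3), ("MlyI", 0),
])
def test_overhang_lengths_match_enzyme_geometry(name, length):
    enz = gg.get_enzyme(name)
    m = gg.DnaMolecule("m", "TTTTTTTTTT" + enz.recognition + "ACGTACGTACGTACGT")
    up, down = gg.digest(m, name)
    assert len(down.left_overhang.seq) == length
    assert enz.overhang_length == length


def test_typeiis_recognitions_are_non_palindromic():
    for name in ("BsaI", "BpiI", "Esp3I", "SapI", "AarI", "MlyI"):
        assert not gg.get_enzyme(name).is_palindromic


def test_colliding_cuts_error_names_both_sites():
    # two convergent BsaI sites whose staggered windows overlap
    m = gg.DnaMolecule("m", "TTGGTCTCA" + "AT" + "TGAGACCTT")
    with pytest.raises(gg.DigestError, match="BsaI"):
        gg.digest(m, "BsaI")


def test_cut_beyond_linear_end_is_an_error():
    m = gg.DnaMolecule("m", "TTTGGTCTCAA")  # downstream cut falls off the end
    with pytest.raises(gg.DigestError):
        gg.digest(m, "BsaI")


def test_nucleotide_conservation_over_random_molecules(rng):
    for _ in range(150):
        name = rng.choice(["BsaI", "BpiI", "Esp3I", "SapI", "MlyI"])
        mol = random_molecule(rng, name)
        frags = gg.digest(mol, name)
        if frags == [mol]:
            continue
        assert sum(len(f.seq) for f in frags) == len(mol.seq)
        n_sites = len(gg.locate_sites(mol, name))
        expected = n_sites if mol.is_circular else n_sites + 1
        assert len(frags) == expected


def test_strand_symmetry_of_digestion(rng):
    for _ in range(60):
        mol = random_molecule(rng, "BsaI", circular=False)
        frags = gg.digest(mol, "BsaI")
        rc_frags = gg.digest(mol.reverse_complement(), "BsaI")
        if frags == [mol]:
            assert len(rc_frags) == 1
            continue
        fwd = [f.seq for f in frags]
        rev = [gg.revcomp(f.seq) for f in rc_frags][::-1]
        # the top-strand split points mirror the bottom-strand cut positions,
        # so compare the full duplex content: junction bases shift between
        # neighbouring fragments but the concatenation is strictly mirrored
        assert "".join(fwd) == "".join(rev)
        assert len(fwd) == len(rev)
        # and the overhang sequences correspond (reverse-complemented, swapped)
        got = [rc_frags[-1 - i].left_overhang.seq for i in range(len(frags))]
        want = [gg.revcomp(f.right_overhang.seq) for f in frags]
        assert got == want


def test_find_unique_cutters(kit):
    panel = ["EcoRI", "HindIII", "XbaI", "PstI", "SphI", "NotI"]
    bb = kit.lii_backbone("1", "2")
    assert gg.find_unique_cutters(bb, panel) == panel
    two = gg.DnaMolecule("m", "GGTCTCAAATTTTTTTGGTCTCAATT" + "T" * 10)
    assert gg.find_unique_cutters(two, ["BsaI"]) == []
    one = gg.DnaMolecule("m", "TTTGAATTCTTTTTTTTTT")
    assert gg.find_unique_cutters(one, ["EcoRI"]) == ["EcoRI"]
    with pytest.raises(gg.UnknownEnzymeError):
        gg.find_unique_cutters(one, ["NoSuchEnzyme"])


def test_features_are_remapped_or_dropped_by_digestion():
    feats = [gg.Feature("keep", "part_payload", 12, 18),
             gg.Feature("cut", "misc", 8, 16)]
    m = gg.DnaMolecule("m", "TTTGGTCTCAAATGCCCCCCCC", features=feats)
    up, down = gg.digest(m, "BsaI")
    # the severed feature is destroyed; the downstream one is rebased
    assert [f.label for f in up.features] == []
    assert [f.label for f in down.features] == ["keep"]
    f = down.features[0]
    assert down.seq[f.start:f.end] == m.seq[12:18]
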