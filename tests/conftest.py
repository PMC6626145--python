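import random

import pytest

import goldengate as gg


@pytest.fixture(scope="session")
def table():
    return gg.default_grammar()


@pytest.fixture(scope="session")
def kit(table):
    return gg.generate_fixture_kit(1, table)


@pytest.fixture(scope="session")
def six_parts(kit):
    spans = [("A", "B"), ("B", "C"), ("C", "D"), ("D", "E"), ("E", "F"), ("F", "G")]
    return [kit.li_part(a, b) for a, b in spans]


@pytest.fixture(scope="session")
def lii_plasmids(kit, table, six_parts):
    """Assembled LII plasmids for every transcription-unit slot."""
    out = []
    for j, k in [("1", "2"), ("2", "3"), ("3", "4"), ("4", "5"), ("5", "6")]:
        rxn = gg.CutLigationReaction([kit.lii_backbone(j, k)] + six_parts,
                                     "BsaI", grammar=table)
        products = gg.apply_selection(gg.simulate_cut_ligation(rxn),
                                      "spectinomycin")
        viable = [p for p in products if p.viable]
        assert len(viable) == 1
        mol = viable[0].molecule
        mol.id = f"lii-{j}{k}"
        out.append(mol)
    return out


@pytest.fixture()
def rng():
    return random.Random(20240917)


def random_molecule(rng, enzyme_name="BsaI", n_sites=None, circular=None,
                    length=None):
    """A random molecule seeded with a chosen number of enzyme sites."""
    enz = gg.get_enzyme(enzyme_name)
    length = length or rng.randrange(60, 140)
    circular = rng.random() < 0.5 if circular is None else circular
    n_sites = rng.randrange(0, 3) if n_sites is None else n_sites
    pats = [enz.recognition, gg.revcomp(enz.recognition)]
    seq = _clean(rng, length, pats)
    margin = len(enz.recognition) + max(abs(enz.cut_top), abs(enz.cut_bottom)) + 2
    placed = 0
    tries = 0
    while placed < n_sites and tries < 200:
        tries += 1
        pos = rng.randrange(margin, length - margin) if length > 2 * margin else None
        if pos is None:
            break
        pat = rng.choice(pats)
        cand = seq[:pos] + pat + seq[pos + len(pat):]
        mol = gg.DnaMolecule("r", cand, "circular" if circular else "linear")
        try:
            frags = gg.digest(mol, enz)
        except gg.DigestError:
            continue
        found = len(gg.locate_sites(mol, enz))
        if found == placed + 1:
            seq = cand
            placed += 1
    mol = gg.DnaMolecule("r", seq, "circular" if circular else "linear")
    try:
        gg.digest(mol, enz)
    except gg.DigestError:
        return random_molecule(rng, enzyme_name, n_sites, circular, length)
    return mol


def _clean(rng, n, pats):
    seq = "".join(rng.choice("ACGT") for _ in range(n))
    for _ in range(200):
        bad = next((p for p in pats if p in seq or p in seq + seq[:6]), None)
        if bad is None:
            return seq
        i = (seq + seq[:6]).find(bad)
        j = (i + rng.randrange(len(bad))) % n
        seq = seq[:j] + rng.choice([b for b in "ACGT" if b != seq[j]]) + seq[j + 1:]
    return seq
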