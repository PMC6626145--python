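# goldengate

An in-silico model of hierarchical Golden Gate ("cut-ligation") cloning, for
molecular biologists and synthetic-biology tool builders who design modular
plasmid assemblies before touching a pipette.

Golden Gate cloning exploits type IIS restriction enzymes, which recognise a
non-palindromic sequence and cleave at a fixed offset *outside* it, so the
4-nt 5′ extensions left behind can be custom designed.  In a one-pot
digestion/ligation cycle, correctly assembled products lose every
recognition site and accumulate.  This package simulates that steady state
exactly, under a three-level position grammar:

* **LI (entry)** — a part is PCR-amplified with primers stacking a BpiI
  module (directional entry cloning) and a BsaI module (position-defining
  fusion sites), then cut-ligated into a universal acceptor backbone;
* **LII (transcription unit)** — LI parts at positions A-B (promoter), B-C
  (N-tag), C-D (ORF), D-E (C-tag), E-F (terminator) and F-G (extras) are
  combined in a BsaI cut-ligation, with ccdB counter-selection plus an
  antibiotic marker selecting the correct circle;
* **LIII (multi-unit)** — LII plasmids at positions 1-2 … 5-6 are combined
  in a BpiI cut-ligation, giving up to five transcription units.

Around that core the package provides:

* a digestion engine (`digest`, `locate_sites`, `find_unique_cutters`) for
  arbitrary type IIS/IIP enzymes on linear or circular molecules;
* overhang-set fidelity auditing (`check_overhang_set`, `max_set_size`):
  duplicates, palindromes, cross-complementary pairs, middle-dinucleotide
  reuse and 5′-trim mis-annealing hazards.  Restricting the middle
  dinucleotide (positions 2–3) of a 4-nt overhang to a single use caps a
  set at **16** overhangs — recomputed by enumeration, not assumed;
* one-pot assembly simulation (`simulate_cut_ligation`, `apply_selection`,
  `plan_assembly`, `verify_expected`) via a fragment-compatibility graph
  and simple-cycle enumeration, with the no-residual-site steady-state rule;
* codon-aware domestication (`scan_forbidden`, `propose_silent_edits`,
  `apply_edits`, `domesticate`): minimal synonymous substitutions that
  destroy internal BsaI/BpiI/Esp3I sites without touching the protein;
* entry- and mutagenesis-primer design (`design_entry_primers`,
  `design_mutagenesis_primers`) with Wallace-rule Tm and virtual PCR;
* restriction-site-loss genotyping (`site_loss_assay`, `call_indel`) for
  reading out genome edits from MlyI-resistant amplicons;
* GenBank/FASTA I/O, a JSON part registry, and a seeded synthetic fixture
  kit (`generate_fixture_kit`) that builds every backbone and part needed
  to exercise the full LI→LII→LIII chain with no external data.

## Worked example

Everything below runs from a fresh checkout; the fixture kit is generated
from a seed, so the numbers are reproducible.

```console
$ goldengate fixtures --seed 1 --out reg
23 molecules written to reg

$ goldengate check-fidelity --overhangs GGAG,TACT,AATG,GCTT,GGTA,CGCT,CCAT
overhang set passes all fidelity rules

$ goldengate assemble -i reg/lii-bb-12.gb -i reg/li-ab.gb -i reg/li-bc.gb \
    -i reg/li-cd.gb -i reg/li-de.gb -i reg/li-ef.gb -i reg/li-fg.gb \
    --enzyme BsaI --marker spectinomycin
product_1: 906 nt, composition li-ab+li-bc+li-cd+li-de+li-ef+li-fg+lii-bb-12, viable=True

$ goldengate infer-position reg/li-cd.gb
li-cd: C-D (released insert 82 nt)

$ goldengate unique-cutters reg/lii-bb-12.gb --candidates EcoRI,HindIII,XbaI,PstI,SphI,NotI
EcoRI,HindIII,XbaI,PstI,SphI,NotI
```

The assembly run digests all seven plasmids, enumerates every circular
ligation product, discards any retaining a BsaI site, and applies
spectinomycin/ccdB selection: exactly one viable transcription-unit plasmid
remains, containing all six parts in grammar order plus the backbone — and
it still carries the two flanking BpiI sites needed for the next assembly
level.  `infer-position` reads a part's position back from its fusion-site
overhangs alone, and `unique-cutters` confirms the backbone carries six
single-cut sites for linearization ahead of in-vitro transcription.

The same operations are available as a library; see the module docstrings
under `src/goldengate/` and the scenarios in `tests/`.

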