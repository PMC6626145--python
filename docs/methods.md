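# Methods

## The model

The package treats DNA as fully base-paired duplex represented by its top
strand (0-based, half-open coordinates; circular arithmetic modulo length).
A type IIS enzyme is a recognition pattern plus two signed cut offsets
measured from the 3′ end of the top-strand recognition: for a +strand site
ending at `e`, the top strand is cut at `e + cut_top` and the bottom strand
at `e + cut_bottom`; minus-strand sites mirror the offsets leftward.  The
difference `cut_bottom − cut_top` is the signed extension length (positive
= 5′ extension, zero = blunt, negative = 3′ extension).  Digestion is
complete (all sites cut simultaneously); partial digests, star activity and
methylation blocking are outside the model.  Two cuts whose staggered
windows overlap are rejected as an error rather than resolved — such
substrates are ill-formed for this system.  Exonucleolytic end-trimming is
not modelled as a stochastic digestion outcome; it enters only as the
deterministic hazard rule in the fidelity audit (below).

Fragments carry the top strand between consecutive top-strand cuts, so a 5′
left extension is a prefix of the fragment sequence while the right
extension's bases (physically on the bottom strand) are recorded in their
top-strand-equivalent form.  This convention makes nucleotide conservation
exact — fragment lengths sum to the input length — and makes ligation a
plain concatenation: fragment X can precede fragment Y iff X's right
overhang equals Y's left overhang (full-length, exact Watson–Crick match;
blunt and 3′ ends never ligate in this system).

**One-pot cut-ligation** is modelled at its steady state: the reaction
cycles digestion and ligation, so any circular product still carrying a
recognition site of the reaction enzyme is re-cut, and only site-free
circles accumulate.  The simulation digests every input, builds the
directed overhang-compatibility graph over all fragments, enumerates simple
cycles (each physical fragment used at most once, which also excludes
concatemers) up to a bound of 12 fragments per product — backbone + six
parts + headroom — materialises each cycle as a circular molecule with
remapped features, drops products with residual sites, and deduplicates by
a rotation- and strand-invariant canonical form.  Linear products are
discarded because transformation selects circles.  Cycle enumeration uses
networkx; everything else (fragment semantics, materialisation, filtering,
canonicalisation) is this package's own.  Identical input molecules yield
identical fragments and therefore collapse to one product; reporting
multiplicities of indistinguishable circles is deliberately out of scope.

**Selection** mirrors plating: a product is viable iff it carries the
backbone's `selection_marker` feature (matching the requested antibiotic)
and no `counter_selection` feature (ccdB or lacZ stuffers travel with the
junk fragments, so only correct assemblies survive).

## Fidelity rules

A junction set passes when no two overhangs can cross-anneal.  The audit
reports literal duplicates, self-complementary 4-mers (flagged as their own
category rather than folded into another rule, since a palindromic end
ligates to itself), cross-complementary pairs (two junctions whose sticky
forms are identical), reuse of the middle dinucleotide (positions 2–3,
1-based, reading 5′→3′), and trim hazards.

The trim hazard models trace exonuclease activity removing the 5′-most base
(position 1) of an extension.  The spec of the hazard is deliberately
narrow: a *single* trimmed end annealing, in duplex register, with the
mating-form end of a *different* junction.  Working out the geometry, that
requires the two overhangs to share positions 2–4 (trimmed plain form vs.
the partner's complementary form) or positions 1–3 (trimmed complementary
form vs. the partner's plain form).  Both conditions contain the middle
dinucleotide, which yields the design theorem the whole grammar rests on:
*a set with all-distinct middles and no cross-complementary pair has zero
trim hazards*.  Off-register annealing of two simultaneously trimmed ends
was considered and excluded: it leaves a one-base gap at both nicks, which
ligase cannot seal, and double-trim events are second-order anyway.  The
property suite verifies the theorem over 10,000 random rule-passing sets.

Because each admissible overhang consumes its middle dinucleotide exactly
once, and there are 4² = 16 dinucleotides, a rule-passing set holds at most
16 overhangs.  `max_set_size` recomputes this by enumeration over all 256
4-mers and returns a witness set, rather than hard-coding the number.

## The position grammar

Fusion-site tables are entirely configuration: the shipped default is a
documented toy table (MoClo-flavoured 4-mers chosen to pass every audit
rule) and any real system's table can be dropped in as JSON.  The entry
overhang pair is configurable independently of the outermost level-2
junctions — the two need not coincide, and keeping them separate is the
more general choice.  Slot counts (6 part slots in A…G, 5 unit slots in
1…6) are derived from the table, never hard-coded.  Dummy parts are
ordinary parts spanning any unit range; landing pads are parts whose
payload carries internal sites of a *second* enzyme plus a
counter-selection/screening feature, enabling two-step replacement routes
(e.g. BsaI assembly first, Esp3I insertion later) as two chained
single-enzyme reactions — no one-pot dual-enzyme protocol is modelled.

## Domestication

Sites inside an annotated plus-strand CDS are removed by single-codon
synonymous substitution: candidates are every synonymous codon of every
codon the recognition touches; a candidate survives if the targeted match
is destroyed on both strands and no *new* forbidden site appears within a
±10 nt window (wide enough for the longest shipped recognition, 7 nt, on
either strand; pre-existing neighbouring sites are tolerated and handled by
their own edits).  Ranking is fewest changed bases, ties broken by the
lexicographically smallest replacement codon, so output is deterministic.
Codon-usage optimisation is deliberately not attempted.  Sites outside a
CDS are never auto-edited — the landing-pad route exists precisely to admit
such parts unmodified — and the error message says so.  Known limitation:
only single-codon substitutions are searched; a site that would need two
codons changed at once reports as undomesticable.

## Primers

Entry primers follow the two-module architecture: 5′ pad (default `TT`,
configurable — type IIS enzymes need flanking bases to cut near an end),
entry enzyme site, spacer, entry overhang, level-2 enzyme site, spacer,
fusion site, homology.  Spacer lengths equal each enzyme's `cut_top` (BpiI
2 nt, BsaI/Esp3I 1 nt) so the cut lands exactly on the intended overhang;
spacer bases are chosen so the finished primer contains no stray sites.
Homology starts at 18 nt and grows to at most 30 until its Wallace-rule Tm
(2·(A+T) + 4·(G+C); chosen for determinism and zero parameters, with
nearest-neighbour left as an extension point) reaches the 52–60 °C window;
unreachable windows yield the closest achievable arm plus a warning.
Mutagenesis pairs share a ≥15 nt overlap centred on the edit, with exact 3′
arms grown the same way.  Virtual PCR and virtual whole-plasmid mutagenesis
demand unique, exact annealing of the homology arms; the entry round-trip
property (PCR → entry cut-ligation → level-2 release reproduces the
requested fusion sites around the untouched template) holds for every
position span and both entry enzymes.

## Genotyping

An allele amplicon is resistant iff it retains zero assay-enzyme sites;
fragment lengths are reported sorted, with bands within 5 % of each other
flagged as co-migrating (a gel resolves by size only).  Indels are called
by global alignment (match +1, mismatch −1, gap of length k costs 4 + k,
i.e. open 4 plus 1 per base — implemented with Biopython's PairwiseAligner,
whose scores are cross-checked in the tests against an independent
hand-rolled affine-gap dynamic program).  Tied gap placements are
normalised leftmost, the standard convention for indel reporting, and event
positions are reported relative to the wild-type cut site.  Alignment is
only attempted when both sequences share ≥10 nt of end identity.

## The synthetic fixture kit

`generate_fixture_kit(seed, grammar)` emulates the platform's molecule
classes: two universal entry acceptors (BpiI and Esp3I variants, each with
a ccdB stuffer between the directional entry overhangs), one LI plasmid per
position span plus per-span dummies and a lacZ landing pad, five level-2
backbones (ccdB stuffer between A and G, flanking BpiI sites releasing the
slot's 1…6 junctions, spectinomycin marker, and one copy each of six
single-cut linearization sites), a level-3 backbone (kanamycin), a CDS
template with one deliberate internal BsaI site for domestication
exercises, and a genotyping amplicon with one central MlyI site.  Filler
sequence is uniform random DNA scrubbed of all assembly-enzyme and panel
recognitions on both strands; each finished molecule is then verified to
contain exactly the intended site counts, with fillers regenerated in the
rare case a junction concatenation recreates a pattern.  Generation is
deterministic in the seed.

What the kit does *not* emulate: realistic plasmid sizes (fixtures are a
few hundred bp, real backbones are kilobases — irrelevant to junction
logic but relevant to runtime claims), sequence composition biases, repeat
structure, methylation, and host biology (origins and markers are feature
annotations, not functional sequences).  Passing tests therefore
demonstrate the correctness of the combinatorial and sequence logic, not
wet-lab efficiency or host behaviour.

## Numerical and procedural choices

Problem sizes in the test suite were chosen to exercise the combinatorics
densely while staying desk-scale: 1,000 random molecules for conservation/
round-trip, 10,000 random rule-passing overhang sets for the fidelity
theorem, 500 random CDSs for protein conservation, 300 random allele edits
for assay consistency, and exhaustive enumeration wherever the space is
tiny (all 256 4-mers; all fragment orderings in the assembly oracle).  Seeds
are fixed in the tests; the acceptance script takes its seed on the command
line.  Cycle enumeration caps at 10,000 cycles and flags truncation in the
result metadata instead of failing.  Canonical forms use the minimum over
all rotations of both strands — O(n²) but applied only to products.

## Known limitations

Ligase kinetics, transformation efficiency and colony counts are not
predicted; fragment stoichiometry is ignored (each input contributes one
copy of each fragment per cycle); multi-copy (concatemeric) products are
excluded by construction; minus-strand CDS domestication is not automated;
Gateway recombination chemistry is treated as opaque payload annotation
only.
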