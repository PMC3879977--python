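# Methods

This note documents the models, parameter choices and numerical decisions
behind `intronscape`, and what the synthetic benchmarks do and do not show
about real data.

## The intron landscape model

The package assumes a genome whose introns fall into three kinds of
classes. *Canonical* spliceosomal introns are singletons: each sequence is
effectively unique, with GT–AG termini and an `NCTGAC` branch-point motif
expected 43–52 nt upstream of the acceptor. *BOC1* introns are a
geography-defined class: short (<75 nt, strict), AT-rich (<43 GC%, strict)
introns inside a configured low-GC chromosomal region; both thresholds are
taken as printed, so boundary cases (length exactly 75, GC exactly 43.0)
fall to canonical. *Introner elements* (IEs) are repeat introns: families
of near-identical copies at unique gene positions, interpreted as recently
mobile introns spreading by intron transposition (reverse splicing of an
excised intron into a pre-mRNA, reverse transcription, homologous
recombination). Because IE membership is sequence evidence while BOC1
membership is geography, IE takes precedence when both rules apply.

Branch-point offsets count from the motif start to the intron's 3'
terminal base, inclusive; the convention is configurable to anchor at the
motif's last base instead, since the printed "43–52 bp upstream" does not
say which end is measured.

## Repeat-family discovery

Families are connected components (single linkage) of a similarity graph:
an edge joins two introns when a gapped local alignment reaches ≥ 70%
identity over ≥ 80% of the shorter sequence. Single linkage is
deliberate — IE subclasses share universal motif blocks, so chained
similarity is biologically expected. Components need ≥ 3 members
(`min_family_size`), small enough that a six-member family is found.

A shared-12-mer prefilter limits the quadratic alignment work. For the
pairs discovery relies on — copies within ~10% of a common master, hence
≥ ~80% mutual identity over ≥ 100 nt — the expected number of shared exact
12-mers is ≈ 10 and the filter is effectively lossless (checked against
the unfiltered scan in the tests). Near the 70% floor it can miss pairs;
`k` is configurable downward when exhaustiveness matters more than time.

Consensus sequences come from a star alignment: members (capped at 50,
sorted by id) are globally aligned to a reference member of median length,
reference columns with > 50% gaps are dropped, and each kept column takes
its majority base. Column conservation is the majority-base fraction *over
the members that carry the column* — a motif block deleted in one
subfamily must remain detectable as a conserved run among the members that
have it. Motif blocks are maximal consensus runs with conservation ≥ 0.8
and length ≥ 20 nt, named A, B, C… 5'→3'; each member is labeled by its
block presence/absence pattern (semi-global block match at ≥ 70%
identity), patterns carried by ≥ 3 members become subfamilies, and rarer
patterns are "ambiguous" — mirroring how indel-degraded elements resist
clean subfamily assignment. A full progressive MSA (or an external MSA
tool) would add little at these divergences and would cost determinism;
the star alignment recovers a 20-member, ≤10%-mutated master to within 2
edits in the tests.

Remnant scanning aligns each family consensus and block semi-globally
along both genome strands. A hit is any location whose exact edit distance
satisfies `d ≤ floor(m·(1 − 0.65))` for a query of length `m` (found by
best-hit-and-split recursion with edlib); overlapping hits merge keeping
the best identity. The same integer rule defines the exhaustive
dynamic-programming oracle the scan is tested against, so "scan equals
oracle" is a well-defined set equality. Hits in coding context are flagged
`cds` but never dropped: their absence in real genomes is an observation
about selection, not a filter.

## Ortholog intron-position comparison

One-to-one orthologs are reciprocal best hits under global protein
alignment (BLOSUM62, gap open −11, extend −1); ties break toward the
smallest partner id, and a caller-supplied ortholog map bypasses RBH
entirely (the hook used when an external orthology exists). An intron
after coding nucleotide `c` projects to the alignment column of residue
`⌈c/3⌉` with phase `c mod 3`; two introns share a position when their
(column, phase) keys are equal and their classes match — cross-class
matches are tallied separately. Introns projecting into a partner gap
column keep their own column and simply find no match: conservative and
deterministic, no nearest-column rescue.

The shared fraction is reported symmetrically as `2·s/(n_A + n_B)`, with
both per-strain fractions `s/n_A`, `s/n_B` always emitted, since the
denominator behind a published "X% of positions are shared" is usually
unstated.

## PAP calling from fragments

Fragments are strand-unknown. Mapping uses an exact 21-mer index of the
reference (ambiguous and high-multiplicity seeds skipped), a dominant
diagonal band to chain colinear seeds, and affine-gap semi-global
extension of the whole fragment into the chained window. Affine scoring
(match 2, mismatch −4, gap −10/−0.5, reference end gaps free) matters:
under unit-cost edit distance, near-identical repeat copies in the window
let the optimum trade one clean structural gap for scattered gaps paired
across the wrong copies. Alignment identity is substitution-level (gap
columns excluded): a 150-nt structural deletion inside an 800-nt fragment
is the signal being sought and must not disqualify the fragment from its
own 90% identity floor; the per-column identity is reported alongside.

A deletion gap matching an annotated IE intron interval within ±5 nt
(slack for microhomology jitter at the splice sites) is an
`absent_in_fragment` event; an insertion gap ≥ 40 nt whose sequence
matches a family consensus semi-globally at ≥ 65% identity, at a point
inside an annotated gene and sense-oriented after flipping to the gene
strand, is `novel_in_fragment`. Both require ≥ 40 fragment bases of flank
on each side of the gap at ≥ 90% identity. Events deduplicate by
(sequence, position ±5, type, family) with supporting-fragment counts.
The two event types are asymmetric by construction: absence calls need
only the reference annotation, novel calls additionally need a family
consensus match.

## The simulator

The simulator is blueprint-based: genes are a coding sequence plus introns
at coding offsets; chromosomes are spacers and genes grouped into GC
zones; genomic coordinates exist only at emission, which is a pure
function of the blueprint. One seeded generator drives everything, so a
run is byte-reproducible.

Default study conditions (one 2-Mb chromosome, GC 0.60 with a 25% low-GC
zone at 0.42; 800 genes of 150–450 codons; 2000 canonical introns of
60–300 nt at GC 0.52 with the branch motif planted at a uniform 43–52
offset; 300 BOC1 introns of 45–74 nt at GC 0.27 confined to the low-GC
zone, 10% with TG/CG acceptors; one IE family: 150-nt GT–AG master at GC
0.55, 300 copies at per-copy divergence U[0, 0.10], insertion probability
∝ (gene CDS GC)^4, phase bias (0.2, 0.2, 0.6)). Canonical introns are
planted outside the low-GC zone and BOC1 introns inside it, giving the
classifier an unambiguous truth; BOC1 GC 0.27 keeps the binomial tail
crossing the 43% threshold below ~1%. Insertion sites are coding positions
without a proto-splice-site requirement (an option exists, default off,
because no insertion-site motif is detectable in the real data); the
RNA-level mechanics of reverse splicing are not simulated — only their
genomic consequence, a planted copy, is observable anyway.

**Strain divergence.** The per-class parameter `q_class` is defined as the
*target shared-position fraction* `2s/(n_A+n_B)`. A model that keeps an
intron in both lineages with probability `q` and otherwise drops it from
one lineage yields an expected shared fraction `2q/(1+q)`, not `q`; the
simulator therefore inverts, using joint-retention probability `q/(2−q)`,
and by default allocates exact counts (a variance-reduction choice that
makes the realized fraction equal the target up to rounding; per-intron
Bernoulli sampling remains available). Post-split IE gains are added per
lineage and never shared. Substitution drift preserves intron termini and
rejects mutations that would create an in-frame stop, so every planted
intron remains excisable to an open reading frame.

**Degradation.** Selected IE copies leave intron context and are planted
in spacers or inside surviving canonical introns, mutated to a target
identity, with indels at a 2:1 deletion:insertion bias (the direction is
documented for the real elements; the exact ratio is a default, not a
measurement) and optional truncation to a 50-nt core.

**Fragments.** Read-like fragments are sampled from the non-reference
lineage with per-base error (default 1%, length 800, n 400), stratified:
half cover a locus where the reference carries an IE the fragment lineage
lacks, a quarter cover a fragment-lineage-specific IE, a quarter are
neutral. The fragment lineage is configured as a conspecific wild relative
(singleton-intron retention 1.0, substitution rate 0.005 per lineage, IE
retention 0.5 plus 50 gains per lineage): the replication analysis this
emulates concerns reads nearly identical to the reference apart from IE
presence, not the deeply diverged sister strain of the shared-position
analysis. Only *isolated* loci are sampled as events — no other repeat
copy (differing or shared) within a fragment length — because two
near-identical copies within one fragment let any aligner parsimoniously
read an absence-plus-novel pair as a single shifted element; clustered
loci are excluded from sensitivity accounting but neutral fragments still
avoid them. This is the main caveat when extrapolating the benchmark
sensitivities to real data, where tandem or nested insertions do occur and
are intrinsically harder.

## What the synthetic benchmarks show

Passing tests demonstrate that each stage recovers what was planted under
the stated noise model: i.i.d. substitutions, modest indels, no
sequencing-quality structure, no annotation error, no paralogy beyond the
planted repeat families. Real genomes add misannotated gene models,
UTR introns (this package restricts to CDS introns; counts may differ from
annotations that include UTRs), segmental duplications that blur RBH
orthology, and repeat families with internal rearrangements. The
benchmarks bound algorithmic correctness, not biological error rates.

## Problem sizes and numerical choices

The acceptance-scale runs use the defaults above (2-Mb genome for
discovery/classification/phase recovery; 1.3-Mb two-strain pairs with
2000 introns per singleton class for the shared-position estimator;
20 sequences ≤ 50 kb with 10 planted blocks each for the scan oracle;
400 fragments for PAP). Consensus sampling caps at 50 members; seed-index
k is 21; fragment chaining tolerates ≤ 2 kb of net indel. All ties break
deterministically (consensus bases A<C<G<T, RBH partners by id, family ids
by size then member id). Degenerate inputs — empty classes, genomes
without genes, families without blocks — return empty artifacts rather
than erroring.
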