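# Methods

## Targetability model

LbCas12a recognizes a TTTV PAM (V = A/C/G) and unwinds the adjacent DNA
so that the crRNA spacer hybridizes the target strand; the
**protospacer** is the corresponding sequence on the PAM-containing
(non-target) strand. Single-nucleotide discrimination is effectively
confined to the **seed**, modeled here as the `seed_size` (default 5)
bases immediately 3′ of the PAM along the protospacer. An SNV is a hit
for a PAM when its seed offset is in `[1, seed_size]`:

* forward-strand PAM over 0-based `[s, e)`: offset = `pos0 − e + 1`;
* reverse-strand PAM over `[s, e)`: offset = `s − pos0` (the seed walks
  leftwards on the reference).

One hit is emitted per (SNV, PAM) pair — an SNV flanked by several PAMs
yields several candidate designs — together with the reference- and
alternate-allele protospacer sequences (`spacer_length`, default 21 nt),
extracted in protospacer orientation; for reverse-strand PAMs the window
is reverse-complemented and the alleles complemented. Hits whose full
spacer window would leave the contig are dropped and counted in a
warning. SNVs that would themselves create or destroy a PAM are out of
scope: PAMs are always located on the reference sequence.

Coordinates follow one rule: VCF positions are 1-based, all internal
arithmetic is 0-based half-open, and the conversion happens once at the
I/O boundary. Contig names must match exactly between FASTA and VCF; a
mismatch is a hard error listing both name sets rather than a silent
`chr`-prefix repair. IUPAC ambiguity codes other than N in the reference
are collapsed to N, and N never satisfies any PAM base.

The PAM motif is configurable as an IUPAC word (compiled to a regular
expression) or as a raw regex; the reverse strand is scanned by matching
the same pattern on the reverse-complemented sequence and mapping
coordinates back, which keeps arbitrary regexes usable on both strands.
Output ordering is deterministic — (contig, position, `+` before `-`,
PAM start) — so repeated runs are byte-identical.

## Filters

**Common-PAM exclusion.** A hit is discarded when a population variant
with allele frequency ≥ `af_threshold` overlaps any PAM base. The
threshold defaults to 0.01, the usual "common variant" convention;
variants with unknown AF never exclude (unknown ≠ zero). The exclusion
window covers the PAM only; an `include_seed` flag extends it over the
seed bases for users who also want to guard the seed against population
variation.

**Keyword filter.** Case-insensitive substring match of any keyword
against any INFO value of the underlying variant (e.g. "melanoma",
"carcinoma" against ClinVar-style disease annotations). An empty keyword
list is the identity.

## Guide, oligo and primer design

The crRNA is the LbCas12a direct repeat `UAAUUUCUACUAAGUGUAGAU` followed
by the spacer, which copies the protospacer with T→U (the spacer and
protospacer share sequence because the spacer pairs with the target
strand). A **synthetic mismatch** is placed at one seed position
`p ≠ seed_pos` of the SNV — the SNV position must stay matched, since it
is the discriminating base — giving `seed_size − 1` designs per allele.
In the default *homopair* mode the crRNA base at `p` is set to the RNA
form of the target-strand base, producing an identical-base pairing
(G·G, A·A, C·C, U·T); an *all* mode emits every mismatching base and
flags G·T / U·G wobble pairings as advisory (flagged, not forbidden).
The package enumerates designs and does not rank them: the optimal
mismatch position and base are empirical and assay-dependent.

Synthetic dsDNA test targets are laid out on the PAM-containing strand
as `[flank]-[PAM]-[protospacer]-[flank]` with ≥ 15-nt flanks (55 nt
with all defaults), built for both alleles (differing at exactly the SNV)
and emitted as complementary top/bottom strands.

Primer checks enforce the two rules that matter for a CRISPRdx
pre-amplification: the amplicon (inclusive of both primer footprints)
must contain the PAM+protospacer span but neither primer may overlap it
(an overlapping primer itself activates Cas12a), and the amplicon length
must lie within configurable bounds, default 60–120 bp to fit on single
cell-free DNA fragments (~160 nt). Each primer must map uniquely and the
pair must be convergent; non-uniqueness is an error, rule violations a
"fail" verdict with reasons. Melting temperature, GC content and dimer
thermodynamics are out of scope (standard external primer tools cover
them).

## Recipe arithmetic

Component volumes are `total × final/stock` after unit normalization
(molar, enzyme activity in U/mL, fold for `10x → 1x` buffers), rounded to
2 decimals **half-up** — the convention required to reproduce sub-0.1 µL
cells such as 0.08 µL Cas12a (40 nM final from a 10 µM stock in 20 µL)
and 0.07 µL RPA primers (467 nM from 100 µM in 15 µL, exact value
0.07005). The water fill absorbs the rounding residue so that
Σ volumes + water = total exactly (verified in `Decimal` arithmetic).
Note that the isothermal-amplification recipe's exact fill is 1.01 µL
(the rounded component volumes sum to 13.99 of 15 µL); bench protocols
typically quote 1 µL. Mastermix scaling (replicates × (1 + surplus),
e.g. ×1.1 for a ~10% surplus) is a pure multiplication of all volumes.
Annealing of the two complementary oligos requires equimolar amounts
(within 1%); the duplex concentration is (stock × volume)/total, 10 µM
for 2 × 5 µL of 100 µM oligos in 50 µL. Order-of-addition constraints
(MgOAc starts the RPA reaction; synthetic target is never pipetted into
the mastermix) are carried as annotations, not modeled kinetically.

## Kinetics

Plate-reader exports are parsed as a delimited matrix with time (minutes)
in the first column and one well per remaining column; replicate
grouping is an explicit well→group map, since adjacency conventions are
instrument-software-specific. Baseline removal is either each trace's
own first timepoint (every corrected trace then starts at exactly 0) or
the timepoint-wise mean of a negative-control group. Group comparison
uses the **endpoint** ratio (last common timepoint by default; plateau
detection is not automated, and area-under-curve aggregation was
deliberately not used): ratio = mean(numerator)/mean(denominator), with
the standard deviation from first-order quotient propagation,
`sd = sqrt((s_n/m_d)² + (r·s_d/m_d)²)` with sample standard deviations
(ddof = 1, zero for n = 1). The ratio is scale-invariant, so detector
gain drops out.

## Synthetic data generator and what it does (not) show

`fixtures.generate_toy_genome` is the test bed: a seeded random
background guaranteed PAM-free for the default motif (no TTT or AAA run
can occur, so no TTTV on either strand), with PAM motifs planted at
well-separated positions on alternating strands, junction bases
sanitized so planted motifs cannot combine with the background into
extra PAMs, and the final sequence verified by exhaustive enumeration
(bounded retries, then an error). SNVs are planted at chosen seed
offsets (hits) and as labeled decoys — offset beyond the seed window,
inside the PAM, far from any PAM, and an indel — so a failing test
localizes the broken rule. Everything derives from one `random.Random`
seed; regeneration is byte-identical.

The generator emulates the *geometry* of the scan problem, not real
genomes: uniform base composition, no repeats, no near-PAM degenerate
motifs beyond what sanitization removes, well-separated features, and a
single toy contig. Passing tests therefore demonstrate correctness of
the coordinate/strand/spacer logic and filters, not performance or hit
yields on human-genome-scale, repeat-rich input.

`fixtures.brute_force_scan` is the independent oracle: exhaustive
sliding-window matching by direct base comparison against a locally
expanded IUPAC table (no regex), explicit enumeration of seed
coordinates and plain slicing, with its own complement table. It shares
only the data containers with the production scan. The test suite and
the acceptance script check exact hit-set equality (including spacer
sequences) across 100 seeded toy genomes of ~0.8–1 kb with 3 PAM
islands, 4 planted hits and 4 decoys each — sizes chosen so the whole
suite runs in seconds while still exercising both strands, all seed
offsets and every decoy class.

## Known limitations

* No off-target search or cleavage-efficiency prediction; hits are
  geometric candidates, not ranked guides.
* PAM-creating/destroying SNVs are not modeled.
* Primer thermodynamics are delegated to external tools.
* Kinetic analysis assumes a shared time axis per plate and endpoint
  ratios; no plateau detection or ANOVA.
* The scan recomputes PAM sites per contig in memory; it is designed for
  desk-scale inputs (toy contigs to full chromosomes), not streaming.
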