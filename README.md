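# artemisdx

Cas12a-targetable SNV discovery and CRISPR-diagnostics (CRISPRdx) assay
design, as a Python library and CLI.

## The problem

LbCas12a interrogates double-stranded DNA next to a T-rich PAM (TTTV,
V = A/C/G) using a crRNA whose spacer base-pairs with the target strand.
Target-activated Cas12a then cleaves a quenched single-stranded reporter
indiscriminately (collateral cleavage), turning target recognition into a
fluorescence signal — the basis of CRISPRdx assays. Cas12a only reliably
discriminates single-nucleotide differences inside the *seed*: the
PAM-proximal ~5 nt of the spacer:protospacer duplex. A single-nucleotide
variant (SNV) is therefore a good diagnostic target only when a PAM
occurrence on either strand places it at seed position 1–5, i.e. within
five nucleotides 3′ of a TTTV PAM. Discrimination is further sharpened by
a *synthetic mismatch*: one deliberate substitution in the crRNA seed at
a position other than the SNV, typically chosen so that the crRNA base
equals the target-strand base (a homopair: G·G, A·A, C·C or U·T).

`artemisdx` implements the full desk-side workflow:

1. **scan** — for every SNV in a VCF, find each (SNV, PAM) pair with the
   SNV in the seed window on either strand of a reference FASTA; emit an
   annotated VCF (`ARTEMIS_PAM`, `ARTEMIS_SEED`, `ARTEMIS_STRAND`,
   `ARTEMIS_GRNA_REF`, `ARTEMIS_GRNA_ALT` INFO keys), with optional
   exclusion of PAMs overlapped by common population variants
   (AF ≥ 0.01 by default) and free-text keyword filtering of the
   variant annotations.
2. **design** — allele-specific crRNAs: the 21-nt LbCas12a direct-repeat
   scaffold `UAAUUUCUACUAAGUGUAGAU` plus a 21-nt spacer copying the
   protospacer (T→U), with all homopair synthetic mismatches enumerated
   over the seed (4 designs for a 5-nt seed).
3. **oligos** — wild-type and mutant synthetic dsDNA test targets laid
   out as `[≥15 nt flank]-[PAM]-[protospacer]-[≥15 nt flank]`
   (55 nt with defaults), both strands.
4. **primers** — amplicon checks for PCR/RPA pre-amplification: 60–120 bp
   amplicons (cfDNA-compatible) that contain but never overlap the
   PAM+protospacer (overlapping primers falsely activate Cas12a).
5. **mix** — exact C1·V1 = C2·V2 recipe arithmetic with water fill for the
   annealing, detection-mastermix, PCR and RPA mixes.
6. **kinetics** — plate-reader kinetic table parsing (wells as columns,
   timepoints as rows), baseline removal, and replicate-aggregated
   endpoint fluorescence ratios with propagated standard deviations.
7. **fixtures** — seeded toy genomes with planted PAMs, seed SNVs and
   labeled decoys, plus an independent brute-force scan oracle.

## Worked example

```bash
# make a toy dataset with 5 planted targetable SNVs and 5 decoys
artemisdx fixtures toydata --seed 1

# scan it (annotated VCF on stdout, just like `scan ref.fa clinvar.vcf > hits.vcf`)
artemisdx scan toydata/toy_genome.fa toydata/toy_variants.vcf > hits.vcf

# crRNA designs with homopair synthetic mismatches
artemisdx design toydata/toy_genome.fa toydata/toy_variants.vcf | head -3

# the detection mastermix
artemisdx mix mastermix
```

The scan logs `scanned 9 SNV record(s) (1 non-SNV skipped): 5 hit(s)`
and writes five VCF records, e.g.

```
chr_toy  323  snv1  C  T  .  .  CLNDN=Melanoma;ARTEMIS_PAM=-7;ARTEMIS_SEED=4;ARTEMIS_STRAND=+;ARTEMIS_GRNA_REF=CAACCACTAGAACAGGTTAAT;ARTEMIS_GRNA_ALT=CAATCACTAGAACAGGTTAAT
```

— the PAM starts 7 bp left of the SNV, the SNV sits at seed position 4,
and the two 21-nt spacer target sequences differ only there. The
mastermix command prints

```
# CRISPRdx mastermix: 20 uL total
reagent	stock	final	volume_ul	note
CutSmart Buffer	10 x	1 x	2.00
FAM reporter	10 uM	100 nM	0.20
crRNA	10 uM	50 nM	0.10
EnGen LbCas12a	10 uM	40 nM	0.08
target DNA	-	-	2.00	add last, outside mastermix
Water	-	-	15.62	fill
```

i.e. a 20 µL reaction at 40 nM Cas12a, 50 nM crRNA and 100 nM reporter,
filled with 15.62 µL water.

In Python the same scan is three lines:

```python
from artemisdx import read_fasta, read_vcf, scan
hits = scan(read_fasta("toydata/toy_genome.fa"),
            read_vcf("toydata/toy_variants.vcf", require_snv=True))
print(hits[0].seed_pos, hits[0].spacer_ref)
```

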