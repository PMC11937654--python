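import pytest

from artemisdx import GenomeSequence, ScanConfig, VariantRecord, scan

# The worked toy case used throughout: a TTTA PAM at [2,6) and an A>G SNV
# at seed position 3 of the adjacent protospacer.
TOY_SEQ = "GGTTTACGATCGATCGATCGATCGATCGATCG"

# Same locus embedded in GC-only padding (which can host no TTTV/BAAA PAM)
# so that 15-nt oligo flanks and a 21-nt spacer window fit on the contig.
PADDED_SEQ = "GCCGGCCGGCCGG" + TOY_SEQ + "CCGGCCGGCC"


@pytest.fixture
def toy_genome():
    return GenomeSequence("chr_toy", TOY_SEQ)


@pytest.fixture
def toy_variant():
    return VariantRecord("chr_toy", 9, "rs_toy", "A", "G",
                         info={"CLNDN": "Melanoma"})


@pytest.fixture
def toy_hit(toy_genome, toy_variant):
    hits = scan({"chr_toy": toy_genome}, [toy_variant], ScanConfig())
    assert len(hits) == 1
    return hits[0]


@pytest.fixture
def padded_genome():
    return GenomeSequence("chr_pad", PADDED_SEQ)


@pytest.fixture
def padded_hit(padded_genome):
    variant = VariantRecord("chr_pad", 22, "rs_pad", "A", "G",
                            info={"CLNDN": "Melanoma"})
    hits = scan({"chr_pad": padded_genome}, [variant], ScanConfig())
    assert len(hits) == 1
    return hits[0]


def write_text_vcf(path, records, contigs=("chr_toy",)):
    """Minimal hand-written VCF for parser tests; records are raw data lines."""
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c}>" for c in contigs]
    lines.append('##INFO=<ID=AF,Number=A,Type=Float,Description="AF">')
    lines.append('##INFO=<ID=CLNDN,Number=.,Type=String,Description="Disease">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    lines += records
    path.write_text("\n".join(lines) + "\n")
    return path
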