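"""Synthetic toy genomes with planted, labeled ground truth, plus an
independent brute-force oracle for the scan.

The generator builds a random background sequence that provably contains
no PAM on either strand (no TTT or AAA runs for the default TTTV motif),
then plants PAM motifs at well-separated positions on alternating
strands, SNVs at chosen seed offsets (hits), and decoy variants (seed
offset beyond the window, inside the PAM, far from any PAM, and an
indel), each labeled in a truth table so failures localize.

:func:`brute_force_scan` re-derives hits by exhaustive enumeration —
direct base comparison against a locally expanded IUPAC table, explicit
seed-coordinate checks and plain slicing, with its own complement table
and no regular expressions — so it shares no logic with the production
scan and serves as a genuine cross-check.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path

import pysam

from .artemis_core import ArtemisHit, PamSite, ScanConfig
from .genome_io import GenomeSequence, Strand, VariantRecord

__all__ = ["PlantedTruth", "generate_toy_genome", "brute_force_scan"]

# local tables, deliberately not imported from genome_io/artemis_core
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
_IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_CLNDN_VOCAB = (
    "Melanoma",
    "Lung_carcinoma",
    "Colorectal_cancer",
    "Cystic_fibrosis",
    "Benign_polymorphism",
)


def _rc(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def _word_matches(word: str, motif: str) -> bool:
    return len(word) == len(motif) and all(
        w in _IUPAC_SETS[m] for w, m in zip(word, motif)
    )


def brute_force_scan(
    genome_map: dict[str, GenomeSequence],
    variants,
    config: ScanConfig = ScanConfig(),
) -> list[ArtemisHit]:
    """Exhaustive-enumeration oracle for the targetability scan.

    For every SNV, every window of PAM length at every position is tested
    on both strands by direct base comparison; seed membership is checked
    by enumerating the seed coordinates explicitly; spacers are assembled
    by direct slicing.  Intended for small inputs (<= 100 kb).
    """
    motif = config.pam_pattern.upper()
    if not all(c in _IUPAC_SETS for c in motif):
        raise ValueError("the brute-force oracle supports plain IUPAC motifs only")
    plen = len(motif)
    spacer_len = config.spacer_length
    hits: list[ArtemisHit] = []
    for variant in variants:
        if not variant.is_snv:
            continue
        genome = genome_map[variant.contig_id]
        seq = genome.sequence
        pos0 = variant.pos - 1
        for start in range(0, len(seq) - plen + 1):
            end = start + plen
            word = seq[start:end]
            if _word_matches(word, motif):
                for k in range(1, config.seed_size + 1):
                    if pos0 == end - 1 + k and end + spacer_len <= len(seq):
                        window = seq[end:end + spacer_len]
                        alt_sp = (
                            window[: k - 1] + variant.alt_allele + window[k:]
                        )
                        hits.append(
                            ArtemisHit(
                                variant,
                                PamSite(genome.contig_id, start, end,
                                        Strand.FORWARD, word),
                                k, window, alt_sp,
                            )
                        )
            if config.both_strands and _word_matches(_rc(word), motif):
                for k in range(1, config.seed_size + 1):
                    if pos0 == start - k and start - spacer_len >= 0:
                        window = _rc(seq[start - spacer_len:start])
                        alt_sp = (
                            window[: k - 1] + _COMP[variant.alt_allele] + window[k:]
                        )
                        hits.append(
                            ArtemisHit(
                                variant,
                                PamSite(genome.contig_id, start, end,
                                        Strand.REVERSE, _rc(word)),
                                k, window, alt_sp,
                            )
                        )
    hits.sort(
        key=lambda h: (
            h.variant.contig_id,
            h.variant.pos - 1,
            h.pam.strand is Strand.REVERSE,
            h.pam.start,
        )
    )
    return hits


@dataclass
class PlantedTruth:
    """A generated toy dataset with its expected scan output.

    ``labels`` maps each variant id to its planted class: ``seed_hit``,
    ``offset_N`` (seed offset beyond the window), ``in_PAM``, ``no_PAM``
    or ``indel``.
    """

    genomes: list[GenomeSequence]
    variants: list[VariantRecord]
    expected_hits: list[ArtemisHit]
    seed: int
    labels: dict[str, str]

    @property
    def genome_map(self) -> dict[str, GenomeSequence]:
        return {g.contig_id: g for g in self.genomes}

    def write(self, directory: str | Path) -> dict[str, Path]:
        """Emit FASTA + VCF + truth TSV; byte-identical for a given seed."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": directory / "toy_genome.fa",
            "vcf": directory / "toy_variants.vcf",
            "truth": directory / "truth.tsv",
        }
        with open(paths["fasta"], "w") as fh:
            for g in self.genomes:
                fh.write(f">{g.contig_id}\n")
                for i in range(0, len(g.sequence), 70):
                    fh.write(g.sequence[i:i + 70] + "\n")
        header = pysam.VariantHeader()
        for g in self.genomes:
            header.add_line(f"##contig=<ID={g.contig_id},length={len(g.sequence)}>")
        header.add_line(
            '##INFO=<ID=CLNDN,Number=.,Type=String,Description="Disease name">'
        )
        header.add_line(
            '##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">'
        )
        out = pysam.VariantFile(str(paths["vcf"]), "w", header=header)
        try:
            for v in self.variants:
                rec = out.new_record(
                    contig=v.contig_id,
                    start=v.pos0,
                    stop=v.pos0 + len(v.ref_allele),
                    alleles=(v.ref_allele, v.alt_allele),
                    id=v.variant_id,
                )
                if "CLNDN" in v.info:
                    rec.info["CLNDN"] = v.info["CLNDN"]
                if v.af is not None:
                    rec.info["AF"] = v.af
                out.write(rec)
        finally:
            out.close()
        hit_by_id = {h.variant.variant_id: h for h in self.expected_hits}
        with open(paths["truth"], "w") as fh:
            fh.write(
                "variant_id\tclass\tcontig\tpos\tref\talt\t"
                "pam_start\tpam_end\tstrand\tseed_pos\n"
            )
            for v in self.variants:
                h = hit_by_id.get(v.variant_id)
                pam_cols = (
                    f"{h.pam.start}\t{h.pam.end}\t{h.pam.strand.value}\t{h.seed_pos}"
                    if h else "\t\t\t"
                )
                fh.write(
                    f"{v.variant_id}\t{self.labels[v.variant_id]}\t{v.contig_id}\t"
                    f"{v.pos}\t{v.ref_allele}\t{v.alt_allele}\t{pam_cols}\n"
                )
        return paths


def _background(length: int, rng: random.Random) -> list[str]:
    """Random sequence with no TTT or AAA run, hence no TTTV PAM on either strand."""
    bases: list[str] = []
    for _ in range(length):
        choices = "ACGT"
        if len(bases) >= 2 and bases[-1] == bases[-2] == "T":
            choices = "ACG"
        elif len(bases) >= 2 and bases[-1] == bases[-2] == "A":
            choices = "CGT"
        bases.append(rng.choice(choices))
    return bases


def _all_pam_sites(seq: str, motif: str) -> set[tuple[int, str]]:
    plen = len(motif)
    found = set()
    for s in range(len(seq) - plen + 1):
        w = seq[s:s + plen]
        if _word_matches(w, motif):
            found.add((s, "+"))
        if _word_matches(_rc(w), motif):
            found.add((s, "-"))
    return found


def generate_toy_genome(
    length: int = 2000,
    n_pams: int = 5,
    n_seed_snvs: int = 5,
    n_decoy_snvs: int = 5,
    seed: int = 0,
    *,
    snv_offsets: list[int] | None = None,
    contig_id: str = "chr_toy",
    config: ScanConfig = ScanConfig(),
    max_retries: int = 20,
) -> PlantedTruth:
    """Generate a toy contig with planted PAMs, seed SNVs and decoys.

    PAMs alternate between the forward and reverse strand.  ``snv_offsets``
    fixes the seed offsets of the PAM-relative SNVs (offsets beyond
    ``config.seed_size`` become labeled decoys, useful for boundary
    fixtures); by default offsets are drawn uniformly from the seed
    window.  Decoys cycle through the classes in-PAM, far-from-PAM and
    indel.  Regeneration with the same seed is byte-identical.
    """
    motif = config.pam_pattern.upper()
    plen = len(motif)
    margin = config.spacer_length + plen + 20
    slot_pitch = 2 * margin
    slots = list(range(margin, length - margin - plen, slot_pitch))
    if n_pams > len(slots):
        raise ValueError(
            f"length {length} too small for {n_pams} PAM islands "
            f"(fits {len(slots)} at pitch {slot_pitch})"
        )
    if snv_offsets is not None:
        n_seed_snvs = len(snv_offsets)
    rng = random.Random(seed)
    for _attempt in range(max_retries):
        seq = _background(length, rng)
        pam_positions = sorted(rng.sample(slots, n_pams))
        pams: list[tuple[int, Strand, str]] = []
        for i, p in enumerate(pam_positions):
            strand = Strand.FORWARD if i % 2 == 0 else Strand.REVERSE
            pam_word = "TTT" + rng.choice("ACG") if motif == "TTTV" else None
            if pam_word is None:
                # expand an arbitrary IUPAC motif to one concrete word
                pam_word = "".join(rng.choice(_IUPAC_SETS[c]) for c in motif)
            text = pam_word if strand is Strand.FORWARD else _rc(pam_word)
            seq[p:p + plen] = list(text)
            # sanitize junctions so planted motifs cannot extend into new PAMs
            if p - 1 >= 0:
                seq[p - 1] = "C"
            if p + plen < length:
                seq[p + plen] = "C"
            pams.append((p, strand, pam_word))
        genome_seq = "".join(seq)
        planted = {(p, s.value) for p, s, _ in pams}
        if _all_pam_sites(genome_seq, motif) == planted:
            break
    else:
        raise ValueError("could not place PAMs without collisions; enlarge length")

    used_positions: set[int] = set()
    variants: list[VariantRecord] = []
    labels: dict[str, str] = {}
    planted_hits: list[tuple[VariantRecord, int, Strand, str, int]] = []

    def snv_at(pos0: int, vid: str, info_idx: int) -> VariantRecord:
        ref = genome_seq[pos0]
        alt = rng.choice([b for b in "ACGT" if b != ref])
        return VariantRecord(
            contig_id=contig_id,
            pos=pos0 + 1,
            variant_id=vid,
            ref_allele=ref,
            alt_allele=alt,
            info={"CLNDN": _CLNDN_VOCAB[info_idx % len(_CLNDN_VOCAB)]},
        )

    def offset_position(pam_idx: int, offset: int) -> int:
        p, strand, _ = pams[pam_idx]
        if strand is Strand.FORWARD:
            return p + plen - 1 + offset
        return p - offset

    # PAM-relative SNVs (hits when offset <= seed_size, labeled decoys beyond)
    placed = 0
    attempt_idx = 0
    while placed < n_seed_snvs:
        offset = (
            snv_offsets[placed]
            if snv_offsets is not None
            else rng.randint(1, config.seed_size)
        )
        pam_idx = attempt_idx % n_pams
        attempt_idx += 1
        pos0 = offset_position(pam_idx, offset)
        if pos0 in used_positions:
            if attempt_idx > n_seed_snvs * n_pams * 4:
                raise ValueError("could not place all PAM-relative SNVs uniquely")
            continue
        used_positions.add(pos0)
        vid = f"snv{placed + 1}"
        variant = snv_at(pos0, vid, placed)
        variants.append(variant)
        if offset <= config.seed_size:
            labels[vid] = "seed_hit"
            p, strand, word = pams[pam_idx]
            planted_hits.append((variant, offset, strand, word, p))
        else:
            labels[vid] = f"offset_{offset}"
        placed += 1

    decoy_classes = ("offset_far", "in_PAM", "no_PAM", "indel")
    for d in range(n_decoy_snvs):
        cls = decoy_classes[d % len(decoy_classes)]
        vid = f"decoy{d + 1}"
        if cls == "offset_far":
            for _ in range(50):
                pos0 = offset_position(
                    rng.randrange(n_pams),
                    config.seed_size + rng.randint(1, 3),
                )
                if pos0 not in used_positions:
                    break
            labels[vid] = f"offset_{config.seed_size + 1}_plus"
        elif cls == "in_PAM":
            for _ in range(50):
                pos0 = pams[rng.randrange(n_pams)][0] + rng.randrange(plen)
                if pos0 not in used_positions:
                    break
            labels[vid] = "in_PAM"
        else:
            for _ in range(200):
                pos0 = rng.randrange(10, length - 10)
                if pos0 not in used_positions and all(
                    abs(pos0 - p) > margin for p, _, _ in pams
                ):
                    break
            labels[vid] = cls
        if pos0 in used_positions:
            raise ValueError("could not place decoy variants uniquely")
        used_positions.add(pos0)
        if cls == "indel":
            ref = genome_seq[pos0]
            variants.append(
                VariantRecord(
                    contig_id=contig_id,
                    pos=pos0 + 1,
                    variant_id=vid,
                    ref_allele=ref,
                    alt_allele=ref + "A",
                    info={"CLNDN": _CLNDN_VOCAB[d % len(_CLNDN_VOCAB)]},
                )
            )
        else:
            variants.append(snv_at(pos0, vid, d))

    variants.sort(key=lambda v: v.pos)
    genome = GenomeSequence(contig_id, genome_seq)

    expected: list[ArtemisHit] = []
    for variant, offset, strand, word, p in planted_hits:
        if strand is Strand.FORWARD:
            window = genome_seq[p + plen:p + plen + config.spacer_length]
            alt_sp = window[: offset - 1] + variant.alt_allele + window[offset:]
        else:
            window = _rc(genome_seq[p - config.spacer_length:p])
            alt_sp = window[: offset - 1] + _COMP[variant.alt_allele] + window[offset:]
        expected.append(
            ArtemisHit(
                variant,
                PamSite(contig_id, p, p + plen, strand, word),
                offset, window, alt_sp,
            )
        )
    expected.sort(
        key=lambda h: (
            h.variant.contig_id,
            h.variant.pos - 1,
            h.pam.strand is Strand.REVERSE,
            h.pam.start,
        )
    )
    return PlantedTruth(
        genomes=[genome],
        variants=variants,
        expected_hits=expected,
        seed=seed,
        labels=labels,
    )
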