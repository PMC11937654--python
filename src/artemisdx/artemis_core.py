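"""The ARTEMIS scan: Cas12a-targetable SNV discovery.

Cas12a requires a short T-rich PAM (default TTTV, V = A/C/G) directly 5'
of its protospacer, and discriminates single-nucleotide differences almost
exclusively inside the *seed* — the PAM-proximal stretch of the
spacer:protospacer duplex (default 5 nt).  An SNV is therefore
"targetable" when some PAM occurrence places it inside the seed window on
either strand.  This module finds every such (SNV, PAM) pair, extracts the
reference- and alternate-allele spacer target sequences in protospacer
orientation, and applies the two downstream filters of the pipeline:
exclusion of PAMs disrupted by common population variants, and free-text
keyword filtering on the variant annotations.
"""

from __future__ import annotations

import bisect
import logging
import re
from dataclasses import dataclass

from .genome_io import (
    GenomeSequence,
    Strand,
    VariantRecord,
    complement_base,
    revcomp,
)

__all__ = [
    "ScanConfig",
    "PamSite",
    "ArtemisHit",
    "ContigMismatchError",
    "ReferenceMismatchError",
    "compile_pam_pattern",
    "find_pam_sites",
    "seed_offset",
    "scan",
    "exclude_common_pam",
    "keyword_filter",
]

logger = logging.getLogger(__name__)

IUPAC_CODES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


class ContigMismatchError(ValueError):
    """Variant contig names do not resolve against the reference contigs."""


class ReferenceMismatchError(ValueError):
    """A VCF REF allele disagrees with the reference genome base."""


@dataclass(frozen=True)
class ScanConfig:
    """Parameters of the targetability scan.

    ``pam_pattern`` is an IUPAC motif (e.g. ``TTTV``) or a raw regular
    expression; ``seed_size`` is the length of the PAM-proximal seed
    window in nt; ``spacer_length`` the protospacer length extracted for
    each hit; ``af_threshold`` the population allele frequency at or above
    which a PAM-overlapping variant disqualifies the site.
    """

    pam_pattern: str = "TTTV"
    seed_size: int = 5
    spacer_length: int = 21
    af_threshold: float = 0.01
    both_strands: bool = True

    def __post_init__(self) -> None:
        if self.seed_size < 1:
            raise ValueError("seed_size must be positive")
        if self.spacer_length < self.seed_size:
            raise ValueError("seed_size must not exceed spacer_length")
        if not 0.0 <= self.af_threshold <= 1.0:
            raise ValueError("af_threshold must lie in [0,1]")
        compile_pam_pattern(self.pam_pattern)  # fail fast on a bad motif


@dataclass(frozen=True)
class PamSite:
    """One PAM occurrence; coordinates are 0-based half-open on the reference.

    ``motif`` is the matched word in PAM orientation: for a reverse-strand
    site it is the reverse complement of the forward-strand text over
    ``[start, end)``.
    """

    contig_id: str
    start: int
    end: int
    strand: Strand
    motif: str

    def seed_interval(self, seed_size: int) -> tuple[int, int]:
        """0-based half-open reference interval of the seed window."""
        if self.strand is Strand.FORWARD:
            return self.end, self.end + seed_size
        return self.start - seed_size, self.start


@dataclass(frozen=True)
class ArtemisHit:
    """A (variant, PAM site) pair with the SNV inside the seed window.

    ``seed_pos`` counts 1..seed_size from the first base 3' of the PAM
    along the protospacer; ``spacer_ref``/``spacer_alt`` are the DNA
    target sequences in protospacer (PAM-strand) orientation and differ at
    exactly ``seed_pos``.
    """

    variant: VariantRecord
    pam: PamSite
    seed_pos: int
    spacer_ref: str
    spacer_alt: str


def compile_pam_pattern(pattern: str) -> re.Pattern[str]:
    """Compile an IUPAC motif, or raw regex, into a forward-strand matcher."""
    text = pattern.strip()
    if not text:
        raise ValueError("empty PAM pattern")
    upper = text.upper()
    if all(c in IUPAC_CODES for c in upper):
        regex = "".join(
            c if len(IUPAC_CODES[c]) == 1 else f"[{IUPAC_CODES[c]}]" for c in upper
        )
    else:
        regex = text
    try:
        return re.compile(regex)
    except re.error as exc:
        raise ValueError(f"invalid PAM pattern {pattern!r}: {exc}") from exc


def _find_matches(seq: str, pattern: re.Pattern[str]) -> list[tuple[int, int, str]]:
    # overlapping occurrences via a zero-width lookahead
    wrapped = re.compile(f"(?=({pattern.pattern}))")
    return [(m.start(), m.start() + len(m.group(1)), m.group(1))
            for m in wrapped.finditer(seq) if m.group(1)]


def find_pam_sites(genome: GenomeSequence, config: ScanConfig) -> list[PamSite]:
    """All PAM occurrences on the forward and (optionally) reverse strand.

    Overlapping occurrences are all reported; ordering is by
    (start, ``+`` before ``-``).
    """
    pattern = compile_pam_pattern(config.pam_pattern)
    sites = [
        PamSite(genome.contig_id, s, e, Strand.FORWARD, motif)
        for s, e, motif in _find_matches(genome.sequence, pattern)
    ]
    if config.both_strands:
        length = len(genome.sequence)
        rc = revcomp(genome.sequence)
        for s, e, motif in _find_matches(rc, pattern):
            sites.append(
                PamSite(genome.contig_id, length - e, length - s, Strand.REVERSE, motif)
            )
    sites.sort(key=lambda p: (p.start, p.strand is Strand.REVERSE, p.end))
    return sites


def seed_offset(pam: PamSite, variant: VariantRecord, config: ScanConfig) -> int | None:
    """Seed position (1..seed_size) of the variant relative to a PAM, or None.

    Position 1 is the first base 3' of the PAM on the protospacer: for a
    forward PAM over ``[s, e)`` that is reference base ``e``; for a
    reverse PAM it is reference base ``s - 1``, walking leftwards.
    """
    if pam.contig_id != variant.contig_id:
        raise ContigMismatchError(
            f"PAM on {pam.contig_id!r} vs variant on {variant.contig_id!r}"
        )
    pos0 = variant.pos0
    if pam.strand is Strand.FORWARD:
        offset = pos0 - pam.end + 1
    else:
        offset = pam.start - pos0
    return offset if 1 <= offset <= config.seed_size else None


def _extract_spacers(
    genome: GenomeSequence, pam: PamSite, variant: VariantRecord, config: ScanConfig
) -> tuple[str, str] | None:
    """(spacer_ref, spacer_alt) in protospacer orientation, or None if the
    spacer window leaves the contig."""
    seq = genome.sequence
    length = config.spacer_length
    if pam.strand is Strand.FORWARD:
        lo, hi = pam.end, pam.end + length
        if hi > len(seq):
            return None
        spacer_ref = seq[lo:hi]
        index = variant.pos0 - lo
        alt_base = variant.alt_allele
        ref_base = variant.ref_allele
    else:
        lo, hi = pam.start - length, pam.start
        if lo < 0:
            return None
        spacer_ref = revcomp(seq[lo:hi])
        index = pam.start - 1 - variant.pos0
        alt_base = complement_base(variant.alt_allele)
        ref_base = complement_base(variant.ref_allele)
    if spacer_ref[index] != ref_base:
        raise ReferenceMismatchError(
            f"{variant.variant_id} at {variant.contig_id}:{variant.pos}: VCF REF "
            f"{variant.ref_allele!r} does not match the reference genome"
        )
    spacer_alt = spacer_ref[:index] + alt_base + spacer_ref[index + 1:]
    return spacer_ref, spacer_alt


def scan(
    genome_map: dict[str, GenomeSequence],
    variants,
    config: ScanConfig = ScanConfig(),
) -> list[ArtemisHit]:
    """Find every (SNV, PAM) pair whose SNV sits in the PAM's seed window.

    An SNV near several PAMs yields several hits.  Hits whose full spacer
    window leaves the contig are dropped (counted in a warning).  Output
    is sorted by (contig, position, ``+`` before ``-``, PAM start) so runs
    are byte-reproducible.  A variant naming a contig absent from the
    reference is a hard error listing both name sets.
    """
    variants = list(variants)
    missing = {v.contig_id for v in variants} - set(genome_map)
    if missing:
        raise ContigMismatchError(
            "variant contigs not found in reference: "
            f"{sorted(missing)}; reference has {sorted(genome_map)}. "
            "Genome builds and contig names must match between the inputs."
        )
    pam_cache: dict[str, tuple[list[PamSite], list[int]]] = {}
    max_reach = config.seed_size + 64  # PAM length bound for the bisect window
    hits: list[ArtemisHit] = []
    dropped = 0
    for variant in variants:
        if not variant.is_snv:
            continue
        contig = variant.contig_id
        if contig not in pam_cache:
            sites = find_pam_sites(genome_map[contig], config)
            pam_cache[contig] = (sites, [p.start for p in sites])
        sites, starts = pam_cache[contig]
        lo = bisect.bisect_left(starts, variant.pos0 - max_reach)
        hi = bisect.bisect_right(starts, variant.pos0 + max_reach)
        for pam in sites[lo:hi]:
            offset = seed_offset(pam, variant, config)
            if offset is None:
                continue
            spacers = _extract_spacers(genome_map[contig], pam, variant, config)
            if spacers is None:
                dropped += 1
                continue
            hits.append(ArtemisHit(variant, pam, offset, spacers[0], spacers[1]))
    if dropped:
        logger.warning("%d hit(s) dropped: spacer window leaves the contig", dropped)
    hits.sort(
        key=lambda h: (
            h.variant.contig_id,
            h.variant.pos0,
            h.pam.strand is Strand.REVERSE,
            h.pam.start,
        )
    )
    return hits


def exclude_common_pam(
    hits: list[ArtemisHit],
    common_variants,
    config: ScanConfig = ScanConfig(),
    include_seed: bool = False,
    removed: list[tuple[ArtemisHit, VariantRecord]] | None = None,
) -> list[ArtemisHit]:
    """Drop hits whose PAM is commonly mutated in the population.

    A hit is removed iff some common variant with allele frequency
    ``>= config.af_threshold`` overlaps any PAM position; variants with
    unknown AF never exclude.  With ``include_seed`` the exclusion window
    extends over the seed bases as well.  Removed (hit, offending variant)
    pairs are appended to ``removed`` when given, and logged.
    """
    by_contig: dict[str, list[VariantRecord]] = {}
    for cv in common_variants:
        if cv.af is not None and cv.af >= config.af_threshold:
            by_contig.setdefault(cv.contig_id, []).append(cv)
    kept: list[ArtemisHit] = []
    for hit in hits:
        windows = [(hit.pam.start, hit.pam.end)]
        if include_seed:
            windows.append(hit.pam.seed_interval(config.seed_size))
        offender = None
        for cv in by_contig.get(hit.pam.contig_id, ()):
            span = cv.ref_span
            if any(span[0] < w_end and w_start < span[1] for w_start, w_end in windows):
                offender = cv
                break
        if offender is None:
            kept.append(hit)
        else:
            if removed is not None:
                removed.append((hit, offender))
            logger.info(
                "hit %s at %s:%d excluded: common variant %s (AF=%.4g) in PAM",
                hit.variant.variant_id, hit.variant.contig_id, hit.variant.pos,
                offender.variant_id, offender.af,
            )
    return kept


def keyword_filter(hits: list[ArtemisHit], keywords: list[str]) -> list[ArtemisHit]:
    """Keep hits whose variant INFO mentions any keyword (case-insensitive
    substring over all INFO values).  An empty keyword list keeps all."""
    if not keywords:
        return list(hits)
    lowered = [k.lower() for k in keywords if k]
    if not lowered:
        return list(hits)
    out = []
    for hit in hits:
        haystacks = [v.lower() for v in hit.variant.info.values()]
        if any(k in text for k in lowered for text in haystacks):
            out.append(hit)
    return out
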