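"""From scan hit to orderable molecules.

Three design products per targetable SNV:

* allele-specific crRNAs — the LbCas12a direct-repeat scaffold plus a
  spacer copying the protospacer (T→U), optionally carrying one synthetic
  seed mismatch.  A synthetic mismatch at a seed position *other than* the
  SNV position sensitizes allele discrimination; the validated flavour is
  the *homopair* (crRNA base equals the target-strand base, giving G·G,
  A·A, C·C or U·T pairings).
* synthetic double-stranded test targets — the genomic
  [flank]-[PAM]-[protospacer]-[flank] layout, built for both alleles, to
  benchmark crRNA specificity in vitro.
* amplicon primer checks — amplicons should stay short (60–120 bp
  default, matching cell-free DNA fragment sizes) and primers must not
  overlap the PAM+protospacer, which would trigger Cas12a without the
  genomic target.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from .artemis_core import ArtemisHit
from .genome_io import GenomeSequence, Strand, revcomp

__all__ = [
    "LBCAS12A_SCAFFOLD",
    "CrRNADesign",
    "OligoTarget",
    "AmpliconCheck",
    "PrimerSearchError",
    "spacer_to_crrna",
    "enumerate_synthetic_mismatches",
    "design_oligo_targets",
    "validate_primer_pair",
]

#: LbCas12a direct-repeat scaffold, 5' of the spacer.
LBCAS12A_SCAFFOLD = "UAAUUUCUACUAAGUGUAGAU"

_DNA_TO_RNA = str.maketrans("T", "U")
_DNA_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_RNA_OF = {"A": "A", "C": "C", "G": "G", "T": "U"}

Allele = Literal["ref", "alt"]


class PrimerSearchError(ValueError):
    """A primer was not found, or found more than once, on the template."""


@dataclass(frozen=True)
class CrRNADesign:
    """A full crRNA (scaffold + spacer, 5'→3') for one allele.

    ``sm_pos`` is the seed position (1..seed_size) of the synthetic
    mismatch, ``sm_base`` the substituted RNA base; both are ``None`` for
    a plain allele-matched guide.  ``wobble_flag`` marks semi-stable
    G·T / U·G crRNA:target pairings, which are advised against.
    """

    spacer: str
    allele: Allele
    scaffold: str = LBCAS12A_SCAFFOLD
    sm_pos: int | None = None
    sm_base: str | None = None
    wobble_flag: bool = False

    def __post_init__(self) -> None:
        bad = set(self.spacer) - set("ACGU")
        if bad:
            raise ValueError(f"spacer must be RNA (ACGU), found {sorted(bad)}")

    @property
    def full_sequence(self) -> str:
        return self.scaffold + self.spacer

    @property
    def name(self) -> str:
        tag = f"sm{self.sm_pos}{self.sm_base}" if self.sm_pos is not None else "plain"
        return f"crRNA_{self.allele}_{tag}"


@dataclass(frozen=True)
class OligoTarget:
    """One synthetic dsDNA test target: [flank5]-[PAM]-[protospacer]-[flank3]."""

    name: str
    allele: Allele
    top_strand: str
    bottom_strand: str
    flank5: int
    flank3: int

    def __post_init__(self) -> None:
        if self.bottom_strand != revcomp(self.top_strand):
            raise ValueError("bottom_strand must be the reverse complement of top_strand")


@dataclass(frozen=True)
class AmpliconCheck:
    """Verdict of a primer-pair check against a template and target span."""

    fwd_primer: str
    rev_primer: str
    amplicon_start: int
    amplicon_end: int
    amplicon_length: int
    overlaps_target: bool
    within_bounds: bool
    verdict: Literal["pass", "fail"]
    reasons: tuple[str, ...] = ()


def spacer_to_crrna(
    spacer_dna: str, allele: Allele, spacer_length: int = 21
) -> CrRNADesign:
    """Plain (no synthetic mismatch) crRNA for a protospacer sequence.

    The crRNA spacer copies the protospacer (PAM-strand) sequence with
    T→U, since the spacer hybridizes the *target* strand.
    """
    seq = spacer_dna.upper()
    if len(seq) != spacer_length:
        raise ValueError(
            f"spacer must be {spacer_length} nt, got {len(seq)} nt"
        )
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"spacer must be DNA (ACGT), found {sorted(bad)}")
    return CrRNADesign(spacer=seq.translate(_DNA_TO_RNA), allele=allele)


def enumerate_synthetic_mismatches(
    hit: ArtemisHit,
    allele: Allele = "alt",
    mode: Literal["homopair", "all"] = "homopair",
    seed_size: int = 5,
) -> list[CrRNADesign]:
    """All single synthetic-mismatch crRNAs for one hit and allele.

    One design per seed position ``p != hit.seed_pos`` (the SNV position
    itself must stay matched so it remains the discriminating base).  In
    ``homopair`` mode the crRNA base at ``p`` becomes the RNA form of the
    target-strand base — an identical-base pairing (G·G, A·A, C·C, U·T);
    ``all`` emits every mismatching base, flagging G·T / U·G wobbles.
    """
    if seed_size < 2:
        raise ValueError("seed_size < 2 leaves no legal synthetic-mismatch position")
    if not 1 <= hit.seed_pos <= seed_size:
        raise ValueError(f"hit seed_pos {hit.seed_pos} outside 1..{seed_size}")
    protospacer = hit.spacer_alt if allele == "alt" else hit.spacer_ref
    base_design = spacer_to_crrna(protospacer, allele, spacer_length=len(protospacer))
    designs: list[CrRNADesign] = []
    for p in range(1, seed_size + 1):
        if p == hit.seed_pos:
            continue
        proto_base = protospacer[p - 1]
        target_base = _DNA_COMP[proto_base]  # target strand, DNA
        if mode == "homopair":
            candidates = [_RNA_OF[target_base]]
        elif mode == "all":
            candidates = [b for b in "ACGU" if b != base_design.spacer[p - 1]]
        else:
            raise ValueError(f"unknown mode {mode!r}")
        for rna_base in candidates:
            spacer = base_design.spacer[: p - 1] + rna_base + base_design.spacer[p:]
            wobble = (rna_base, target_base) in {("G", "T"), ("U", "G")}
            designs.append(
                CrRNADesign(
                    spacer=spacer,
                    allele=allele,
                    sm_pos=p,
                    sm_base=rna_base,
                    wobble_flag=wobble,
                )
            )
    return designs


def design_oligo_targets(
    genome_map: dict[str, GenomeSequence],
    hit: ArtemisHit,
    flank: int = 15,
    spacer_length: int = 21,
    min_flank: int = 15,
    enforce_min: bool = True,
) -> tuple[OligoTarget, OligoTarget]:
    """Wild-type and mutant synthetic dsDNA duplexes for one hit.

    The top strand follows the PAM-containing strand as
    [flank]-[PAM]-[protospacer]-[flank]; for a reverse-strand hit the
    layout is built on that strand and both strands emitted.  The two
    alleles differ at exactly the SNV position.  Flanks below
    ``min_flank`` (default 15 nt) are refused unless enforcement is off.
    """
    if enforce_min and flank < min_flank:
        raise ValueError(f"flank {flank} nt is below the {min_flank}-nt minimum")
    genome = genome_map[hit.pam.contig_id]
    seq = genome.sequence
    pam = hit.pam
    if pam.strand is Strand.FORWARD:
        lo = pam.start - flank
        hi = pam.end + spacer_length + flank
    else:
        lo = pam.start - spacer_length - flank
        hi = pam.end + flank
    if lo < 0 or hi > len(seq):
        deficit = max(-lo, hi - len(seq))
        raise ValueError(
            f"flank {flank} nt exceeds contig {genome.contig_id!r} boundary by {deficit} nt"
        )
    ref_window = seq[lo:hi]
    idx = hit.variant.pos0 - lo
    alt_window = ref_window[:idx] + hit.variant.alt_allele + ref_window[idx + 1:]
    if pam.strand is Strand.REVERSE:
        ref_window, alt_window = revcomp(ref_window), revcomp(alt_window)
    stem = f"{hit.variant.variant_id}_{hit.variant.contig_id}_{hit.variant.pos}"
    oligos = tuple(
        OligoTarget(
            name=f"{stem}_{allele}",
            allele=allele,
            top_strand=top,
            bottom_strand=revcomp(top),
            flank5=flank,
            flank3=flank,
        )
        for allele, top in (("ref", ref_window), ("alt", alt_window))
    )
    return oligos  # type: ignore[return-value]


def _find_unique(template: str, query: str, label: str) -> int:
    positions = []
    start = template.find(query)
    while start != -1:
        positions.append(start)
        start = template.find(query, start + 1)
    if not positions:
        raise PrimerSearchError(f"{label} primer {query!r} not found on template")
    if len(positions) > 1:
        raise PrimerSearchError(
            f"{label} primer {query!r} maps {len(positions)} times on template (ambiguous)"
        )
    return positions[0]


def validate_primer_pair(
    template: str,
    target_span: tuple[int, int],
    fwd: str,
    rev: str,
    bounds: tuple[int, int] = (60, 120),
) -> AmpliconCheck:
    """Check a primer pair against the amplicon-length and no-overlap rules.

    ``fwd`` must occur once on the forward strand of ``template`` and
    ``rev`` once as its reverse complement; the amplicon spans both primer
    footprints inclusively.  Pass requires: primers convergent, amplicon
    containing ``target_span`` (0-based half-open over PAM+protospacer),
    no primer footprint overlapping the target, and amplicon length
    within ``bounds``.
    """
    template = template.upper()
    fwd_u, rev_u = fwd.upper(), rev.upper()
    f_start = _find_unique(template, fwd_u, "forward")
    f_end = f_start + len(fwd_u)
    r_start = _find_unique(template, revcomp(rev_u), "reverse")
    r_end = r_start + len(rev_u)
    reasons: list[str] = []
    amp_start, amp_end = min(f_start, r_start), max(f_end, r_end)
    convergent = f_start < r_start and f_end <= r_end
    if not convergent:
        reasons.append("primers are not in convergent orientation")
    length = amp_end - amp_start
    t_start, t_end = target_span
    overlaps = (f_start < t_end and t_start < f_end) or (
        r_start < t_end and t_start < r_end
    )
    if overlaps:
        reasons.append("a primer footprint overlaps the target sequence")
    within = bounds[0] <= length <= bounds[1]
    if not within:
        reasons.append(
            f"amplicon length {length} bp outside bounds {bounds[0]}-{bounds[1]} bp"
        )
    contains = amp_start <= t_start and t_end <= amp_end
    if not contains:
        reasons.append("amplicon does not contain the target span")
    verdict = "pass" if convergent and not overlaps and within and contains else "fail"
    return AmpliconCheck(
        fwd_primer=fwd_u,
        rev_primer=rev_u,
        amplicon_start=amp_start,
        amplicon_end=amp_end,
        amplicon_length=length,
        overlaps_target=overlaps,
        within_bounds=within,
        verdict=verdict,
        reasons=tuple(reasons),
    )
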