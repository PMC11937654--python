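"""Reading and writing the on-disk formats the pipeline touches.

FASTA references are parsed with Biopython, VCF files with pysam (HTSlib),
so plain, bgzipped and indexed inputs all work.  One coordinate rule holds
package-wide: VCF positions are 1-based, every internal computation is
0-based half-open, and the conversion happens in this module only
(:attr:`VariantRecord.pos` is the 1-based VCF position,
:attr:`VariantRecord.pos0` its 0-based twin).

Annotated output VCFs carry five INFO keys of this package's own naming
(the upstream tool's field names are not published):

``ARTEMIS_PAM``
    signed offset of the PAM start relative to the SNV, both 0-based, on
    the reference strand (``pam.start - pos0``).
``ARTEMIS_SEED``
    seed position of the SNV, 1..seedsize, counted 5'→3' along the
    protospacer from the first base 3' of the PAM.
``ARTEMIS_STRAND``
    ``+`` or ``-``: the strand carrying the PAM.
``ARTEMIS_GRNA_REF`` / ``ARTEMIS_GRNA_ALT``
    DNA spacer target sequences in protospacer orientation for the
    reference and alternate allele.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterator, Mapping

import pysam
from Bio import SeqIO

if TYPE_CHECKING:  # pragma: no cover
    from .artemis_core import ArtemisHit

__all__ = [
    "Strand",
    "GenomeSequence",
    "VariantRecord",
    "VcfParseError",
    "DuplicateContigError",
    "read_fasta",
    "VcfReader",
    "read_vcf",
    "write_hits_vcf",
    "revcomp",
    "complement_base",
]

_DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_RNA_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")
_VALID_BASES = frozenset("ACGTN")
# IUPAC ambiguity codes other than N are collapsed to N on read; N never
# matches a PAM base downstream.
_AMBIGUITY = frozenset("RYSWKMBDHV")


class DuplicateContigError(ValueError):
    """Two FASTA records share an identifier."""


class VcfParseError(ValueError):
    """A VCF file could not be parsed."""


class Strand(enum.Enum):
    """Orientation of a feature on the reference."""

    FORWARD = "+"
    REVERSE = "-"

    @property
    def opposite(self) -> "Strand":
        return Strand.REVERSE if self is Strand.FORWARD else Strand.FORWARD

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def complement_base(base: str) -> str:
    """Complement of a single DNA base (N ↦ N)."""
    return base.translate(_DNA_COMPLEMENT)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA or RNA sequence.

    DNA (T) and RNA (U) alphabets are both accepted; a sequence mixing T
    and U is rejected.  ``revcomp`` is an involution:
    ``revcomp(revcomp(x)) == x``.
    """
    s = seq.upper()
    has_t, has_u = "T" in s, "U" in s
    if has_t and has_u:
        raise ValueError("sequence mixes T and U; cannot tell DNA from RNA")
    table = _RNA_COMPLEMENT if has_u else _DNA_COMPLEMENT
    alphabet = "ACGUN" if has_u else "ACGTN"
    bad = set(s) - set(alphabet)
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    return s.translate(table)[::-1]


@dataclass(frozen=True)
class GenomeSequence:
    """A named contig with an uppercase A/C/G/T/N nucleotide string."""

    contig_id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"contig {self.contig_id!r} is empty")
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise ValueError(
                f"contig {self.contig_id!r} contains non-ACGTN characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class VariantRecord:
    """One normalized variant from a VCF (one ALT allele per record).

    ``pos`` follows the VCF convention (1-based); ``pos0`` is the 0-based
    position used everywhere else in the package.  ``af`` is the allele
    frequency when the source VCF provided one, otherwise ``None``
    (unknown, never assumed zero).
    """

    contig_id: str
    pos: int
    variant_id: str
    ref_allele: str
    alt_allele: str
    info: Mapping[str, str] = field(default_factory=dict)
    af: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"VCF position must be >= 1, got {self.pos}")
        if self.af is not None and not 0.0 <= self.af <= 1.0:
            raise ValueError(f"allele frequency outside [0,1]: {self.af}")

    @property
    def pos0(self) -> int:
        """0-based position of the variant."""
        return self.pos - 1

    @property
    def is_snv(self) -> bool:
        return (
            len(self.ref_allele) == 1
            and len(self.alt_allele) == 1
            and self.ref_allele in "ACGT"
            and self.alt_allele in "ACGT"
            and self.ref_allele != self.alt_allele
        )

    @property
    def ref_span(self) -> tuple[int, int]:
        """0-based half-open interval covered by the REF allele."""
        return self.pos0, self.pos0 + len(self.ref_allele)


def read_fasta(path: str | Path) -> dict[str, GenomeSequence]:
    """Read a (multi-record) FASTA into a contig-id → :class:`GenomeSequence` map.

    Sequences are uppercased; IUPAC ambiguity codes other than N are
    collapsed to N with a warning; U (RNA) is rejected.  Duplicate record
    ids and empty files are errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    contigs: dict[str, GenomeSequence] = {}
    with open(path) as handle:
        for record in SeqIO.parse(handle, "fasta"):
            if record.id in contigs:
                raise DuplicateContigError(
                    f"duplicate contig id in {path}: {record.id!r}"
                )
            seq = str(record.seq).upper()
            if "U" in seq:
                raise ValueError(
                    f"contig {record.id!r} contains U; this pipeline expects DNA "
                    "references"
                )
            ambiguous = set(seq) & _AMBIGUITY
            if ambiguous:
                warnings.warn(
                    f"contig {record.id!r}: IUPAC ambiguity codes {sorted(ambiguous)} "
                    "collapsed to N",
                    stacklevel=2,
                )
                seq = "".join("N" if b in _AMBIGUITY else b for b in seq)
            contigs[record.id] = GenomeSequence(record.id, seq)
    if not contigs:
        raise ValueError(f"no FASTA records found in {path}")
    return contigs


def _stringify_info_value(value: object) -> str:
    if isinstance(value, (tuple, list)):
        return ",".join(_stringify_info_value(v) for v in value)
    if isinstance(value, float):
        return format(value, ".6g")
    if value is True:
        return "True"
    return str(value)


class VcfReader:
    """Ordered stream of :class:`VariantRecord` from a VCF file.

    Multi-allelic records are split into one record per ALT allele.  With
    ``require_snv`` non-SNV records are skipped and counted on
    :attr:`skipped_non_snv`.  The allele frequency is pulled from the INFO
    key named by ``af_key`` (per-ALT for ``Number=A`` fields); an absent
    key leaves ``af`` as ``None``.
    """

    def __init__(self, path: str | Path, require_snv: bool = False, af_key: str = "AF"):
        self.path = Path(path)
        self.require_snv = require_snv
        self.af_key = af_key
        self.skipped_non_snv = 0
        if not self.path.exists():
            raise FileNotFoundError(f"VCF file not found: {self.path}")
        try:
            self._vcf = pysam.VariantFile(str(self.path))
        except (ValueError, OSError) as exc:
            raise VcfParseError(f"cannot parse VCF header of {self.path}: {exc}") from exc

    @property
    def header(self) -> pysam.VariantHeader:
        return self._vcf.header

    def __iter__(self) -> Iterator[VariantRecord]:
        iterator = iter(self._vcf)
        index = 0
        while True:
            try:
                rec = next(iterator)
            except StopIteration:
                return
            except (ValueError, OSError) as exc:
                raise VcfParseError(
                    f"malformed VCF record #{index + 1} in {self.path}: {exc}"
                ) from exc
            index += 1
            info_items = list(rec.info.items())
            for alt_index, alt in enumerate(rec.alts or ()):
                info = {k: _stringify_info_value(v) for k, v in info_items}
                af = self._allele_frequency(rec, alt_index)
                variant = VariantRecord(
                    contig_id=rec.chrom,
                    pos=rec.pos,
                    variant_id=rec.id or ".",
                    ref_allele=rec.ref or "",
                    alt_allele=str(alt),
                    info=info,
                    af=af,
                )
                if self.require_snv and not variant.is_snv:
                    self.skipped_non_snv += 1
                    continue
                yield variant

    def _allele_frequency(self, rec: pysam.VariantRecord, alt_index: int) -> float | None:
        if self.af_key not in rec.info:
            return None
        value = rec.info[self.af_key]
        if isinstance(value, (tuple, list)):
            if alt_index >= len(value) or value[alt_index] is None:
                return None
            value = value[alt_index]
        try:
            return float(value)
        except (TypeError, ValueError):
            return None


def read_vcf(
    path: str | Path, require_snv: bool = False, af_key: str = "AF"
) -> VcfReader:
    """Open a VCF as an ordered :class:`VariantRecord` stream (see :class:`VcfReader`)."""
    return VcfReader(path, require_snv=require_snv, af_key=af_key)


_ARTEMIS_INFO_LINES = (
    '##INFO=<ID=ARTEMIS_PAM,Number=1,Type=Integer,Description='
    '"Signed offset of PAM start relative to the SNV (0-based, reference strand)">',
    '##INFO=<ID=ARTEMIS_SEED,Number=1,Type=Integer,Description='
    '"Seed position of the SNV, 1..seedsize from the PAM-proximal base">',
    '##INFO=<ID=ARTEMIS_STRAND,Number=1,Type=Character,Description='
    '"Strand carrying the PAM (+ or -)">',
    '##INFO=<ID=ARTEMIS_GRNA_REF,Number=1,Type=String,Description='
    '"Reference-allele spacer target sequence, protospacer orientation (DNA)">',
    '##INFO=<ID=ARTEMIS_GRNA_ALT,Number=1,Type=String,Description='
    '"Alternate-allele spacer target sequence, protospacer orientation (DNA)">',
)


def _cast_info_for_header(header: pysam.VariantHeader, key: str, text: str):
    meta = header.info[key]
    if meta.type == "Flag":
        return text not in ("False", "0", "")
    caster = {"Integer": int, "Float": float}.get(meta.type, str)
    if meta.number in (0, 1):
        return caster(text)
    parts = text.split(",")
    if len(parts) == 1:
        return caster(parts[0])
    return tuple(caster(p) for p in parts)


def write_hits_vcf(
    hits: "list[ArtemisHit]",
    sink: str | Path,
    source_header: pysam.VariantHeader | None = None,
) -> None:
    """Write scan hits as a valid VCF; ``sink`` may be a path or ``-`` for stdout.

    Each hit becomes one record carrying the original variant's fields plus
    the five ``ARTEMIS_*`` INFO keys.  Every INFO key used by a hit is
    declared in the emitted header, so the output round-trips through
    :func:`read_vcf` field-for-field.
    """
    header = source_header.copy() if source_header is not None else pysam.VariantHeader()
    reserved = {"ARTEMIS_PAM", "ARTEMIS_SEED", "ARTEMIS_STRAND",
                "ARTEMIS_GRNA_REF", "ARTEMIS_GRNA_ALT"}
    for line in _ARTEMIS_INFO_LINES:
        key = line.split("ID=")[1].split(",")[0]
        if key not in header.info:
            header.add_line(line)
    for hit in hits:
        if hit.variant.contig_id not in header.contigs:
            header.add_line(f"##contig=<ID={hit.variant.contig_id}>")
        for key in hit.variant.info:
            if key not in header.info and key not in reserved:
                header.add_line(
                    f'##INFO=<ID={key},Number=.,Type=String,Description="Carried over">'
                )
    out = pysam.VariantFile(str(sink), "w", header=header)
    try:
        for hit in hits:
            v = hit.variant
            rec = out.new_record(
                contig=v.contig_id,
                start=v.pos0,
                stop=v.pos0 + len(v.ref_allele),
                alleles=(v.ref_allele, v.alt_allele),
                id=None if v.variant_id == "." else v.variant_id,
            )
            for key, text in v.info.items():
                if key in reserved:
                    continue
                rec.info[key] = _cast_info_for_header(header, key, text)
            rec.info["ARTEMIS_PAM"] = hit.pam.start - v.pos0
            rec.info["ARTEMIS_SEED"] = hit.seed_pos
            rec.info["ARTEMIS_STRAND"] = hit.pam.strand.value
            rec.info["ARTEMIS_GRNA_REF"] = hit.spacer_ref
            rec.info["ARTEMIS_GRNA_ALT"] = hit.spacer_alt
            out.write(rec)
    finally:
        out.close()
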