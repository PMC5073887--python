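"""Reading and writing the standard formats the pipeline touches.

FASTA and FASTQ go through Biopython; VCF and SAM go through pysam.
Coordinates are 1-based and fully closed (VCF convention) everywhere in this
package; the single conversion from SAM's 0-based ``reference_start`` happens
here at ingestion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "ReferenceGenome",
    "IndelLocus",
    "SamAlignment",
    "read_fasta",
    "write_fasta",
    "read_variant_profile",
    "write_variant_profile",
    "write_reads_fastq",
    "read_alignments_sam",
    "write_alignments_sam",
]

_ALPHABET = frozenset("ACGTN")

# CIGAR op codes (pysam numeric) -> our symbols; '='/'X' collapse to 'M'
# because match/mismatch is re-derived against the reference when needed.
_CIGAR_DECODE = {0: "M", 7: "M", 8: "M", 1: "I", 2: "D", 4: "S"}
_CIGAR_ENCODE = {"M": 0, "I": 1, "D": 2, "S": 4}
_READ_CONSUMING = frozenset("MIS")
_REF_CONSUMING = frozenset("MD")


@dataclass
class ReferenceGenome:
    """An in-memory reference: chromosome name -> uppercase DNA string."""

    sequences: Dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            if not seq:
                raise ValidationError(f"chromosome {name!r} has an empty sequence")
            bad = set(seq) - _ALPHABET
            if bad:
                raise ValidationError(
                    f"chromosome {name!r} contains non-ACGTN characters: {sorted(bad)}"
                )

    @property
    def lengths(self) -> Dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Substring at the 1-based, fully closed interval [start, end]."""
        seq = self.sequences[chrom]
        if start < 1 or end > len(seq) or start > end:
            raise ValueError(f"interval {chrom}:{start}-{end} out of bounds")
        return seq[start - 1 : end]


@dataclass(frozen=True)
class IndelLocus:
    """One variant-profile entry in anchored representation.

    ``ref_allele`` occupies the reference at [pos, pos + |ref| - 1]; every alt
    shares its first base with the reference allele and at least one alt
    changes length (the x1|x2|...|xk notation with x1 the reference allele).
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_alleles: Tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.alt_alleles:
            raise ValidationError(f"{self.chrom}:{self.pos}: no ALT alleles")
        for alt in self.alt_alleles:
            if alt == self.ref_allele:
                raise ValidationError(f"{self.chrom}:{self.pos}: ALT equals REF")

    @property
    def end(self) -> int:
        """1-based last reference position of the REF allele."""
        return self.pos + len(self.ref_allele) - 1

    @property
    def interval(self) -> Tuple[int, int]:
        return (self.pos, self.end)

    @property
    def is_indel(self) -> bool:
        return any(len(a) != len(self.ref_allele) for a in self.alt_alleles)

    def validate_against(self, reference: ReferenceGenome) -> None:
        actual = reference.fetch(self.chrom, self.pos, self.end)
        if actual != self.ref_allele:
            raise ValidationError(
                f"{self.chrom}:{self.pos}: REF {self.ref_allele!r} disagrees with "
                f"reference sequence {actual!r}"
            )


@dataclass
class SamAlignment:
    """A mapped read as carried in a SAM record (plumbing for aligner output).

    ``pos`` is the 1-based leftmost reference position of the first aligned
    base.  ``read_sequence`` is stored in reference orientation, exactly as in
    the SAM SEQ column (reverse-strand hits are therefore already comparable
    to the forward reference).
    """

    read_id: str
    chrom: str
    pos: int
    cigar: Tuple[Tuple[str, int], ...]
    read_sequence: str
    is_reverse: bool = False

    def __post_init__(self) -> None:
        consumed = sum(n for op, n in self.cigar if op in _READ_CONSUMING)
        if consumed != len(self.read_sequence):
            raise FormatError(
                f"{self.read_id}: CIGAR consumes {consumed} read bases, "
                f"sequence has {len(self.read_sequence)}"
            )

    @property
    def ref_span(self) -> int:
        return sum(n for op, n in self.cigar if op in _REF_CONSUMING)

    @property
    def ref_end(self) -> int:
        return self.pos + self.ref_span - 1

    @property
    def interval(self) -> Tuple[int, int]:
        """1-based closed genomic interval covered on the reference."""
        return (self.pos, self.ref_end)


def read_fasta(path: Union[str, Path]) -> ReferenceGenome:
    """Load a (multi-record) FASTA into memory, upper-cased.

    Raises :class:`FormatError` for duplicate record names, empty records or
    a file that is not FASTA at all.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.read(1)
        if first != ">":
            raise FormatError(f"{path}: not FASTA (first character {first!r})")
    sequences: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise FormatError(f"{path}: duplicate chromosome name {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        sequences[rec.id] = seq
    if not sequences:
        raise FormatError(f"{path}: no FASTA records")
    return ReferenceGenome(sequences)


def write_fasta(genome: ReferenceGenome, path: Union[str, Path], width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_variant_profile(
    path: Union[str, Path], reference: ReferenceGenome
) -> List[IndelLocus]:
    """Load the INDEL entries of a VCF as :class:`IndelLocus` records.

    Only length-changing ALT alleles are retained; rows left with none (pure
    SNV rows) are skipped and counted in the log.  REF alleles are validated
    against the reference; records that are not in anchored form are
    re-anchored using the reference base at ``pos - 1``.
    """
    loci: List[IndelLocus] = []
    snv_rows = 0
    reanchored = 0
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.alts is None:
                snv_rows += 1
                continue
            ref = rec.ref.upper()
            alts = [a.upper() for a in rec.alts if len(a) != len(ref)]
            if not alts:
                snv_rows += 1
                continue
            pos = rec.pos
            if any(a[0] != ref[0] for a in alts):
                if pos < 2:
                    raise ValidationError(
                        f"{rec.chrom}:{pos}: unanchored INDEL at chromosome start"
                    )
                base = reference.fetch(rec.chrom, pos - 1, pos - 1)
                pos -= 1
                ref = base + ref
                alts = [base + a for a in alts]
                reanchored += 1
            locus = IndelLocus(rec.chrom, pos, ref, tuple(alts))
            locus.validate_against(reference)
            loci.append(locus)
    if snv_rows:
        logger.info("skipped %d rows with no length-changing ALT", snv_rows)
    if reanchored:
        logger.info("re-anchored %d unanchored records", reanchored)
    return loci


def write_variant_profile(
    loci: Sequence[IndelLocus], reference: ReferenceGenome, path: Union[str, Path]
) -> None:
    """Write loci as a minimal sorted VCF 4.2 with contig header lines."""
    header = pysam.VariantHeader()
    for name, length in reference.lengths.items():
        header.add_line(f"##contig=<ID={name},length={length}>")
    order = {name: k for k, name in enumerate(reference.sequences)}
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for locus in sorted(loci, key=lambda l: (order[l.chrom], l.pos)):
            rec = out.new_record(
                contig=locus.chrom,
                start=locus.pos - 1,
                alleles=(locus.ref_allele, *locus.alt_alleles),
            )
            out.write(rec)


def write_reads_fastq(reads: Sequence, path: Union[str, Path]) -> int:
    """Write synthetic reads as FASTQ with constant quality; returns the count.

    Read ids encode the truth locus (``chrom:pos:a<idx>:f<flank>``) so SAM
    records can be matched back to their :class:`~indelbias.reads.ReadRecord`.
    """
    if not reads:
        raise ValidationError("no reads to write")
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
        rec.letter_annotations["phred_quality"] = [40] * len(r.sequence)
        records.append(rec)
    return SeqIO.write(records, str(path), "fastq")


def read_alignments_sam(path: Union[str, Path]) -> List[SamAlignment]:
    """Load mapped records from a SAM text file.

    Unmapped records are excluded from the returned list (their count is
    logged).  Soft clips are preserved in the CIGAR.  A CIGAR whose
    read-consuming length disagrees with the sequence raises
    :class:`FormatError`.
    """
    out: List[SamAlignment] = []
    unmapped = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for a in sam:
            if a.is_unmapped:
                unmapped += 1
                continue
            if a.cigartuples is None or a.query_sequence is None:
                raise FormatError(f"{a.query_name}: mapped record without CIGAR/SEQ")
            try:
                cigar = tuple((_CIGAR_DECODE[op], n) for op, n in a.cigartuples)
            except KeyError as exc:
                raise FormatError(
                    f"{a.query_name}: unsupported CIGAR operation code {exc}"
                ) from None
            out.append(
                SamAlignment(
                    read_id=a.query_name,
                    chrom=a.reference_name,
                    pos=a.reference_start + 1,
                    cigar=cigar,
                    read_sequence=a.query_sequence.upper(),
                    is_reverse=a.is_reverse,
                )
            )
    if unmapped:
        logger.info("excluded %d unmapped records", unmapped)
    return out


def write_alignments_sam(
    alignments: Sequence[SamAlignment],
    reference: ReferenceGenome,
    path: Union[str, Path],
) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": name, "LN": length} for name, length in reference.lengths.items()],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for a in alignments:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = a.read_id
            seg.flag = 16 if a.is_reverse else 0
            seg.reference_id = out.header.get_tid(a.chrom)
            seg.reference_start = a.pos - 1
            seg.mapping_quality = 60
            seg.cigartuples = [(_CIGAR_ENCODE[op], n) for op, n in a.cigar]
            seg.query_sequence = a.read_sequence
            seg.query_qualities = pysam.qualitystring_to_array("I" * len(a.read_sequence))
            out.write(seg)
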