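"""Construction of alt-allele-bearing reads around INDEL loci.

This reverse-engineers how a variant profile's INDELs would have been seen by
an aligner: for a locus whose reference allele sits at position ``pos``, a
read ``r = u · alt · v`` is built from a left reference flank ``u``, the
alternative allele, and a right reference flank ``v``.  Flank lengths are
symmetric and evenly spaced over [flank_min, flank_max] so a biallelic locus
yields ``reads_per_locus`` reads of length |u| + |alt| + |v| (roughly 50-100
at the 25-50 defaults), i.e. 10x coverage of the locus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import pandas as pd

from .errors import ParameterError, ValidationError
from .seqio import IndelLocus, ReferenceGenome, SamAlignment

logger = logging.getLogger(__name__)

__all__ = [
    "ReadRecord",
    "ReadSetManifest",
    "flank_lengths",
    "make_reads",
    "is_correctly_mapped",
    "write_manifest",
    "read_manifest",
]


@dataclass(frozen=True)
class ReadRecord:
    """One synthetic read plus its ground truth.

    ``truth_interval`` is the 1-based closed genomic interval the read's
    reference-derived bases span, i.e. where a correct mapping must land.
    """

    read_id: str
    sequence: str
    chrom: str
    locus: IndelLocus
    allele_index: int
    flank_left: int
    flank_right: int
    truth_start: int
    truth_end: int

    @property
    def alt_allele(self) -> str:
        return self.locus.alt_alleles[self.allele_index]

    @property
    def truth_interval(self) -> Tuple[int, int]:
        return (self.truth_start, self.truth_end)


@dataclass
class ReadSetManifest:
    """All reads generated for a profile, plus the scheme that produced them."""

    reads: List[ReadRecord]
    reads_per_locus: int
    flank_scheme: Tuple[int, ...]
    skipped_loci: List[Tuple[IndelLocus, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.reads)

    def per_locus_counts(self) -> Dict[Tuple[str, int], int]:
        counts: Dict[Tuple[str, int], int] = {}
        for r in self.reads:
            key = (r.chrom, r.locus.pos)
            counts[key] = counts.get(key, 0) + 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.reads:
            rows.append(
                {
                    "read_id": r.read_id,
                    "chrom": r.chrom,
                    "pos": r.locus.pos,
                    "ref_allele": r.locus.ref_allele,
                    "alt_alleles": ",".join(r.locus.alt_alleles),
                    "allele_index": r.allele_index,
                    "flank_left": r.flank_left,
                    "flank_right": r.flank_right,
                    "truth_start": r.truth_start,
                    "truth_end": r.truth_end,
                    "sequence": r.sequence,
                }
            )
        return pd.DataFrame(rows)


def flank_lengths(flank_min: int, flank_max: int, n: int) -> Tuple[int, ...]:
    """``n`` distinct symmetric flank lengths evenly spaced over the range."""
    if flank_min < 1 or flank_max < flank_min:
        raise ParameterError(f"invalid flank range [{flank_min}, {flank_max}]")
    if flank_max - flank_min + 1 < n:
        raise ParameterError(
            f"flank range [{flank_min}, {flank_max}] cannot host {n} distinct lengths"
        )
    if n == 1:
        return (flank_max,)
    step = (flank_max - flank_min) / (n - 1)
    # half-up rounding keeps the sequence strictly increasing
    return tuple(int(flank_min + k * step + 0.5) for k in range(n))


def make_reads(
    ref: ReferenceGenome,
    loci: Sequence[IndelLocus],
    flank_min: int = 25,
    flank_max: int = 50,
    reads_per_locus: int = 10,
) -> ReadSetManifest:
    """Build the read set R: one read per (locus, alt allele, flank length).

    Loci closer than ``flank_max`` (+ allele length) to a chromosome end are
    skipped and logged; a REF allele that disagrees with the reference raises
    :class:`ValidationError`.  Multi-allelic loci yield ``reads_per_locus``
    reads *per alternative allele*.
    """
    scheme = flank_lengths(flank_min, flank_max, reads_per_locus)
    manifest = ReadSetManifest([], reads_per_locus, scheme)
    for locus in loci:
        locus.validate_against(ref)
        chrom_len = ref.lengths[locus.chrom]
        if locus.pos - flank_max < 1 or locus.end + flank_max > chrom_len:
            manifest.skipped_loci.append((locus, "too close to chromosome end"))
            logger.info("skipping %s:%d: too close to chromosome end", locus.chrom, locus.pos)
            continue
        seq = ref.sequences[locus.chrom]
        for ai, alt in enumerate(locus.alt_alleles):
            for k in scheme:
                u = seq[locus.pos - 1 - k : locus.pos - 1]
                v = seq[locus.end : locus.end + k]
                manifest.reads.append(
                    ReadRecord(
                        read_id=f"{locus.chrom}:{locus.pos}:a{ai}:f{k}",
                        sequence=u + alt + v,
                        chrom=locus.chrom,
                        locus=locus,
                        allele_index=ai,
                        flank_left=k,
                        flank_right=k,
                        truth_start=locus.pos - k,
                        truth_end=locus.end + k,
                    )
                )
    return manifest


def is_correctly_mapped(a: SamAlignment, r: ReadRecord) -> bool:
    """True iff the mapping overlaps the INDEL locus the read was built for.

    Overlap of the mapped reference interval with [pos, pos + |ref| - 1] by
    at least one base, on the same chromosome.
    """
    if a.chrom != r.chrom:
        return False
    lo, hi = r.locus.interval
    return a.pos <= hi and a.ref_end >= lo


def write_manifest(manifest: ReadSetManifest, path: Union[str, Path]) -> None:
    manifest.to_frame().to_csv(path, sep="\t", index=False)


def read_manifest(path: Union[str, Path]) -> ReadSetManifest:
    """Rebuild a manifest (losing only the flank scheme metadata) from TSV."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sequence": str})
    reads: List[ReadRecord] = []
    loci_cache: Dict[Tuple[str, int, str, str], IndelLocus] = {}
    for row in df.itertuples(index=False):
        key = (row.chrom, int(row.pos), row.ref_allele, row.alt_alleles)
        locus = loci_cache.get(key)
        if locus is None:
            locus = IndelLocus(
                row.chrom, int(row.pos), row.ref_allele, tuple(row.alt_alleles.split(","))
            )
            loci_cache[key] = locus
        reads.append(
            ReadRecord(
                read_id=row.read_id,
                sequence=row.sequence,
                chrom=row.chrom,
                locus=locus,
                allele_index=int(row.allele_index),
                flank_left=int(row.flank_left),
                flank_right=int(row.flank_right),
                truth_start=int(row.truth_start),
                truth_end=int(row.truth_end),
            )
        )
    flanks = tuple(sorted({r.flank_left for r in reads}))
    per_locus = max(
        (sum(1 for r in reads if r.locus is l and r.allele_index == 0) for l in loci_cache.values()),
        default=0,
    )
    return ReadSetManifest(reads, per_locus, flanks)
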