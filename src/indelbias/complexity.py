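"""Per-locus INDEL complexity: the number of co-optimal alignments.

The complexity ``n_i`` of an INDEL location is the number of optimal
alignments obtained when a read bearing an alternative allele is aligned
(fitting, affine-gap model) against the reference window around the locus.
``n_i = 1`` means the recorded representation is forced; ``n_i > 1`` means an
aligner's reported alignment — and hence the profile's recorded INDEL — was an
arbitrary pick among ``n_i`` equally good candidates.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import pandas as pd

from .align import ScoringScheme, enumerate_optimal
from .errors import AmbiguityOverflowError, ValidationError
from .seqio import IndelLocus, ReferenceGenome

logger = logging.getLogger(__name__)

__all__ = ["ComplexityRecord", "ComplexityProfile", "locus_complexity", "profile_complexity"]


@dataclass(frozen=True)
class ComplexityRecord:
    """Optimal-alignment counts for one locus (max over alt alleles)."""

    locus: IndelLocus
    n_simple: int
    n_affine: int
    per_alt: Tuple[Tuple[int, int], ...]  # (n_simple, n_affine) per alt allele
    flank: int

    @property
    def is_ambiguous(self) -> bool:
        return self.n_affine > 1


@dataclass
class ComplexityProfile:
    """Genome-wide complexity summary (the tabular content behind the
    per-chromosome distribution and density figures)."""

    records: List[ComplexityRecord]
    failures: List[Tuple[IndelLocus, str]] = field(default_factory=list)

    @property
    def total(self) -> int:
        return len(self.records)

    @property
    def n_multiple(self) -> int:
        """Loci with more than one optimal affine alignment."""
        return sum(1 for r in self.records if r.n_affine > 1)

    def histogram(self) -> Dict[str, Counter]:
        """Per-chromosome histogram of n_affine."""
        out: Dict[str, Counter] = {}
        for r in self.records:
            out.setdefault(r.locus.chrom, Counter())[r.n_affine] += 1
        return out

    def record_for(self, chrom: str, pos: int) -> Optional[ComplexityRecord]:
        if not hasattr(self, "_index"):
            self._index = {(r.locus.chrom, r.locus.pos): r for r in self.records}
        return self._index.get((chrom, pos))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [r.locus.chrom for r in self.records],
                "pos": [r.locus.pos for r in self.records],
                "ref_allele": [r.locus.ref_allele for r in self.records],
                "alt_alleles": [",".join(r.locus.alt_alleles) for r in self.records],
                "n_simple": [r.n_simple for r in self.records],
                "n_affine": [r.n_affine for r in self.records],
            }
        )

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for chrom, counter in sorted(self.histogram().items()):
            for n, count in sorted(counter.items()):
                rows.append({"chrom": chrom, "n_affine": n, "loci": count})
        return pd.DataFrame(rows, columns=["chrom", "n_affine", "loci"])

    def write_table(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def write_summary(self, path: Union[str, Path]) -> None:
        self.summary_frame().to_csv(path, sep="\t", index=False)


def locus_complexity(
    ref: ReferenceGenome,
    locus: IndelLocus,
    s: ScoringScheme = ScoringScheme(),
    flank: int = 50,
    cap: int = 1000,
) -> ComplexityRecord:
    """Count optimal fitting alignments at one locus, both models.

    For each alternative allele the alt-bearing read (symmetric flanks of
    ``flank`` bases) is aligned against the reference window — the locus
    interval padded by ``flank`` on both sides — and all optimal alignments
    are enumerated under the affine scheme ``s`` and its equal-penalty
    counterpart.  The locus complexity is the maximum over alt alleles
    (an aligner faces each read separately; the maximum is the worst-case
    ambiguity); per-alt counts are retained in the record.
    """
    locus.validate_against(ref)
    chrom_len = ref.lengths[locus.chrom]
    if locus.pos - flank < 1 or locus.end + flank > chrom_len:
        raise ValidationError(f"{locus.chrom}:{locus.pos}: flank {flank} out of bounds")
    window = ref.fetch(locus.chrom, locus.pos - flank, locus.end + flank)
    if "N" in window:
        raise ValidationError(f"{locus.chrom}:{locus.pos}: window contains N")
    seq = ref.sequences[locus.chrom]
    u = seq[locus.pos - 1 - flank : locus.pos - 1]
    v = seq[locus.end : locus.end + flank]
    simple = s.as_simple()
    per_alt: List[Tuple[int, int]] = []
    for alt in locus.alt_alleles:
        read = u + alt + v
        try:
            n_aff = len(enumerate_optimal(read, window, s, mode="fitting", cap=cap))
            n_sim = (
                n_aff
                if not s.is_affine
                else len(enumerate_optimal(read, window, simple, mode="fitting", cap=cap))
            )
        except AmbiguityOverflowError as exc:
            raise AmbiguityOverflowError(exc.cap, f"{locus.chrom}:{locus.pos}") from None
        per_alt.append((n_sim, n_aff))
    return ComplexityRecord(
        locus=locus,
        n_simple=max(n for n, _ in per_alt),
        n_affine=max(n for _, n in per_alt),
        per_alt=tuple(per_alt),
        flank=flank,
    )


def profile_complexity(
    ref: ReferenceGenome,
    loci: Sequence[IndelLocus],
    s: ScoringScheme = ScoringScheme(),
    flank: int = 50,
    cap: int = 1000,
) -> ComplexityProfile:
    """Complexity for every locus of a profile; per-locus failures are logged
    and tallied rather than fatal.  Deterministic given its inputs."""
    profile = ComplexityProfile([])
    for locus in loci:
        try:
            profile.records.append(locus_complexity(ref, locus, s, flank, cap))
        except (ValidationError, AmbiguityOverflowError) as exc:
            profile.failures.append((locus, str(exc)))
            logger.warning("complexity failed at %s:%d: %s", locus.chrom, locus.pos, exc)
    return profile
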