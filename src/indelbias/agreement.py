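"""Agreement between alignments and a variant profile, and its null model.

Given reads bearing alternative alleles, an aligner's output either reproduces
the profile's recorded INDEL representation ("agrees") or lands on one of the
other co-optimal representations.  If an aligner picked uniformly at random
among the ``n_i`` optimal alignments at locus ``i``, each trial would agree
with probability ``1/n_i``, so across trials

* expected agreement      mu      = sum(1/n_i)
* its variance            sigma^2 = sum((1/n_i) * (1 - 1/n_i))
* observed deviation      lambda  = agreeing - mu

and the one-sided Chebyshev–Cantelli tail bound sigma^2 / (sigma^2 + lambda^2)
bounds the probability of a deviation at least that large by chance — the
"p-value bound" reported per aligner/policy, one table row each.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .align import (
    PairAlignment,
    ScoringScheme,
    VariantCall,
    alignment_to_calls,
    enumerate_optimal,
)
from .complexity import ComplexityProfile
from .errors import AmbiguityOverflowError, ValidationError
from .reads import ReadRecord, is_correctly_mapped
from .seqio import IndelLocus, ReferenceGenome, SamAlignment

logger = logging.getLogger(__name__)

__all__ = [
    "CallComparison",
    "AgreementSummary",
    "sam_to_pair_alignment",
    "compare_call",
    "summarize",
    "simulate_policy_alignments",
    "agreement_table",
]

POLICIES = ("leftmost", "rightmost", "uniform")


@dataclass(frozen=True)
class CallComparison:
    """Outcome of scoring one aligned read against the profile."""

    read_id: str
    chrom: str
    locus_pos: int
    mapped_correctly: bool
    calls: Tuple[VariantCall, ...]
    matched: bool
    flagged: bool = False  # CIGAR inconsistent with the reference; excluded from N


@dataclass
class AgreementSummary:
    """One aligner/policy row: mapping rate, agreement, and the null model."""

    label: str
    total_reads: int
    correct_mapped: int
    n_trials: int  # N: trials at multiple-optimal loci, correctly mapped
    agreeing: int
    mu: float
    sigma2: float
    trial_unit: str = "reads"
    below_expectation: bool = False
    degenerate: bool = False  # sigma2 == 0 and lambda == 0

    @property
    def correct_mapped_pct(self) -> float:
        return 100.0 * self.correct_mapped / self.total_reads if self.total_reads else float("nan")

    @property
    def actual_pct(self) -> float:
        return 100.0 * self.agreeing / self.n_trials if self.n_trials else float("nan")

    @property
    def expected_pct(self) -> float:
        return 100.0 * self.mu / self.n_trials if self.n_trials else float("nan")

    @property
    def lam(self) -> float:
        """Observed deviation from expectation, in counts."""
        return self.agreeing - self.mu

    @property
    def p_bound(self) -> float:
        """Chebyshev–Cantelli bound sigma^2 / (sigma^2 + lambda^2).

        Depends on the deviation only through its magnitude, so strong
        disagreement (lambda < 0) is as unlikely under the null as strong
        agreement; a zero deviation (or a degenerate zero-variance null)
        yields the trivial bound 1.
        """
        lam = self.lam
        if lam == 0:
            return 1.0
        return self.sigma2 / (self.sigma2 + lam * lam)

    def to_row(self) -> Dict[str, object]:
        return {
            "aligner": self.label,
            "correct_mapping_pct": round(self.correct_mapped_pct, 2),
            "actual_agreement_pct": round(self.actual_pct, 2),
            "expected_agreement_pct": round(self.expected_pct, 2),
            "p_bound": self.p_bound,
            "N": self.n_trials,
        }

    def summary(self) -> str:
        lines = [
            f"Agreement summary [{self.label}] ({self.trial_unit} as trials)",
            f"  reads total / correctly mapped : {self.total_reads} / {self.correct_mapped}"
            f" ({self.correct_mapped_pct:.1f} %)",
            f"  trials at ambiguous loci (N)   : {self.n_trials}",
            f"  agreeing / actual agreement    : {self.agreeing} ({self.actual_pct:.1f} %)",
            f"  expected agreement mu          : {self.mu:.3f} ({self.expected_pct:.1f} %)",
            f"  variance sigma^2               : {self.sigma2:.3f}",
            f"  deviation lambda               : {self.lam:+.3f}",
            f"  Chebyshev-Cantelli p-bound     : {self.p_bound:.3g}",
        ]
        if self.below_expectation:
            lines.append("  note: agreement below expectation")
        if self.degenerate:
            lines.append("  note: degenerate null (sigma^2 = 0)")
        return "\n".join(lines)


def sam_to_pair_alignment(a: SamAlignment, reference: ReferenceGenome) -> PairAlignment:
    """Expand a SAM record's CIGAR into an explicit column alignment.

    ``M`` runs are split into match/mismatch against the reference; soft
    clips are dropped (they are not part of the alignment, so the resulting
    read is the clipped sequence).  Raises :class:`ValidationError` when the
    record runs off the chromosome.
    """
    seq = reference.sequences[a.chrom]
    cols: List[str] = []
    read_parts: List[str] = []
    ref_i = a.pos - 1  # 0-based
    read_i = 0
    for op, n in a.cigar:
        if op == "S":
            read_i += n
        elif op == "M":
            if ref_i + n > len(seq):
                raise ValidationError(f"{a.read_id}: alignment runs off {a.chrom}")
            for k in range(n):
                cols.append("M" if a.read_sequence[read_i + k] == seq[ref_i + k] else "X")
            read_parts.append(a.read_sequence[read_i : read_i + n])
            ref_i += n
            read_i += n
        elif op == "I":
            cols.append("I" * n)
            read_parts.append(a.read_sequence[read_i : read_i + n])
            read_i += n
        elif op == "D":
            if ref_i + n > len(seq):
                raise ValidationError(f"{a.read_id}: alignment runs off {a.chrom}")
            cols.append("D" * n)
            ref_i += n
        else:  # pragma: no cover - seqio restricts the alphabet
            raise ValidationError(f"{a.read_id}: unsupported CIGAR op {op}")
    return PairAlignment(
        read="".join(read_parts), columns="".join(cols), window_start=a.pos, score=0.0
    )


def compare_call(
    a: SamAlignment, r: ReadRecord, locus: IndelLocus, ref: ReferenceGenome
) -> CallComparison:
    """Score one alignment of read ``r`` against the profile entry ``locus``.

    The alignment *matches* when one of its extracted anchored calls equals
    the recorded (pos, REF, ALT) exactly — for the alt allele the read was
    built from.  An equivalent gap placed one repeat unit away is correctly
    mapped but does not match.
    """
    mapped = is_correctly_mapped(a, r)
    if not mapped:
        return CallComparison(r.read_id, r.chrom, locus.pos, False, (), False)
    try:
        pa = sam_to_pair_alignment(a, ref)
        calls = tuple(alignment_to_calls(pa, a.chrom, ref, validate=False))
    except (ValidationError, IndexError) as exc:
        logger.warning("flagged %s: %s", r.read_id, exc)
        return CallComparison(r.read_id, r.chrom, locus.pos, True, (), False, flagged=True)
    target = VariantCall(locus.chrom, locus.pos, locus.ref_allele, r.alt_allele)
    return CallComparison(r.read_id, r.chrom, locus.pos, True, calls, target in calls)


def summarize(
    comparisons: Sequence[CallComparison],
    complexity: ComplexityProfile,
    label: str,
    trial_unit: str = "reads",
) -> AgreementSummary:
    """Aggregate comparisons into one agreement-table row.

    Only loci with multiple optimal affine alignments enter the analysis.
    With ``trial_unit="reads"`` (default, matching the 10x design) every
    correctly mapped read is one trial with success probability ``1/n_i``;
    with ``trial_unit="loci"`` each locus with at least one correctly mapped
    read is a single trial, agreeing when any of its reads agrees.
    """
    if trial_unit not in ("reads", "loci"):
        raise ValueError(f"unknown trial unit {trial_unit!r}")
    total = len(comparisons)
    correct = sum(1 for c in comparisons if c.mapped_correctly and not c.flagged)
    trials: List[Tuple[CallComparison, int]] = []
    for c in comparisons:
        if not c.mapped_correctly or c.flagged:
            continue
        rec = complexity.record_for(c.chrom, c.locus_pos)
        if rec is None:
            raise ValidationError(f"no complexity record for {c.chrom}:{c.locus_pos}")
        if rec.n_affine > 1:
            trials.append((c, rec.n_affine))
    if trial_unit == "loci":
        by_locus: Dict[Tuple[str, int], Tuple[bool, int]] = {}
        for c, n in trials:
            key = (c.chrom, c.locus_pos)
            agreed, _ = by_locus.get(key, (False, n))
            by_locus[key] = (agreed or c.matched, n)
        agreeing = sum(1 for agreed, _ in by_locus.values() if agreed)
        ns = [n for _, n in by_locus.values()]
    else:
        agreeing = sum(1 for c, _ in trials if c.matched)
        ns = [n for _, n in trials]
    mu = float(sum(1.0 / n for n in ns))
    sigma2 = float(sum((1.0 / n) * (1.0 - 1.0 / n) for n in ns))
    summary = AgreementSummary(
        label=label,
        total_reads=total,
        correct_mapped=correct,
        n_trials=len(ns),
        agreeing=agreeing,
        mu=mu,
        sigma2=sigma2,
        trial_unit=trial_unit,
        below_expectation=agreeing < mu,
        degenerate=sigma2 == 0.0 and agreeing == mu,
    )
    if summary.degenerate:
        logger.info("[%s] degenerate null: sigma^2 = 0 and lambda = 0", label)
    if summary.below_expectation:
        logger.info("[%s] agreement below expectation (lambda < 0)", label)
    return summary


def _gap_key(a: PairAlignment, genome_start: int) -> Tuple:
    """Sort key ordering co-optimal alignments by genomic gap coordinates."""
    positions = []
    ref_pos = genome_start + a.window_start - 1
    for c in a.columns:
        if c in "MX":
            ref_pos += 1
        elif c == "D":
            positions.append(ref_pos)
            ref_pos += 1
        else:
            positions.append(ref_pos)
    return (tuple(positions), a.window_start, a.columns)


def simulate_policy_alignments(
    reads: Sequence[ReadRecord],
    ref: ReferenceGenome,
    policy: str,
    s: ScoringScheme = ScoringScheme(),
    seed: Optional[int] = None,
    cap: int = 1000,
    pad: int = 8,
) -> List[SamAlignment]:
    """An idealized aligner that maps every read to its truth window.

    For each read, all optimal fitting alignments against the (padded) truth
    window are enumerated and the policy picks one: ``leftmost``/``rightmost``
    place the gap at the smallest/largest genomic coordinate (the two
    deterministic conventions real aligners implicitly implement), while
    ``uniform`` draws uniformly among the optima (the null model behind the
    expected-agreement statistic).  Reads whose ambiguity exceeds ``cap`` are
    skipped and logged.
    """
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}; expected one of {POLICIES}")
    rng = np.random.default_rng(seed)
    out: List[SamAlignment] = []
    for r in reads:
        chrom_len = ref.lengths[r.chrom]
        w_start = max(1, r.truth_start - pad)
        w_end = min(chrom_len, r.truth_end + pad)
        window = ref.fetch(r.chrom, w_start, w_end)
        try:
            alns = enumerate_optimal(r.sequence, window, s, mode="fitting", cap=cap)
        except AmbiguityOverflowError as exc:
            logger.warning("skipping %s: %s", r.read_id, exc)
            continue
        ordered = sorted(alns, key=lambda a: _gap_key(a, w_start))
        if policy == "leftmost":
            pick = ordered[0]
        elif policy == "rightmost":
            pick = ordered[-1]
        else:
            pick = ordered[int(rng.integers(len(ordered)))]
        out.append(
            SamAlignment(
                read_id=r.read_id,
                chrom=r.chrom,
                pos=w_start + pick.window_start - 1,
                cigar=_columns_to_cigar(pick.columns),
                read_sequence=r.sequence,
            )
        )
    return out


def _columns_to_cigar(columns: str) -> Tuple[Tuple[str, int], ...]:
    ops: List[Tuple[str, int]] = []
    for c in columns:
        op = "M" if c in "MX" else c
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + 1)
        else:
            ops.append((op, 1))
    return tuple(ops)


def agreement_table(summaries: Sequence[AgreementSummary]) -> pd.DataFrame:
    """The aligner-comparison table: one row per aligner/policy."""
    return pd.DataFrame([s.to_row() for s in summaries])
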