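"""Synthetic reference + INDEL profile with oracle-known alignment ambiguity.

The generator emulates the structure of the real study inputs — a
multi-chromosome reference and an INDEL profile — while controlling exactly
which loci are ambiguous.  Ambiguous loci embed an INDEL whose allele is one
unit of a tandem repeat of ``c`` copies (unit length ``L``):

* deleting one unit from ``c`` copies admits ``(c-1)·L + 1`` equivalent
  contiguous gap placements,
* inserting one extra unit next to ``c`` copies admits ``c·L + 1``,

and the immediate neighbours of the repeat are chosen to break any accidental
extension, so those counts are exact.  Every equivalent anchored
representation is computed by a sliding-equality check (independent of the
alignment DP) and stored as ground truth; the profile's recorded
representation follows a configurable convention (leftmost / rightmost /
uniform-random among the equivalents).  Unambiguous loci are placed in
repeat-free context, verified by the same check.

Background sequence is seeded i.i.d. uniform {A,C,G,T}; loci are spaced far
enough apart that reads with the maximum flank never span two loci.
Generation is a pure function of the :class:`SyntheticSpec`.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .errors import CapacityError, ParameterError
from .seqio import IndelLocus, ReferenceGenome, write_fasta, write_variant_profile

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticSpec",
    "LocusTruth",
    "SyntheticDataset",
    "generate",
    "write_truth",
    "read_truth",
    "spec_from_config",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic study; generation is deterministic in these.

    ``ambiguous_n_pool`` is the pool the per-locus target complexity is drawn
    from; the default puts the mode at n = 3, the regime where most ambiguous
    INDELs have three co-optimal alignments.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chromosome_length: int = 60_000
    n_loci: int = 100
    fraction_ambiguous: float = 0.3
    unit_len_range: Tuple[int, int] = (1, 3)
    copies_range: Tuple[int, int] = (2, 4)
    indel_len_range: Tuple[int, int] = (1, 4)
    ambiguous_n_pool: Tuple[int, ...] = (2, 3, 3, 3, 4, 5)
    recording_convention: str = "leftmost"
    flank_max: int = 50

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_ambiguous <= 1.0:
            raise ParameterError("fraction_ambiguous must lie in [0, 1]")
        for lo, hi in (self.unit_len_range, self.copies_range, self.indel_len_range):
            if lo < 1 or hi < lo:
                raise ParameterError("length/count ranges must be positive and ordered")
        if self.recording_convention not in ("leftmost", "rightmost", "uniform"):
            raise ParameterError(
                f"unknown recording convention {self.recording_convention!r}"
            )
        if min(self.ambiguous_n_pool, default=0) < 2:
            raise ParameterError("ambiguous target complexities must be >= 2")
        if self.n_chromosomes < 1 or self.n_loci < 0 or self.chromosome_length < 1:
            raise ParameterError("counts and lengths must be positive")


@dataclass(frozen=True)
class LocusTruth:
    """Ground truth for one generated locus.

    ``equivalents`` lists every anchored representation (pos, REF, ALT) of
    the same physical variant; the recorded representation is one of them and
    ``n_true`` equals their number.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    kind: str  # "del" | "ins"
    ambiguous: bool
    n_true: int
    equivalents: Tuple[Tuple[int, str, str], ...]

    def __post_init__(self) -> None:
        if (self.pos, self.ref_allele, self.alt_allele) not in self.equivalents:
            raise ValueError("recorded representation missing from equivalent set")
        if len(self.equivalents) != self.n_true:
            raise ValueError("equivalent set size disagrees with n_true")


@dataclass
class SyntheticDataset:
    spec: SyntheticSpec
    genome: ReferenceGenome
    loci: List[IndelLocus]
    truth: List[LocusTruth]

    def truth_frame(self) -> pd.DataFrame:
        return _truth_frame(self.truth)

    def write(self, outdir: Union[str, Path]) -> Dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "reference.fa",
            "vcf": outdir / "profile.vcf",
            "truth": outdir / "truth.tsv",
        }
        write_fasta(self.genome, paths["fasta"])
        write_variant_profile(self.loci, self.genome, paths["vcf"])
        write_truth(self.truth, paths["truth"])
        return paths


def _is_primitive(unit: str) -> bool:
    L = len(unit)
    return all(unit != unit[:d] * (L // d) for d in range(1, L) if L % d == 0)


def _random_unit(rng: np.random.Generator, L: int) -> str:
    while True:
        unit = "".join(_BASES[b] for b in rng.integers(0, 4, L))
        if _is_primitive(unit):
            return unit


def _deletion_placements(w_ref: str, w_alt: str, d: int) -> List[int]:
    """0-based window offsets i where deleting w_ref[i:i+d] yields w_alt."""
    return [i for i in range(1, len(w_ref) - d + 1) if w_ref[:i] + w_ref[i + d :] == w_alt]


def _place_ambiguous(
    arr: List[str], site: int, rng: np.random.Generator, spec: SyntheticSpec
) -> Tuple[List[Tuple[int, str, str]], str, int]:
    """Embed a tandem-repeat INDEL at ``site`` (0-based); returns the
    equivalent representations (1-based), the kind, and the expected n."""
    n_target = int(rng.choice(np.asarray(spec.ambiguous_n_pool)))
    ulo, uhi = spec.unit_len_range
    clo, chi = spec.copies_range
    cands: List[Tuple[str, int, int]] = []
    for L in range(ulo, uhi + 1):
        if (n_target - 1) % L:
            continue
        q = (n_target - 1) // L
        if q + 1 >= 2 and clo <= q + 1 <= chi:
            cands.append(("del", L, q + 1))
        if q >= 1 and clo <= q <= chi:
            cands.append(("ins", L, q))
    if not cands:  # the ranges cannot express n_target as a proper repeat: fall
        # back to a homopolymer, which can express any n
        cands = [("del", 1, n_target)]
    kind, L, c = cands[int(rng.integers(len(cands)))]
    unit = _random_unit(rng, L)
    span = c * L
    arr[site : site + span] = list(unit * c)
    # break the repeat at both boundaries so the equivalent set is exact
    arr[site - 1] = _BASES.replace(unit[-1], "")[int(rng.integers(3))]
    arr[site + span] = _BASES.replace(unit[0], "")[int(rng.integers(3))]
    m0 = L + 4
    w0 = site - m0  # 0-based genomic start of the check window
    w_ref = "".join(arr[w0 : site + span + m0])
    if kind == "del":
        w_alt = w_ref[:m0] + w_ref[m0 + L :]
        placements = _deletion_placements(w_ref, w_alt, L)
        expected = (c - 1) * L + 1
        reps = [(w0 + i, w_ref[i - 1 : i + L], w_ref[i - 1]) for i in placements]
    else:
        w_alt = w_ref[:m0] + unit + w_ref[m0:]
        placements = _deletion_placements(w_alt, w_ref, L)
        expected = c * L + 1
        reps = [(w0 + i, w_alt[i - 1], w_alt[i - 1 : i + L]) for i in placements]
    if len(reps) != expected:  # pragma: no cover - construction contract
        raise RuntimeError(
            f"self-check failed at site {site}: {len(reps)} placements, expected {expected}"
        )
    return reps, kind, expected


def _place_plain(
    arr: List[str], site: int, rng: np.random.Generator, spec: SyntheticSpec
) -> Tuple[Tuple[int, str, str], str]:
    """Embed an unambiguous INDEL at ``site``; returns its single anchored
    representation (1-based) and the kind."""
    kind = "del" if rng.random() < 0.5 else "ins"
    dlo, dhi = spec.indel_len_range
    d = int(rng.integers(dlo, dhi + 1))
    a = site  # 0-based anchor
    m = d + 4
    for _ in range(200):
        if kind == "del":
            w_ref = "".join(arr[a - m : a + 1 + d + m])
            w_alt = w_ref[: m + 1] + w_ref[m + 1 + d :]
            placements = _deletion_placements(w_ref, w_alt, d)
            if len(placements) == 1:
                return (a + 1, w_ref[m : m + 1 + d], w_ref[m]), kind
            # accidental repeat: rewrite the local background and retry
            for k in range(a - 2, a + d + 3):
                arr[k] = _BASES[int(rng.integers(4))]
        else:
            ins = "".join(_BASES[b] for b in rng.integers(0, 4, d))
            w_ref = "".join(arr[a - m : a + 1 + m])
            w_alt = w_ref[: m + 1] + ins + w_ref[m + 1 :]
            placements = _deletion_placements(w_alt, w_ref, d)
            if len(placements) == 1:
                return (a + 1, w_ref[m], w_ref[m] + ins), kind
    raise RuntimeError(f"could not place unambiguous locus at site {site}")  # pragma: no cover


def generate(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate (reference, profile, ground truth) from a spec.

    Raises :class:`CapacityError` when the requested loci cannot be placed
    with the required spacing (2 x flank_max plus margin, so no read spans
    two loci).
    """
    rng = np.random.default_rng(spec.seed)
    names = [f"chr{i + 1}" for i in range(spec.n_chromosomes)]
    base_count, rem = divmod(spec.n_loci, spec.n_chromosomes)
    counts = [base_count + (1 if i < rem else 0) for i in range(spec.n_chromosomes)]
    edge = spec.flank_max + 20
    min_spacing = 2 * spec.flank_max + 30
    for name, count in zip(names, counts):
        usable = spec.chromosome_length - 2 * edge
        if count > 0 and (usable <= 0 or usable / count < min_spacing):
            raise CapacityError(
                f"{count} loci do not fit on {name} "
                f"({spec.chromosome_length} bp, spacing >= {min_spacing} required)"
            )
    n_amb = round(spec.fraction_ambiguous * spec.n_loci)
    amb_idx = set(int(i) for i in rng.permutation(spec.n_loci)[:n_amb])

    sequences: Dict[str, str] = {}
    loci: List[IndelLocus] = []
    truths: List[LocusTruth] = []
    gi = 0
    for name, count in zip(names, counts):
        arr = [_BASES[b] for b in rng.integers(0, 4, spec.chromosome_length)]
        if count:
            spacing = (spec.chromosome_length - 2 * edge) / count
            for k in range(count):
                center = edge + (k + 0.5) * spacing
                site = int(center + rng.uniform(-0.15, 0.15) * spacing)
                ambiguous = gi in amb_idx
                if ambiguous:
                    reps, kind, n_true = _place_ambiguous(arr, site, rng, spec)
                else:
                    rep, kind = _place_plain(arr, site, rng, spec)
                    reps, n_true = [rep], 1
                if spec.recording_convention == "leftmost":
                    recorded = reps[0]
                elif spec.recording_convention == "rightmost":
                    recorded = reps[-1]
                else:
                    recorded = reps[int(rng.integers(len(reps)))]
                pos, ref, alt = recorded
                loci.append(IndelLocus(name, pos, ref, (alt,)))
                truths.append(
                    LocusTruth(
                        chrom=name,
                        pos=pos,
                        ref_allele=ref,
                        alt_allele=alt,
                        kind=kind,
                        ambiguous=ambiguous,
                        n_true=n_true,
                        equivalents=tuple(reps),
                    )
                )
                gi += 1
        sequences[name] = "".join(arr)
    genome = ReferenceGenome(sequences)
    for locus in loci:
        locus.validate_against(genome)
    logger.info(
        "generated %d loci (%d ambiguous) on %d chromosomes",
        len(loci),
        n_amb,
        spec.n_chromosomes,
    )
    return SyntheticDataset(spec, genome, loci, truths)


def _truth_frame(truths: Sequence[LocusTruth]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [t.chrom for t in truths],
            "pos": [t.pos for t in truths],
            "ref_allele": [t.ref_allele for t in truths],
            "alt_allele": [t.alt_allele for t in truths],
            "kind": [t.kind for t in truths],
            "ambiguous": [int(t.ambiguous) for t in truths],
            "n_true": [t.n_true for t in truths],
            "equivalents": [
                ";".join(f"{p}:{r}>{a}" for p, r, a in t.equivalents) for t in truths
            ],
        }
    )


def write_truth(truths: Sequence[LocusTruth], path: Union[str, Path]) -> None:
    _truth_frame(truths).to_csv(path, sep="\t", index=False)


def read_truth(path: Union[str, Path]) -> List[LocusTruth]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    out: List[LocusTruth] = []
    for row in df.itertuples(index=False):
        equivalents = []
        for part in str(row.equivalents).split(";"):
            p, rest = part.split(":", 1)
            r, a = rest.split(">", 1)
            equivalents.append((int(p), r, a))
        out.append(
            LocusTruth(
                chrom=row.chrom,
                pos=int(row.pos),
                ref_allele=row.ref_allele,
                alt_allele=row.alt_allele,
                kind=row.kind,
                ambiguous=bool(row.ambiguous),
                n_true=int(row.n_true),
                equivalents=tuple(equivalents),
            )
        )
    return out


def spec_from_config(path: Union[str, Path]) -> SyntheticSpec:
    """Parse a flat ``key = value`` config file into a :class:`SyntheticSpec`.

    Comma-separated values become integer tuples; unknown keys raise
    :class:`ParameterError`.
    """
    fields = {f: t for f, t in SyntheticSpec.__annotations__.items()}
    kwargs: Dict[str, object] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ParameterError(f"{path}:{lineno}: expected key = value")
        key, value = (part.strip() for part in line.split("=", 1))
        if key not in fields:
            raise ParameterError(f"{path}:{lineno}: unknown key {key!r}")
        if key == "recording_convention":
            kwargs[key] = value
        elif "," in value:
            kwargs[key] = tuple(int(v) for v in value.split(","))
        elif key == "fraction_ambiguous":
            kwargs[key] = float(value)
        else:
            kwargs[key] = int(value)
    return SyntheticSpec(**kwargs)
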