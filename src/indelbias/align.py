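"""Pairwise alignment with exhaustive enumeration of all co-optimal alignments.

Two scoring models are supported:

* the *equal-penalty* (linear gap) model, in which every gapped base costs the
  gap-extension score ``ε``, and
* the *affine-gap* model, in which a gap of length ``k`` costs ``ρ + k·ε`` so
  that one long gap is cheaper than several short ones.

The dynamic programs are the classic Needleman–Wunsch recurrence and the
three-matrix Gotoh recurrence.  Unlike ordinary aligners, the traceback here
follows *every* co-optimal predecessor at every cell and therefore returns the
complete set of maximum-scoring alignments.  The size of that set is the
"INDEL complexity" of a locus and the object of study of this package: when it
exceeds one, any single alignment an aligner reports is an arbitrary pick.

Alignments are represented as column strings over ``M`` (match), ``X``
(mismatch), ``D`` (reference base aligned to a read gap, i.e. a deletion from
the read's point of view) and ``I`` (read base aligned to a reference gap, an
insertion).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, List, Optional, Sequence, Tuple, Union

from .errors import AmbiguityOverflowError, ValidationError

__all__ = [
    "ScoringScheme",
    "DPState",
    "PairAlignment",
    "VariantCall",
    "fill_simple",
    "fill_affine",
    "enumerate_optimal",
    "alignment_to_calls",
    "alignment_score",
    "format_alignment",
]

NEG_INF = float("-inf")

#: read-consuming column types (must total the read length)
READ_COLS = frozenset("MXI")
#: reference-consuming column types (must total the reference span)
REF_COLS = frozenset("MXD")


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scores: a match reward, a mismatch score, and gap costs.

    ``gap_extend`` (ε) is the per-base gap cost; ``gap_open`` (ρ) is the extra
    cost charged once per gap.  ``gap_open == 0`` selects the equal-penalty
    model.  Defaults follow bwa-like ratios; the values themselves matter less
    than the fact that a contiguous gap is favoured over split gaps and over
    runs of mismatches.
    """

    match: float = 1
    mismatch: float = -4
    gap_open: float = -6
    gap_extend: float = -1

    def __post_init__(self) -> None:
        if not self.match > self.mismatch:
            raise ValueError("match score must exceed mismatch score")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap costs must be <= 0")

    @property
    def is_affine(self) -> bool:
        return self.gap_open != 0

    def score(self, a: str, b: str) -> float:
        """Substitution score for aligning read base ``a`` to reference base ``b``."""
        return self.match if a == b else self.mismatch

    def as_simple(self) -> "ScoringScheme":
        """The equal-penalty counterpart (``ρ = 0``) of this scheme."""
        return replace(self, gap_open=0)


@dataclass
class DPState:
    """Filled dynamic-programming matrices for one read/window pair.

    ``M`` always holds the overall-best score for each prefix pair.  In the
    affine model ``X`` holds the best score for alignments ending with a read
    base in a gap and ``Y`` for alignments ending with a reference base in a
    gap; in the simple model both are ``None``.
    """

    model: str  # "simple" | "affine"
    mode: str  # "global" | "fitting"
    x: str
    y: str
    scheme: ScoringScheme
    M: List[List[float]]
    X: Optional[List[List[float]]] = None
    Y: Optional[List[List[float]]] = None

    @property
    def optimum(self) -> float:
        last = self.M[len(self.x)]
        return last[len(self.y)] if self.mode == "global" else max(last)


@dataclass(frozen=True)
class PairAlignment:
    """One alignment of a read against a reference window.

    ``window_start`` is the 1-based position (in the coordinate system of the
    window/reference handed to the aligner) of the first reference base the
    alignment consumes.  For fitting alignments the window may overhang on
    either side at no cost, so ``window_start`` can exceed 1.
    """

    read: str
    columns: str
    window_start: int
    score: float

    @property
    def ref_span(self) -> int:
        return sum(1 for c in self.columns if c in REF_COLS)

    @property
    def window_end(self) -> int:
        """1-based position of the last reference base consumed."""
        return self.window_start + self.ref_span - 1

    def __post_init__(self) -> None:
        n_read = sum(1 for c in self.columns if c in READ_COLS)
        if n_read != len(self.read):
            raise ValidationError(
                f"columns consume {n_read} read bases, read has {len(self.read)}"
            )


@dataclass(frozen=True, order=True)
class VariantCall:
    """An anchored variant call: REF and ALT share their first base at ``pos``
    for INDELs; SNVs are plain single-base substitutions."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValidationError("REF and ALT must differ")

    @property
    def is_indel(self) -> bool:
        return len(self.ref_allele) != len(self.alt_allele)

    def __str__(self) -> str:  # the x1|x2 notation used throughout
        return f"{self.chrom}:{self.pos}:{self.ref_allele}|{self.alt_allele}"


def _check_pair(x: str, y: str) -> None:
    if not x or not y:
        raise ValueError("alignment requires non-empty sequences")


def fill_simple(x: str, y: str, s: ScoringScheme, mode: str = "global") -> DPState:
    """Fill the single-matrix DP under the equal-penalty model.

    Boundaries are gap-scored prefixes: ``M[i][0] = i·ε`` and, in global mode,
    ``M[0][j] = j·ε``.  In fitting mode the window's leading overhang is free
    (``M[0][j] = 0``) and the optimum is read off the last row.
    """
    _check_pair(x, y)
    n, m = len(x), len(y)
    e = s.gap_extend
    ms, mm = s.match, s.mismatch
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        M[i][0] = i * e
    if mode == "global":
        for j in range(1, m + 1):
            M[0][j] = j * e
    for i in range(1, n + 1):
        xi = x[i - 1]
        Mi, Mi1 = M[i], M[i - 1]
        for j in range(1, m + 1):
            best = Mi1[j - 1] + (ms if xi == y[j - 1] else mm)
            t = Mi1[j] + e
            if t > best:
                best = t
            t = Mi[j - 1] + e
            if t > best:
                best = t
            Mi[j] = best
    return DPState("simple", mode, x, y, s, M)


def fill_affine(x: str, y: str, s: ScoringScheme, mode: str = "global") -> DPState:
    """Fill the three-matrix (Gotoh) DP under the affine-gap model.

    A gap's first base costs ``ρ + ε`` and each further base ``ε``, so leading
    gaps cost ``ρ + k·ε``.  ``M`` is the overall best; ``X``/``Y`` force the
    last column to be a read-in-gap / reference-in-gap column respectively.
    """
    _check_pair(x, y)
    n, m = len(x), len(y)
    e, oe = s.gap_extend, s.gap_open + s.gap_extend
    ms, mm = s.match, s.mismatch
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        X[i][0] = s.gap_open + i * e
        M[i][0] = X[i][0]
    if mode == "global":
        for j in range(1, m + 1):
            Y[0][j] = s.gap_open + j * e
            M[0][j] = Y[0][j]
    # fitting mode: M[0][j] = 0 (free leading window overhang), X/Y stay -inf
    for i in range(1, n + 1):
        xi = x[i - 1]
        Mi, Mi1 = M[i], M[i - 1]
        Xi, Xi1 = X[i], X[i - 1]
        Yi = Y[i]
        for j in range(1, m + 1):
            xv = Mi1[j] + oe
            t = Xi1[j] + e
            if t > xv:
                xv = t
            Xi[j] = xv
            yv = Mi[j - 1] + oe
            t = Yi[j - 1] + e
            if t > yv:
                yv = t
            Yi[j] = yv
            best = Mi1[j - 1] + (ms if xi == y[j - 1] else mm)
            if xv > best:
                best = xv
            if yv > best:
                best = yv
            Mi[j] = best
    return DPState("affine", mode, x, y, s, M, X, Y)


def _trace_simple(state: DPState, cap: int) -> List[Tuple[int, str]]:
    x, y, M = state.x, state.y, state.M
    s, e, mode = state.scheme, state.scheme.gap_extend, state.mode
    n, m = len(x), len(y)
    best = state.optimum
    ends = [m] if mode == "global" else [j for j in range(m + 1) if M[n][j] == best]
    out: List[Tuple[int, str]] = []
    for j_end in ends:
        stack: List[Tuple[int, int, Tuple[str, ...]]] = [(n, j_end, ())]
        while stack:
            i, j, cols = stack.pop()
            if i == 0 and (mode == "fitting" or j == 0):
                out.append((j + 1, "".join(cols)))
                if len(out) > cap:
                    raise AmbiguityOverflowError(cap)
                continue
            v = M[i][j]
            if i > 0 and j > 0 and v == M[i - 1][j - 1] + s.score(x[i - 1], y[j - 1]):
                c = "M" if x[i - 1] == y[j - 1] else "X"
                stack.append((i - 1, j - 1, (c,) + cols))
            if i > 0 and v == M[i - 1][j] + e:
                stack.append((i - 1, j, ("I",) + cols))
            # a fitting alignment never starts or ends with a deletion column:
            # the free overhang subsumes it
            if j > 0 and i > 0 and v == M[i][j - 1] + e and not (mode == "fitting" and not cols):
                stack.append((i, j - 1, ("D",) + cols))
            if j > 0 and i == 0 and mode == "global":
                # leading reference gap in a global alignment
                if v == M[0][j - 1] + e:
                    stack.append((0, j - 1, ("D",) + cols))
    return out


def _trace_affine(state: DPState, cap: int) -> List[Tuple[int, str]]:
    x, y = state.x, state.y
    M, X, Y = state.M, state.X, state.Y
    s, mode = state.scheme, state.mode
    e, oe = s.gap_extend, s.gap_open + s.gap_extend
    n, m = len(x), len(y)
    best = state.optimum
    ends = [m] if mode == "global" else [j for j in range(m + 1) if M[n][j] == best]
    out: List[Tuple[int, str]] = []
    for j_end in ends:
        stack: List[Tuple[str, int, int, Tuple[str, ...]]] = [("M", n, j_end, ())]
        while stack:
            mat, i, j, cols = stack.pop()
            if mat == "M":
                if i == 0 and (mode == "fitting" or j == 0):
                    out.append((j + 1, "".join(cols)))
                    if len(out) > cap:
                        raise AmbiguityOverflowError(cap)
                    continue
                v = M[i][j]
                if i > 0 and j > 0 and v == M[i - 1][j - 1] + s.score(x[i - 1], y[j - 1]):
                    c = "M" if x[i - 1] == y[j - 1] else "X"
                    stack.append(("M", i - 1, j - 1, (c,) + cols))
                if i > 0 and v == X[i][j]:
                    stack.append(("X", i, j, cols))
                if j > 0 and v == Y[i][j] and not (mode == "fitting" and not cols):
                    stack.append(("Y", i, j, cols))
            elif mat == "X":
                v = X[i][j]
                if v == M[i - 1][j] + oe:
                    stack.append(("M", i - 1, j, ("I",) + cols))
                if i > 1 and v == X[i - 1][j] + e:
                    stack.append(("X", i - 1, j, ("I",) + cols))
            else:  # Y
                v = Y[i][j]
                if v == M[i][j - 1] + oe:
                    stack.append(("M", i, j - 1, ("D",) + cols))
                if j > 1 and v == Y[i][j - 1] + e:
                    stack.append(("Y", i, j - 1, ("D",) + cols))
    return out


def enumerate_optimal(
    x: str,
    y: str,
    s: ScoringScheme,
    mode: str = "fitting",
    cap: int = 1000,
    model: Optional[str] = None,
) -> List[PairAlignment]:
    """Return ALL distinct optimal alignments of read ``x`` against window ``y``.

    The model follows the scheme: ``gap_open == 0`` selects the equal-penalty
    DP, anything else the affine-gap DP with a matrix-tagged recursive trace
    (``model`` forces one of ``"simple"``/``"affine"`` explicitly — with
    ``ρ = 0`` the two are interchangeable).
    Every co-optimal predecessor is followed at every step, so the result is
    the union of all optimal alignments; duplicates that can arise when
    different matrix routes converge on the same column sequence are removed.

    Parameters
    ----------
    mode
        ``"global"`` anchors both sequence ends; ``"fitting"`` (default)
        requires the read to be consumed end-to-end while the window may
        overhang on either side at no cost — the geometry of aligning a short
        read into a padded genomic window.
    cap
        Raise :class:`AmbiguityOverflowError` instead of returning more than
        this many alignments.

    Returns
    -------
    list of PairAlignment, sorted by (window_start, columns) for determinism.
    """
    if mode not in ("global", "fitting"):
        raise ValueError(f"unknown mode {mode!r}")
    if model is None:
        model = "affine" if s.is_affine else "simple"
    if model == "affine":
        state = fill_affine(x, y, s, mode)
        raw = _trace_affine(state, cap)
    else:
        state = fill_simple(x, y, s, mode)
        raw = _trace_simple(state, cap)
    best = state.optimum
    seen = sorted(set(raw))
    if len(seen) > cap:
        raise AmbiguityOverflowError(cap)
    return [
        PairAlignment(read=x, columns=cols, window_start=start, score=best)
        for start, cols in seen
    ]


def alignment_score(a: PairAlignment, window: str, s: ScoringScheme) -> float:
    """Recompute an alignment's score column by column (independent of the DP).

    Each maximal run of ``D`` or ``I`` columns is one gap: it costs ``k·ε``
    plus, under the affine model, one ``ρ``.
    """
    score = 0.0
    ref_i = a.window_start - 1  # 0-based index into window
    read_i = 0
    cols = a.columns
    k = 0
    while k < len(cols):
        c = cols[k]
        if c in "MX":
            score += s.score(a.read[read_i], window[ref_i])
            ref_i += 1
            read_i += 1
            k += 1
        else:
            run = k
            while run < len(cols) and cols[run] == c:
                run += 1
            length = run - k
            score += s.gap_open + length * s.gap_extend
            if c == "D":
                ref_i += length
            else:
                read_i += length
            k = run
    return score


def _resolve_sequence(reference: Union[str, "object"], chrom: str) -> str:
    # accept either a bare window/chromosome string or a ReferenceGenome
    if isinstance(reference, str):
        return reference
    return reference.sequences[chrom]


def alignment_to_calls(
    a: PairAlignment,
    chrom: str,
    reference: Union[str, "object"],
    validate: bool = True,
) -> List[VariantCall]:
    """Convert one alignment into anchored variant calls.

    Each maximal run of ``D`` columns becomes one anchored deletion call whose
    anchor is the last reference base before the run; each maximal run of
    ``I`` columns becomes one anchored insertion; each mismatch column becomes
    one SNV.  A gap run at the very start of the alignment is anchored on the
    reference base at ``window_start - 1``; if no such base exists
    (``window_start == 1``) a :class:`ValidationError` is raised.

    ``reference`` may be a :class:`~indelbias.seqio.ReferenceGenome` or a
    plain string; ``a.window_start`` is interpreted 1-based in its coordinates.
    """
    seq = _resolve_sequence(reference, chrom)
    calls: List[VariantCall] = []
    ref_pos = a.window_start  # 1-based next reference base to consume
    read_i = 0
    cols = a.columns
    k = 0
    while k < len(cols):
        c = cols[k]
        if c in "MX":
            if validate:
                same = a.read[read_i] == seq[ref_pos - 1]
                if (c == "M") != same:
                    raise ValidationError(
                        f"column {k} ({c}) inconsistent with reference at {chrom}:{ref_pos}"
                    )
            if c == "X":
                calls.append(VariantCall(chrom, ref_pos, seq[ref_pos - 1], a.read[read_i]))
            ref_pos += 1
            read_i += 1
            k += 1
            continue
        run = k
        while run < len(cols) and cols[run] == c:
            run += 1
        length = run - k
        anchor = ref_pos - 1
        if anchor < 1:
            raise ValidationError(
                f"gap at alignment start with no reference anchor ({chrom}:{ref_pos})"
            )
        anchor_base = seq[anchor - 1]
        if c == "D":
            deleted = seq[ref_pos - 1 : ref_pos - 1 + length]
            calls.append(VariantCall(chrom, anchor, anchor_base + deleted, anchor_base))
            ref_pos += length
        else:  # I
            inserted = a.read[read_i : read_i + length]
            calls.append(VariantCall(chrom, anchor, anchor_base, anchor_base + inserted))
            read_i += length
        k = run
    calls.sort(key=lambda v: (v.pos, v.ref_allele, v.alt_allele))
    return calls


def format_alignment(a: PairAlignment, window: str) -> str:
    """Two-row gapped text rendering (reference on top, read below)."""
    top, mid, bot = [], [], []
    ref_i = a.window_start - 1
    read_i = 0
    for c in a.columns:
        if c in "MX":
            top.append(window[ref_i])
            bot.append(a.read[read_i])
            mid.append("|" if c == "M" else ".")
            ref_i += 1
            read_i += 1
        elif c == "D":
            top.append(window[ref_i])
            bot.append("-")
            mid.append(" ")
            ref_i += 1
        else:
            top.append("-")
            bot.append(a.read[read_i])
            mid.append(" ")
            read_i += 1
    return "".join(top) + "\n" + "".join(mid) + "\n" + "".join(bot)
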