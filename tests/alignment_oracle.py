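"""Independent brute-force oracle: exhaustive enumeration of every monotone
alignment of two short strings, scored from scratch.

Deliberately shares no code with the package's dynamic programs: alignments
are generated as explicit column patterns and scored by walking them, so the
oracle can certify both the optimal score and the *complete set* of optimal
alignments for small inputs.
"""

from functools import lru_cache
from typing import List, Set, Tuple


@lru_cache(maxsize=None)
def _patterns(i: int, j: int) -> Tuple[str, ...]:
    """All column patterns consuming i read bases and j reference bases.

    'P' = aligned pair (match or mismatch), 'I' = read base vs gap,
    'D' = reference base vs gap.
    """
    if i == 0 and j == 0:
        return ("",)
    out: List[str] = []
    if i > 0 and j > 0:
        out.extend(p + "P" for p in _patterns(i - 1, j - 1))
    if i > 0:
        out.extend(p + "I" for p in _patterns(i - 1, j))
    if j > 0:
        out.extend(p + "D" for p in _patterns(i, j - 1))
    return tuple(out)


def _concretize(pattern: str, x: str, y_sub: str) -> str:
    cols = []
    xi = yi = 0
    for c in pattern:
        if c == "P":
            cols.append("M" if x[xi] == y_sub[yi] else "X")
            xi += 1
            yi += 1
        elif c == "I":
            cols.append("I")
            xi += 1
        else:
            cols.append("D")
            yi += 1
    return "".join(cols)


def _score(cols: str, x: str, y_sub: str, match, mismatch, gap_open, gap_extend, affine):
    score = 0.0
    xi = yi = 0
    k = 0
    while k < len(cols):
        c = cols[k]
        if c in "PMX":
            score += match if x[xi] == y_sub[yi] else mismatch
            xi += 1
            yi += 1
            k += 1
        else:
            run = k
            while run < len(cols) and cols[run] == c:
                run += 1
            length = run - k
            score += length * gap_extend + (gap_open if affine else 0.0)
            if c == "I":
                xi += length
            else:
                yi += length
            k = run
    return score


def oracle_enumerate(
    x: str,
    y: str,
    match: float,
    mismatch: float,
    gap_open: float,
    gap_extend: float,
    mode: str = "global",
    affine=None,
) -> Tuple[float, Set[Tuple[int, str]]]:
    """Optimal score and the set of all optimal alignments.

    Returns ``(best_score, {(window_start_1based, column_string), ...})``.
    In fitting mode the read is consumed end-to-end against any contiguous
    (possibly empty) window substring, with no leading or trailing reference
    gap column (a free overhang subsumes those).
    """
    if affine is None:
        affine = gap_open != 0
    best = float("-inf")
    opt: Set[Tuple[int, str]] = set()
    if mode == "global":
        spans = [(0, len(y))]
    else:
        spans = [(s, e) for s in range(len(y) + 1) for e in range(s, len(y) + 1)]
    for s, e in spans:
        y_sub = y[s:e]
        for pattern in _patterns(len(x), e - s):
            if mode == "fitting" and (pattern.startswith("D") or pattern.endswith("D")):
                continue
            sc = _score(pattern, x, y_sub, match, mismatch, gap_open, gap_extend, affine)
            if sc > best:
                best = sc
                opt = set()
            if sc == best:
                opt.add((s + 1, _concretize(pattern, x, y_sub)))
    return best, opt
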