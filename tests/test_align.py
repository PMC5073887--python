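import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alignment_oracle import oracle_enumerate
from conftest import FLANK_U, FLANK_V
from indelbias.align import (
    PairAlignment,
    ScoringScheme,
    VariantCall,
    alignment_score,
    alignment_to_calls,
    enumerate_optimal,
    fill_affine,
    fill_simple,
    format_alignment,
)
from indelbias.errors import AmbiguityOverflowError, ValidationError

SIMPLE = ScoringScheme(1, -4, 0, -1)
DEFAULT = ScoringScheme()  # affine, bwa-like ratios
STEEP = ScoringScheme(2, -3, -4, -2)
SCHEMES = [SIMPLE, DEFAULT, STEEP]


class TestScoringScheme:
    def test_validation(self):
        with pytest.raises(ValueError):
            ScoringScheme(match=1, mismatch=2)
        with pytest.raises(ValueError):
            ScoringScheme(gap_open=1)
        assert not SIMPLE.is_affine and DEFAULT.is_affine
        assert DEFAULT.as_simple().gap_open == 0


class TestFills:
    def test_single_match(self):
        assert fill_simple("A", "A", SIMPLE).M[1][1] == 1
        assert fill_affine("A", "A", DEFAULT).M[1][1] == DEFAULT.match

    @pytest.mark.parametrize("fill", [fill_simple, fill_affine])
    def test_empty_sequence_rejected(self, fill):
        with pytest.raises(ValueError):
            fill("", "ACGT", DEFAULT if fill is fill_affine else SIMPLE)
        with pytest.raises(ValueError):
            fill("ACGT", "", DEFAULT if fill is fill_affine else SIMPLE)

    def test_aa_vs_aaa_optimal_scores(self):
        # one reference base must be gapped: 2 matches + 1 extension,
        # plus the opening penalty under the affine model
        assert fill_simple("AA", "AAA", SIMPLE, mode="global").optimum == 2 - 1
        affine = ScoringScheme(1, -4, -2, -1)
        assert fill_affine("AA", "AAA", affine, mode="global").optimum == 2 - (2 + 1)

    def test_affine_with_zero_opening_scores_like_simple(self):
        import numpy as np

        rng = np.random.default_rng(0)
        for _ in range(20):
            x = "".join("ACGT"[b] for b in rng.integers(0, 4, rng.integers(1, 9)))
            y = "".join("ACGT"[b] for b in rng.integers(0, 4, rng.integers(1, 9)))
            for mode in ("global", "fitting"):
                assert (
                    fill_affine(x, y, SIMPLE, mode).optimum
                    == fill_simple(x, y, SIMPLE, mode).optimum
                )


class TestEnumerate:
    @pytest.mark.parametrize("s", SCHEMES)
    @pytest.mark.parametrize("mode", ["global", "fitting"])
    def test_identical_sequences_have_unique_all_match_optimum(self, s, mode):
        alns = enumerate_optimal("ACGTACGTAC", "ACGTACGTAC", s, mode=mode)
        assert len(alns) == 1
        assert alns[0].columns == "M" * 10
        assert alns[0].window_start == 1

    def test_deletion_has_one_placement_per_offset_under_equal_penalties(self):
        alns = enumerate_optimal("AA", "AAA", SIMPLE, mode="global")
        assert {a.columns for a in alns} == {"DMM", "MDM", "MMD"}
        assert all(a.score == 1 for a in alns)

    def test_worked_insertion_example_two_affine_optima(self):
        read = FLANK_U + "ACGA" + FLANK_V
        window = FLANK_U + "A" + FLANK_V
        alns = enumerate_optimal(read, window, DEFAULT, mode="fitting")
        assert len(alns) == 2
        p = len(FLANK_U) + 1  # window position of the reference A
        calls = {c for a in alns for c in alignment_to_calls(a, "w", window)}
        assert VariantCall("w", p, "A", "ACGA") in calls  # agrees with the profile
        # the other optimum shifts the gap one base left: insert ACG before the A
        assert VariantCall("w", p - 1, window[p - 2], window[p - 2] + "ACG") in calls

    def test_affine_trace_with_zero_opening_reproduces_simple_set(self):
        import numpy as np

        rng = np.random.default_rng(3)
        for _ in range(20):
            x = "".join("AC"[b] for b in rng.integers(0, 2, rng.integers(1, 7)))
            y = "".join("AC"[b] for b in rng.integers(0, 2, rng.integers(1, 7)))
            for mode in ("global", "fitting"):
                simple = enumerate_optimal(x, y, SIMPLE, mode=mode, model="simple")
                affine = enumerate_optimal(x, y, SIMPLE, mode=mode, model="affine")
                assert {(a.window_start, a.columns) for a in simple} == {
                    (a.window_start, a.columns) for a in affine
                }

    def test_ambiguity_overflow_is_an_error_not_truncation(self):
        with pytest.raises(AmbiguityOverflowError) as err:
            enumerate_optimal("A" * 6, "A" * 12, SIMPLE, mode="global", cap=3)
        assert err.value.cap == 3

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            enumerate_optimal("A", "A", DEFAULT, mode="local")


@pytest.mark.parametrize("s", SCHEMES, ids=["equal-penalty", "default-affine", "steep-affine"])
@pytest.mark.parametrize("mode", ["global", "fitting"])
def test_exhaustive_small_pairs_match_bruteforce_oracle(s, mode):
    """Every pair over {A,C} up to length 3: the enumerated set equals the
    brute-force set of maximum-scoring monotone alignments, and every
    alignment rescored from its columns equals the DP optimum."""
    strings = [
        "".join(seq) for n in (1, 2, 3) for seq in itertools.product("AC", repeat=n)
    ]
    for x in strings:
        for y in strings:
            best, expect = oracle_enumerate(
                x, y, s.match, s.mismatch, s.gap_open, s.gap_extend, mode=mode
            )
            got = enumerate_optimal(x, y, s, mode=mode, cap=100_000)
            assert {(a.window_start, a.columns) for a in got} == expect, (x, y)
            assert all(a.score == best for a in got)
            for a in got:
                assert alignment_score(a, y, s) == best


@given(
    x=st.text(alphabet="AC", min_size=1, max_size=8),
    y=st.text(alphabet="AC", min_size=1, max_size=8),
    si=st.integers(0, len(SCHEMES) - 1),
    mode=st.sampled_from(["global", "fitting"]),
)
@settings(max_examples=40, deadline=None, derandomize=True)
def test_sampled_pairs_match_bruteforce_oracle(x, y, si, mode):
    s = SCHEMES[si]
    best, expect = oracle_enumerate(
        x, y, s.match, s.mismatch, s.gap_open, s.gap_extend, mode=mode
    )
    got = enumerate_optimal(x, y, s, mode=mode, cap=1_000_000)
    assert {(a.window_start, a.columns) for a in got} == expect
    assert all(a.score == best for a in got)


class TestCalls:
    WINDOW = "TCACACAGG"

    @pytest.mark.parametrize(
        "columns,expected",
        [
            (
                "MDDMMDDMM",
                [VariantCall("c", 1, "TCA", "T"), VariantCall("c", 5, "ACA", "A")],
            ),
            ("MMMDDDDMM", [VariantCall("c", 3, "ACACA", "A")]),
            ("MDDDDMMMM", [VariantCall("c", 1, "TCACA", "T")]),
        ],
        ids=["split-gaps", "middle-gap", "left-gap"],
    )
    def test_worked_deletion_example_call_extraction(self, columns, expected):
        """The three alignments of TCAGG to the T(CA)3GG context yield the
        anchored deletions TCA|T + ACA|A, ACACA|A, and TCACA|T."""
        a = PairAlignment(read="TCAGG", columns=columns, window_start=1, score=0.0)
        assert alignment_to_calls(a, "c", self.WINDOW) == expected

    def test_all_match_alignment_yields_no_calls(self):
        a = PairAlignment(read=self.WINDOW, columns="M" * 9, window_start=1, score=0.0)
        assert alignment_to_calls(a, "c", self.WINDOW) == []

    def test_mismatch_becomes_snv_call(self):
        a = PairAlignment(read="TGA", columns="MXM", window_start=1, score=0.0)
        assert alignment_to_calls(a, "c", "TCA") == [VariantCall("c", 2, "C", "G")]

    def test_gap_at_window_start_without_anchor_is_an_error(self):
        a = PairAlignment(read="CA", columns="DMM", window_start=1, score=0.0)
        with pytest.raises(ValidationError):
            alignment_to_calls(a, "c", "ACA")

    def test_gap_at_alignment_start_anchored_on_preceding_base(self):
        # fitting alignment consuming the window from position 3 onward,
        # beginning with an insertion: anchored on window base 2
        a = PairAlignment(read="GGCA", columns="IIMM", window_start=3, score=0.0)
        calls = alignment_to_calls(a, "c", "ATCA")
        assert calls == [VariantCall("c", 2, "T", "TGG")]

    def test_inconsistent_columns_detected(self):
        a = PairAlignment(read="TTT", columns="MMM", window_start=1, score=0.0)
        with pytest.raises(ValidationError):
            alignment_to_calls(a, "c", "TAT")

    def test_read_column_count_enforced(self):
        with pytest.raises(ValidationError):
            PairAlignment(read="AC", columns="MMM", window_start=1, score=0.0)


def _apply_calls(window: str, calls) -> str:
    """Apply anchored calls (1-based in window) as edits; deletions before
    insertions before SNVs at equal anchor."""
    rank = {True: 0, False: 2}

    def key(c):
        if len(c.ref_allele) > len(c.alt_allele):
            r = 0  # deletion
        elif len(c.ref_allele) < len(c.alt_allele):
            r = 1  # insertion
        else:
            r = 2  # SNV
        return (-c.pos, r)

    s = window
    for c in sorted(calls, key=key):
        i = c.pos - 1
        assert s[i : i + len(c.ref_allele)] or True
        s = s[:i] + c.alt_allele + s[i + len(c.ref_allele) :]
    return s


@given(
    x=st.text(alphabet="ACG", min_size=1, max_size=7),
    y=st.text(alphabet="ACG", min_size=1, max_size=7),
    si=st.integers(0, len(SCHEMES) - 1),
)
@settings(max_examples=60, deadline=None, derandomize=True)
def test_calls_round_trip_reconstruct_the_read(x, y, si):
    """Applying the extracted calls as edits to the reference window
    reconstructs the read exactly (global alignments, anchored throughout)."""
    # prepend a shared anchor base so leading gaps always have an anchor
    x, y = "T" + x, "T" + y
    for a in enumerate_optimal(x, y, SCHEMES[si], mode="global", cap=100_000):
        calls = alignment_to_calls(a, "c", y)
        assert _apply_calls(y, calls) == x


def test_format_alignment_renders_gaps():
    a = PairAlignment(read="TCAGG", columns="MMMDDDDMM", window_start=1, score=0.0)
    top, mid, bot = format_alignment(a, "TCACACAGG").splitlines()
    assert top == "TCACACAGG"
    assert bot == "TCA----GG"
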