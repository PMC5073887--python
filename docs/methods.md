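# Methods

## The problem being modeled

A variant profile records an INDEL as one anchored `(pos, REF, ALT)` triple.
When the variant sits in or near a tandem repeat, a read carrying the
alternative allele can be aligned to the reference in several ways that score
identically; each placement of the gap implies a different anchored triple.
All of these representations describe the same physical variant and are
equally supported by the data, so the recorded one is an artifact of whichever
aligner (and tie-break) produced it. The package quantifies this at three
levels: enumeration of the co-optimal alignments, per-locus complexity, and a
profile-level agreement statistic.

## Alignment models

Two scoring models are implemented over column alphabets
match/mismatch/deletion/insertion:

* **Equal-penalty (linear) model.** Single matrix `M` with
  `M[i,j] = max(M[i-1,j-1] + match(x_i, y_j), M[i-1,j] + ε, M[i,j-1] + ε)`.
  Every gapped base costs the extension score ε regardless of context.
* **Affine-gap model** (three-matrix Gotoh form). `M` holds the overall best
  score; `X` and `Y` the best score for alignments ending in a read-gap or
  reference-gap column:
  `X[i,j] = max(M[i-1,j] + ρ + ε, X[i-1,j] + ε)`, symmetrically for `Y`,
  and `M[i,j] = max(M[i-1,j-1] + match, X[i,j], Y[i,j])`. A gap of length k
  costs ρ + k·ε, so one contiguous gap beats split gaps whenever ρ < 0.

Boundaries are gap-scored prefixes (`i·ε`, or `ρ + i·ε` in the affine model),
i.e. consistent with maximization throughout. Two geometries are supported:
**global** (both sequences consumed end to end) and **fitting** (default for
read-vs-window work: the read is consumed end to end, the window may overhang
on both sides at no cost). A fitting alignment by definition neither starts
nor ends with a reference-gap column — a free overhang subsumes those — which
also makes the enumeration's identity `(window offset, column string)`
unambiguous.

### Enumerating *all* optimal alignments

After the fill, traceback starts from every cell holding the optimum (the
single corner cell in global mode; every maximal last-row cell in fitting
mode) and follows **every** predecessor whose value reproduces the cell's
value — in the affine model the trace is matrix-tagged, so a gap can be
entered and extended along either the open-from-`M` or extend-within-`X`/`Y`
route. Ties are never broken: they are the object of study. Distinct traceback
routes that converge on the same column sequence (possible when ρ = 0 makes
open and extend coincide) are deduplicated. The number of co-optimal
alignments is capped (default 1000); exceeding the cap raises an explicit
overflow error rather than silently truncating, because a truncated set would
corrupt every downstream count.

Correctness is certified against an independent brute-force oracle that
enumerates every monotone column pattern of two short strings and scores it
from scratch: the enumerated set must equal the oracle's maximum-score set,
exhaustively for all pairs over {A,C} up to length 3 and on a seeded sample up
to length 8, under three schemes for both models and both geometries. (An
exhaustive sweep at length 8 would require scoring on the order of 10^11
pattern evaluations; the sampled property covers the same input space.)

### Scoring defaults

`match = +1, mismatch = −4, gap_open ρ = −6, gap_extend ε = −1` — bwa-like
ratios, chosen so that a contiguous gap is always preferred to split gaps and
to mismatch runs. The specific magnitudes are not critical for the package's
statements; what matters is the ordering, and every value is configurable
(`ρ = 0` selects the equal-penalty model). With these defaults, the optimal
affine alignments of an alt-bearing read around an isolated tandem-repeat
INDEL are exactly the contiguous placements of one gap — which is what makes
the generator's ground-truth counts (below) provable by a sliding-equality
argument rather than by the DP itself.

### From alignments to calls

Each maximal run of deletion columns becomes one anchored deletion call
(anchor = last reference base before the run), each maximal insertion run one
anchored insertion, each mismatch column one SNV. A gap run at the alignment
start is anchored on the reference base before the window start; if none
exists (window at position 1) this is an error rather than a silent
half-anchored call. Calls use 1-based, fully closed VCF-style coordinates;
the only 0-based conversion in the package happens at SAM ingestion.

## Read construction

For each locus and each alternative allele, reads `r = u·alt·v` are built
from symmetric reference flanks, with 10 distinct flank lengths evenly spaced
over [25, 50] bp — so a biallelic locus yields exactly 10 reads of length
|u| + |alt| + |v| (roughly 50–100 bp), a 10× coverage of the locus. Reads are
exact (no sequencing error): the question under study is tie-breaking among
mathematically equal alignments, and error would only add an orthogonal
nuisance term. Flank lengths are deterministic rather than sampled, keeping
every run reproducible without a seed; multi-allelic loci get 10 reads per
alt allele, treating each alt as its own alignment problem.

A read is **correctly mapped** when its mapped reference interval overlaps
the locus interval `[pos, pos + |REF| − 1]` by at least one base on the same
chromosome — mapping correctness and alignment agreement are deliberately
decoupled, since a read can be mapped correctly yet aligned to a different
co-optimal representation.

## Complexity

`n_i` is the number of optimal *affine* fitting alignments of the alt-bearing
read (symmetric 50 bp flanks) against the locus window (locus interval padded
by the same flank). Both models are counted and reported; for multi-allelic
loci the locus complexity is the maximum over alt alleles (the worst-case
ambiguity an aligner faces), with per-alt counts retained. Counting is over
distinct optimal alignments, not distinct resulting call sets, matching the
`p_i = 1/n_i` arithmetic of the agreement statistic. Windows containing `N`
are excluded and logged (match scoring for `N` is undefined here).
Complexity is invariant to the flank length once flanks exceed the repeat
context; the tests pin this at flanks 25 vs 50.

## Agreement statistic

Only loci with `n_i > 1` enter the analysis. Each correctly mapped read at
such a locus is a trial that succeeds when one of its extracted calls equals
the recorded `(pos, REF, ALT)` exactly. Under the null hypothesis that an
aligner picks uniformly among the `n_i` co-optimal alignments, the success
probability of a trial is `1/n_i`, giving

* μ = Σ 1/n_i, σ² = Σ (1/n_i)(1 − 1/n_i) over the N analyzed trials,
* λ = X − μ for the observed agreement count X,
* Chebyshev–Cantelli bound p ≤ σ² / (σ² + λ²).

λ is kept in count units (the inequality concerns the random variable X);
percentages are derived for display. The bound depends on λ only through λ²,
and it is reported for deviations of either sign: an aligner agreeing far
*below* expectation is exactly as incompatible with random tie-breaking as
one far above it — it is simply following the opposite convention — and the
summary carries an explicit below-expectation flag alongside. When λ = 0 (or
the null is degenerate with σ² = 0) the trivial bound 1 is reported and
flagged.

Trials default to reads (consistent with the 10× design). A loci-as-trials
grouping is exposed as an option, counting each locus once with success when
any of its correctly mapped reads agrees; since the simulated policies are
deterministic in the alignment problem, reads of one locus almost always
agree or disagree together and the two groupings give the same qualitative
picture.

### Idealized aligner policies

Rather than running external aligners, three pick policies stand in for them:
`leftmost` and `rightmost` place the gap at the smallest / largest genomic
coordinate among the co-optimal alignments (the two deterministic conventions
real aligners effectively implement), and `uniform` draws uniformly at random
(seeded) — the null model itself. External aligner output can be scored
through the same machinery by ingesting SAM; reverse-strand records need no
special handling because SAM stores the sequence in reference orientation.

## Synthetic data

The generator emulates the *structure* of a real study — a multi-chromosome
reference plus an INDEL profile whose recorded representation follows a
convention — with full ground truth:

* **Background**: seeded i.i.d. uniform {A,C,G,T}.
* **Ambiguous loci**: an INDEL whose allele is one unit of an embedded tandem
  repeat (unit length L, copy number c). Deleting one unit admits
  (c−1)·L + 1 contiguous gap placements; inserting one admits c·L + 1. The
  bases flanking the repeat are chosen to break any accidental extension, so
  these counts are exact; the generator additionally verifies each locus's
  equivalent-representation set by a sliding-equality check that is
  independent of the alignment DP, and records the full set.
* **Unambiguous loci**: an indel in repeat-free context, rejection-sampled
  until the sliding check certifies a unique representation.
* **Recording convention**: `leftmost` (the smallest-position member of the
  equivalent set — standard left-normalized VCF), `rightmost`, or `uniform`.
* **Spacing**: at least 2 × flank_max + margin between loci, so no read spans
  two loci; requesting more loci than fit is a capacity error.
* **Regime**: the per-locus target complexity is drawn from a pool with mode
  3 (defaults `(2,3,3,3,4,5)`), placing the modal ambiguous complexity at
  three co-optimal alignments; defaults are 2 chromosomes × 60 kb, 100 loci,
  30 % ambiguous.

What the generator does **not** emulate: sequencing error and quality
models, SNV linkage, allele frequencies, coverage variation, paired ends,
and the long-range repeat structure of real genomes. Tests passing on this
data therefore certify the algorithmic claims (enumeration correctness,
complexity counting, the agreement statistic and its null calibration) — not
aligner robustness to noisy reads, which is outside the package's scope.

## Problem sizes and numerical choices

The statistical checks run at 100 ambiguous loci × 10 reads (N = 1000
trials), large enough that the dichotomy bounds (agreement ≥ 95 % with
p-bound < 0.01 for the matching convention; the mirrored regime for the
opposite one) and the ±3σ null-recovery band are comfortably decided, and
small enough to run in seconds. Scores are exact (integer-valued floats), so
tie detection uses exact equality; no tolerance is involved anywhere in the
DP. Degenerate inputs are rejected early: empty sequences, non-ACGTN
references, unanchored records at a chromosome start, flank ranges too narrow
for the requested number of distinct lengths.

## Known limitations

* Complexity counts depend on the scoring scheme; a profile computed under
  one scheme is not comparable to one computed under another. Genome-scale
  counts from real data are inherently parameter-sensitive for the same
  reason.
* The enumeration is exact but exponential in the worst case (long
  homopolymers under the equal-penalty model); the cap turns pathological
  loci into explicit errors, and the per-locus tallies report them.
* The fitting geometry assumes the read belongs at the window; it does not
  model mapping ambiguity across distant repeat copies (a mapping, not an
  alignment, problem).
* Multi-allelic loci are analyzed per alt allele; interactions between
  overlapping variants are not modeled.
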