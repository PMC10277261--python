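# Methods

## Data model and conventions

A pairwise divergence time is the age, in millions of years (MY), of the
most recent common ancestor (MRCA) of two species, reported as the median
(or adjusted median) over published studies. Records travel in two
shapes:

- the **vectorized table** — rows of (taxon A, taxon B, time, optional CI
  bounds and study count). The default export is the *full* ordered form:
  all n² ordered pairs including self-pairs at time 0, matching how batch
  retrieval naturally iterates; an *unordered* form with n(n−1)/2 rows is
  available for economy.
- the **divergence matrix** — square, symmetric, nonnegative, zero
  diagonal, labels in first-appearance order of the user's species list
  (not alphabetical), so output is stable against the input file.

A missing time is a first-class value (`None`; an empty CSV field; the
strings "NA"/"n. a" are accepted on read, mapping to 0 for a self-pair's
time and to missing elsewhere). Unresolved retrievals therefore never
abort a batch run; they surface afterwards through `find_missing` and can
be re-queried with `repair_missing`. A median is deliberately *not*
constrained to lie inside its CI, since medians and study ranges are
reported independently upstream.

When a full table carries both orderings of a pair they must agree within
a tolerance, default **0.05 MY** (upstream data are printed to one
decimal); the ordering whose first taxon appears earlier in the species
list wins. Duplicate species in an input list are dropped with a warning
rather than an error, which keeps long batch lists usable.

## Matrix ↔ tree conventions

Matrix entries are **MRCA ages**, not total tip-to-tip path lengths:
cophenetic conventions differ by a factor of two, and the age convention
is the one under which the crown age of a clade equals the maximum matrix
entry. Ultrametricity is judged by the spread of root-to-tip depths,
default tolerance **0.01 MY** absolute (matching the 0.1-MY print
precision of the data; simulated fixtures satisfy 1e-9).

Reconstruction of a tree from a matrix uses average-linkage agglomeration
(UPGMA), with the merge height equal to the average divergence between
the merged clusters — exact on any matrix satisfying the ultrametric
three-point condition (for every triple, the two largest pairwise
distances agree; checked before reconstruction, default tolerance 1e-6,
violations reported with the worst triple). Ties are broken by merging
the pair whose sorted member labels are lexicographically smallest, so
reconstruction is deterministic. Internal nodes are left unlabelled.
Trees are treated as rooted throughout; there are no rerooting utilities.

## Diversification-rate estimators

Only crown-age estimators are provided. With `n` extant species and crown
age `Δt`:

    r = (ln n − ln 2)/Δt

and with extinction ratio ε = μ/λ ∈ [0, 1):

    r = (1/Δt)(ln[n(1−ε²)/2 + 2ε + (1−ε)/2 · √(n(nε² − 8ε + 2nε + n))] − ln 2)

**The logarithm is natural.** This is the single most consequential
reading choice: ln(12/2)/4.73 ≈ 0.379 and ln(11/2)/9 ≈ 0.189 round to
the conventional printed values 0.38 and 0.19, whereas base-10 logs would
give 0.16 and 0.08. The reduction of the ε-form to the simple form at
ε = 0 is algebraic (the radicand becomes n², the bracket becomes n) and
is property-tested to 1e-12 relative; the ε-form is checked against a
50-digit symbolic evaluation at random valid points to 1e-10. On the
valid domain the radicand is positive; ε ≥ 1 is rejected (at ε = 1 the
log argument degenerates to 2 and the estimator is undefined). Internal
values are full precision; rounding to 2 decimal places happens only at
presentation. `rate_from_clade` takes Δt from an ultrametric tree's crown
height and lets the user supply a larger known richness than the tree's
tip count, because retrieved trees routinely undersample a clade.

No confidence intervals, rate-shift detection, or likelihood birth–death
fitting are attempted; those belong to dedicated diversification
software.

## Mantel test and correlogram

The Mantel statistic is the Pearson correlation over upper-triangle
entries; the null permutes rows and columns of the second matrix
simultaneously (the first matrix stays fixed — the standard scheme). The
p-value uses the plus-one rule, p = (#{|r*| ≥ |r|} + 1)/(B + 1), so it is
never exactly zero, and the test is two-sided on |r| by default (the
upstream use reports significance stars without stating sidedness;
one-sided options are provided). Default B = 999 permutations.

For n ≤ 7 labels, `mantel_exact` enumerates all n! label permutations
and reports the exact fraction at least as extreme (identity included);
it serves as the oracle for the Monte-Carlo test and is checked to agree
within three Monte-Carlo standard errors at 99,999 permutations.

The correlogram recomputes the Mantel statistic per divergence-time
class against the 0/1 class-membership indicator, with the same
permutation scheme (each class uses a distinct seeded stream). Classes
default to equal-width bins over (0, max time] by Sturges' rule on the
pair count; classes with fewer than 3 pairs are flagged untestable rather
than tested, and a class capturing *all* pairs makes the indicator
constant, which is reported as the zero-variance error it is.

## Synthetic data

The fixture backend packages a published-style four-species full table
(off-diagonal medians 70.0, 27.6, 80.0 MY; CIs 64.5–80.0, 25.4–38.1,
73.7–97.3; study counts 16, 5, 3), one worked pair (Swainson's thrush ×
Superb fairywren, 35 MYA), and two synthetic genus trees with fixed tip
counts and crown ages (12 tips / 4.73 MY; 11 tips / 9.0 MY — the
thrush-like crown span is quoted both as 4.73 and 4.74 in its source;
4.73 is adopted, and both round to the same rate). The genus trees are
simulated, not retrieved: a **pure-birth (Yule)** process starting from
the crown split, with uniformly chosen splitting lineages and exponential
waiting times, rescaled so the root height hits the target crown age
exactly. Pure birth suffices because the fixtures only need ultrametric
structure with a fixed crown age — extinction enters the toolkit
analytically through ε, not through the simulator. Tip labels are real
congener binomials so availability and tree queries behave like a live
resource, but node ages and topology are synthetic (filenames carry
`_synthetic`); a green test against these fixtures establishes that the
pipeline's algebra, I/O and bookkeeping are correct, not that any real
clade has the simulated node ages. Within-genus pair queries are answered
from the packaged trees, so tree and pairwise answers agree by
construction. The backend does not model how a live resource would choose
a "similar species" substitute — substitution is recorded, not invented.

A self-pair query for a species the backend does not know is treated as
unresolved rather than answered 0: the backend cannot vouch for a name it
has never seen, and this keeps availability and divergence answers
consistent.

Fixtures regenerate bit-identically via `scripts/make_fixtures.py`
(fixed seeds 1201 and 1101).

## Known limitations

- The live web client is a documented contract only (polite-client
  defaults: ≥1 s between requests, 3 retries with backoff); no HTML
  parsing or network I/O exists in this build, so behaviours specific to
  the live resource (name substitution heuristics, adjusted-median
  selection) are out of reach of the test suite.
- Timeline "figures" from the fixture backend are schematic placeholder
  JPEGs embedding the species name, not reproductions of real timelines.
- Correlogram significance on real 40-species F_ST data, external
  speciation/extinction-through-time analyses, and wall-clock/memory
  benchmarking of live retrieval are out of scope and not reproduced
  here.
- No fuzzy taxon-name resolution or synonym lookup is attempted; names
  are normalized (whitespace, underscores) and matched exactly, with
  common-name aliases only for the four packaged species.
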