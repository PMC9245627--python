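# Methods

## The problem

Phased haplotype panels are binary M x N matrices whose rows are shaped by
genealogy: haplotypes that descend from a recent common ancestor are
identical over long stretches (identity by descent, IBD). Exact-matching
machinery such as the positional Burrows-Wheeler transform (PBWT) exploits
this to find shared segments in O(MN) time — but a single genotyping error
(typical array/sequencing rates are 0.1-0.5% per genotype) cuts an exact
match in two, fragmenting long matches and making multiway match blocks
all but undetectable. `hapsmooth` *actively corrects* such mismatches
before matching, instead of passively tolerating them.

## The smoothing model

For haplotype i at site k, consider the haplotypes identical to i over the
L sites on each side of a g-site gap containing k: the left one-sided
block, the right one-sided block, and their intersection, the
**bidirectional block** B. Members of B are plausibly IBD with i through
site k (requiring both flanks filters out one-sided chance matches), so
their alleles at k are a reference set for what i's allele *should* be.
The prior is deliberately rule-based rather than probabilistic: an
observed allele b is implausible iff the reference set is large enough
(|R| >= W) and the in-block frequency of b is below a threshold
(AF(b) < rho). The smoothing pass applies the operational form of this
rule blockwise: for each gap site of each bidirectional block of width
>= W, if the minor-allele count satisfies 0 < min(zeros, ones) <= |B|*rho,
every minority member is set to the majority allele.

Two deliberate asymmetries in the rule:

* **Non-strict threshold** (`min <= |B|*rho`) is the default because it is
  the most operational statement of the rule; the strict variant
  (`< |B|*rho`, matching the AF(b) < rho form) is exposed as
  `strict_maf=True`. The two differ only when |B|*rho is attained exactly.
* **Zero-minor-allele sites** are untouched (nothing to correct), and ties
  (zeros == ones) can never qualify for rho < 0.5, so no tie-break rule is
  needed; rho is validated to (0, 0.5).

### Parameters

| name | units | default | role |
|------|-------|---------|------|
| L    | sites | 20 | flank length; longer flanks = stronger IBD evidence, fewer blocks |
| W    | haplotypes | 20 | minimum block width; the evidence sample size (set to the target cluster width for cluster calling) |
| g    | sites | 1  | gap width; sites eligible for correction per anchor |
| rho  | fraction | 0.05 | in-block minor-allele-frequency ceiling for a correction |

With the defaults, a block must have at least 20 members before a
singleton mismatch (MAF 1/|B| <= 0.05) is corrected — the algebraic reason
narrow panels see few corrections.

## The scan

One reverse PBWT pass assigns every haplotype a reverse block ID at every
site (runs of the positional prefix array whose divergence values reach
back L sites, filtered to width >= W); the table is held in memory
(int32, N x M) or spilled to a temporary memory map. The forward pass then
maintains a single PBWT column; at each anchor k it forms forward block
IDs the same way, sorts haplotypes on the (forward, reverse-at-k+g) ID
pair (haplotypes outside any qualifying block carry unique negative
sentinels so they can never co-group), and every (pair)-group of width
>= W is a bidirectional block whose gap sites [k, k+g) get the correction
rule, vectorized across blocks. Corrections are applied before the forward
PBWT consumes the corrected column, so a repaired mismatch immediately
lengthens downstream forward matches (single-pass semantics); the reverse
table is fixed from the original panel. A `frozen_input` mode keeps the
forward PBWT on the original panel for ablation. Sites within L of the
left end and within L+g-1 of the right end are never corrected — they lack
one flank — and panels shorter than 2L+g are returned unchanged with a
warning.

Complexities: O(MN) time (each of the two passes does O(M) work per
site); beyond the panel and the reverse table, working state is the PBWT
column plus the gap buffer, O(gM).

Because blocks at one anchor are disjoint and a corrected gap site is
stable (its minority count is 0 or above |B|*rho afterwards), application
order within an anchor is irrelevant; across anchors the scan is fixed
left-to-right, making output deterministic. Determinism everywhere else
comes from stable sorting (ties keep prior order) and fixed sort-key
order (forward ID major, reverse ID minor).

## Cluster calling

A multiway IBD cluster is a maximal match block: a set of haplotypes
identical over [start, end), where the set is complete for the interval
and no one-site extension preserves it. Nested blocks (wider, shorter)
are separately reported when themselves maximal. Enumeration works per
PBWT column with a monotone stack over the divergence array, emitting
each candidate (interval, run) pair exactly once in O(M) amortized per
column; right-maximality is checked against the next allele column. The
caller also understands a ternary alphabet in which -1 matches nothing
(not even another -1) — used for ground-truth extraction (below).
Cluster length is measured as `cm[end-1] - cm[start]`, the genetic span
of the matched sites, consistent with the pairwise-match convention.

Smooth-then-cluster (`ps_cluster`) runs the smoothing scan and feeds each
column to the cluster scanner as soon as it is final (the last anchor
whose gap covers site k is k itself), so the fused single pass provably
equals the sequential composition; both paths are exposed and tested for
identity. Smoothing width W defaults to the target cluster width.

## Synthetic data and ground truth

The coalescent generator emulates the benchmarking conditions used
throughout: 4000 haplotypes over a 10 Mb region (flat 1e-8 recombination
and mutation, so 1 cM = 1 Mb), a hand-coded Tennessen-style European size
history (ancestral 7,310; 14,474 from 5,920 generations ago; bottleneck
1,861 from 2,040; 0.307%/generation growth from 920; 1.95%/generation
growth from 205 to ~512k today), and removal of sites with MAF < 0.1 —
smoothing and cluster calling operate on common variants, where haplotype
sharing is blocky. Binary mutations keep sites biallelic under recurrence.

**Error model.** Errors are injected per *genotype*-site cell: each of the
(M/2) x N cells is hit independently with the configured rate and one
uniformly chosen allele of that individual flips. The published error
counts at M=4000, N=47,821 match the expectation rate x (M/2) x N at all
three rates, and are inconsistent (2x) with a per-haplotype model; the
test suite pins this calibration.

**Ground-truth pairwise IBD** is read off the tree sequence. Two
extraction modes exist because "IBD" needs a convention:

* `horizon` (default): all tracts on which a pair's most recent common
  ancestor is younger than `ibd_horizon_gens` (default 300 generations,
  ~7,500 years — within the recent expansion epoch). Under a time
  horizon, pairwise relatedness at a site is an ultrametric, so the
  per-site sharing classes are clades and multiway ground truth is
  well-defined and abundant.
* `span`: all same-ancestor tracts of genetic length >= `min_segment_cm`.
  Because a tract of genetic length x requires a common ancestor within
  roughly 50/x generations, span-based truth at >= 1 cM demands near-
  contemporary ancestry; under growth demographies such pairs are so rare
  that multiway truth at realistic widths is essentially empty. The mode
  is retained for pairwise-segment experiments.

**Interim panel.** Multiway truth is distilled from pairwise tracts
exactly as the evaluation framework prescribes: a {-1,0,1} panel starts
all-sentinel; iterating segments in input order and sites left-to-right,
an unset pair is seeded with a random bit, a half-set pair copies the set
value, and a fully-set conflicting pair is left unchanged (conflicts are
possible because pairwise IBD is not transitive at a fixed site; under
horizon extraction they are rare). Running the ternary cluster caller on
this panel — where -1 matches nothing — yields the ground-truth clusters.
The random seeding means interim *values* vary by seed but the equality
structure is driven by the segments.

**Copy-group fixtures.** For download-free deterministic tests, groups of
exact haplotype copies over planted intervals sit on independent
Bernoulli(1/2) backgrounds; the planted clusters are ground truth by
construction, and isolated planted flips are guaranteed corrected when the
group width is >= W and the flip is >= L sites from the panel ends.

## Metrics

Cluster area = width x number of sites; overlap = shared haplotypes x
shared sites. Power of a truth cluster = (max overlap with any reported
cluster)/its area, averaged over truth; accuracy of a reported cluster =
(max overlap with any truth cluster)/its area, averaged over reported.
Degenerate denominators (no truth / nothing reported; zero injected
errors / zero corrections) are reported as NA, never as 0. An injected
error counts as corrected only if the correction restores the pre-error
allele. Pairwise-segment metrics reuse the same construction on width-2
objects restricted to identical pairs.

## What passing tests do and do not show

The simulation reproduces the error-correction operating point closely
(recall ~84% and precision ~80% at a 0.2% error rate with default
parameters) and the qualitative cluster result decisively: at 0.2% error,
plain cluster calling retains under half of the truth-cluster power that
smooth-then-cluster keeps. Absolute cluster power/accuracy values depend
on the ground-truth horizon: with the 300-generation default, power at
(1 cM, 10) saturates near 97% — higher than an extraction with a more
generous horizon would give — and accuracy at small cluster counts is
noisy across seeds. The generator models neither phasing errors nor
genotyping-error clustering along the genome (errors are independent
cells), and real panels carry recent/private mutations that are
indistinguishable from errors — on real data a fraction of "nonerror"
corrections are mutations, so measured precision is a lower bound on
mismatch-removal precision.

## Numerical and degenerate-input choices

The threshold comparison `min <= |B|*rho` is evaluated in floating point;
|B|*rho is exact for the defaults and off by at most one ulp otherwise.
cM thresholds use plain `>=` comparisons. Genetic-map interpolation is
piecewise linear with constant extrapolation beyond the anchors; when no
map is supplied, matrix panels default to zero genetic length and
cM-denominated operations refuse to run rather than invent distances.
Empty panels, unphased/multiallelic/missing VCF genotypes, ragged matrix
rows and out-of-range truth segments are hard errors naming the offending
record or line.

## Known limitations

Single chromosome per run; diploid phased input only; no BCF/tabix, no
run-length PBWT compression, no set-maximal query mode; the prior is not
applied to imputation of unobserved genotypes; errors and true mutations
are not distinguished (corrections of rare mutations are deliberate for
the matching objective); biobank-scale disk-streaming of the reverse
PBWT beyond the simple memory-map spill is not implemented.
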