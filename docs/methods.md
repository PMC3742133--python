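# Methods

## The model

The package operationalizes a predictive promoter model for HMX1: a
promoter is a predicted target when the window spanning `upstream` bases
before and `downstream` bases after its transcription start site (defaults
250 and 200; the TSS base is `+1`, signed coordinates skip 0) contains at
least `min_pairs` (default 1) admissible homotypic binding-site pairs.

A *site* is an exact occurrence of the canonical hexamer (`CAAGTG` or its
reverse complement `CACTTG`) or of the minimal core (`CAAG`/`CTTG`).
Matching is case-insensitive and `N` never matches, so soft-masked or
gap-containing genomes are handled without special cases. No weight-matrix
scanning is offered: no PWM exists for HMX1, and the model is defined on
exact motifs.

A *pair* is admissible when the start-to-start distance between two
non-overlapping sites lies in `[min_distance, max_distance]` (defaults 90
and 190 nt). Orientation is deliberately ignored. Three tiers relax the
site strength required of the members:

| tier | members |
|---|---|
| PPM | two canonical sites |
| LS-PPM | at least one canonical site, the other canonical or core |
| VLS-PPM | any two sites |

Because a core embedded inside a canonical site is the same physical site,
the site universe of a window is the canonical hits plus only those core
hits that do not overlap any canonical span; one piece of DNA never counts
as two pair members. Under this hierarchy the qualifying pair sets nest
(PPM ⊆ LS ⊆ VLS), so tier fits are monotone — the property that makes the
tiered sensitivity/specificity table interpretable. An alternative literal
reading ("exactly one canonical plus one standalone core") breaks that
monotonicity for windows with two canonical sites and was rejected for that
reason.

### Distance measure

"Spacing" between motifs of unequal length is ambiguous. The default is
start-to-start (5′-most base to 5′-most base): it is well defined across
the 6-nt and 4-nt motifs, it makes tier relaxation distance-preserving (a
canonical pair is a core-strength pair at the identical distance), and it
reproduces the published combination maxima (3 pairs from 3 sites, 5 from
4). The end-to-start gap measure is available via
`PairConstraint(measure="gap")` for sensitivity analysis; note that
examples computed under one measure do not transfer to the other (a
96/96/96 start-gap cluster yields 5 pairs under the gap measure but 3 under
start-to-start, whose maximal 4-site cluster uses 95-nt steps).

### Pair-combination maxima

`max_simultaneous_pairs(k)` answers: over all placements of *k*
non-overlapping sites in the window, how many pairs can be admissible at
once? Brute force over placements is infeasible for k = 4 in a 450-nt
window, so the search is exhaustive over subsets of the C(k,2) candidate
pairs in decreasing size, testing each subset's realizability as a system
of difference constraints on the site starts (pairwise bounds, non-overlap
separation, total span) with Bellman–Ford. Any placement realizes exactly
the pair set of its admissible pairs, and any feasible integer
difference-constraint system has an integer solution, so the first feasible
subset size is the exact maximum; a witness placement is recovered from the
shortest-path potentials. The unit tests cross-check this against full
brute force on small windows.

## Statistics

* **Fold enrichment** between training sets is the ratio of fitting-gene
  proportions; a zero negative count reports infinity with a flag rather
  than raising.
* **Fisher's exact test** (two-sided) sums hypergeometric point
  probabilities not exceeding the observed one, with a 10⁻⁷ relative
  tolerance for ties; a zero margin gives p = 1. The scipy implementation
  is used only as an independent oracle in tests.
* **Sensitivity/specificity CIs** are exact Clopper–Pearson intervals
  computed from beta quantiles (lower solves P(X ≥ k) = α/2, upper
  P(X ≤ k) = α/2). For 3/30 this gives 2.11–26.53%; tools that apply
  additional rounding conventions report 2.2–26.6%, a ≤ 0.1-point
  difference that is documented rather than emulated.
* **Pathway over-representation** uses the χ² statistic with Yates
  continuity correction, Σ(|O−E|−0.5)²/E with the correction floored at
  zero when |O−E| < 0.5, against a 25,504-gene universe by default; zero
  expected cells raise an error advising the exact test.
* **Displayed percentages and folds** are rounded half-up to one decimal
  from exact count ratios (so 1991/2000 renders 99.6%, 1707/2000 renders
  85.4%); raw values are retained alongside.

## Gene-level semantics

All alternative promoters of a gene are screened; windows identical in
(gene, sequence) — redundancy from alternative splicing — are merged first.
A gene fits a tier if *any* of its windows fits. Screen hits report the
best window (most admissible pairs, then most canonical sites, then
lexicographically first transcript id). Conservation crossing requires only
that both orthologs fit in their own species — positions and orientations
are not compared — and co-occurrence selection keeps genes with ≥ 3
canonical sites forming ≥ 2 admissible pairs (both thresholds
configurable), ranked by pair count, then site count, then symbol.

## Synthetic data: what it emulates, what it does not

The generators produce one contig per gene with the window embedded between
random flanks on a random strand, so extraction and orientation logic is
exercised end to end. Planted structure is exact by construction: planted
windows are drawn canonical-free first, the pair (or multi-site cluster) is
written in, and placements that would create or destroy canonical sites
beyond the plant are rejected and resampled; truth tables therefore list
every canonical site present. Chance core sites are allowed and only affect
the relaxed tiers, mirroring the core motif's weak specificity. For
planted-truth recovery experiments the background windows are additionally
rejected if they fit the strict tier (`clean_background`), which makes the
recovery assertions exact for any seed.

Background sequence is iid (uniform by default; a ~42%-GC genomic-like
preset and an optional first-order Markov chain are provided). Real
promoter sequence is neither iid nor composition-homogeneous, so the
synthetic false-positive rate of the strict tier (~0.6% on genomic-like
backgrounds) brackets but does not equal the ~0.45% observed on real random
promoters; passing tests demonstrate the pipeline's correctness on data
with known truth, not the field performance of the model on real genomes.
The DE-table generator assigns FDR values to match a configured
stratification (defaults: 146 genes < 0.1, 70 up and 76 down; 30 genes
< 0.01, 14 up and 16 down; 3 of the 30 carrying a planted pair) — it does
not simulate intensities or moderated statistics. Negative training sets
are sampled excluding positive genes; at realistic scales (30 positives in
a 25,504-gene universe) this exclusion is numerically irrelevant but avoids
label contamination.

Default problem sizes (2,500-gene validation universe, 600-gene species
pairs, 10,000-window null estimates, 20-replicate recovery) were chosen so
each analysis completes in seconds while keeping binomial noise well inside
the assertion margins.

## Fold-recovery check

The end-to-end recovery experiment plants a 10% positive rate (3 of 30
positive-set promoters) against 2,000-window random negative sets and asks
whether validation recovers the planted rate ratio
(s + (1−s)·b)/b, where b is the background fitting rate estimated from a
10,000-window null. Because a single replicate's exact 95% interval misses
the truth a few percent of the time, per-replicate assertions across 20
replicates would fail spuriously for many seeds; the check instead pools
counts over the 20 replicates and requires the conservative
Clopper–Pearson ratio interval of the pooled fold to contain the planted
ratio — a coverage test that is stable for arbitrary seeds.

## Known limitations

* Exact-match scanning only; degenerate or mismatched sites are invisible
  to the model by design.
* The window is promoter-proximal; intronic or distal enhancer clusters are
  only reachable by supplying custom windows.
* Published genome-wide gene lists depend on the annotation snapshot used
  to build them and are not reproduction targets; the genome-wide stages
  are validated against planted synthetic truth instead.
* The `[-250, +250]` vs `[-250, +200]` ambiguity in the model's provenance
  is resolved in favour of `[-250, +200]`; both bounds are configurable and
  every report embeds the window actually used.
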