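# Methods

## Depletion classification

Expression of a circRNA candidate in a sample is its BSJ read count per
million raw reads (RPM); raw per-sample totals are supplied in metadata
and used as denominators unchanged (if the user deduplicated reads,
they supply post-deduplication totals — deduplication itself is out of
scope).  For each mock/treated pair, candidates with at least 2 mock
BSJ reads are classified by the treat/mock RPM ratio: ratio ≥ 1 →
not-depleted, ratio < 1 → depleted; candidates with fewer mock reads
are excluded.  The boundary is exact — a ratio of exactly 1 is
not-depleted and no epsilon is applied.  A sample pair is considered
adequate when more than 600 candidates are detected in the mock sample
and more than one third of them are also detected in the treated
sample; the pipeline reports this rule per pair and, by default,
continues with a warning when it fails (small demonstrations cannot
reach 600 candidates), with `enforce_inclusion` making it fatal.

## BSJ read assignment

Each candidate is represented by a pseudo-sequence: the 50 exonic-strand
nucleotides ending at the donor site concatenated with the 50 starting
at the acceptor site (truncated flanks shorten the sequence and shift
the junction index; a warning is emitted).  A read supports a BSJ when
its best local alignment to the pseudo-sequence covers at least 80 % of
the pseudo-sequence length and extends at least 10 nt into both sides
of the junction.  The coverage phrasing is ambiguous between alignment
coverage and identity, so both are exposed: coverage ≥ `min_cover_frac`
(default 0.8) of the pseudo-sequence plus per-column identity ≥
`min_identity` (default 0.95).  Reverse-complement reads are accepted by
default (unstranded libraries); a `check_revcomp=False` mode disables
it.  A read matching several pseudo-sequences counts for all of them by
default; `unique_assignment` drops multi-assigned reads instead.

Alignment is a built-in Smith–Waterman (match +1, mismatch −1, gap −2,
configurable), run after two cheap filters: an exact-substring fast
path, and a shared-k-mer prefilter (12-mers; with the default criteria
any countable alignment must contain an exact run ≥ 16 nt, so the
prefilter cannot lose a countable read).  Before pseudo-sequence
matching, reads that match the linear genome exactly on either strand
are removed (`exclude_linear`, on by default), mirroring the use of
genome-unmapped reads only; raw totals remain the RPM denominators.
The DP core is JIT-compiled with numba when available, with a
pure-numpy fallback.

The ambiguity screen is a seed-and-verify reimplementation of the
concept of removing candidates whose pseudo-sequence has a colinear
explanation: a candidate is flagged when (a) the full pseudo-sequence
aligns to one contiguous genomic window (at most twice its length) or
to an annotated transcript's spliced sequence at ≥ 90 % identity over
≥ 80 % of its length, or (b) either 50-nt half matches two or more
distinct genomic loci at ≥ 90 % identity over ≥ 90 % of the half.
Flagged candidates are dropped before all downstream statistics.

## Factors

* **Identification** — per-pair BSJ read count (`f1`); detection by ≥ 2
  tools (`f2`, from the `n_tools` input column); full-length evidence
  (`f3`); all passthrough metadata except `f1`.
* **Conservation** — number of samples (`f4`), tissues, species
  (passthrough); mean conservation score over four 10-nt windows just
  inside/outside the acceptor and donor (strand-aware; missing bases
  skipped and coverage reported).
* **Biogenesis** — donor/acceptor boundaries matching annotated exon
  ends/starts of any transcript at the locus (`f5` = both), a single
  transcript carrying both boundaries (`f6`), alternative splicing of
  both sites (`f7`), reverse-complementary sequence (RCS) counts, and
  CLIP RBP sites within ±1,000 nt of either BSJ coordinate with the
  minimum site-to-junction distance.
* **Function** — junction-spanning predicted sites (G-quadruplex ≥ 5 nt
  on both sides, miRNA ≥ 5 nt, RBP ≥ 2 nt) and the count of nine
  functional features (`f8`): seven coding-potential evidence types
  plus the miRNA- and RBP-span flags; missing flags count as false.
* **Supporting-factor count** — how many of {multi-tool, full-length,
  n_samples ≥ 3, both annotated, same isoform, both AS, functional
  features ≥ 3} hold (0–7); the count cutoff of 3 is configurable.

Alternative splicing is never formally defined by annotation alone, so
two minimal annotation-only rules are used, each of which can be
disabled: a site is AS if (a) it pairs with two or more distinct intron
partner sites across a gene's transcripts, or (b) it is a boundary in
one transcript but unused in another transcript of the same gene whose
span covers it.  The rules are evaluated gene by gene, so an
overlapping neighbour gene cannot make a constitutive site look
alternative, while boundary/same-isoform matching considers all
transcripts at the locus.

RCS detection counts maximal exact reverse-complement match pairs of
length ≥ `min_len` (default 30, an Alu-core-scale approximation)
between the two ±20,000-nt flanks (`rcs_across`) and within each
individual flank (`rcs_within`, summed over the two flanks by default,
`max` selectable; self-reverse-palindromic segments are not pairs and
are excluded).  Anchoring uses 64-bit rolling hashes with every anchor
verified by direct string comparison, so hash collisions cannot create
matches; the exact-match contract is what makes the brute-force oracle
comparison in the tests meaningful.

Splice-site strength and the tissue-specificity index are passthrough
input columns (external tools produce them); a minimal G-quadruplex
detector (four runs of ≥ 2 G, loops ≤ 36 nt, span ≤ 30 nt, presence
only) is available when no site table is given.  Missing optional
inputs leave the corresponding factor columns missing; candidates drop
only from analyses that use the missing factor (pairwise deletion),
except in the GLM, which deletes listwise so full and reduced models
share rows.

## Statistics

Binary factors: two-tailed Fisher exact test on the
factor × depletion-class 2×2 table; the odds ratio is the sample
cross-product a·d/(b·c), with Haldane's +0.5 applied only to report a
finite OR when a cell is zero (flagged; the p-value is always the
uncorrected exact test), and a Woolf logit 95 % CI.  Quantitative
factors: one-sided Wilcoxon rank-sum test — exact enumeration when both
groups are ≤ 25 and tie-free, otherwise the tie-corrected normal
approximation with 0.5 continuity correction — with effect size
r = |Z|/√N and a seeded percentile-bootstrap 95 % CI (1,000 replicates
by default).  All-tied data yield a one-sided p of 0.5, r = 0 and a
warning.  P-values are Benjamini–Hochberg adjusted within each factor's
family of tests across sample pairs (a global family is selectable).  A
factor is *important* when it is FDR-significant with a consistent
direction in every analyzed pair.  Trend tables report the percentage
of not-depleted candidates per factor level with both Spearman (levels
are ordinal bins) and Pearson correlations.  External label sets
(validated circRNAs, database-specific candidates, multi-replicate
detections) reuse the same Fisher machinery with per-class membership
percentages, and the supporting-factor stratification reports the
labeled percentage at each factor count (exact and cumulative).

## GLM and RCVE

The response is y = 1 for not-depleted, 0 for depleted.  The full
logistic model with intercept is fit by maximum likelihood
(statsmodels GLM/IRLS); perfect separation triggers a small-ridge refit
(α = 1e-4, flagged in the diagnostics).  For each factor the reduced
model is refit on the identical rows and

RCVE = (r²_all − r²_reduced) / r²_all.

McFadden's pseudo-r² (1 − ll/ll₀) is the default because nesting then
guarantees RCVE ∈ [0, 1]; Cox–Snell, Nagelkerke and Tjur definitions
are selectable.  Tiny negative RCVE values from convergence noise are
clipped to 0 with a diagnostic.  Numeric factors enter untransformed by
default.  Factors are ranked per pair by RCVE rounded to 8 decimals
(so numerically equal factors tie and receive mid-ranks) and averaged
across pairs.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
not real sequence biology.  A random-nucleotide genome carries
single-isoform genes, exon-skipping genes, alternative-donor/acceptor
genes (the second isoform shifts both ends of an internal exon) and
interleaved companion genes (one exon inside each host intron, same
strand), so every boundary/isoform/AS flag combination has realizable
coordinates: skipped-exon circles give same-isoform AS-positive cases,
cross-isoform pairs give annotated sites with no shared transcript,
and host/companion cross-gene pairs give annotated, isoform-disjoint,
constitutive cases.  Candidate truth labels fill exact quotas; factor
values are drawn class-conditionally so each factor's implied logistic
coefficient equals the configured effect (naive-Bayes construction:
binary factors shift the base rate on the logit scale, Poisson counts
scale the rate by e^β, the nine functional-feature flags are
Bernoulli with a logit-shifted success probability).  Two deviations
from the exact logistic target are accepted and documented: the
same-isoform flag is forced false when both-annotated is false
(hierarchy constraint), and sampled flag combinations are realized from
the gene catalog with a fallback order when a pool is exhausted.
Artifact coordinates are annotated-boundary perturbations (±2–10 nt,
kept off every annotated site) or two-gene chimeras of constitutive
sites (which realize the annotated/different-isoform/non-AS
combination).

Reads: per candidate, mock BSJ reads are Poisson with a class-dependent
rate; treated reads are a Binomial survival subsample with a retention
probability per treatment group and truth class (Poisson/Binomial was
chosen over negative binomial as the simplest model matching the
pipeline's needs).  Read starts keep every read junction-spanning with
at least 10 nt on both sides, and the default 90-nt reads cover ≥ 80 %
of a full pseudo-sequence, so generated reads satisfy the counting rule
by construction.  Linear background reads (random genomic substrings,
both strands) fill both libraries to their configured totals.  Because
treated libraries lose digested linear RNA, the default treated total
is half the mock total, so a retained circRNA gains in RPM: the
expected class is not-depleted when retention × (mock total / treated
total) ≥ 1.  All randomness derives from a single master seed with one
child stream per stage (reference, candidates, per-pair reads), making
stages independently reproducible and outputs byte-identical across
reruns.

What the generator does not emulate: sequencing errors and quality
scores, paired-end inserts, rRNA, GC and coverage biases, realistic
repeat structure (Alu-driven RCS), or correlated factors.  Passing
tests therefore demonstrate the correctness of the computation and the
recovery of known effects under the generative model, not performance
on real libraries.

## Problem sizes and defaults

The default simulated study uses 2 × 120-kb chromosomes, 50 genes,
150 + 150 candidates, λ_mock = 12, 60k/30k-read libraries and three
sample pairs (one per treatment group; retention 0.9/0.1, 0.85/0.08,
0.8/0.15).  The verification runs use 150 + 150 candidates at
λ_mock = 50 with 25k/25k libraries and retention 1/0 for the
classification check, 20 replicate logistic pairs of n = 5,000 for
RCVE recovery, and 500 null replicates of 200 candidates × 3 pairs for
FDR calibration — sizes chosen so the entire suite runs comfortably on
one CPU while keeping Monte-Carlo error well inside the asserted
margins.

## Known limitations

* The ambiguity screen is a deliberately simplified stand-in for a full
  colinear-comparator analysis; it detects planted duplications and
  transcript-colinear pseudo-sequences but not all repeat-mediated
  ambiguity.
* Near-duplicate candidates (a few nt apart) can cross-capture each
  other's reads because a small junction offset still aligns within the
  identity threshold; with multi-assignment on (the default), a handful
  of artifacts adjacent to true circles can inherit their reads — the
  observed ~1–2 % sensitivity loss in the truth-recovery run.
* Wilcoxon p-values for large groups use the normal approximation; the
  exact path is enumeration-based and limited to small tie-free groups.
* The RCS exact-match contract undercounts diverged (mismatch-containing)
  repeat pairs relative to alignment-based repeat finders.
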