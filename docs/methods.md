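# Methods

This note documents the models and procedures `mirvar` implements, the
defaults and why, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was open.

## Read preprocessing

Reads pass four stages: quality gate, adapter trimming, length/ambiguity
filter, collapsing.

**Quality gate.** A read is kept iff *every* base quality strictly exceeds
`min_phred` (default 20). The strict inequality is deliberate — a base at
exactly Q20 fails — and users who prefer ≥ can pass `min_phred=19`.

**Adapter trimming.** The 3' adapter is located as the *leftmost* position
at which an adapter prefix of at least `min_adapter_overlap` (default 8)
bases aligns with mismatch rate ≤ `max_adapter_mismatch_rate` (default
0.1); the prefix may be shortened where it runs off the 3' end of the
read. These are conventional small-RNA trimming defaults; the adapter
sequence itself is always a required input because it is kit-specific.
Reads in which no position qualifies are discarded: without the adapter
the insert boundary is unknown. No 5' adapter handling is performed —
reads are assumed insert-first, as produced by standard small-RNA
chemistry.

**Length/ambiguity filter.** Inserts shorter than 17 nt or containing
non-ACGT characters are discarded. No upper length cap is imposed; the
17–31 nt range typical of small-RNA libraries is an observation, not a
rule.

**Collapsing.** Identical inserts across all libraries become one unique
tag with per-sample counts (conserved by construction: per sample, tag
counts sum to the number of valid reads). Tags are ordered by descending
total count, ties broken lexicographically, so output is deterministic.

Everything is stored internally as DNA (U→T); RNA letters appear only in
display names. Coordinates are 0-based half-open throughout.

## Annotation cascade and isomiR classification

Matching is exact full-length identity, in this order:

1. equality with a primary-species mature ⇒ **canonical**;
2. exact substring of a primary-species hairpin whose interval overlaps a
   mature locus ⇒ **template isomiR** of that mature;
3. equality with a mature of another species ⇒ **mammalian canonical**;
4. otherwise **unannotated**.

If step 2 finds placements overlapping loci of more than one distinct
mature name the tag is **ambiguous** and excluded from isomiR statistics.
Placements at several loci of the *same* name (multi-copy miRNAs) are
allowed; the most parsimonious placement (smallest total end offset, ties
by hairpin name then coordinate) is used. Only template variants are
modelled: non-template 3' tailing and internal edits are out of scope.

End calls follow from interval arithmetic: with tag interval `[ts, te)`
and mature locus `[ms, me)` on the same hairpin, `ts − ms > 0` is a 5' DEL
(of the mature's leading bases), `< 0` a 5' ADD (of upstream hairpin
bases); the 3' end is symmetric. Modified bases are read off the hairpin
and rendered as RNA in names: `miR-x DEL G` (3', unmarked end), `miR-x 5'
DEL U`, and for both ends the 5' clause first. Sizes above 6 nt are
classified but flagged, since reported template modifications rarely
exceed 1–6 nt.

The **seed** is fixed at positions 2–8 (7 nt). The population summary
reports site shares (3'-only / 5'-only / both, over all isomiRs),
ADD-vs-DEL shares per end (both-end variants count at each of their ends),
and size spectra per end and kind. **Seed families** group annotated tags
by identical seed and sum their normalized counts per sample — the
quantity of interest when canonical and 3' isomiRs act through the same
seed. An optional second pass (`rescue_with_newer_reference`) re-annotates
unannotated tags against a newer mature release.

## Expression statistics

**Filter.** A tag is kept iff in at least one group the number of samples
with ≥ `min_reads` (default 10) reads reaches the group's requirement
(default 4; per-group exceptions, e.g. a group with a failed library, can
lower it).

**Normalization.** Trimmed mean of M-values: the reference sample is the
one whose upper-quartile of count fractions is closest to the mean; M and
A values over tags non-zero in both samples are trimmed (30% per tail on
M, 5% on A) and the factor is 2^mean(M), with factors rescaled to
geometric mean 1. Normalized expression is CPM over the effective library
size. Pure depth differences give unit factors (handled by CPM);
composition skew moves the factor.

**Dispersion.** A single common NB dispersion φ is estimated by the
method of moments: mean over tags and groups (≥ 2 replicates) of
max(0, (s² − m)/m²) on normalized counts. This is simpler than
conditional-ML approaches, testable against simulations (recovers a true
φ = 0.1 within 25% at realistic depth), and slightly conservative at low
means, which errs on the safe side for FDR. The estimator is a pluggable
argument to the test.

**Exact test.** Libraries are first equalized to the geometric-mean
effective size (scaled and rounded). For each tag the group sums (s_A,
s_B) are compared under the conditional law of s_A given s_A + s_B: with
per-sample NB size r = 1/φ the group sums have sizes n_A·r and n_B·r and
the conditional distribution is negative hypergeometric — free of the
mean, so no nuisance parameter remains; φ = 0 gives the binomial limit.
The two-sided p-value sums the probabilities of all splits no more
probable than the observed one (with a 1e-10 relative tolerance on the
comparison to absorb floating-point ties). log2FC = log2((CPM_B + 0.5) /
(CPM_A + 0.5)); the 0.5 CPM pseudo-count keeps fold changes finite at
zero counts. Multi-group day-course comparisons are run as all pairwise
exact tests with BH over the union — a documented divergence from
omnibus ANOVA-like procedures, chosen for exactness and testability.

**Multiple testing.** Benjamini–Hochberg step-up (via statsmodels),
validated against the definitional oracle. "Significant" means
|log2FC| ≥ 1 **and** FDR < 0.05; the FDR reading of "p < 0.05
BH-corrected" is adjusted-value < 0.05.

## Clustering

Profiles are group means of log2(CPM+1), mean-centered per row (constant
rows are excluded with a warning — correlation is undefined on them).
Pearson distance d = 1 − r lies in [0, 2]. Hierarchical clustering is
scipy average linkage on the condensed distance matrix.

**SOTA** is implemented from scratch: a binary tree of cells, initialized
by splitting the root (global centroid). Each growth cycle runs training
epochs — every profile is presented in fixed order to its nearest leaf,
which moves toward it by `lr_winner` (default 0.01); the parent moves by
`lr_parent` (0.005) and a leaf sibling by `lr_sibling` (0.001) — until the
summed winner distance stops improving (relative tolerance 1e-9) or
`max_epochs` (1000) is reached. Then the leaf with the highest resource
(mean member distance to its centroid) is split, its two children seeded
at the two mutually most distant members (deterministic, and robust on
well-separated data; cells with < 2 members fall back to jittered centroid
copies under the seeded RNG). Growth stops at `max_clusters` leaves, or
earlier when a `variability_threshold` is set and no leaf exceeds it. The
distance is Pearson by default (euclidean available). The per-profile
update rule makes converged centroids approach member means as the
effective learning step vanishes.

## Target-site scanning

Site types follow the canonical definitions: the 6mer core is the
reverse complement of miRNA positions 2–7; a match to the complement of
position 8 on the 5' side of the site gives 7mer-m8, an A opposite
position 1 gives 7mer-A1, both give an 8mer; each core occurrence is
reported once at its highest type, with the efficacy hierarchy
8mer > 7mer-m8 > 7mer-A1 > 6mer. Because the 2–8 seed string equals the
2–7 core plus the position-8 base, 7mer-m8/8mer calls are equivalent
under either convention. Target sets are "≥ 1 site at or above a type
threshold" (default 7mer-A1) on user-provided UTRs — no conservation,
context scoring or ortholog mapping, so these are sequence-match sets,
not database-backed predictions. The canonical-vs-isomiR comparison
deletes `shift5` leading bases and reports Venn regions of the two target
sets; note that overlapping seeds (6 of 7 shared bases) naturally produce
overlapping repertoires.

## Synthetic data: what it emulates, and what it does not

`make_reference` draws random matures (22 nt) with pairwise distinct
seeds, each embedded exactly once in a random 80-nt hairpin with ≥ 6 nt of
flank on both sides (so every template ADD up to 6 nt exists).
`simulate_reads` draws, per read: a parent (uniform), a modification
category with defaults {none 0.30, 3'-only 0.48, 5'-only 0.07, both 0.15}
— chosen so 3'-only ≈ 69% of modified reads, as observed in real isomiR
populations — a DEL (vs ADD) probability of 0.66 (3') / 0.71 (5'), and a
size from {1..6} at the 3' end (44% single-base deletions) but at most 2
nt at the 5' end, all reflecting reported spectra. The insert is cut from
the hairpin, the 3' adapter appended, and the read truncated to 40 nt.
Qualities are truncated Gaussian (mean 36, sd 3, floor 2); because that
model almost never produces a sub-Q20 base on its own, 1% of reads get one
deliberately degraded base so the strict quality gate is exercised.
Insert lengths therefore span mature ± 8 nt (2 at 5' + 6 at 3') with mode
at the mature length.

Expected consequences visible in results: read-weighted category shares
match the configured distribution, but *tag-level* shares do not — there
are far more distinct both-end forms than 3'-only forms, so unique-tag
censuses over-represent "both". Deletions totalling ≥ 6 nt push an insert
below the 17-nt floor, removing ~2% of 3'-only and ~4.5% of both-end
reads; the induced bias on the recovered 3'-only share (< 0.3 percentage
points) is well inside sampling noise at 10⁴ reads.

`simulate_counts` draws NB counts with log-uniform baseline means
(20–1000), common dispersion (default 0.05), and a ± planted log2FC
(default magnitude 2 on 10% of tags) applied to one group.

Not modelled: sequencing substitution errors, PCR duplication bias,
non-template tailing, 5' adapters, expression correlation between a
miRNA's isomiRs in the count model, and any real secondary structure in
the hairpins. Passing round-trip tests therefore demonstrates the
correctness of the offset arithmetic, the cascade and the statistics on
template variants — not robustness to sequencing noise or non-template
biology.

## Problem sizes and determinism

Validation uses 10,000 reads over 50 miRNAs for the round-trip, 2,000
tags × 10 samples for DE recovery, 200 tags for null calibration, and
30–56 profiles for clustering — sizes at which every stochastic check has
comfortable margins (e.g. the 3'-only share is tested within 3 binomial
SDs). All generators and SOTA take explicit seeds; every pipeline stage is
deterministic given its inputs (ties in collapsing, placement parsimony
and linkage are broken by fixed rules).

## Known limitations

- The exact test uses a single common dispersion; no tagwise shrinkage or
  GLM framework, so strongly heteroskedastic tags are mis-calibrated.
- The method-of-moments dispersion is biased upward at low normalized
  means (≈ 1/mean), which is conservative.
- Annotation is exact-identity only: one mismatch (SNP, sequencing error)
  makes a tag unannotated rather than fuzzy-matched.
- The expression filter's per-group exception map is static
  configuration; it is not inferred from library QC.
- SOTA with a target cluster count will split zero-variability cells only
  by peeling members off the largest cell; on data with fewer real
  patterns than the target k the extra clusters are arbitrary.
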