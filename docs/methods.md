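# Methods

## Scope

`methsilence` implements the computational core of a whole-genome comparison
of DNA methylation, transcription, and 24-nt siRNA abundance across silencing
mutants in a plant genome: windowed calling of differentially methylated
regions (DMRs), strict-overlap classification of DMR sets with hypergeometric
enrichment, a fold-change + Fisher differential-expression rule,
feature-level methylation classes, and RPTM-normalized siRNA dependence
profiling. Read alignment, isoform quantification, and bisulfite chemistry
are out of scope: the package consumes cytosine reports, annotations, and
count tables, the formats those upstream tools emit.

## DMR calling

Per-cytosine records carry methylated/unmethylated read counts, strand, and
context (CG, CHG, or CHH, where H is A, T, or C). Sites with coverage below
`min_coverage` (default 5) are discarded. Remaining sites are pooled into
non-overlapping `window_size` = 50-bp windows anchored at coordinate 0 of
each chromosome. Window methylation is *weighted*: pooled methylated reads
over pooled total reads, per context and for all contexts combined
("total"). A window with no qualifying reads in a context has an undefined
level there, never zero.

For two genotypes on the same grid, a window is tested only if present in
both. With pooled counts (m_A, u_A) and (m_B, u_B) on the chosen context set,
Δ = m_B/(m_B+u_B) − m_A/(m_A+u_A) and p is the two-sided Fisher exact test on
the 2×2 table, point-probability rule. Windows with |Δ| ≥ `delta_min`
(default 0.10, boundary inclusive) and p < `alpha` (default 0.01) are
retained and tagged hypo (Δ < 0) or hyper. Same-direction windows on one
chromosome chain into a DMR when the gap between consecutive windows is ≤
`max_gap` (default 50 bp, boundary inclusive); hypo and hyper chains never
mix. The DMR's Δ_total is recomputed from the pooled counts of its
constituent windows, and p_min is the smallest window p.

Choices the procedure leaves open, fixed here: the grid is non-overlapping
(simplest reading of "every 50-bp window"); the test unit is the pooled
window count (the only construction giving one p per window); symmetric CG
strand pairs are not collapsed (coverage filtering stays per report row); no
multiple-testing correction is applied because the decision rule thresholds
raw p-values, and the null-calibration test shows the raw rule is
conservative at the retained-window level; DMR calling defaults to the
"total" context with per-context calling exposed as an option. The |Δ|
filter is applied before the exact test, which changes nothing in the
retained set but skips the test where it cannot matter.

`fisher_exact_two_sided` and `hypergeometric_upper_tail` delegate to
`scipy.stats` (`fisher_exact`, `hypergeom.sf`); the test suite checks both
against independent full-enumeration oracles in exact rational arithmetic to
1e-12 on random tables with totals ≤ 60.

## DMR comparison

Two regions "overlap" only when the shared span strictly exceeds
`min_overlap` = 50 bp; a region of one set is *shared* if any region of the
other set qualifies, else *specific*, and all qualifying pairs are listed. A
consequence worth knowing: a single-window (50-bp) call can never be shared.
Enrichment of the observed overlap count uses the hypergeometric upper tail;
because the appropriate universe (tested windows vs annotated features)
depends on the question, N is always an explicit argument and is echoed into
every report — the pipeline uses the number of tested windows for DMR
overlap and the annotated feature count for expression overlap. Genomic
composition assigns each DMR to gene, TE, or other (unannotated) space by
maximal base-pair overlap, ties broken TE > gene > other.

## Differential expression

For each feature, counts from one library per genotype are compared: the
fold change of counts normalized to the smaller library total (with a
pseudocount c₀ = 0.5 applied to the fold change only), and a two-sided
Fisher exact test of (feature count, rest of library) across genotypes on
the raw counts. "Up" requires fold > `fc_min` = 2 and p < 0.01; "down" is the
mirrored rule. The pseudocount never enters the test, so the test stays
exact. With one library per genotype the within-feature sampling model is
Poisson given the underlying abundance, under which the Fisher construction
is exactly calibrated; biological replicate variance is not modeled (see
Limitations).

## Feature methylation

TE bodies and 1-kb promoters are scored by the same weighted pooled level as
windows. The promoter is the `promoter_len` = 1000 bp immediately upstream
of the annotated 5′ end on the coding strand, truncated at chromosome bounds;
overlaps with neighboring features are permitted (no clipping). Methylation
classes use the total-cytosine level with strict thresholds: TE bodies >
20%, gene promoters > 5%; undefined levels are excluded, not zero-filled.
Group comparisons use Welch's two-sample t-test (two-sided, unequal
variance — the safer default when only "t-test" is specified), with
significance stars at 0.05/0.01; the degenerate zero-within-variance case is
flagged and reported as the appropriate limit.

## siRNA profiling

24-nt read counts per feature are normalized as RPTM = count × 10⁷ /
library total. Dependence on a polymerase is read off the fold change
(mutant RPTM + 1)/(WT RPTM + 1): below `dependence_cutoff` = 0.5 the siRNA
class depends on that polymerase (nrpd1 → Pol IV, nrpe1 → Pol V). The
cutoff has no published value; 0.5 is this package's choice and is a
mandatory, echoed parameter. Features with WT abundance below 5 RPTM are
labeled uninformative rather than classified.

## Synthetic data

The generator is first-class, tested code. It emulates:

* **Genome/annotation** — 2 chromosomes × 200 kb with 120 genes (1.5 kb) and
  120 TEs (0.8 kb), non-overlapping, randomly spaced and stranded.
* **Methylomes** — per-bp site placement (CG 0.05, CHG 0.05, CHH 0.15 — about
  one cytosine per 4 bp, giving ~12 sites per 50-bp window), coverage ~
  Poisson(λ = 20), methylated reads ~ Binomial(coverage, level). Baselines by
  (kind × context): TE 0.85/0.45/0.30, gene 0.05/0.02/0.02, intergenic
  0.04/0.02/0.02 for CG/CHG/CHH. The TE CHH baseline of 0.30 reflects
  RdDM-targeted heterochromatic TEs and accommodates the planted CHH delta of
  −0.30. Planted hypo-DMRs are 300-bp intervals inside TEs with deltas CG
  −0.10, CHG −0.15, CHH −0.30: 60 in the suvh2/9-like genotype, 15 of them
  shared with the morc6-like genotype, plus 6 morc6-specific ones (added so
  the overlap partition has both shared and specific mass on both sides). A
  subset of 40 gene promoters carries static (genotype-independent) promoter
  methylation.
* **Expression** — per-feature baseline abundance drawn once from a gamma
  distribution with CV² = 0.1 (so one library's counts are marginally
  negative-binomial with dispersion 0.1 across features), base means TE 30 /
  gene 100, library total 10⁶; one Poisson count per genotype library, with
  planted 4-fold up-regulation at 30 TEs per mutant (12 shared) and 19/25
  genes (6 shared). Up-regulated features are deliberately disjoint from
  DMR-carrying TEs, so the morc6-like up-regulated class has exactly zero
  planted methylation change — the synthetic analogue of silencing release
  without methylation loss.
* **siRNA** — per-feature 24-nt means (TE ~200, gene ~60 reads; library
  2×10⁶) scaled ×0.02 in nrpd1 for Pol IV-dependent features (all of them)
  and ×0.05 in nrpe1 for the Pol V-dependent half, ×1.0 for the Pol
  V-independent half; minor Poisson(3) background at 21–23 nt.

Site layout, annotation, and per-feature abundances come from seed
substreams independent of genotype, so all genotypes share one genome; read
sampling uses per-genotype substreams. Every generator is a pure function of
(config, annotation, truth, genotype) and is byte-reproducible under a fixed
seed.

The scenario mirrors the qualitative structure of a real study at roughly
one-tenth scale; problem sizes (400-kb genome, 240 features, 8,000 windows)
were chosen so an end-to-end run completes in seconds while every planted
class retains enough members for stable recovery statistics.

### What the generator does not model

Sequence-derived contexts (contexts are assigned by proportion, not read
from a genome sequence); symmetric CG strand pairing; bisulfite
non-conversion error (an optional rate exists conceptually but defaults to
0 — the estimator assumes converted reads); spatial autocorrelation of
methylation outside planted DMRs; biological replicates and batch effects in
expression; mapping ambiguity of multi-copy TEs. Passing recovery tests
therefore demonstrates correctness of the decision rules under the stated
sampling models, not performance on real libraries, where overdispersion
between biological replicates would inflate the false-positive rate of the
single-library Fisher rule.

## Numerical and degenerate-input choices

All-zero Fisher tables return p = 1 with a warning. Hypergeometric
arguments are validated, not clamped. BED scores are −log10(p_min) capped at
300, so p_min round-trips through files only down to 1e-300 and to the
6-significant-digit precision of the score column. Threshold comparisons
follow the printed inequalities: |Δ| ≥ 0.10 (selection attained at exactly
10%), merge gap ≤ 50, overlap > 50, fold > 2, methylation classes > 5% / >
20%; each boundary is a config knob and each is pinned by a boundary test.
Undefined levels (no qualifying reads) propagate as None/NaN and are
excluded from filters and medians rather than treated as zero.

## Pipeline

Stages (simulate → DMR calling → comparison → expression → feature
methylation → siRNA → summary) communicate only through files, so any stage
can be re-run in isolation. All thresholds live in one `PipelineParams`
namespace and are echoed, with the config and per-output SHA-256 checksums,
into `manifest.json`. `summary.tsv` is byte-deterministic for a fixed seed;
wall-clock runtimes appear only in the manifest. `evaluate_against_truth`
reports DMR sensitivity/precision under the strict >50-bp overlap rule, DE
sensitivity and false-positive rate, and siRNA label accuracy (an
uninformative call counts as a miss).

## Known limitations

The expression rule assumes one library per genotype; with replicates a
dispersion-aware test (e.g. a negative-binomial GLM) would be preferable and
is deliberately not provided here. The hypergeometric enrichment treats
regions as exchangeable units, ignoring length and clustering; a
permutation null is out of scope. Promoter definition ignores annotated
TSSs, UTRs, and bidirectional promoters. Chromosome name matching is exact
string comparison with an explicit rename map — no aliasing heuristics.
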