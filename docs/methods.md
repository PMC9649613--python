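# Methods

This note records the analytical conventions, the synthetic-data model, the
numerical choices, and the limits of what the tests demonstrate.

## Event model and conventions

Every genomic interval in the package is 0-based half-open; rMATS
`*_0base` columns are taken as 0-based starts and the end columns as
exclusive, which makes rMATS coordinates, BED peaks and the annotation
boundary list directly comparable. An event's canonical key is
`type|chrom|strand|c1-c2-…` over the per-type coordinate tuple, so the
identical junction found in independent rMATS runs maps to the identical
key. ΔPSI is group-1 mean PSI minus group-2 mean PSI with group 2 the
target condition; a negative value means inclusion in the target. Only the
junction-count (JC) flavor of rMATS output is consumed.

An event is flagged `novel_ss` when either target-exon boundary is absent
from the supplied annotation exon-boundary set. This reproduces the
*meaning* of the novel-splice-site flag — an exon not present in the
reference annotation — without re-deriving rMATS's internal bookkeeping;
callers working from real rMATS output can supply the annotation from the
same GTF that rMATS saw.

## Filtering

Coverage requires IJC+SJC ≥ 10 in **every** sample of both groups.
"Covered" is read as total junction support for the event, because a PSI
estimate needs both isoforms' denominators; requiring it per sample makes
the masked cells of the cluster matrix well defined. Significance keeps
FDR < 0.05 **and** |ΔPSI| > 0.1, both strict, so an event at exactly
FDR = 0.05 or |ΔPSI| = 0.1 is dropped; the unit fixtures plant rows at
exactly these values to pin the boundary behavior. The rescue stage uses a
*different*, deliberately verbatim rule — strictly more than 10 reads per
sample — and the two thresholds are implemented and tested separately.

## ΔPSI matrix and clustering

Rows are the union of events significant in ≥ 1 of the four drug-response
comparisons; a cell carries that comparison's ΔPSI when the event passed
coverage there and is masked otherwise. k-means cannot consume missing
values, so masked cells are imputed with 0 — the neutral "no change" on the
ΔPSI scale — before estimation; the imputation value is recorded in the
`ClusterAssignment` and never alters unmasked cells. Distance is squared
Euclidean on raw ΔPSI (all columns already share the [−1, 1] scale, so no
standardization). Defaults follow the estimator specification used in this
analysis tradition: random initialization, k = 10, 10 restarts, 300
iterations, seed 42; identical inputs and seed give identical labels, and
tests compare partitions by adjusted Rand index because cluster ids are
arbitrary. A cluster is "coherent" when every unmasked cell shares one
sign; coherent-inclusion clusters define the drug-induced exon set carried
into the k-mer stage.

## Splice-site k-mer enrichment

Windows are 5 nt on each side of a splice-site boundary (a 10-nt window,
the tightest that fits an 8-mer, with three 8-mer offsets); the flank is
configurable because larger contexts are equally defensible. Foreground
windows sit at the target exon's 3′ and 5′ splice sites, background windows
at the upstream exon's 3′ and the downstream exon's 5′ splice site, all
reverse-complemented on the minus strand so the splice-site grammar reads
in the sense direction. Counting pools occurrences across events (a
per-event presence mode would weight events rather than occurrences; pooled
counting is the default here). Each k-mer's 2×2 table of foreground vs
background occurrences is tested with a two-sided Fisher exact test —
sidedness is not dictated by the analysis, so the conservative two-sided
test is used and enrichment direction is read from the odds ratio, with a
+0.5 continuity correction when any cell is zero. No multiple-testing
correction is applied by default; `recompute_bh_fdr` is available. The
analysis is restricted to cassette-exon (SE) geometries, the geometry the
windows are defined for.

## RBP binding enrichment

Peaks pass at −log₁₀(P) ≥ 3 and log₂(fold change) ≥ 3, both inclusive.
An event's region spans the upstream exon start to the downstream exon end;
binding is ≥ 1 bp overlap with ≥ 1 significant peak of that RBP, counted
once per event. Peaks are pooled across files per RBP by default (per-cell-
line analysis is the caller's choice via the manifest), and intersection
ignores strand by default (eCLIP peaks are stranded; a flag enables
strand-aware matching). Enrichment of a foreground event set against the
coverage-passing background is the upper-tail hypergeometric probability
P(X ≥ k | N, K, n); fold enrichment is (k/n)/(K/N), the natural
frequency-ratio reading of "binding enrichment". Binding differences
between rescued and unrescued events use a two-sided Fisher exact test.

## Rescue quantification

Group PSI is the arithmetic mean of per-sample inclusion levels. For each
qualifying disease event the absolute deviation |ψ̄_Ctrl-DMSO − ψ̄_HD-arm| is
computed under vehicle and under drug; rescued means the drug-arm deviation
is strictly below 0.1. The summary reports mean deviations, percent
reduction 100·(1 − mean_drug/mean_DMSO), the rescued fraction, the
pie-chart partition (rescued / still-included / still-excluded, direction
from the sign of ψ̄_Ctrl − ψ̄_HD-drug), and a two-sided Wilcoxon rank-sum
test between the two deviation samples (scipy's normal-approximation
statistic; adequate at the event counts involved here).

## Synthetic data model

The generator emulates the study design: two cell types (4 and 3 replicates
per group) with four condition groups each, and all five AS event types
laid out on two synthetic contigs with realistic exon/intron spacing.
Per event and sample, PSI ~ truncated-normal(group mean, σ = 0.05) on
[0, 1]; the per-sample read total is Poisson with mean 100 (4 for planted
low-coverage events), split between inclusion and skipping junctions with
probability ψlᵢ/(ψlᵢ + (1−ψ)lₛ), so the length-normalized PSI formula
inverts the simulation and the emitted inclusion levels agree with the
emitted counts to within printing precision (0.0005). Table P values come
from a per-event Welch t-test on per-sample PSI with BH correction across
the comparison — a deliberate stand-in for the rMATS likelihood, which is
out of scope and irrelevant to downstream correctness. σ = 0.05 reflects
replicate-to-replicate PSI variability typical of human donor lines; depth
100 puts events comfortably above the coverage threshold so that filtering
outcomes are driven by the planted structure, not by depth noise.

Planted structure: disease events receive a Ctrl-vs-HD ΔPSI of ±[0.15,
0.6]; a configurable fraction reverts exactly to the Ctrl level under drug
("rescued"), the rest keep their disease level, and a null mode leaves all
disease events untouched by the drug. Drug-induced events are cassette
exons with PSI ∈ [0.01, 0.08] under vehicle and [0.5, 0.9] under drug (or
fixed per-cluster offsets when planted response clusters are requested);
their target splice sites are omitted from the annotation boundary list
(making them novel) and carry the chosen 5′/3′ splice-site 8-mers written
into the genome at a fixed window offset. Scattered events respond to the
drug independently per cohort and supply the cluster-analysis background.
Peak files contain one passing peak per bound event plus sub-threshold
decoys; the first RBP binds rescued disease events preferentially
(P = 0.7 vs 0.15). Gene counts are Poisson with planted consistent log₂
drug effects of ±[0.5, 1.5] on a subset of induced-exon genes.

Truth is recorded two ways. Membership truth (disease/drug/rescued sets,
bound sets, motif carriers, planted clusters) is the planted assignment.
Outcome truth — which events pass coverage and significance, which genes
are sign-consistent, the percent reduction — is re-derived at generation
time by independent brute-force scans of the emitted values, so tests
compare the pipeline against a computation that shares no code with it.
Two percent-reduction references are stored: one from the latent group
means and one from the realized per-sample PSIs. The second is the
truth-implied value of the statistic the pipeline actually estimates —
absolute deviations of noisy replicate means have a positive floor
(E|N(0,σ)| > 0) that the latent-mean number lacks — and is the reference
used for recovery checks.

Limitations of the emulation: no read-level simulation, no realistic gene
structures or GC/ mappability biases, per-event independence (no
co-regulation), and the table statistics are t-tests rather than the rMATS
likelihood. Passing tests therefore demonstrate the downstream chain is
correct and calibrated on data with the assumed structure, not that any
specific biological dataset would yield particular numbers.

## Numerical and design choices

- Exact tests come from scipy (`fisher_exact`, `hypergeom`); the acceptance
  suite proves them equal to exhaustive enumeration over all small tables
  (margins ≤ 12), so larger cases rest on the library's continuity.
- The null calibration of the enrichment P value uses a large background
  (N = 20 000, K = 10 000, n = 2 000): the hypergeometric P is discrete, and
  uniformity is only expected when the support is fine; small backgrounds
  give conservative, stair-stepped P values by construction.
- The k-mer and interval stages use `intervaltree` for intersection;
  brute-force quadratic oracles pin the semantics (half-open, ≥ 1 bp).
- BH adjustment delegates to `statsmodels.stats.multitest.multipletests`.
- Chromosome naming is normalized across the `chr1`/`1` styles before
  intersection; an event on a chromosome absent from the peaks or query
  intervals counts as non-overlapping with a warning.
- `run_all` reduces k when the ΔPSI matrix has fewer rows than the
  configured k (to half the row count, minimum 2) and records the effective
  k in the summary; the library-level `cluster_events` keeps the strict
  error so programmatic users are not silently re-parameterized.
- In `run_all`, the k-mer foreground is the SE events of coherent-inclusion
  clusters; when no cluster is coherent it falls back to novel significant
  SE events from the drug comparisons.
- Problem sizes in the test and acceptance runs (50-event fixtures,
  1000-event rescue bundles, 20 motif seeds, 1000 calibration replicates)
  were chosen so each statistical check has comfortable power at desk
  scale.

## Known limitations

- The reading frame entering an induced exon cannot be derived without the
  real transcript; stop-codon counting is parameterized by the incoming
  frame offset and reported as unknown when it is not supplied.
- Formal differential-expression testing is out of scope; the expression
  stage provides RPKM and sign-consistent log₂ ratios only.
- MXE ΔPSI refers to the first exon's inclusion, per rMATS convention, and
  the k-mer stage covers cassette-exon geometries only.
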