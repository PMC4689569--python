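# Methods

## Codon usage and enrichment calls

Each gene is an in-frame list of sense codons; the terminal stop is
stripped at parse time, and sequences with internal stops, ambiguous
bases, or lengths not divisible by 3 are rejected (skipped with a logged
warning when reading FASTA). The universe is the 61 sense codons; stop
codons never enter counts or the genome pool.

Enrichment of codon *c* in a gene compares the gene's count *k* (of *n*
codons) with the genome pool (*K* of *N*) under Hypergeometric(N, K, n).
The pool includes the focal gene: at genome scale the difference is
negligible, and it makes the pool gene-independent and cacheable. The
Z-score uses the finite-population-corrected hypergeometric standard
deviation; calls use the exact inclusive tails P(X ≥ k) and P(X ≤ k) with
a strict threshold (p < 0.01 by default). Where the variance degenerates
(n = N, K = 0, or K = N) Z is reported as NaN but the tail probabilities
are still exact. Frequencies are reported per 1,000 codons.

## Differential proteomics

Protein ratio = arithmetic mean of peptide ratios (linear scale,
sample/internal standard); proteins need ≥ 2 non-missing replicates per
strain. The test is a two-sided, equal-variance (classic Student)
two-sample t-test on log2 replicate ratios — the literal reading of
"Student's t-test" for 3-vs-3 replicates; the fold change is the ratio of
linear-scale replicate means. Thresholds are strict and two-sided:
down = fold < 1/1.2 and p < 0.05; up = fold > 1.2 and p < 0.05. A row with
zero variance in both strains gets p = 1 when the means agree and p = 0
otherwise (the infinite-t limit). Replicate dispersion is summarized as
RSD = |sd/mean|.

## Group statistics and resampling nulls

For a codon group (genes called *over* for that codon, intersected with
the quantified proteome) the statistics are percent-down = 100·n_down/n
and D/U = n_down/n_up (undefined when n_up = 0; flagged, never silently
0 or ∞). The null draws |group| proteins without replacement from the
complement pool and recomputes the statistic; the empirical p is the
inclusive fraction of draws at least as large as the observed value.
Draws whose D/U is undefined (no up-regulated proteins drawn) are counted
as at-least-as-extreme — conservative for the direction of inference.
Both statistics are evaluated on the same draws.

Because both statistics depend only on how many drawn proteins are down-
and up-regulated, the implementation samples the (down, up, other) counts
from the multivariate hypergeometric distribution rather than
materialising gene subsets. The distribution is identical to literal
subset sampling — the test suite checks this against exhaustive
enumeration over all C(10,5) subsets of a small pool — and it makes
100,000 samplings essentially free.

Controls:

* **mRNA filter** — a changed protein is "explained by mRNA" when its
  mRNA moved in the same direction with |fold| > 1.2 and p < 0.05,
  mirroring the protein-level rule; such proteins are removed before the
  group statistics. Genes absent from the mRNA table pass through.
* **Abundance matching** — abundance deciles are computed on the union of
  group and pool; each draw takes exactly the group's per-bin count from
  the pool members of that bin, so the group's abundance histogram is
  preserved in every iteration. Tied abundances share a bin (average-rank
  binning): identical values collapse to one stratum, so flat abundance
  degenerates to the plain resampling null instead of letting an
  arbitrary tie-break leak group membership into the strata. A bin whose
  pool is smaller than the group's demand is an error naming the bin.
* **Co-enrichment exclusion** — group statistics recomputed after
  removing members also enriched for another codon (both directions);
  an emptied group is flagged rather than scored.
* **Frequency bins** — D/U per codon-frequency bin [0,10), [10,20), …,
  last bin open-ended (7 bins of width 10 per-1000 by default), plus the
  Spearman rank correlation between per-gene codon frequency and log2
  protein change.

## Codon runs and shuffle nulls

The target set is {AGA, GAA}. The window profile is the target fraction
in a 15-**codon** sliding window (step 1, fully inside the gene) minus
the gene-wide target fraction; positive peaks mark clusters. A k-mer run
is any window of k consecutive target codons, counted with overlap — the
simplest definition that is consistent across k = 3, 4, 5 and monotone
non-increasing in k.

The per-gene null shuffles the codon order (composition preserved) and
recounts; 10,000 shuffles by default. Only the target/non-target
indicator matters for run counts, so the kernel permutes the boolean
indicator — distributionally identical to permuting the codon list. The
empirical p is the inclusive fraction of shuffles with count ≥ actual.
Each gene draws from its own RNG stream keyed by (master seed,
crc32(gene id)), so per-gene results do not depend on iteration order.
The "randomized" comparator for the actual-vs-null comparison is the
per-gene mean over shuffles, keeping both compared vectors one value per
gene. Group comparisons use the two-sided Mann–Whitney U as implemented
in scipy with `method="auto"`: exact for small untied samples, the
tie-corrected normal approximation otherwise; two jointly constant
samples return p = 1 explicitly.

## Ribosome pausing

FP/T (footprint rpkm over mRNA rpkm) proxies per-gene ribosome density;
pausing is a strict mutant/wild-type fold increase > 1.2. Genes with
T rpkm below a floor (default 1.0) in either strain are excluded with a
reason, not silently dropped — low denominators make FP/T unstable.
rpkm tables are assumed library-size normalized upstream. Associations:

* pausing × differential expression — 2×2 Pearson chi-square (df = 1,
  **no** continuity correction; this choice reproduces both published
  p-values from the published tables to < 1%) plus K-S on log2
  fold-change distributions; genes present in both layers only.
* pausing × codon enrichment — chi-square on paused × enriched over all
  pausing genes, plus K-S on combined AGA+GAA usage.
* pausing × runs — Mann–Whitney and K-S on per-gene run counts, also
  restricted to enriched genes to control for overall usage.

Empty strata flag the affected table; the others are still produced.

## Synthetic universe

The generator emulates the statistical structure the analysis assumes,
not the biology of any instrument:

* **Genome** — 5,000 genes, log-normal lengths (median ≈ 365 codons,
  clipped to [60, 4000]), codons i.i.d. from a baseline distribution
  (uniform over the 61 sense codons by default; a yeast-like table can be
  supplied). 10% of genes are *enriched*: their AGA/GAA probabilities are
  boosted 3× (renormalized) and up to 2 interior windows of 5 codons are
  overwritten with target codons (each attempt succeeds with probability
  0.7, so some enriched genes carry no run and both pausing strata stay
  populated among them). Length is preserved by planting; composition is
  not — the composition change *is* the signal. Genes start with ATG and
  are written with a terminal TAA.
* **Proteomics** — true log2 fold-change = −0.02 × (AGA+GAA per-1000
  frequency, centered), zero for a 30% null fraction; enriched genes sit
  ≈ 60 per-1000 units above the mean, i.e. a true fold of ≈ 0.45. Three
  replicates per strain with N(0, 0.2²) log2 noise; log-normal abundance.
* **mRNA** — null N(0, 0.1²) log2 changes with uniform p; 4% of
  truly-changed genes get an mRNA change equal to their protein change
  with p = 10⁻⁴ (exercises the mRNA filter).
* **Footprints** — T log-normal per strain; FP = T × base ratio × noise
  (log sd 0.05); the mutant ratio is additionally inflated by
  1 + 0.3 × planted_runs, so ≥ 1 planted run crosses the 1.2 cutoff in
  the noiseless limit.

Everything is a pure function of (config, master seed); the genome uses
one sub-stream per gene index so a single gene can be regenerated alone,
and the other tables use dedicated streams per table.

What passing tests on this universe do **not** show: real peptide-level
measurement structure (shared peptides, intensity-dependent variance),
real codon-usage covariation between synonymous families, isoform or
mapping artifacts in rpkm, or any upstream normalization issues — genes
here are independent draws, which real genomes are not.

## Problem sizes in the test suite and acceptance script

Simulation-backed checks use sizes chosen to keep the suite fast while
leaving the Monte-Carlo error well below the tested margins: the
calibration study runs 50 genomes of 2,000 genes with 5,000 resampling
draws; the recovery study runs 20 seeds of the full 5,000-gene default
with 10,000 resampling draws, and estimates per-gene shuffle-null means
from 200 shuffles (the mean converges orders of magnitude faster than
the tail that the 10,000-shuffle default is sized for). The acceptance
script runs one full default universe at the supplied seed.

## Known limitations

* The enrichment scan treats codons independently; no synonymous-family
  (RSCU-style) normalization or codon-adaptation index is computed.
* Empirical p-values are plain inclusive fractions; with n samplings the
  smallest reportable nonzero value is 1/n, and 0 means "no draw reached
  the observed value", not a literal zero probability.
* No multiple-testing correction across the 61 codon groups is applied;
  the reported empirical p-values are raw.
* Pausing is gene-level only: codon-resolution ribosome occupancy is out
  of scope by design.
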