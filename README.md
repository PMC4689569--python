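# codonshift

Tools for asking whether a proteome shift is **codon-biased**: when a tRNA
wobble-uridine modification is lost (e.g. the Trm9-dependent mcm⁵U/mcm⁵s²U
modifications in budding yeast), translation of mRNAs that rely heavily on
the cognate codons — AGA and GAA — is expected to suffer selectively.
`codonshift` implements the full statistical pipeline for testing that
hypothesis from three data layers:

1. **Gene-specific codon usage** — for each gene, the count *k* of a codon
   among its *n* codons is compared with the genome pool (*K* of *N*) under
   a hypergeometric model. The enrichment score is

   Z = (k − nK/N) / √( n·(K/N)·(1−K/N)·(N−n)/(N−1) )

   and a gene is called *enriched* when the exact upper-tail probability
   P(X ≥ k) < 0.01 (61 sense codons; stops excluded).
2. **Differential proteomics** — replicate SILAC ratios (sample / heavy
   internal standard) are averaged per protein, filtered to ≥ 2 replicates
   per strain, and tested with a two-sided equal-variance t-test on log2
   ratios; calls require p < 0.05 and fold change > 1.2 (or < 1/1.2).
   Group selectivity is quantified as percent-down and the down/up ratio
   (D/U), with empirical p-values from equal-size draws out of the
   non-enriched pool (100,000 samplings by default), plus mRNA-change,
   abundance-matched, and co-enrichment controls.
3. **Codon clustering and ribosome pausing** — overlapping k-codon runs of
   {AGA, GAA} are counted per gene and compared with composition-preserving
   codon shuffles (10,000 by default); per-gene ribosome density is the
   footprint/mRNA rpkm ratio (FP/T), and a mutant/wild-type FP/T fold
   > 1.2 calls a gene *paused*. Associations use Pearson chi-square (df=1,
   no continuity correction), Kolmogorov–Smirnov, and Mann–Whitney tests.

A synthetic-data generator (`codonshift.simulate`) produces the whole input
universe — CDS FASTA, replicate ratio table, mRNA table, rpkm table — with
planted, recorded effects, so every stage is testable end to end without
any external download.

## Worked example

The numbered drivers under `analysis/` run the whole study on the synthetic
universe (seed 17) and write their tables under `results/`:

```sh
python analysis/01_simulate.py
python analysis/02_codon_usage.py
python analysis/03_differential_expression.py
python analysis/04_enrichment_groups.py
python analysis/05_codon_runs.py
python analysis/06_pausing.py
```

Selected output:

```
wrote 5000 genes to results/data
  enriched genes: 543
  genes with planted runs: 493
...
AGA: n=462, 68.2% down, D/U=157.50
  empirical p (percent-down / D/U / abundance-matched D/U): 0.00000 / 0.00000 / 0.00000
  Spearman usage vs log2 change: rho=-0.472 (p=1.37e-275)
...
  pausing_x_runs_enriched_only: Mann-Whitney p=1.37e-29 KS p=1.00e-22
```

Reading: 543 of 5,000 genes were generated with boosted AGA/GAA usage; the
usage scan recovers 462 of them as AGA-enriched at p < 0.01. Within that
group 68.2% of proteins are down-regulated versus 9.2% genome-wide, and no
random draw of 462 non-enriched proteins out of 20,000 reaches that value
(empirical p < 5·10⁻⁵), with or without abundance matching. Planted codon
runs exceed their shuffle nulls, and genes with runs are exactly the genes
whose ribosome density rises — the association survives restriction to
enriched genes only.

The same machinery is exposed as a CLI (`codonshift simulate | codon-usage |
de | enrich | runs | pausing | report`), e.g.

```sh
codonshift enrich --usage results/usage.tsv --de results/de.tsv \
    --codon AGA --statistic du --n-samplings 100000 --seed 17
```

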