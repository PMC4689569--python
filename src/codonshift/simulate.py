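"""Synthetic input universe with planted, recorded effects.

Generates everything the pipeline consumes — a yeast-like CDS FASTA, a
replicate SILAC ratio table, a mostly-null mRNA fold-change table, and an
FP/T rpkm table — from a single config and master seed, together with a
truth table of the planted effects (enriched genes, planted codon runs,
true protein changes, paused genes) for recovery tests.

Planted structure:

* a fraction of genes draw their codons from a distribution in which the
  target codons (AGA, GAA) are boosted by a multiplicative factor, and
  additionally carry contiguous planted runs of target codons;
* each gene's true protein log2 fold-change is ``-de_slope`` times its
  centered target-codon frequency (per 1000), zero for a null fraction;
  replicate ratios add log2-normal noise around it;
* mRNA changes are null except for a small fraction matched to the protein
  change (exercising the mRNA filter);
* the mutant FP/T ratio is inflated by ``1 + pausing_boost * planted_runs``.

All generators are pure functions of (config, master_seed); the genome uses
one sub-stream per gene index so any single gene can be regenerated alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .codon_stats import CODON_TO_INDEX, SENSE_CODONS, CodingSequence

DEFAULT_TARGETS = ("AGA", "GAA")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic universe (defaults are genome-like)."""

    n_genes: int = 5000
    #: log-normal gene length in codons (yeast CDSs average a few hundred codons)
    length_mean_log: float = 5.9
    length_sd_log: float = 0.55
    min_length: int = 60
    max_length: int = 4000
    #: baseline codon probabilities over the 61 sense codons (uniform by default)
    baseline_freqs: tuple[float, ...] = field(
        default_factory=lambda: tuple([1.0 / len(SENSE_CODONS)] * len(SENSE_CODONS))
    )
    target_codons: tuple[str, ...] = DEFAULT_TARGETS
    enriched_fraction: float = 0.10
    enrichment_boost: float = 3.0
    run_plant_length: int = 5
    runs_per_enriched_gene: int = 2
    #: each planting attempt succeeds with this probability, so some enriched
    #: genes carry no run — both pausing strata stay populated among them
    run_plant_prob: float = 0.7
    #: protein log2fc per unit of centered target-codon frequency (per 1000)
    de_slope: float = 0.02
    null_fraction: float = 0.30
    n_replicates: int = 3
    replicate_sd: float = 0.20  # log2 replicate noise
    abundance_mean_log: float = 13.8  # ~1e6 arbitrary intensity units
    abundance_sd_log: float = 1.0
    mrna_matched_fraction: float = 0.04
    mrna_null_sd: float = 0.10  # log2
    t_mean_log: float = 3.9  # ~50 rpkm
    t_sd_log: float = 1.0
    base_fp_ratio: float = 1.0
    pausing_boost: float = 0.30  # FP/T inflation per planted run
    fp_noise_sd: float = 0.05  # log-scale measurement noise on FP
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.enriched_fraction <= 1 or not 0 <= self.null_fraction <= 1:
            raise ValueError("fractions must lie in [0, 1]")
        if not 0 <= self.mrna_matched_fraction <= 1:
            raise ValueError("fractions must lie in [0, 1]")
        if min(self.enrichment_boost, self.replicate_sd + 1, self.n_genes) <= 0:
            raise ValueError("scale parameters must be positive")
        if abs(sum(self.baseline_freqs) - 1.0) > 1e-9:
            raise ValueError("baseline codon frequencies must sum to 1")

    def with_seed(self, master_seed: int) -> "SyntheticConfig":
        return replace(self, master_seed=master_seed)


def _stream(cfg: SyntheticConfig, tag: int) -> np.random.Generator:
    return np.random.default_rng([cfg.master_seed % (2**31), int(tag)])


def _gene_rng(cfg: SyntheticConfig, index: int) -> np.random.Generator:
    # sub-seed = (master seed, gene index): any gene regenerable in isolation
    return np.random.default_rng([cfg.master_seed % (2**31), 1_000_000 + index])


def _boosted_freqs(cfg: SyntheticConfig) -> np.ndarray:
    p = np.asarray(cfg.baseline_freqs, dtype=float).copy()
    for c in cfg.target_codons:
        p[CODON_TO_INDEX[c]] *= cfg.enrichment_boost
        if p[CODON_TO_INDEX[c]] > 1.0:
            raise ValueError(f"enrichment boost drives codon {c} frequency above 1")
    return p / p.sum()


def generate_genome(cfg: SyntheticConfig) -> tuple[list[CodingSequence], pd.DataFrame]:
    """Draw the CDS set and record planted enrichment/runs in a truth table.

    Genes start with ATG; codons are drawn i.i.d. from the baseline (or
    boosted) frequencies; enriched genes get ``runs_per_enriched_gene``
    non-overlapping interior windows of length ``run_plant_length``
    overwritten with target codons (length preserved, composition not —
    that is the planted signal).
    """
    head = _stream(cfg, 0)
    lengths = np.exp(head.normal(cfg.length_mean_log, cfg.length_sd_log, cfg.n_genes))
    lengths = np.clip(np.round(lengths).astype(int), cfg.min_length, cfg.max_length)
    enriched = head.random(cfg.n_genes) < cfg.enriched_fraction
    base_p = np.asarray(cfg.baseline_freqs, dtype=float)
    boost_p = _boosted_freqs(cfg)
    codon_arr = np.array(SENSE_CODONS)
    target_idx = np.array([CODON_TO_INDEX[c] for c in cfg.target_codons])
    atg = CODON_TO_INDEX["ATG"]

    genes: list[CodingSequence] = []
    truth_rows = []
    for i in range(cfg.n_genes):
        rng = _gene_rng(cfg, i)
        L = int(lengths[i])
        p = boost_p if enriched[i] else base_p
        codes = rng.choice(len(SENSE_CODONS), size=L, p=p)
        codes[0] = atg
        planted = 0
        if enriched[i] and cfg.run_plant_length > 0:
            k = cfg.run_plant_length
            occupied: list[tuple[int, int]] = []
            for _ in range(cfg.runs_per_enriched_gene):
                if rng.random() >= cfg.run_plant_prob:
                    continue
                for _attempt in range(20):
                    start = int(rng.integers(1, L - k + 1))
                    if all(start + k <= s or start >= e for s, e in occupied):
                        codes[start : start + k] = rng.choice(target_idx, size=k)
                        occupied.append((start, start + k))
                        planted += 1
                        break
        freq = 1000.0 * np.isin(codes, target_idx).sum() / L
        gene_id = f"g{i:05d}"
        genes.append(CodingSequence(gene_id, tuple(codon_arr[codes])))
        truth_rows.append((gene_id, bool(enriched[i]), planted, L, freq))
    truth = pd.DataFrame(
        truth_rows, columns=["gene_id", "is_enriched", "planted_runs", "length", "target_freq_per_1000"]
    )
    return genes, truth


def generate_proteomics(truth: pd.DataFrame, cfg: SyntheticConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replicate SILAC ratio table and the truth annotated with true log2fc.

    true log2fc = -de_slope * (target frequency, centered over genes) for
    effect genes, 0 for the null fraction; each strain contributes
    ``n_replicates`` ratios 2^(effect + N(0, replicate_sd)), the wild type
    carrying no effect. Abundance is log-normal.
    """
    rng = _stream(cfg, 1)
    n = len(truth)
    freq = truth["target_freq_per_1000"].to_numpy(dtype=float)
    centered = freq - freq.mean()
    is_null = rng.random(n) < cfg.null_fraction
    true_log2fc = np.where(is_null, 0.0, -cfg.de_slope * centered)
    reps = cfg.n_replicates
    wt = 2.0 ** rng.normal(0.0, cfg.replicate_sd, (n, reps))
    mut = 2.0 ** (true_log2fc[:, None] + rng.normal(0.0, cfg.replicate_sd, (n, reps)))
    abundance = np.exp(rng.normal(cfg.abundance_mean_log, cfg.abundance_sd_log, n))
    table = pd.DataFrame({"gene_id": truth["gene_id"]})
    for j in range(reps):
        table[f"wt_r{j + 1}"] = wt[:, j]
    for j in range(reps):
        table[f"mut_r{j + 1}"] = mut[:, j]
    table["abundance"] = abundance
    truth = truth.copy()
    truth["true_log2fc"] = true_log2fc
    truth["is_de_down"] = true_log2fc < -math.log2(1.2)
    return table, truth


def generate_mrna(truth: pd.DataFrame, cfg: SyntheticConfig) -> pd.DataFrame:
    """Mostly-null mRNA table (gene_id, log2fc, p).

    A fraction ``mrna_matched_fraction`` of genes with a real protein
    effect get an mRNA change equal to their protein change with a tiny p;
    all others are null noise with uniform p.
    """
    if "true_log2fc" not in truth.columns:
        raise ValueError("run generate_proteomics first (truth lacks true_log2fc)")
    rng = _stream(cfg, 2)
    n = len(truth)
    log2fc = rng.normal(0.0, cfg.mrna_null_sd, n)
    p = rng.random(n)
    effect = truth["true_log2fc"].to_numpy() != 0.0
    matched = effect & (rng.random(n) < cfg.mrna_matched_fraction)
    log2fc[matched] = truth.loc[matched, "true_log2fc"]
    p[matched] = 1e-4
    return pd.DataFrame({"gene_id": truth["gene_id"], "log2fc": log2fc, "p": p})


def generate_footprints(truth: pd.DataFrame, cfg: SyntheticConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """FP/T rpkm table; mutant FP inflated by planted runs.

    FP = T * base_ratio * lognormal noise per strain; the mutant ratio is
    additionally multiplied by (1 + pausing_boost * planted_runs). Returns
    the rpkm table and the truth annotated with is_paused (the noiseless
    fold exceeding 1.2).
    """
    rng = _stream(cfg, 3)
    n = len(truth)
    t_wt = np.exp(rng.normal(cfg.t_mean_log, cfg.t_sd_log, n))
    t_mut = np.exp(rng.normal(cfg.t_mean_log, cfg.t_sd_log, n))
    inflation = 1.0 + cfg.pausing_boost * truth["planted_runs"].to_numpy(dtype=float)
    fp_wt = t_wt * cfg.base_fp_ratio * np.exp(rng.normal(0.0, cfg.fp_noise_sd, n))
    fp_mut = t_mut * cfg.base_fp_ratio * inflation * np.exp(rng.normal(0.0, cfg.fp_noise_sd, n))
    table = pd.DataFrame(
        {"gene_id": truth["gene_id"], "fp_wt": fp_wt, "t_wt": t_wt, "fp_mut": fp_mut, "t_mut": t_mut}
    )
    truth = truth.copy()
    truth["is_paused"] = inflation > 1.2
    return table, truth


def generate_all(cfg: SyntheticConfig) -> dict:
    """Full synthetic bundle: genes, proteomics, mrna, rpkm, truth."""
    genes, truth = generate_genome(cfg)
    proteomics, truth = generate_proteomics(truth, cfg)
    mrna = generate_mrna(truth, cfg)
    rpkm, truth = generate_footprints(truth, cfg)
    return {"genes": genes, "proteomics": proteomics, "mrna": mrna, "rpkm": rpkm, "truth": truth}
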