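"""Gene-level ribosome pausing from footprint (FP) and mRNA (T) abundances.

The FP/T rpkm ratio proxies per-gene ribosome density; a mutant/wild-type
fold increase > 1.2 (strict) calls the gene "paused". Cross-tabulations
against differential-expression calls, codon enrichment, and codon-run
counts use Pearson chi-square (df=1, no continuity correction),
Kolmogorov-Smirnov, and Mann-Whitney tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .runs import compare_run_vectors

logger = logging.getLogger(__name__)

DEFAULT_FOLD_CUTOFF = 1.2
DEFAULT_T_FLOOR = 1.0


def call_pausing(
    rpkm: pd.DataFrame,
    fold_cutoff: float = DEFAULT_FOLD_CUTOFF,
    t_floor: float = DEFAULT_T_FLOOR,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene pausing calls from a four-column rpkm table.

    Input columns: gene_id, fp_wt, t_wt, fp_mut, t_mut (library-size
    normalized upstream). Genes whose T rpkm falls below ``t_floor`` in
    either strain are excluded (unstable FP/T) and returned separately with
    a reason. Returns (pausing table, excluded table).
    """
    required = ["gene_id", "fp_wt", "t_wt", "fp_mut", "t_mut"]
    missing = [c for c in required if c not in rpkm.columns]
    if missing:
        raise ValueError(f"rpkm table missing columns {missing}")
    vals = rpkm[required[1:]].to_numpy(dtype=float)
    if np.any(vals < 0):
        raise ValueError("rpkm values must be non-negative")
    low = (rpkm["t_wt"] < t_floor) | (rpkm["t_mut"] < t_floor)
    excluded = rpkm.loc[low, ["gene_id", "t_wt", "t_mut"]].copy()
    excluded["reason"] = f"T rpkm below floor {t_floor}"
    if len(excluded):
        logger.info("excluded %d genes with T rpkm below %.3g", len(excluded), t_floor)
    kept = rpkm.loc[~low].reset_index(drop=True)
    ratio_wt = kept["fp_wt"] / kept["t_wt"]
    ratio_mut = kept["fp_mut"] / kept["t_mut"]
    fold = ratio_mut / ratio_wt
    out = pd.DataFrame(
        {
            "gene_id": kept["gene_id"],
            "ratio_wt": ratio_wt,
            "ratio_mut": ratio_mut,
            "fold": fold,
            "paused": fold > fold_cutoff,  # strict
        }
    )
    return out, excluded.reset_index(drop=True)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Rows: condition present/absent. Columns: outcome present/absent."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty contingency table")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


def chi_square_2x2(table: ContingencyTable2x2) -> tuple[float, float]:
    """Pearson chi-square (df=1, no continuity correction), two-sided p."""
    arr = table.as_array()
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("zero marginal: chi-square undefined")
    stat, p, _, expected = stats.chi2_contingency(arr, correction=False)
    if np.any(expected <= 0):
        raise ValueError("non-positive expected count")
    return float(stat), float(p)


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov D with asymptotic two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(x, y, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)


def _table_from_masks(cond: np.ndarray, outcome: np.ndarray) -> ContingencyTable2x2:
    return ContingencyTable2x2(
        a=int(np.count_nonzero(cond & outcome)),
        b=int(np.count_nonzero(cond & ~outcome)),
        c=int(np.count_nonzero(~cond & outcome)),
        d=int(np.count_nonzero(~cond & ~outcome)),
    )


def _chi_square_or_flag(tab: ContingencyTable2x2) -> dict:
    entry = {"table": [[tab.a, tab.b], [tab.c, tab.d]]}
    try:
        stat, p = chi_square_2x2(tab)
        entry.update({"chi2": stat, "p": p, "degenerate": False})
    except ValueError as exc:
        entry.update({"chi2": None, "p": None, "degenerate": True, "reason": str(exc)})
    return entry


def pausing_cross_tabs(
    pausing: pd.DataFrame,
    calls: pd.DataFrame | None = None,
    enriched_ids=None,
    run_counts: pd.DataFrame | None = None,
    usage_freq: pd.Series | None = None,
) -> dict:
    """The three pausing associations, each on its own shared-gene universe.

    * pausing x differential expression: 2x2 chi-square on paused vs
      down-called, plus K-S on log2 fold-change distributions (needs
      ``calls`` with fold_change) — genes in both layers only.
    * pausing x codon enrichment: 2x2 chi-square on paused vs enriched
      (``enriched_ids``), plus K-S on target-codon usage (``usage_freq``,
      per-1000, indexed by gene) — all pausing genes.
    * pausing x codon runs: Mann-Whitney and K-S on per-gene run counts
      (``run_counts`` with gene_id/actual), paused vs not, repeated
      restricted to enriched genes.

    Degenerate strata are flagged rather than fatal.
    """
    results: dict = {}
    paused_by_gene = pausing.set_index("gene_id")["paused"]

    if calls is not None:
        joint = calls.join(paused_by_gene, on="gene_id").dropna(subset=["paused"])
        n_dropped = len(calls) - len(joint)
        if n_dropped:
            logger.info("pausing x DE: dropped %d genes absent from the pausing layer", n_dropped)
        cond = joint["paused"].to_numpy(dtype=bool)
        down = (joint["call"] == "down").to_numpy()
        entry = _chi_square_or_flag(_table_from_masks(cond, down))
        entry["n_joint"] = len(joint)
        if cond.any() and (~cond).any():
            fc = np.log2(joint["fold_change"].to_numpy(dtype=float))
            d, p = ks_two_sample(fc[cond], fc[~cond])
            entry["ks"] = {"D": d, "p": p}
        else:
            entry["ks"] = {"D": None, "p": None, "degenerate": True}
        results["pausing_x_de"] = entry

    if enriched_ids is not None:
        enriched_ids = set(enriched_ids)
        cond = pausing["paused"].to_numpy(dtype=bool)
        enr = pausing["gene_id"].isin(enriched_ids).to_numpy()
        entry = _chi_square_or_flag(_table_from_masks(cond, enr))
        entry["n_joint"] = len(pausing)
        if usage_freq is not None and cond.any() and (~cond).any():
            freq = pausing.join(usage_freq.rename("freq"), on="gene_id")["freq"].to_numpy(dtype=float)
            ok = ~np.isnan(freq)
            d, p = ks_two_sample(freq[ok & cond], freq[ok & ~cond])
            entry["ks"] = {"D": d, "p": p}
        results["pausing_x_enrichment"] = entry

    if run_counts is not None:
        joined = run_counts.join(paused_by_gene, on="gene_id").dropna(subset=["paused"])
        for label, sub in (
            ("pausing_x_runs", joined),
            (
                "pausing_x_runs_enriched_only",
                joined.loc[joined["gene_id"].isin(enriched_ids)] if enriched_ids is not None else None,
            ),
        ):
            if sub is None:
                continue
            cond = sub["paused"].to_numpy(dtype=bool)
            counts = sub["actual"].to_numpy(dtype=float)
            if cond.any() and (~cond).any():
                u, p_mw = compare_run_vectors(counts[cond], counts[~cond])
                d, p_ks = ks_two_sample(counts[cond], counts[~cond])
                results[label] = {
                    "n_paused": int(cond.sum()),
                    "n_unpaused": int((~cond).sum()),
                    "mannwhitney": {"U": u, "p": p_mw},
                    "ks": {"D": d, "p": p_ks},
                    "degenerate": False,
                }
            else:
                results[label] = {"degenerate": True, "reason": "a pausing stratum is empty"}
    return results
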