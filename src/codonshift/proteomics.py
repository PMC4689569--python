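"""SILAC proteomics: replicate aggregation, filtering, and differential calls.

Protein ratios (sample / heavy internal standard, linear scale) are averaged
over peptides, proteins must be quantified in at least two replicates per
strain, and mutant-vs-wild-type differential expression is a two-sided
equal-variance t-test on log2 replicate ratios combined with a fold-change
threshold (down: fold < 1/1.2; up: fold > 1.2; both require p < 0.05).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_ALPHA = 0.05
DEFAULT_FC = 1.2
DEFAULT_MIN_REPS = 2


def protein_ratio(peptide_ratios) -> float:
    """Protein-level ratio = arithmetic mean of its peptide ratios.

    An empty list yields NaN (missing value for that replicate).
    """
    vals = np.asarray(list(peptide_ratios), dtype=float)
    if vals.size == 0:
        return math.nan
    if np.any(vals <= 0):
        raise ValueError("peptide ratios must be positive")
    return float(vals.mean())


def rsd(values) -> float:
    """Relative standard deviation |sample sd / mean| of replicate ratios."""
    vals = np.asarray(list(values), dtype=float)
    if vals.size < 2:
        raise ValueError("rsd needs at least 2 values")
    mean = vals.mean()
    if mean == 0:
        raise ValueError("rsd undefined for zero mean")
    return float(abs(vals.std(ddof=1) / mean))


def _strain_columns(df: pd.DataFrame) -> tuple[list[str], list[str]]:
    wt = [c for c in df.columns if c.startswith("wt_r")]
    mut = [c for c in df.columns if c.startswith("mut_r")]
    if not wt or not mut:
        raise ValueError("expected replicate columns named wt_r* and mut_r*")
    return wt, mut


def replicate_filter(df: pd.DataFrame, min_reps: int = DEFAULT_MIN_REPS) -> pd.DataFrame:
    """Keep proteins with >= min_reps non-missing replicate ratios in each strain."""
    wt, mut = _strain_columns(df)
    ok = (df[wt].notna().sum(axis=1) >= min_reps) & (df[mut].notna().sum(axis=1) >= min_reps)
    return df.loc[ok].reset_index(drop=True)


@dataclass(frozen=True)
class DECall:
    gene_id: str
    fold_change: float  # mean(mut ratios) / mean(wt ratios), linear scale
    p_value: float
    call: str  # down | up | unchanged


def _ttest_log2(wt: np.ndarray, mut: np.ndarray) -> np.ndarray:
    """Row-wise two-sided equal-variance t-test on log2 ratios; NaN-aware.

    Degenerate rows (zero variance in both groups): p = 1 if the group
    means are equal, else p = 0 (infinite t).
    """
    lw = np.log2(wt)
    lm = np.log2(mut)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # near-identical rows trip scipy's precision-loss warning; those rows
        # are overwritten by the explicit degenerate handling below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(lm, lw, axis=1, equal_var=True, nan_policy="omit")
        p = np.asarray(res.pvalue, dtype=float)
    mw = np.nanmean(lw, axis=1)
    mm = np.nanmean(lm, axis=1)
    vw = np.nanvar(lw, axis=1)
    vm = np.nanvar(lm, axis=1)
    degenerate = np.isnan(p) & (vw == 0) & (vm == 0)
    p[degenerate & np.isclose(mw, mm)] = 1.0
    p[degenerate & ~np.isclose(mw, mm)] = 0.0
    return p


def de_table(
    df: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    fc: float = DEFAULT_FC,
    min_reps: int = DEFAULT_MIN_REPS,
) -> pd.DataFrame:
    """Differential-expression table from a replicate-ratio table.

    Input columns: gene_id, wt_r1..wt_rk, mut_r1..mut_rk (linear ratios,
    NaN = missing), optional abundance. Output: gene_id, fold_change,
    p_value, call (+ abundance if present), replicate-filtered.
    """
    if fc < 1.0:
        raise ValueError("fold-change threshold must be >= 1")
    kept = replicate_filter(df, min_reps=min_reps)
    wt_cols, mut_cols = _strain_columns(kept)
    wt = kept[wt_cols].to_numpy(dtype=float)
    mut = kept[mut_cols].to_numpy(dtype=float)
    if np.any(wt[~np.isnan(wt)] <= 0) or np.any(mut[~np.isnan(mut)] <= 0):
        raise ValueError("replicate ratios must be positive")
    fold = np.nanmean(mut, axis=1) / np.nanmean(wt, axis=1)
    p = _ttest_log2(wt, mut)
    call = np.full(len(kept), "unchanged", dtype=object)
    call[(fold < 1.0 / fc) & (p < alpha)] = "down"
    call[(fold > fc) & (p < alpha)] = "up"
    out = pd.DataFrame(
        {"gene_id": kept["gene_id"], "fold_change": fold, "p_value": p, "call": call}
    )
    if "abundance" in kept.columns:
        out["abundance"] = kept["abundance"].to_numpy()
    return out


def differential_call(
    gene_id: str,
    ratios_wt,
    ratios_mut,
    alpha: float = DEFAULT_ALPHA,
    fc: float = DEFAULT_FC,
) -> DECall:
    """Single-protein differential call (see :func:`de_table` for the rule)."""
    wt = np.asarray(list(ratios_wt), dtype=float)[None, :]
    mut = np.asarray(list(ratios_mut), dtype=float)[None, :]
    if wt.size < 2 or mut.size < 2:
        raise ValueError("need >= 2 replicates per strain (apply replicate_filter first)")
    if fc < 1.0:
        raise ValueError("fold-change threshold must be >= 1")
    fold = float(np.nanmean(mut) / np.nanmean(wt))
    p = float(_ttest_log2(wt, mut)[0])
    if fold < 1.0 / fc and p < alpha:
        call = "down"
    elif fold > fc and p < alpha:
        call = "up"
    else:
        call = "unchanged"
    return DECall(gene_id=gene_id, fold_change=fold, p_value=p, call=call)
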