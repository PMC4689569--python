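"""Group statistics for codon-enriched protein sets and resampling nulls.

For a group of proteins whose genes over-use a focal codon, the module
computes the fraction significantly down-regulated and the down/up ratio
(D/U), and asks how often random draws of equal size from the non-enriched
pool reach a value at least as large (inclusive empirical p). Confound
controls: co-enrichment exclusion, an mRNA-change filter, abundance-matched
(decile-stratified) resampling, codon-frequency binning, and Spearman rank
correlation between codon usage and protein change.

Both group statistics depend only on how many drawn proteins are down- and
up-regulated, so resampling draws the (down, up, other) counts directly
from the multivariate hypergeometric distribution — exactly equivalent to
sampling gene subsets without replacement, at a fraction of the cost.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_N_SAMPLINGS = 100_000
DEFAULT_N_BINS_ABUNDANCE = 10
DEFAULT_FREQ_BIN_WIDTH = 10.0
DEFAULT_N_FREQ_BINS = 7
STATISTICS = ("percent_down", "du")


@dataclass(frozen=True)
class GroupStats:
    """Down/up composition of a protein group."""

    n: int
    n_down: int
    n_up: int

    def __post_init__(self) -> None:
        if self.n_down + self.n_up > self.n:
            raise ValueError("down + up exceeds group size")

    @property
    def percent_down(self) -> float:
        return 100.0 * self.n_down / self.n if self.n else math.nan

    @property
    def du(self) -> float:
        """Down/up ratio; NaN (undefined) when the group has no up calls."""
        return self.n_down / self.n_up if self.n_up > 0 else math.nan

    @property
    def du_defined(self) -> bool:
        return self.n_up > 0

    def statistic(self, which: str) -> float:
        if which not in STATISTICS:
            raise ValueError(f"unknown statistic {which!r}")
        return self.percent_down if which == "percent_down" else self.du


def _call_series(calls: pd.DataFrame) -> pd.Series:
    return calls.set_index("gene_id")["call"]


def codon_group(usage: pd.DataFrame, codon: str, quantified_ids) -> set[str]:
    """Genes called 'over' for a codon, intersected with the quantified proteome."""
    over = set(usage.loc[(usage["codon"] == codon) & (usage["call"] == "over"), "gene_id"])
    return over & set(quantified_ids)


def group_stats(members, calls: pd.DataFrame) -> GroupStats:
    """Count down/up calls within a gene-id group; every member needs a call."""
    members = set(members)
    series = _call_series(calls)
    missing = members - set(series.index)
    if missing:
        raise KeyError(f"{len(missing)} group members lack DE calls, e.g. {sorted(missing)[:3]}")
    sub = series.loc[list(members)]
    return GroupStats(n=len(members), n_down=int((sub == "down").sum()), n_up=int((sub == "up").sum()))


@dataclass(frozen=True)
class ResamplingResult:
    """Observed group statistic against equal-size random draws from a pool."""

    observed: GroupStats
    statistic: str
    n_samplings: int
    null_values: np.ndarray  # the sampled statistic, one per draw (NaN = undefined D/U)
    empirical_p: float  # inclusive: fraction of draws >= observed (undefined D/U counts)
    seed: int


def _null_counts(
    pool_stats: GroupStats, group_size: int, n_samplings: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    colors = [
        pool_stats.n_down,
        pool_stats.n_up,
        pool_stats.n - pool_stats.n_down - pool_stats.n_up,
    ]
    draws = rng.multivariate_hypergeometric(colors, group_size, size=n_samplings)
    return draws[:, 0], draws[:, 1]


def _empirical_p(null_down, null_up, observed: GroupStats, statistic: str) -> tuple[np.ndarray, float]:
    n_samplings = null_down.size
    g = observed.n
    if statistic == "percent_down":
        null_vals = 100.0 * null_down / g
        hits = null_vals >= observed.percent_down
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            null_vals = np.where(null_up > 0, null_down / np.maximum(null_up, 1), np.nan)
        undefined = null_up == 0
        if observed.du_defined:
            # draws with no up calls are treated as at-least-as-extreme
            hits = undefined | (np.nan_to_num(null_vals, nan=-1.0) >= observed.du)
        else:
            hits = undefined
    return null_vals, float(np.count_nonzero(hits)) / n_samplings


def resample_null(
    group,
    pool,
    calls: pd.DataFrame,
    statistic: str = "percent_down",
    n_samplings: int = DEFAULT_N_SAMPLINGS,
    seed: int = 0,
) -> ResamplingResult:
    """Empirical p for a group statistic under random equal-size draws.

    ``pool`` is the complement set (non-enriched quantified proteins); draws
    are without replacement. Inclusive tail per 'a value no less than'.
    """
    group = set(group)
    pool = set(pool)
    if statistic not in STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}")
    if group & pool:
        raise ValueError("pool must be disjoint from the group")
    if len(pool) < len(group):
        raise ValueError(f"pool ({len(pool)}) smaller than group ({len(group)})")
    observed = group_stats(group, calls)
    pool_stats = group_stats(pool, calls)
    rng = np.random.default_rng(seed)
    null_down, null_up = _null_counts(pool_stats, observed.n, n_samplings, rng)
    null_vals, p = _empirical_p(null_down, null_up, observed, statistic)
    return ResamplingResult(observed, statistic, n_samplings, null_vals, p, seed)


def abundance_matched_null(
    group,
    pool,
    abundance: pd.Series,
    calls: pd.DataFrame,
    statistic: str = "du",
    n_bins: int = DEFAULT_N_BINS_ABUNDANCE,
    n_samplings: int = DEFAULT_N_SAMPLINGS,
    seed: int = 0,
) -> ResamplingResult:
    """Resampling null stratified by protein abundance.

    Abundance deciles are defined on the union of group and pool (ties
    broken by stable rank); every draw takes exactly the group's per-bin
    member count from pool members of the same bin, so the group's
    abundance-bin histogram is preserved in every iteration.
    """
    group = sorted(set(group))
    pool = sorted(set(pool))
    if set(group) & set(pool):
        raise ValueError("pool must be disjoint from the group")
    union = sorted(group + pool)  # neutral order so rank ties never encode membership
    missing = [g for g in union if g not in abundance.index or pd.isna(abundance.get(g))]
    if missing:
        raise KeyError(f"abundance missing for {len(missing)} proteins, e.g. {missing[:3]}")
    vals = abundance.loc[union]
    # tied abundances share a bin (average rank): identical values collapse to
    # one stratum, so flat abundance degenerates to plain resampling
    ranks = vals.rank(method="average")
    bins = np.clip(((ranks - 0.5) * n_bins / len(union)).astype(int), 0, n_bins - 1)
    bin_of = dict(zip(union, bins))
    series = _call_series(calls)
    observed = group_stats(group, calls)
    rng = np.random.default_rng(seed)
    total_down = np.zeros(n_samplings, dtype=np.int64)
    total_up = np.zeros(n_samplings, dtype=np.int64)
    for b in range(n_bins):
        g_b = [g for g in group if bin_of[g] == b]
        if not g_b:
            continue
        p_b = [g for g in pool if bin_of[g] == b]
        if len(p_b) < len(g_b):
            raise ValueError(
                f"abundance bin {b}: pool has {len(p_b)} proteins but the group needs {len(g_b)}"
            )
        sub = series.loc[p_b]
        pool_stats = GroupStats(len(p_b), int((sub == "down").sum()), int((sub == "up").sum()))
        d, u = _null_counts(pool_stats, len(g_b), n_samplings, rng)
        total_down += d
        total_up += u
    null_vals, p = _empirical_p(total_down, total_up, observed, statistic)
    return ResamplingResult(observed, statistic, n_samplings, null_vals, p, seed)


def exclusion_analysis(
    focal: str, other: str, groups: dict[str, set[str]], calls: pd.DataFrame
) -> tuple[GroupStats | None, GroupStats | None]:
    """Group statistics after removing co-enriched members, both directions.

    Returns (focal minus other's members, other minus focal's members);
    an emptied group yields None for that side.
    """
    if focal == other:
        raise ValueError("focal and other codon must differ")
    focal_left = groups[focal] - groups[other]
    other_left = groups[other] - groups[focal]
    return (
        group_stats(focal_left, calls) if focal_left else None,
        group_stats(other_left, calls) if other_left else None,
    )


def mrna_filter(
    calls: pd.DataFrame,
    mrna: pd.DataFrame,
    fc: float = 1.2,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, int]:
    """Drop significantly changed proteins explained by same-direction mRNA change.

    A protein call (down/up) is removed when its mRNA moved the same way
    with |fold| > fc and p < alpha. ``mrna`` columns: gene_id, log2fc, p.
    Genes absent from the mRNA table pass through. Returns (filtered calls,
    number removed).
    """
    m = mrna.set_index("gene_id")
    log2_fc = math.log2(fc)
    joined = calls.join(m[["log2fc", "p"]], on="gene_id")
    sig_m = joined["p"] < alpha
    explained = (
        (joined["call"] == "down") & (joined["log2fc"] < -log2_fc) & sig_m
    ) | ((joined["call"] == "up") & (joined["log2fc"] > log2_fc) & sig_m)
    explained = explained.fillna(False)
    return calls.loc[~explained.to_numpy()].reset_index(drop=True), int(explained.sum())


def bin_by_frequency(
    calls: pd.DataFrame,
    usage: pd.DataFrame,
    codon: str,
    bin_width: float = DEFAULT_FREQ_BIN_WIDTH,
    n_bins: int = DEFAULT_N_FREQ_BINS,
) -> pd.DataFrame:
    """Per-bin D/U over codon frequency bins [0,10), [10,20), ... (last open-ended).

    Returns one row per bin: bin_index, freq_lo, freq_hi (NaN for the
    open-ended last bin), n, n_down, n_up, mean_freq, percent_down, du
    (NaN where undefined).
    """
    freq = usage.loc[usage["codon"] == codon].set_index("gene_id")["freq_per_1000"]
    joined = calls.join(freq, on="gene_id").dropna(subset=["freq_per_1000"])
    idx = np.minimum((joined["freq_per_1000"] // bin_width).astype(int), n_bins - 1)
    rows = []
    for b in range(n_bins):
        sub = joined.loc[idx == b]
        n_down = int((sub["call"] == "down").sum())
        n_up = int((sub["call"] == "up").sum())
        rows.append(
            {
                "bin_index": b,
                "freq_lo": b * bin_width,
                "freq_hi": (b + 1) * bin_width if b < n_bins - 1 else math.nan,
                "n": len(sub),
                "n_down": n_down,
                "n_up": n_up,
                "mean_freq": float(sub["freq_per_1000"].mean()) if len(sub) else math.nan,
                "percent_down": 100.0 * n_down / len(sub) if len(sub) else math.nan,
                "du": n_down / n_up if n_up > 0 else math.nan,
            }
        )
    return pd.DataFrame(rows)


def freq_change_correlation(freq, log2_changes) -> tuple[float, float]:
    """Spearman rank correlation between codon frequency and protein change."""
    x = np.asarray(freq, dtype=float)
    y = np.asarray(log2_changes, dtype=float)
    if x.size != y.size:
        raise ValueError("paired vectors must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
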