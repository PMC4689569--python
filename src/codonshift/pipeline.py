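"""End-to-end orchestration: usage -> DE -> enrichment -> runs -> pausing.

Produces per-stage tables and one consolidated JSON report. Every random
procedure derives its stream from the config seed, so a report can be
regenerated bit-exactly from its logged config.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .codon_stats import CodingSequence, read_cds_fasta, usage_table
from .config import RunConfig
from .enrichment import (
    abundance_matched_null,
    bin_by_frequency,
    codon_group,
    exclusion_analysis,
    freq_change_correlation,
    group_stats,
    mrna_filter,
    resample_null,
)
from .io import read_table, write_json_report, write_table
from .pausing import call_pausing, pausing_cross_tabs
from .proteomics import de_table
from .runs import compare_run_vectors, run_null_table

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending context."""


def _sanitize(obj):
    """NaN/numpy -> JSON-safe (None / plain Python) recursively."""
    if isinstance(obj, dict):
        return {str(k): _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if math.isnan(f) or math.isinf(f) else f
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def _stats_dict(gs) -> dict:
    if gs is None:
        return {"empty": True}
    return {
        "n": gs.n,
        "n_down": gs.n_down,
        "n_up": gs.n_up,
        "percent_down": gs.percent_down,
        "du": gs.du if gs.du_defined else None,
        "du_defined": gs.du_defined,
    }


def enrichment_report(
    usage: pd.DataFrame,
    calls: pd.DataFrame,
    cfg: RunConfig,
    mrna: pd.DataFrame | None = None,
) -> dict:
    """Group statistics, resampling nulls, and controls for each focal codon."""
    quantified = set(calls["gene_id"])
    groups = {c: codon_group(usage, c, quantified) for c in cfg.focal_codons}
    if cfg.apply_mrna_filter and mrna is not None:
        calls_used, n_removed = mrna_filter(calls, mrna, fc=cfg.fc, alpha=cfg.alpha_de)
        quantified = set(calls_used["gene_id"])
        groups = {c: g & quantified for c, g in groups.items()}
    else:
        calls_used, n_removed = calls, 0
    out: dict = {"mrna_filter": {"applied": mrna is not None and cfg.apply_mrna_filter,
                                 "n_removed": n_removed}}
    log2fc = np.log2(calls_used["fold_change"].to_numpy(dtype=float))
    freq_by_codon = {
        c: usage.loc[usage["codon"] == c].set_index("gene_id")["freq_per_1000"]
        for c in cfg.focal_codons
    }
    for codon in cfg.focal_codons:
        group = groups[codon]
        pool = quantified - group
        entry: dict = {"group": _stats_dict(group_stats(group, calls_used) if group else None)}
        if group and len(pool) >= len(group):
            for stat in ("percent_down", "du"):
                res = resample_null(group, pool, calls_used, statistic=stat,
                                    n_samplings=cfg.n_samplings, seed=cfg.seed)
                entry[f"empirical_p_{stat}"] = res.empirical_p
            if cfg.match_abundance and "abundance" in calls_used.columns:
                ab = calls_used.set_index("gene_id")["abundance"]
                res = abundance_matched_null(group, pool, ab, calls_used, statistic="du",
                                             n_bins=cfg.n_bins_abundance,
                                             n_samplings=cfg.n_samplings, seed=cfg.seed)
                entry["empirical_p_du_abundance_matched"] = res.empirical_p
        else:
            entry["degenerate"] = True
        others = [c for c in cfg.focal_codons if c != codon]
        entry["exclusion"] = {}
        for other in others:
            focal_left, other_left = exclusion_analysis(codon, other, groups, calls_used)
            entry["exclusion"][other] = {
                "focal_minus_other": _stats_dict(focal_left),
                "other_minus_focal": _stats_dict(other_left),
            }
        bins = bin_by_frequency(calls_used, usage, codon,
                                bin_width=cfg.freq_bin_width, n_bins=cfg.n_bins_freq)
        entry["frequency_bins"] = bins.to_dict(orient="records")
        joined = calls_used.join(freq_by_codon[codon], on="gene_id").dropna(subset=["freq_per_1000"])
        if len(joined) >= 3:
            rho, p = freq_change_correlation(
                joined["freq_per_1000"].to_numpy(),
                np.log2(joined["fold_change"].to_numpy(dtype=float)),
            )
            entry["spearman"] = {"rho": rho, "p": p}
        out[codon] = entry
    out["_log2fc_summary"] = {"n": int(log2fc.size), "mean": float(log2fc.mean())}
    return out


def run_pipeline(
    cfg: RunConfig,
    genes: list[CodingSequence],
    proteomics: pd.DataFrame,
    mrna: pd.DataFrame | None = None,
    rpkm: pd.DataFrame | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Execute all stages on in-memory inputs and return the report dict.

    ``rpkm`` (and the pausing stage) and ``mrna`` are optional. When
    ``outdir`` is given, per-stage tables and report.json are written there.
    """
    report: dict = {"version": __version__, "config": cfg.to_dict()}
    targets = set(cfg.focal_codons)

    try:
        usage = usage_table(genes, alpha=cfg.alpha_enrich)
    except Exception as exc:  # pragma: no cover - defensive
        raise PipelineError(f"codon-usage stage failed: {exc}") from exc
    n_over = usage.loc[usage["call"] == "over"].groupby("codon")["gene_id"].count()
    report["codon_usage"] = {
        "n_genes": len(genes),
        "n_enriched": {c: int(n_over.get(c, 0)) for c in cfg.focal_codons},
    }

    try:
        calls = de_table(proteomics, alpha=cfg.alpha_de, fc=cfg.fc)
    except Exception as exc:
        raise PipelineError(f"differential-expression stage failed: {exc}") from exc
    whole = group_stats(set(calls["gene_id"]), calls)
    report["de"] = _stats_dict(whole)

    try:
        report["enrichment"] = enrichment_report(usage, calls, cfg, mrna=mrna)
    except Exception as exc:
        raise PipelineError(f"enrichment stage failed: {exc}") from exc

    try:
        run_tab = run_null_table(genes, targets=targets, k=cfg.run_k,
                                 n_shuffles=cfg.n_shuffles, master_seed=cfg.seed)
        actual = run_tab["actual"].to_numpy(dtype=float)
        u, p = compare_run_vectors(actual, run_tab["null_mean"].to_numpy(dtype=float))
        runs_report = {"k": cfg.run_k, "n_shuffles": cfg.n_shuffles,
                       "actual_vs_randomized": {"U": u, "p": p},
                       "frac_actual_above_null": float(np.mean(actual > run_tab["null_mean"]))}
        down_ids = set(calls.loc[calls["call"] == "down", "gene_id"])
        by_gene = run_tab.set_index("gene_id")["actual"]
        quantified = [g for g in calls["gene_id"] if g in by_gene.index]
        dn = by_gene.loc[[g for g in quantified if g in down_ids]].to_numpy(dtype=float)
        ot = by_gene.loc[[g for g in quantified if g not in down_ids]].to_numpy(dtype=float)
        if dn.size and ot.size:
            u, p = compare_run_vectors(dn, ot)
            runs_report["down_vs_other"] = {"U": u, "p": p}
        enriched_union = set().union(*(codon_group(usage, c, set(calls["gene_id"]))
                                       for c in cfg.focal_codons))
        dn_e = by_gene.loc[[g for g in quantified if g in down_ids and g in enriched_union]]
        ot_e = by_gene.loc[[g for g in quantified if g not in down_ids and g in enriched_union]]
        if len(dn_e) and len(ot_e):
            u, p = compare_run_vectors(dn_e.to_numpy(float), ot_e.to_numpy(float))
            runs_report["down_vs_other_enriched_only"] = {"U": u, "p": p}
        report["runs"] = runs_report
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"codon-runs stage failed: {exc}") from exc

    pausing_tab = excluded = None
    if rpkm is not None:
        try:
            pausing_tab, excluded = call_pausing(rpkm, fold_cutoff=cfg.pausing_cutoff,
                                                 t_floor=cfg.t_floor)
            enriched_union = set().union(*(codon_group(usage, c, set(usage["gene_id"]))
                                           for c in cfg.focal_codons))
            focal_usage = usage.loc[usage["codon"].isin(cfg.focal_codons)]
            combined_freq = focal_usage.groupby("gene_id")["freq_per_1000"].sum()
            tabs = pausing_cross_tabs(pausing_tab, calls=calls, enriched_ids=enriched_union,
                                      run_counts=run_tab, usage_freq=combined_freq)
            report["pausing"] = {
                "n_genes": len(pausing_tab),
                "n_paused": int(pausing_tab["paused"].sum()),
                "n_excluded_low_t": len(excluded),
                "associations": tabs,
            }
        except Exception as exc:
            raise PipelineError(f"pausing stage failed: {exc}") from exc

    report = _sanitize(report)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_table(usage, outdir / "usage.tsv")
        write_table(calls, outdir / "de.tsv")
        write_table(run_tab, outdir / "runs.tsv")
        if pausing_tab is not None:
            write_table(pausing_tab, outdir / "pausing.tsv")
            if excluded is not None and len(excluded):
                write_table(excluded, outdir / "pausing_excluded.tsv")
        write_json_report(report, outdir / "report.json")
        logger.info("report written to %s (seed=%d)", outdir, cfg.seed)
    return report


def run_pipeline_from_paths(
    cfg: RunConfig,
    fasta,
    proteomics,
    mrna=None,
    rpkm=None,
    outdir=None,
) -> dict:
    """File-based front end of :func:`run_pipeline`."""
    genes = read_cds_fasta(fasta)
    prot = read_table(proteomics)
    mrna_df = read_table(mrna) if mrna else None
    rpkm_df = read_table(rpkm) if rpkm else None
    return run_pipeline(cfg, genes, prot, mrna=mrna_df, rpkm=rpkm_df, outdir=outdir)


def round_for_display(report, ndigits: int = 1):
    """One-decimal display rounding of percent/ratio fields (print precision)."""
    keys = {"percent_down", "du", "mean_freq"}
    if isinstance(report, dict):
        return {
            k: (round(v, ndigits) if k in keys and isinstance(v, (int, float)) and v is not None
                else round_for_display(v, ndigits))
            for k, v in report.items()
        }
    if isinstance(report, list):
        return [round_for_display(v, ndigits) for v in report]
    return report
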