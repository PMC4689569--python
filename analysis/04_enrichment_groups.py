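"""Test whether codon-enriched protein groups are selectively down-regulated.

For each focal codon (AGA, GAA): group percent-down and D/U, empirical p
against 20,000 equal-size draws from the non-enriched pool, the same after
removing proteins whose mRNA moved with them, an abundance-matched
(decile-stratified) null, co-enrichment exclusion, 7-bin frequency trends,
and the Spearman correlation between usage and protein change.
"""

import json
from pathlib import Path

import numpy as np

from codonshift.enrichment import (
    abundance_matched_null,
    bin_by_frequency,
    codon_group,
    exclusion_analysis,
    freq_change_correlation,
    group_stats,
    mrna_filter,
    resample_null,
)
from codonshift.io import read_table, write_table

ROOT = Path(__file__).resolve().parent.parent / "results"
N_SAMPLINGS = 20_000
SEED = 17
FOCAL = ("AGA", "GAA")


def main() -> None:
    usage = read_table(ROOT / "usage.tsv")
    calls = read_table(ROOT / "de.tsv")
    mrna = read_table(ROOT / "data" / "mrna.tsv")
    quantified = set(calls["gene_id"])
    groups = {c: codon_group(usage, c, quantified) for c in FOCAL}
    calls_f, n_removed = mrna_filter(calls, mrna)
    print(f"mRNA filter removed {n_removed} proteins whose mRNA moved with them")

    report = {"n_samplings": N_SAMPLINGS, "seed": SEED, "mrna_removed": n_removed}
    abundance = calls.set_index("gene_id")["abundance"]
    for codon in FOCAL:
        group, pool = groups[codon], quantified - groups[codon]
        gs = group_stats(group, calls)
        res_pct = resample_null(group, pool, calls, "percent_down", N_SAMPLINGS, seed=SEED)
        res_du = resample_null(group, pool, calls, "du", N_SAMPLINGS, seed=SEED)
        res_ab = abundance_matched_null(group, pool, abundance, calls, "du",
                                        n_samplings=N_SAMPLINGS, seed=SEED)
        other = [c for c in FOCAL if c != codon][0]
        excl_focal, _ = exclusion_analysis(codon, other, groups, calls)
        bins = bin_by_frequency(calls, usage, codon)
        write_table(bins, ROOT / f"bins_{codon}.tsv")
        freq = usage.loc[usage["codon"] == codon].set_index("gene_id")["freq_per_1000"]
        joined = calls.join(freq, on="gene_id").dropna(subset=["freq_per_1000"])
        rho, p_rho = freq_change_correlation(
            joined["freq_per_1000"], np.log2(joined["fold_change"])
        )
        report[codon] = {
            "n": gs.n, "n_down": gs.n_down, "n_up": gs.n_up,
            "percent_down": gs.percent_down,
            "du": gs.du if gs.du_defined else None,
            "empirical_p_percent_down": res_pct.empirical_p,
            "empirical_p_du": res_du.empirical_p,
            "empirical_p_du_abundance_matched": res_ab.empirical_p,
            "exclusion_minus_" + other: None if excl_focal is None else {
                "n": excl_focal.n, "percent_down": excl_focal.percent_down,
                "du": excl_focal.du if excl_focal.du_defined else None,
            },
            "spearman": {"rho": rho, "p": p_rho},
        }
        print(f"{codon}: n={gs.n}, {gs.percent_down:.1f}% down, "
              f"D/U={gs.du:.2f}" if gs.du_defined else f"{codon}: n={gs.n}")
        print(f"  empirical p (percent-down / D/U / abundance-matched D/U): "
              f"{res_pct.empirical_p:.5f} / {res_du.empirical_p:.5f} / {res_ab.empirical_p:.5f}")
        print(f"  Spearman usage vs log2 change: rho={rho:.3f} (p={p_rho:.2e})")

    (ROOT / "enrichment.json").write_text(json.dumps(report, indent=2) + "\n")
    print(f"details -> {ROOT / 'enrichment.json'}")


if __name__ == "__main__":
    main()
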