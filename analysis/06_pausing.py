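"""Integrate ribosome-footprint FP/T ratios with the proteome.

Calls per-gene pausing (mutant FP/T more than 1.2x wild type) and tests
its association with down-regulation (chi-square + K-S), with AGA/GAA
enrichment (chi-square + K-S), and with codon-run counts (Mann-Whitney +
K-S, also restricted to enriched genes).
"""

import json
from pathlib import Path

from codonshift.io import read_table, write_table
from codonshift.pausing import call_pausing, pausing_cross_tabs
from codonshift.pipeline import _sanitize

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    rpkm = read_table(ROOT / "data" / "rpkm.tsv")
    pausing, excluded = call_pausing(rpkm, fold_cutoff=1.2, t_floor=1.0)
    write_table(pausing, ROOT / "pausing.tsv")
    print(f"{len(pausing)} genes: {int(pausing['paused'].sum())} paused, "
          f"{len(excluded)} excluded below the T floor")

    calls = read_table(ROOT / "de.tsv")
    usage = read_table(ROOT / "usage.tsv")
    runs = read_table(ROOT / "runs.tsv")
    focal = usage.loc[usage["codon"].isin(["AGA", "GAA"])]
    enriched = set(focal.loc[focal["call"] == "over", "gene_id"])
    combined_freq = focal.groupby("gene_id")["freq_per_1000"].sum()
    tabs = _sanitize(pausing_cross_tabs(pausing, calls=calls, enriched_ids=enriched,
                                        run_counts=runs, usage_freq=combined_freq))
    (ROOT / "pausing_associations.json").write_text(json.dumps(tabs, indent=2) + "\n")
    for key in ("pausing_x_de", "pausing_x_enrichment"):
        t = tabs[key]
        print(f"  {key}: table={t['table']} chi2 p={t['p']:.2e} KS p={t['ks']['p']:.2e}")
    for key in ("pausing_x_runs", "pausing_x_runs_enriched_only"):
        t = tabs[key]
        if not t.get("degenerate"):
            print(f"  {key}: Mann-Whitney p={t['mannwhitney']['p']:.2e} "
                  f"KS p={t['ks']['p']:.2e}")
    print(f"details -> {ROOT / 'pausing_associations.json'}")


if __name__ == "__main__":
    main()
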