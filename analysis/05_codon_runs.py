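"""Ask whether AGA/GAA codons cluster physically along transcripts.

Counts overlapping 3-codon runs of {AGA, GAA} per gene, compares each
against 300 composition-preserving codon shuffles, and contrasts run
counts between down-regulated and other proteins (Mann-Whitney), overall
and within enriched genes only.
"""

from pathlib import Path

from codonshift.codon_stats import read_cds_fasta
from codonshift.io import read_table, write_table
from codonshift.runs import compare_run_vectors, run_null_table

ROOT = Path(__file__).resolve().parent.parent / "results"
TARGETS = frozenset({"AGA", "GAA"})
N_SHUFFLES = 300
SEED = 17


def main() -> None:
    genes = read_cds_fasta(ROOT / "data" / "genes.fasta")
    tab = run_null_table(genes, TARGETS, k=3, n_shuffles=N_SHUFFLES, master_seed=SEED)
    write_table(tab, ROOT / "runs.tsv")
    u, p = compare_run_vectors(tab["actual"].to_numpy(float), tab["null_mean"].to_numpy(float))
    print(f"3-codon runs for {len(tab)} genes ({N_SHUFFLES} shuffles each) -> {ROOT/'runs.tsv'}")
    print(f"  actual vs randomized (Mann-Whitney, two-sided): U={u:.0f}, p={p:.2e}")

    calls = read_table(ROOT / "de.tsv")
    usage = read_table(ROOT / "usage.tsv")
    by_gene = tab.set_index("gene_id")["actual"]
    down = set(calls.loc[calls["call"] == "down", "gene_id"])
    quantified = [g for g in calls["gene_id"] if g in by_gene.index]
    dn = by_gene.loc[[g for g in quantified if g in down]].to_numpy(float)
    ot = by_gene.loc[[g for g in quantified if g not in down]].to_numpy(float)
    u, p = compare_run_vectors(dn, ot)
    print(f"  down-regulated ({dn.size}) vs other ({ot.size}): p={p:.2e}")

    enriched = set(usage.loc[(usage["call"] == "over") & usage["codon"].isin(TARGETS), "gene_id"])
    dn_e = by_gene.loc[[g for g in quantified if g in down and g in enriched]].to_numpy(float)
    ot_e = by_gene.loc[[g for g in quantified if g not in down and g in enriched]].to_numpy(float)
    if dn_e.size and ot_e.size:
        u, p = compare_run_vectors(dn_e, ot_e)
        print(f"  same, enriched genes only ({dn_e.size} vs {ot_e.size}): p={p:.2e}")


if __name__ == "__main__":
    main()
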