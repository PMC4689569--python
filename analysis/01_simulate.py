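"""Generate the synthetic study universe with planted effects.

Writes a 5,000-gene CDS FASTA (10% of genes enriched in AGA/GAA and
carrying planted codon runs), a 3+3-replicate SILAC ratio table whose true
protein changes track AGA+GAA usage, a mostly-null mRNA table, and an FP/T
rpkm table with pausing tied to the planted runs — plus the truth table.
"""

from pathlib import Path

from codonshift.io import write_fasta, write_table
from codonshift.simulate import SyntheticConfig, generate_all

SEED = 17
OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    cfg = SyntheticConfig(master_seed=SEED)
    bundle = generate_all(cfg)
    OUT.mkdir(parents=True, exist_ok=True)
    write_fasta(bundle["genes"], OUT / "genes.fasta")
    for name in ("proteomics", "mrna", "rpkm", "truth"):
        write_table(bundle[name], OUT / f"{name}.tsv")
    truth = bundle["truth"]
    print(f"wrote {cfg.n_genes} genes to {OUT}")
    print(f"  enriched genes: {int(truth['is_enriched'].sum())}")
    print(f"  genes with planted runs: {int((truth['planted_runs'] > 0).sum())}")
    print(f"  truly down (fold < 1/1.2): {int(truth['is_de_down'].sum())}")
    print(f"  truly paused: {int(truth['is_paused'].sum())}")


if __name__ == "__main__":
    main()
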