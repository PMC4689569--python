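"""Call differential protein expression between the two strains.

Proteins quantified in >= 2 replicates per strain are tested with a
two-sided equal-variance t-test on log2 ratios; calls need p < 0.05 and a
fold change beyond 1.2 in either direction.
"""

from pathlib import Path

from codonshift.enrichment import group_stats
from codonshift.io import read_table, write_table
from codonshift.proteomics import de_table

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    prot = read_table(ROOT / "data" / "proteomics.tsv")
    calls = de_table(prot, alpha=0.05, fc=1.2)
    write_table(calls, ROOT / "de.tsv")
    gs = group_stats(set(calls["gene_id"]), calls)
    print(f"{gs.n} quantified proteins -> {ROOT / 'de.tsv'}")
    print(f"  down-regulated: {gs.n_down} ({gs.percent_down:.1f}%)")
    print(f"  up-regulated:   {gs.n_up}")
    if gs.du_defined:
        print(f"  D/U ratio: {gs.du:.2f}")


if __name__ == "__main__":
    main()
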