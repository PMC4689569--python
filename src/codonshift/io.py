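"""Shared readers and writers: FASTA, tab-separated tables, JSON reports.

All coordinates in outputs are 0-based codon indices with half-open
windows; table writers stamp that convention in a header comment and the
reader skips such comments.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .codon_stats import CodingSequence

COORD_HEADER = "# coordinates: 0-based codon indices, half-open windows"


def write_fasta(genes: list[CodingSequence], path, stop_codon: str = "TAA", width: int = 60) -> None:
    """Write coding sequences as FASTA, appending a terminal stop codon."""
    path = Path(path)
    with path.open("w") as fh:
        for g in genes:
            seq = "".join(g.codons) + stop_codon
            fh.write(f">{g.gene_id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_table(df: pd.DataFrame, path, float_format: str = "%.6g") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        fh.write(COORD_HEADER + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format=float_format)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_json_report(report: dict, path) -> None:
    """Deterministic JSON (sorted keys, fixed separators) so reruns are byte-identical."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(report, indent=2, sort_keys=True, allow_nan=True) + "\n")
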