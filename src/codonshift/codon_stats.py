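"""Gene-specific codon usage and hypergeometric enrichment scoring.

Each gene's usage of a codon (count ``k`` out of ``n`` codons) is compared
against the genome-wide pool (``K`` occurrences out of ``N`` codons) with a
hypergeometric model: the Z-score uses the finite-population-corrected
standard deviation, and over/under calls use the exact inclusive tail
probabilities at a configurable alpha (default 0.01).

Stop codons are excluded throughout: the universe is the 61 sense codons,
and a terminal stop is stripped at parse time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy import stats

logger = logging.getLogger(__name__)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
ALL_CODONS = tuple(a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT")
#: the 61 sense codons, lexicographic order — the counting universe
SENSE_CODONS = tuple(c for c in ALL_CODONS if c not in STOP_CODONS)
CODON_TO_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}

DEFAULT_ALPHA = 0.01


class CodingSequenceError(ValueError):
    """Raised when a nucleotide sequence is not a clean single-ORF CDS."""


@dataclass(frozen=True)
class CodingSequence:
    """A gene's in-frame codon list (sense codons only, stop stripped)."""

    gene_id: str
    codons: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.codons:
            raise CodingSequenceError(f"{self.gene_id}: empty codon list")

    def __len__(self) -> int:
        return len(self.codons)

    @property
    def length(self) -> int:
        """Gene length in codons (stop excluded)."""
        return len(self.codons)

    def codes(self) -> np.ndarray:
        """Integer codes into :data:`SENSE_CODONS` (for vectorised kernels)."""
        return np.fromiter(
            (CODON_TO_INDEX[c] for c in self.codons), dtype=np.int64, count=len(self.codons)
        )


def parse_codons(gene_id: str, sequence: str) -> CodingSequence:
    """Split an ORF nucleotide sequence into sense codons.

    The terminal stop codon, if present, is removed. Sequences whose length
    is not a multiple of 3, or that contain internal stops or non-ACGT
    characters, are rejected with :class:`CodingSequenceError`.
    """
    seq = str(sequence).upper().replace("U", "T")
    if len(seq) % 3 != 0:
        raise CodingSequenceError(f"{gene_id}: length {len(seq)} not divisible by 3")
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    if not codons:
        raise CodingSequenceError(f"{gene_id}: no sense codons")
    for i, c in enumerate(codons):
        if c in STOP_CODONS:
            raise CodingSequenceError(f"{gene_id}: internal stop codon {c} at codon {i}")
        if c not in CODON_TO_INDEX:
            raise CodingSequenceError(f"{gene_id}: invalid codon {c!r} at codon {i}")
    return CodingSequence(gene_id=gene_id, codons=tuple(codons))


def read_cds_fasta(path) -> list[CodingSequence]:
    """Read a multi-record CDS FASTA; unparseable genes are skipped with a warning.

    The record ID up to the first whitespace is the gene id.
    """
    genes: list[CodingSequence] = []
    n_rejected = 0
    for record in SeqIO.parse(str(path), "fasta"):
        try:
            genes.append(parse_codons(record.id, str(record.seq)))
        except CodingSequenceError as exc:
            n_rejected += 1
            logger.warning("skipping gene: %s", exc)
    if n_rejected:
        logger.warning("rejected %d of %d records in %s", n_rejected, n_rejected + len(genes), path)
    if not genes:
        raise CodingSequenceError(f"no parseable coding sequences in {path}")
    return genes


def codon_frequency(cds: CodingSequence, codon: str) -> tuple[int, float]:
    """Count a sense codon in a gene and express it per thousand codons."""
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon} is outside the 61-codon universe")
    if codon not in CODON_TO_INDEX:
        raise ValueError(f"invalid codon {codon!r}")
    k = sum(1 for c in cds.codons if c == codon)
    return k, 1000.0 * k / len(cds)


def count_matrix(genes: list[CodingSequence]) -> pd.DataFrame:
    """Per-gene sense-codon counts; rows = genes (input order), columns = 61 codons."""
    mat = np.zeros((len(genes), len(SENSE_CODONS)), dtype=np.int64)
    for i, g in enumerate(genes):
        mat[i] = np.bincount(g.codes(), minlength=len(SENSE_CODONS))
    return pd.DataFrame(mat, index=[g.gene_id for g in genes], columns=list(SENSE_CODONS))


@dataclass(frozen=True)
class GenomeCodonPool:
    """Genome-wide codon totals: the reference the per-gene test draws from."""

    counts: dict[str, int] = field(repr=False)
    total: int = 0

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.total:
            raise ValueError("pool totals inconsistent")

    def k_codon(self, codon: str) -> int:
        return self.counts[codon]


def build_pool(genes: list[CodingSequence]) -> GenomeCodonPool:
    """Sum codon counts over all genes (the focal gene included)."""
    if not genes:
        raise ValueError("empty genome: cannot build codon pool")
    mat = count_matrix(genes)
    totals = mat.sum(axis=0)
    return GenomeCodonPool(counts=dict(zip(mat.columns, totals.to_numpy().tolist())),
                           total=int(totals.sum()))


def hypergeom_enrichment(k, n, K, N):
    """Hypergeometric Z-score and inclusive tail probabilities.

    ``k`` of ``n`` gene codons are the focal codon; ``K`` of ``N`` genome
    codons are. Returns ``(z, p_over, p_under)``; all arguments broadcast.
    ``z`` is NaN where the variance degenerates (n=N, K=0 or K=N).
    """
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    K = np.asarray(K, dtype=float)
    N = np.asarray(N, dtype=float)
    if np.any((k < 0) | (k > n) | (n > N) | (k > K) | (K > N)):
        raise ValueError("require 0 <= k <= n <= N and k <= K <= N")
    mean = n * K / N
    with np.errstate(divide="ignore", invalid="ignore"):
        var = n * (K / N) * (1.0 - K / N) * (N - n) / np.where(N > 1, N - 1.0, np.nan)
        z = np.where(var > 0, (k - mean) / np.sqrt(var), np.nan)
    p_over = stats.hypergeom.sf(k - 1, N, K, n)
    p_under = stats.hypergeom.cdf(k, N, K, n)
    if z.ndim == 0:
        return float(z), float(p_over), float(p_under)
    return z, p_over, p_under


def call_enrichment(p_over: float, p_under: float, alpha: float = DEFAULT_ALPHA) -> str:
    """'over' if p_over < alpha, 'under' if p_under < alpha, else 'none' (strict <)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if not (0.0 <= p_over <= 1.0 and 0.0 <= p_under <= 1.0):
        raise ValueError("tail probabilities must lie in [0, 1]")
    over = p_over < alpha
    under = p_under < alpha
    if over and under:
        raise RuntimeError("both tails significant: inconsistent inclusive tails")
    return "over" if over else ("under" if under else "none")


def usage_table(
    genes: list[CodingSequence],
    alpha: float = DEFAULT_ALPHA,
    codons: list[str] | None = None,
    pool: GenomeCodonPool | None = None,
) -> pd.DataFrame:
    """Long-format per-gene x per-codon usage/enrichment table.

    Columns: gene_id, codon, count, length, freq_per_1000, z, p_over,
    p_under, call. ``codons`` restricts the scored codons (all 61 by
    default); ``pool`` overrides the genome pool (defaults to these genes).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    which = list(SENSE_CODONS) if codons is None else list(codons)
    for c in which:
        if c not in CODON_TO_INDEX:
            raise ValueError(f"invalid or stop codon {c!r}")
    mat = count_matrix(genes)
    if pool is None:
        pool = GenomeCodonPool(
            counts=dict(zip(mat.columns, mat.sum(axis=0).to_numpy().tolist())),
            total=int(mat.to_numpy().sum()),
        )
    kmat = mat[which].to_numpy(dtype=float)                      # (G, C)
    n = mat.sum(axis=1).to_numpy(dtype=float)[:, None]           # (G, 1)
    K = np.array([pool.k_codon(c) for c in which], dtype=float)  # (C,)
    N = float(pool.total)
    z, p_over, p_under = hypergeom_enrichment(kmat, n, K, N)
    call = np.where(p_over < alpha, "over", np.where(p_under < alpha, "under", "none"))
    G, C = kmat.shape
    out = pd.DataFrame(
        {
            "gene_id": np.repeat(mat.index.to_numpy(), C),
            "codon": np.tile(np.array(which), G),
            "count": kmat.astype(int).ravel(),
            "length": np.repeat(n.astype(int).ravel(), C),
            "freq_per_1000": (1000.0 * kmat / n).ravel(),
            "z": z.ravel(),
            "p_over": p_over.ravel(),
            "p_under": p_under.ravel(),
            "call": call.ravel(),
        }
    )
    return out
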