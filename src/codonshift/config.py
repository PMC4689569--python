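"""Run configuration: every analysis threshold in one serializable place."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml


@dataclass(frozen=True)
class RunConfig:
    """Thresholds, sizes, and seeds for a full pipeline run.

    Defaults are the analysis constants: enrichment alpha 0.01; DE alpha
    0.05 with fold threshold 1.2; pausing fold cutoff 1.2 with T-rpkm
    floor 1.0; 15-codon window; 3-codon runs; 100,000 resampling draws;
    10,000 codon shuffles; 10 abundance bins; 7 frequency bins of width
    10 per-1000.
    """

    alpha_enrich: float = 0.01
    alpha_de: float = 0.05
    fc: float = 1.2
    pausing_cutoff: float = 1.2
    window: int = 15
    run_k: int = 3
    n_samplings: int = 100_000
    n_shuffles: int = 10_000
    n_bins_abundance: int = 10
    n_bins_freq: int = 7
    freq_bin_width: float = 10.0
    t_floor: float = 1.0
    seed: int = 0
    focal_codons: tuple[str, ...] = ("AGA", "GAA")
    match_abundance: bool = False
    apply_mrna_filter: bool = True

    def __post_init__(self) -> None:
        positive = [
            self.alpha_enrich, self.alpha_de, self.fc, self.pausing_cutoff, self.window,
            self.run_k, self.n_samplings, self.n_shuffles, self.n_bins_abundance,
            self.n_bins_freq, self.freq_bin_width, self.t_floor,
        ]
        if any(v <= 0 for v in positive):
            raise ValueError("all thresholds and sizes must be positive")

    def replace(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["focal_codons"] = list(self.focal_codons)
        return d

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "focal_codons" in raw:
            raw["focal_codons"] = tuple(raw["focal_codons"])
        return cls(**raw)
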