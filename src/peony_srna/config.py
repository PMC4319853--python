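"""Structured pipeline configuration.

Every stage parameter lives in one flat, serializable dataclass whose
defaults are the thresholds the analysis is defined by: 15-30 nt length
window, two mismatches for conserved-miRNA alignment, hairpin MFE at or
below -18, read support above 5, three terminal mismatches for novel
read counting, G:U priced at 0.5 mismatches, duplex-MFE ratio 0.75,
adjusted p below 0.01 and |log2 fold-change| above 1.  Unknown keys in
a config file are rejected.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .synthetic_data import ADAPTOR_3P, ADAPTOR_5P

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # cleaning
    adaptor_3p: str = ADAPTOR_3P
    adaptor_5p: str = ADAPTOR_5P
    min_len: int = 15
    max_len: int = 30
    polya_fraction: float = 0.8  # repo default
    min_mean_quality: float = 20.0  # repo default
    adaptor_seed_len: int = 8  # repo default
    # conserved miRNA identification
    max_mismatches: int = 2
    # novel miRNA discovery
    flank: int = 150  # repo default
    near: int = 20  # repo default
    mfe_max: float = -18.0
    max_bulge: int = 3  # repo default
    min_paired_fraction: float = 0.75  # repo default
    min_reads: int = 6  # strictly more than 5 reads
    max_terminal_mismatches: int = 3
    fold_backend: str = "embedded"
    # target prediction
    max_score: float = 4.0
    max_score_1_12: float = 2.5
    min_mfe_ratio: float = 0.75
    # differential expression
    p_thresh: float = 0.01
    lfc_thresh: float = 1.0
    pseudo_tpm: float = 0.01  # repo default
    adjust: bool = True
    # simulation
    seed: int = 42
    depth_ck: int = 100_000
    depth_tr: int = 100_000
    n_transcripts: int = 30
    n_planted_precursors: int = 30
    n_conserved_families: int = 12
    n_ncrna: int = 12

    @classmethod
    def from_yaml(cls, source: str | Path) -> "PipelineConfig":
        if isinstance(source, Path) or (isinstance(source, str)
                                        and "\n" not in source
                                        and Path(source).exists()):
            text = Path(source).read_text()
        else:
            text = str(source)
        data = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def hairpin_params(self):
        from .hairpin import HairpinParams

        return HairpinParams(flank=self.flank, near=self.near,
                             mfe_max=self.mfe_max, max_bulge=self.max_bulge,
                             min_paired_fraction=self.min_paired_fraction,
                             min_reads=self.min_reads,
                             fold_backend=self.fold_backend)

    def target_params(self):
        from .targets import TargetParams

        return TargetParams(max_score=self.max_score,
                            max_score_1_12=self.max_score_1_12,
                            min_mfe_ratio=self.min_mfe_ratio)

    def cleaning_params(self):
        from .sra_io import CleaningParams

        return CleaningParams(min_len=self.min_len, max_len=self.max_len,
                              polya_fraction=self.polya_fraction,
                              min_mean_quality=self.min_mean_quality,
                              adaptor_seed_len=self.adaptor_seed_len)
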