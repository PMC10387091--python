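"""Run configuration: every stage constant in one serialisable object.

Stage code never hard-codes these thresholds; they are plumbed through
from a :class:`RunConfig`, which round-trips through YAML so a run is
fully described by its config file.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Union

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # channel (a): germline-specific regions
    min_region_len: int = 500  # bp, minimum fully-testis-covered region
    min_overlap: int = 10  # bp, read-region overlap to select a barcode
    # channel (b): diagnostic k-mers
    kmer_k: int = 29  # bp, k-mer length around each germline SNP
    min_alt_reads: int = 2  # pileup caller: alt support per sample (stand-in
    #                         threshold; the tissue filter is the real gate)
    # channel (c): germline-restricted repeat
    repeat_min_len: int = 100  # bp
    repeat_min_identity: float = 0.90  # exclusive lower bound
    # coverage / copy number
    window: int = 1000  # bp
    # homology
    merge_gap: int = 10_000  # bp, footprint merge distance
    homology_min_len: int = 500  # bp, direct GRC-GRC alignment floor
    homology_min_identity: float = 0.90
    # gene content
    evalue_max: float = 1e-6
    completeness_floor: float = 0.75
    include_min_completeness: float = 0.25
    orf_open_fraction: float = 0.95
    # cytology
    univalent_divisor: float = 1.5
    # mapper
    seed_k: int = 21
    # randomness
    seed: int = 0

    def to_yaml(self, path: Union[str, Path, None] = None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: Union[str, Path]) -> "RunConfig":
        path = Path(source)
        text = path.read_text() if path.exists() else str(source)
        data = yaml.safe_load(text) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)
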