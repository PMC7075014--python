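"""Pipeline configuration: every tunable in one place.

Defaults follow the analysis they reproduce: cut-site smoothing shift -100 /
extsize 200 (a 200 bp window centred on the Tn5 insertion), broad-domain
weak cutoff 0.1, region score threshold tau = 15, gene-linking window
w = 10 kb.  Bin size (50 bp), pseudocount (1.0, applied after per-million
scaling) and the promoter window (+-1 kb of the TSS) are conventional
choices the upstream analysis leaves open.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import List, Optional

import yaml


@dataclass
class PipelineConfig:
    shift: int = -100
    extsize: int = 200
    binsize: int = 50
    pseudocount: float = 1.0
    score_threshold: float = 15.0
    gene_window: int = 10_000
    promoter_window: int = 1_000
    qcut: float = 0.05
    broad_cutoff: float = 0.1
    link_gap: Optional[int] = None  # default 4 x binsize
    local_window: int = 10_000
    min_peak_len: Optional[int] = None  # default binsize
    excluded_chroms: List[str] = field(default_factory=lambda: ["chrM"])
    seed: int = 1

    def __post_init__(self) -> None:
        positive = {
            "extsize": self.extsize, "binsize": self.binsize,
            "pseudocount": self.pseudocount, "local_window": self.local_window,
            "promoter_window": self.promoter_window,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.gene_window < 0:
            raise ValueError("gene_window must be >= 0")
        if not (0 < self.qcut <= 1) or not (0 < self.broad_cutoff <= 1):
            raise ValueError("qcut and broad_cutoff must lie in (0, 1]")

    @property
    def effective_link_gap(self) -> int:
        return self.link_gap if self.link_gap is not None else 4 * self.binsize

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in d.items() if k in known})

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
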