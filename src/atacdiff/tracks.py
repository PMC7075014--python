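"""Fixed-width binned coverage tracks.

A :class:`CoverageTrack` holds one numeric vector per chromosome on a fixed
``binsize`` grid.  Raw-count tracks store mean per-base fragment coverage per
bin (so ``sum(values) * binsize`` equals total covered bases); log2-ratio
tracks store the differential signal defined on every bin of the genome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict

import numpy as np

from .intervals import ChromSizes

KINDS = ("raw", "normalized", "log2ratio")


@dataclass
class CoverageTrack:
    binsize: int
    data: Dict[str, np.ndarray] = field(default_factory=dict)
    kind: str = "raw"

    def __post_init__(self) -> None:
        if self.binsize <= 0:
            raise ValueError("binsize must be > 0")
        if self.kind not in KINDS:
            raise ValueError(f"unknown track kind {self.kind!r}")
        for chrom, v in self.data.items():
            v = np.asarray(v, dtype=np.float64)
            if not np.all(np.isfinite(v)):
                raise ValueError(f"non-finite values on {chrom}")
            self.data[chrom] = v

    @classmethod
    def zeros(cls, sizes: ChromSizes, binsize: int, kind: str = "raw") -> "CoverageTrack":
        data = {
            chrom: np.zeros(n_bins(length, binsize)) for chrom, length in sizes.items()
        }
        return cls(binsize=binsize, data=data, kind=kind)

    @property
    def chroms(self):
        return list(self.data)

    @property
    def total_signal(self) -> float:
        return float(sum(v.sum() for v in self.data.values()))

    def same_grid(self, other: "CoverageTrack") -> bool:
        return self.binsize == other.binsize and {
            c: len(v) for c, v in self.data.items()
        } == {c: len(v) for c, v in other.data.items()}

    def scaled(self, factor: float, kind: str | None = None) -> "CoverageTrack":
        return CoverageTrack(
            binsize=self.binsize,
            data={c: v * factor for c, v in self.data.items()},
            kind=kind or self.kind,
        )

    def value_at(self, chrom: str, pos: int) -> float:
        return float(self.data[chrom][pos // self.binsize])


def n_bins(length: int, binsize: int) -> int:
    return int(math.ceil(length / binsize))
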