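"""Genome-scale containers: genetic map and ancestry-informative site panels.

Coordinates are 1-based for site positions (as in VCF) and half-open
``[start, end)`` 0-based for ancestry blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Genome-wide recombination rate used throughout (Morgans per bp), the ratio
#: of a 14.7 M map length to a 375 Mb genome.
DEFAULT_RECOMBINATION_RATE = 3.9e-8

PANEL_COLUMNS = ["chrom", "pos", "allele_a", "allele_b", "freq_g", "freq_n"]


@dataclass(frozen=True)
class GeneticMap:
    """Chromosome lengths (bp) plus a uniform recombination rate (M/bp)."""

    lengths: dict[str, int]
    rate: float = DEFAULT_RECOMBINATION_RATE

    def __post_init__(self) -> None:
        if not np.isfinite(self.rate) or self.rate <= 0:
            raise ValueError(f"recombination rate must be positive, got {self.rate}")
        if not self.lengths:
            raise ValueError("genetic map needs at least one chromosome")
        for chrom, length in self.lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length {length}")

    @property
    def chromosomes(self) -> list[str]:
        return list(self.lengths)

    @property
    def total_bp(self) -> int:
        return int(sum(self.lengths.values()))

    def morgans(self, bp: float) -> float:
        """Genetic distance spanned by ``bp`` base pairs."""
        return bp * self.rate

    @classmethod
    def uniform(cls, n_chromosomes: int = 14, chrom_bp: int = 26_800_000,
                rate: float = DEFAULT_RECOMBINATION_RATE) -> "GeneticMap":
        """A genome of equal-length chromosomes (default ~375 Mb over 14)."""
        return cls({f"chr{i + 1:02d}": chrom_bp for i in range(n_chromosomes)}, rate)


@dataclass
class SitePanel:
    """Ancestry-informative sites with parental allele frequencies.

    ``sites`` has columns chrom, pos (1-based), allele_a, allele_b, freq_g,
    freq_n where the frequencies refer to allele_a in each parental panel.
    Sites must be sorted with strictly increasing positions per chromosome.
    """

    sites: pd.DataFrame
    min_difference: float = 0.0
    _offsets: dict[str, slice] = field(init=False, repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        df = self.sites
        missing = [c for c in PANEL_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"panel missing columns {missing}")
        df = df.reset_index(drop=True)
        for col in ("freq_g", "freq_n"):
            f = df[col].to_numpy(float)
            if np.any((f < 0) | (f > 1) | ~np.isfinite(f)):
                raise ValueError(f"{col} outside [0, 1]")
        if self.min_difference > 0:
            diff = np.abs(df["freq_g"].to_numpy(float) - df["freq_n"].to_numpy(float))
            if np.any(diff < self.min_difference):
                raise ValueError(
                    f"panel contains sites with |freq_g - freq_n| < {self.min_difference}"
                )
        start = 0
        for chrom, sub in df.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")
            self._offsets[str(chrom)] = slice(start, start + len(sub))
            start += len(sub)
        self.sites = df

    def __len__(self) -> int:
        return len(self.sites)

    @property
    def chromosomes(self) -> list[str]:
        return list(self._offsets)

    def chrom_slice(self, chrom: str) -> slice:
        """Row slice of ``sites`` covering one chromosome (sites are grouped)."""
        return self._offsets[chrom]

    def positions(self, chrom: str) -> np.ndarray:
        return self.sites["pos"].to_numpy()[self.chrom_slice(chrom)]

    def to_tsv(self, path) -> None:
        self.sites.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, **kwargs) -> "SitePanel":
        return cls(pd.read_csv(path, sep="\t"), **kwargs)
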