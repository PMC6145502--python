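"""Core in-memory containers: the phased haplotype panel and genomic windows.

The haplotype panel is the substrate of every statistic in the package:
a binary matrix with haplotypes as rows and biallelic sites as columns,
polarized so that 0 is the ancestral and 1 the derived allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class GenomicWindow:
    """A genomic interval in 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid window [{self.start}, {self.end}): need 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains_position(self, pos_1based: int) -> bool:
        """Whether a 1-based physical position falls inside this window."""
        return self.start < pos_1based <= self.end


@dataclass
class HaplotypePanel:
    """Phased binary haplotype x site matrix with positions and populations.

    Parameters
    ----------
    matrix
        (n_haplotypes, n_sites) array of {0, 1}; 0 = ancestral, 1 = derived.
    positions
        1-based physical bp per column, strictly increasing.
    populations
        Population label per row (haplotype). Two consecutive rows form one
        diploid individual.
    chrom
        Chromosome / contig name.
    region_length
        Length in bp of the region the panel was ascertained over (used by
        sliding-window arithmetic); defaults to the last position.
    focal_index
        Optional column index of a designated focal SNP.
    """

    matrix: np.ndarray
    positions: np.ndarray
    populations: np.ndarray
    chrom: str = "1"
    region_length: int | None = None
    focal_index: int | None = None
    _pop_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.populations = np.asarray(self.populations, dtype=object)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-dimensional")
        n_hap, n_sites = self.matrix.shape
        if self.positions.shape != (n_sites,):
            raise ValueError("positions length must equal the column count")
        if n_sites > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        if self.populations.shape != (n_hap,):
            raise ValueError("one population label per haplotype row required")
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValueError("matrix entries must be 0 (ancestral) or 1 (derived)")
        if self.region_length is None:
            self.region_length = int(self.positions[-1]) if n_sites else 0
        if self.focal_index is not None and not (0 <= self.focal_index < n_sites):
            raise ValueError("focal_index out of range")

    @property
    def n_haplotypes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def population_names(self) -> list[str]:
        """Distinct population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(str(p), None)
        return list(seen)

    def rows_for(self, population: str) -> np.ndarray:
        """Row indices of haplotypes belonging to ``population``."""
        key = str(population)
        if key not in self._pop_cache:
            self._pop_cache[key] = np.flatnonzero(self.populations == key)
        return self._pop_cache[key]

    def subset(self, population: str) -> "HaplotypePanel":
        """Panel restricted to one population (columns are kept as-is)."""
        rows = self.rows_for(population)
        if rows.size == 0:
            raise KeyError(f"no haplotypes labelled {population!r}")
        return HaplotypePanel(
            matrix=self.matrix[rows].copy(),
            positions=self.positions.copy(),
            populations=self.populations[rows].copy(),
            chrom=self.chrom,
            region_length=self.region_length,
            focal_index=self.focal_index,
        )

    def derived_frequency(self, column: int, population: str | None = None) -> float:
        """Derived-allele frequency at a column, optionally within one population."""
        rows = slice(None) if population is None else self.rows_for(population)
        col = self.matrix[rows, column]
        return float(col.mean())

    def site_columns_in(self, window: GenomicWindow) -> np.ndarray:
        """Column indices whose position falls in the window."""
        lo = np.searchsorted(self.positions, window.start + 1, side="left")
        hi = np.searchsorted(self.positions, window.end, side="right")
        return np.arange(lo, hi)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HaplotypePanel):
            return NotImplemented
        return (
            self.chrom == other.chrom
            and self.region_length == other.region_length
            and self.focal_index == other.focal_index
            and np.array_equal(self.matrix, other.matrix)
            and np.array_equal(self.positions, other.positions)
            and np.array_equal(self.populations, other.populations)
        )
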