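"""Genomic coordinate primitives.

All coordinates are 0-based, half-open ``[start, end)`` — the bedGraph/BED
convention. A :class:`GenomeModel` fixes chromosome names, lengths and the
default bin width used to discretize coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["GenomicInterval", "GenomeModel"]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start in {self.chrom}:{self.start}-{self.end}")
        if self.end <= self.start:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> float:
        return (self.start + self.end) / 2

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def jaccard(self, other: "GenomicInterval") -> float:
        """Interval Jaccard index: |A ∩ B| / |A ∪ B| (0 across chromosomes)."""
        inter = self.overlap_len(other)
        union = self.length + other.length - inter
        return inter / union

    def gap_to(self, other: "GenomicInterval") -> int:
        """Edge-to-edge distance in bp; 0 if the intervals overlap or touch."""
        if self.chrom != other.chrom:
            raise ValueError("gap undefined across chromosomes")
        return max(0, max(self.start, other.start) - min(self.end, other.end))


@dataclass(frozen=True)
class GenomeModel:
    """Chromosome names and lengths plus the default coverage bin width."""

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]
    bin_size: int = 150
    _index: dict = field(init=False, repr=False, compare=False, hash=False, default=None)

    def __post_init__(self) -> None:
        names = tuple(self.chrom_names)
        lengths = tuple(int(x) for x in self.chrom_lengths)
        object.__setattr__(self, "chrom_names", names)
        object.__setattr__(self, "chrom_lengths", lengths)
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if len(names) != len(lengths):
            raise ValueError("chrom_names and chrom_lengths differ in length")
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        for name, length in zip(names, lengths):
            if length < self.bin_size:
                raise ValueError(
                    f"chromosome {name} ({length} bp) is shorter than one bin "
                    f"({self.bin_size} bp)"
                )
        object.__setattr__(self, "_index", dict(zip(names, lengths)))

    def length_of(self, chrom: str) -> int:
        try:
            return self._index[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def n_bins(self, chrom: str, bin_size: int | None = None) -> int:
        """Number of bins on ``chrom``; the last bin may be clipped short."""
        b = self.bin_size if bin_size is None else bin_size
        return -(-self.length_of(chrom) // b)  # ceil division

    def contains(self, interval: GenomicInterval) -> bool:
        return (
            interval.chrom in self._index
            and interval.end <= self._index[interval.chrom]
        )

    def check_contains(self, interval: GenomicInterval, what: str = "interval") -> None:
        if interval.chrom not in self._index:
            raise ValueError(f"{what} on unknown chromosome {interval.chrom!r}")
        if not self.contains(interval):
            raise ValueError(
                f"{what} {interval.chrom}:{interval.start}-{interval.end} extends "
                f"beyond chromosome end ({self._index[interval.chrom]} bp)"
            )
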