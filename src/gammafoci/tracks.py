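"""Binned coverage tracks and input normalization.

The central container is :class:`BinnedTrack`: per-chromosome fixed-width bin
tag counts, playing the role a tag directory plays for an aligned ChIP-seq
sample. Treatment/control comparison happens on the depth-normalized scale:
each track is scaled to a common library size (``scale_to`` tags) and the
per-bin fold enrichment is

    (t * scale_to / T + pseudocount) / (c * scale_to / C + pseudocount)

where ``T`` and ``C`` are the two library totals. The pseudocount keeps the
ratio finite over zero-input bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import GenomeModel

__all__ = [
    "BinnedTrack",
    "NormalizedSignal",
    "TrackStats",
    "read_bedgraph",
    "write_bedgraph",
    "normalize",
    "rebin",
    "track_stats",
]

DEFAULT_SCALE_TO = 10_000_000.0


@dataclass
class BinnedTrack:
    """Fixed-width per-chromosome bin counts with a library-size total.

    The last bin of each chromosome may cover fewer than ``bin_size`` bp
    (clipped at the chromosome end). Counts are stored as floats because
    rebinned bedGraph mass is allocated fractionally.
    """

    genome: GenomeModel
    counts: dict[str, np.ndarray]
    bin_size: int | None = None

    def __post_init__(self) -> None:
        if self.bin_size is None:
            self.bin_size = self.genome.bin_size
        for chrom in self.genome.chrom_names:
            if chrom not in self.counts:
                self.counts[chrom] = np.zeros(
                    self.genome.n_bins(chrom, self.bin_size), dtype=float
                )
            arr = np.asarray(self.counts[chrom], dtype=float)
            expected = self.genome.n_bins(chrom, self.bin_size)
            if arr.shape != (expected,):
                raise ValueError(
                    f"{chrom}: expected {expected} bins of {self.bin_size} bp, "
                    f"got shape {arr.shape}"
                )
            if (arr < 0).any():
                raise ValueError(f"{chrom}: negative bin counts")
            self.counts[chrom] = arr

    @property
    def total_tags(self) -> float:
        return float(sum(arr.sum() for arr in self.counts.values()))

    def same_grid(self, other: "BinnedTrack") -> bool:
        return self.genome == other.genome and self.bin_size == other.bin_size

    def bin_interval(self, chrom: str, i: int) -> tuple[int, int]:
        start = i * self.bin_size
        return start, min(start + self.bin_size, self.genome.length_of(chrom))


@dataclass
class NormalizedSignal:
    """Per-bin depth-normalized treatment/control fold enrichment."""

    genome: GenomeModel
    values: dict[str, np.ndarray]
    pseudocount: float
    bin_size: int

    def __post_init__(self) -> None:
        for chrom, arr in self.values.items():
            arr = np.asarray(arr, dtype=float)
            if not np.isfinite(arr).all() or (arr < 0).any():
                raise ValueError(f"{chrom}: non-finite or negative signal values")
            self.values[chrom] = arr


@dataclass(frozen=True)
class TrackStats:
    total: float
    mean_per_bin: float
    nonzero_fraction: float
    n_bins: int


def read_bedgraph(path, genome: GenomeModel, bin_size: int | None = None) -> BinnedTrack:
    """Read a 4-column bedGraph into a fixed-grid :class:`BinnedTrack`.

    A record's value is interpreted as tags per ``bin_size`` bp and is
    allocated to each overlapped bin in proportion to the overlap length, so
    the length-weighted mass of the file is conserved exactly.
    """
    b = genome.bin_size if bin_size is None else bin_size
    track = BinnedTrack(genome, {}, bin_size=b)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
                value = float(parts[3])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed record: {exc}") from None
            if chrom not in genome.chrom_names:
                raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if start < 0 or end <= start or end > genome.length_of(chrom):
                raise ValueError(
                    f"{path}:{lineno}: interval {start}-{end} outside "
                    f"{chrom} (length {genome.length_of(chrom)})"
                )
            arr = track.counts[chrom]
            first, last = start // b, (end - 1) // b
            if first == last:
                arr[first] += value * (end - start) / b
            else:
                edges = np.arange(first, last + 2) * b
                lo = np.maximum(edges[:-1], start)
                hi = np.minimum(edges[1:], end)
                arr[first : last + 1] += value * (hi - lo) / b
    return track


def write_bedgraph(track: BinnedTrack, path) -> None:
    """Write a track as bedGraph, run-length merging equal-valued bins.

    Values are expressed as tags per ``bin_size`` bp so that
    :func:`read_bedgraph` round-trips exactly, including a clipped last bin.
    """
    b = track.bin_size
    with open(path, "w") as fh:
        for chrom in track.genome.chrom_names:
            arr = track.counts[chrom]
            clen = track.genome.length_of(chrom)
            n = arr.size
            i = 0
            while i < n:
                j = i
                start, end = i * b, min((i + 1) * b, clen)
                full = end - start == b
                if full:
                    while (
                        j + 1 < n
                        and arr[j + 1] == arr[i]
                        and min((j + 2) * b, clen) - (j + 1) * b == b
                    ):
                        j += 1
                    end = (j + 1) * b
                    value = arr[i]
                else:  # short last bin: rescale so length-weighted read-back is exact
                    value = arr[i] * b / (end - start)
                if value != 0.0:
                    fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")
                i = j + 1


def rebin(track: BinnedTrack, new_bin_size: int) -> BinnedTrack:
    """Reallocate bin counts onto a coarser/finer grid, conserving totals.

    Each source bin's count is split across destination bins in proportion
    to overlap length.
    """
    if new_bin_size <= 0:
        raise ValueError("new_bin_size must be positive")
    if new_bin_size == track.bin_size:
        return BinnedTrack(track.genome, {c: a.copy() for c, a in track.counts.items()},
                           bin_size=track.bin_size)
    out = BinnedTrack(track.genome, {}, bin_size=new_bin_size)
    b_old, b_new = track.bin_size, new_bin_size
    for chrom in track.genome.chrom_names:
        src = track.counts[chrom]
        dst = out.counts[chrom]
        clen = track.genome.length_of(chrom)
        starts = np.arange(src.size) * b_old
        ends = np.minimum(starts + b_old, clen)
        widths = ends - starts
        # per-bp density of each source bin
        dens = np.where(widths > 0, src / widths, 0.0)
        for i in np.nonzero(src)[0]:
            s, e = starts[i], ends[i]
            first, last = s // b_new, (e - 1) // b_new
            edges = np.arange(first, last + 2) * b_new
            lo = np.maximum(edges[:-1], s)
            hi = np.minimum(edges[1:], e)
            dst[first : last + 1] += dens[i] * (hi - lo)
    return out


def normalize(
    treatment: BinnedTrack,
    control: BinnedTrack,
    scale_to: float = DEFAULT_SCALE_TO,
    pseudocount: float = 1.0,
) -> NormalizedSignal:
    """Depth-normalized treatment/control fold enrichment per bin."""
    if not treatment.same_grid(control):
        raise ValueError("treatment and control are on different genomes or bin grids")
    t_total, c_total = treatment.total_tags, control.total_tags
    if t_total <= 0 or c_total <= 0:
        raise ValueError("cannot normalize a track with zero total tags")
    st, sc = scale_to / t_total, scale_to / c_total
    values = {
        chrom: (treatment.counts[chrom] * st + pseudocount)
        / (control.counts[chrom] * sc + pseudocount)
        for chrom in treatment.genome.chrom_names
    }
    return NormalizedSignal(
        genome=treatment.genome,
        values=values,
        pseudocount=pseudocount,
        bin_size=treatment.bin_size,
    )


def track_stats(track: BinnedTrack) -> TrackStats:
    all_counts = np.concatenate([track.counts[c] for c in track.genome.chrom_names])
    n = all_counts.size
    return TrackStats(
        total=float(all_counts.sum()),
        mean_per_bin=float(all_counts.mean()) if n else 0.0,
        nonzero_fraction=float((all_counts > 0).mean()) if n else 0.0,
        n_bins=int(n),
    )
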