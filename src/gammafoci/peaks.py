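"""Differential region finding on binned tracks.

Fixed-width candidate windows are scored by depth-normalized fold enrichment
of the treatment track over the control track, filtered by a minimum fold
(the "peak filtering" threshold, default 2.5) and a Poisson enrichment test
against the depth-scaled control expectation (the conventional default filter
of tag-directory peak callers, p < 1e-4), then thinned greedily so accepted
window centers sit at least ``min_dist`` apart — highest score wins, ties
broken by leftmost coordinate.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .genome import GenomicInterval
from .tracks import DEFAULT_SCALE_TO, BinnedTrack

__all__ = ["Peak", "PeakSet", "find_regions"]


@dataclass(frozen=True)
class Peak:
    interval: GenomicInterval
    score: float  # fold enrichment of the window
    summit: int  # bp, window center

    @property
    def center(self) -> float:
        return self.interval.center


@dataclass
class PeakSet:
    """Peaks sorted by (chrom, start), with the parameters that produced them."""

    peaks: list[Peak]
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.peaks = sorted(
            self.peaks, key=lambda p: (p.interval.chrom, p.interval.start)
        )

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def intervals(self) -> list[GenomicInterval]:
        return [p.interval for p in self.peaks]


def find_regions(
    treatment: BinnedTrack,
    control: BinnedTrack,
    size: int = 150,
    min_dist: int = 370,
    fold: float = 2.5,
    scale_to: float = DEFAULT_SCALE_TO,
    pseudocount: float = 1.0,
    max_poisson_p: float | None = 1e-4,
) -> PeakSet:
    """Greedy fixed-width differential region finding.

    Windows of ``size`` bp (assembled from whole bins, sliding at bin
    resolution) are scored by depth-normalized treatment/control fold.
    Windows passing the fold threshold (and, unless ``max_poisson_p`` is
    None, a Poisson upper-tail test of the treatment count against the
    depth-scaled control count) are accepted in descending score order;
    a window is suppressed when its center lies strictly closer than
    ``min_dist`` to an already accepted center on the same chromosome.
    """
    if not treatment.same_grid(control):
        raise ValueError("treatment and control are on different genomes or bin grids")
    b = treatment.bin_size
    if size < b:
        raise ValueError(f"window size {size} bp is smaller than the bin width {b} bp")
    w = -(-size // b)  # whole bins covering >= size
    t_total, c_total = treatment.total_tags, control.total_tags
    if t_total <= 0 or c_total <= 0:
        raise ValueError("cannot score enrichment on a track with zero total tags")
    st, sc = scale_to / t_total, scale_to / c_total
    depth_ratio = t_total / c_total

    candidates = []  # (score, chrom_idx, start_bin, t_win)
    genome = treatment.genome
    for ci, chrom in enumerate(genome.chrom_names):
        t = treatment.counts[chrom]
        c = control.counts[chrom]
        if t.size < w:
            continue
        kernel_t = np.convolve(t, np.ones(w), mode="valid")
        kernel_c = np.convolve(c, np.ones(w), mode="valid")
        score = (kernel_t * st + pseudocount) / (kernel_c * sc + pseudocount)
        keep = score >= fold
        if max_poisson_p is not None:
            expected = np.maximum(kernel_c * depth_ratio, 1e-12)
            # sf(k-1, mu) = P(Poisson(mu) >= k)
            pvals = stats.poisson.sf(np.ceil(kernel_t) - 1, expected)
            keep &= pvals < max_poisson_p
        for i in np.nonzero(keep)[0]:
            candidates.append((float(score[i]), ci, int(i)))

    # descending score, ties by (chrom order, leftmost start)
    candidates.sort(key=lambda x: (-x[0], x[1], x[2]))

    accepted_centers: dict[int, list[float]] = {}
    peaks: list[Peak] = []
    width = w * b
    for score, ci, i in candidates:
        chrom = genome.chrom_names[ci]
        start = i * b
        center = start + width / 2
        centers = accepted_centers.setdefault(ci, [])
        pos = bisect.bisect_left(centers, center)
        if pos > 0 and center - centers[pos - 1] < min_dist:
            continue
        if pos < len(centers) and centers[pos] - center < min_dist:
            continue
        bisect.insort(centers, center)
        end = min(start + width, genome.length_of(chrom))
        peaks.append(
            Peak(
                interval=GenomicInterval(chrom, start, end),
                score=score,
                summit=int(center),
            )
        )
    return PeakSet(
        peaks,
        params={
            "size": size,
            "min_dist": min_dist,
            "fold": fold,
            "scale_to": scale_to,
            "pseudocount": pseudocount,
            "max_poisson_p": max_poisson_p,
        },
    )
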