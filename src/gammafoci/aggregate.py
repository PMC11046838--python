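"""Reference-point aggregation profiles.

For a set of anchor intervals (e.g. CTCF binding sites) the profile reports,
at each offset from the anchor center across a ±flank window, the fold
enrichment of depth-normalized treatment coverage over control coverage.
The y value at each offset is the ratio of cross-site means (pooled
normalization): mean treatment over all sites divided by mean control over
all sites, which stays finite when individual sites have zero control
coverage. A mean-of-per-site-ratios variant is available for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomicInterval
from .tracks import DEFAULT_SCALE_TO, BinnedTrack

__all__ = ["AggregationProfile", "profile_around_sites", "compare_profiles"]


@dataclass
class AggregationProfile:
    offsets: np.ndarray  # bp relative to anchor center (- upstream, + downstream)
    mean_fold: np.ndarray
    n_sites: int
    profile_bin: int
    n_excluded: int = 0

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=int)
        self.mean_fold = np.asarray(self.mean_fold, dtype=float)
        if self.offsets.shape != self.mean_fold.shape:
            raise ValueError("offsets and mean_fold differ in shape")
        if self.n_sites <= 0:
            raise ValueError("profile computed over zero sites")
        if not np.array_equal(self.offsets, -self.offsets[::-1]):
            raise ValueError("offsets must be symmetric about 0")
        if (self.mean_fold < 0).any() or not np.isfinite(self.mean_fold).all():
            raise ValueError("mean_fold must be finite and non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"offset": self.offsets, "mean_fold": self.mean_fold, "n_sites": self.n_sites}
        )

    def central_mean(self, halfwidth: int = 250) -> float:
        sel = np.abs(self.offsets) <= halfwidth
        return float(self.mean_fold[sel].mean())


def _sample_matrix(track: BinnedTrack, centers, offsets) -> np.ndarray:
    """Sample per-bin counts at center+offset for every (site, offset)."""
    b = track.bin_size
    out = np.empty((len(centers), offsets.size), dtype=float)
    for i, (chrom, center) in enumerate(centers):
        arr = track.counts[chrom]
        idx = ((center + offsets) // b).astype(int)
        out[i] = arr[idx]
    return out


def profile_around_sites(
    treatment: BinnedTrack,
    control: BinnedTrack,
    sites,
    flank: int = 2000,
    profile_bin: int | None = None,
    scale_to: float = DEFAULT_SCALE_TO,
    pseudocount: float = 1.0,
    per_site_ratio: bool = False,
) -> AggregationProfile:
    """Fold-enrichment metaprofile in a ±``flank`` bp window around site centers.

    Sites whose ±flank window leaves the chromosome are excluded (not
    clipped) and counted in ``n_excluded``. Anchors are interval centers;
    strand is ignored.
    """
    if not treatment.same_grid(control):
        raise ValueError("treatment and control are on different genomes or bin grids")
    pb = treatment.bin_size if profile_bin is None else profile_bin
    genome = treatment.genome
    # sample positions must stay inside the half-open [c-flank, c+flank) window
    n_off = (flank - 1) // pb
    offsets = np.arange(-n_off, n_off + 1) * pb

    site_ivs = [s.interval if hasattr(s, "interval") else s for s in sites]
    centers = []
    n_excluded = 0
    for iv in site_ivs:
        c = int(iv.center)
        if c - flank < 0 or c + flank > genome.length_of(iv.chrom):
            n_excluded += 1
            continue
        centers.append((iv.chrom, c))
    if not centers:
        raise ValueError(
            f"no usable sites: {len(site_ivs)} provided, "
            f"{n_excluded} excluded at chromosome edges"
        )

    st = scale_to / treatment.total_tags
    sc = scale_to / control.total_tags
    t_mat = _sample_matrix(treatment, centers, offsets) * st
    c_mat = _sample_matrix(control, centers, offsets) * sc
    if per_site_ratio:
        fold = ((t_mat + pseudocount) / (c_mat + pseudocount)).mean(axis=0)
    else:
        fold = (t_mat.mean(axis=0) + pseudocount) / (c_mat.mean(axis=0) + pseudocount)
    return AggregationProfile(
        offsets=offsets,
        mean_fold=fold,
        n_sites=len(centers),
        profile_bin=pb,
        n_excluded=n_excluded,
    )


def compare_profiles(
    a: AggregationProfile, b: AggregationProfile, central_halfwidth: int = 250
) -> tuple[pd.DataFrame, float]:
    """Pair two profiles offset-by-offset.

    Returns the paired table (offset, fold_a, fold_b, delta) and a scalar
    summary: the difference of the two profiles' means over the central
    ±``central_halfwidth`` bp.
    """
    if not np.array_equal(a.offsets, b.offsets):
        raise ValueError("profiles have mismatched offsets")
    table = pd.DataFrame(
        {
            "offset": a.offsets,
            "fold_a": a.mean_fold,
            "fold_b": b.mean_fold,
            "delta": b.mean_fold - a.mean_fold,
        }
    )
    central_delta = b.central_mean(central_halfwidth) - a.central_mean(central_halfwidth)
    return table, central_delta
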