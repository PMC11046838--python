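"""Synthetic data with known ground truth.

Everything the pipeline consumes can be generated here: binned treatment and
control coverage with planted broad enrichment domains and point-source
binding sites, well-level qPCR Ct tables with known fold effects, and
IP/input Ct pairs consistent with a known percent-input occupancy.

Count noise is Poisson per bin (matching tag counts); a negative-binomial
switch adds overdispersion when wanted. One global seed drives everything:
each operation derives its own stream by hashing its name, so adding a stage
never perturbs the draws of another.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .genome import GenomeModel, GenomicInterval
from .io import write_bed, write_manifest, write_truth_tsv
from .tracks import BinnedTrack, write_bedgraph

__all__ = [
    "PlantedDomain",
    "PlantedSite",
    "SyntheticTruth",
    "derived_rng",
    "random_truth",
    "simulate_tracks",
    "simulate_ct_table",
    "simulate_chip_qpcr",
    "write_fixtures",
]


@dataclass(frozen=True)
class PlantedDomain:
    """A broad enrichment domain planted in the treatment track."""

    interval: GenomicInterval
    fold: float
    label: str

    def __post_init__(self) -> None:
        if self.fold <= 1:
            raise ValueError(f"domain {self.label}: fold must exceed 1")


@dataclass(frozen=True)
class PlantedSite:
    """A point-source binding site with local enrichment of ±half_width bp."""

    chrom: str
    position: int
    half_width: int
    fold: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.fold <= 1:
            raise ValueError(f"site {self.label or self.position}: fold must exceed 1")
        if self.half_width <= 0:
            raise ValueError("half_width must be positive")

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.position - self.half_width, self.position + self.half_width
        )


@dataclass(frozen=True)
class SyntheticTruth:
    domains: tuple[PlantedDomain, ...]
    sites: tuple[PlantedSite, ...]
    background_rate: float
    seed: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "domains", tuple(self.domains))
        object.__setattr__(self, "sites", tuple(self.sites))
        if self.background_rate <= 0:
            raise ValueError("background_rate must be positive")


def derived_rng(seed: int, op_name: str) -> np.random.Generator:
    """Operation-specific stream: the global seed plus a stable name hash."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(op_name.encode())])
    )


def random_truth(
    genome: GenomeModel,
    n_domains: int = 20,
    domain_length_range: tuple[int, int] = (2000, 10000),
    domain_fold: float = 4.0,
    n_sites: int = 50,
    site_half_width: int = 150,
    site_fold: float = 3.0,
    background_rate: float = 10.0,
    seed: int = 0,
    min_separation: int = 30_000,
) -> SyntheticTruth:
    """Place non-overlapping domains and sites uniformly, kept apart.

    Features are separated by at least ``min_separation`` bp (and sites stay
    clear of domains), emulating the genomic sparsity of double-strand-break
    domains so that planted features remain individually resolvable.
    """
    rng = derived_rng(seed, "random_truth")
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.chrom_names}
    total = sum(genome.chrom_lengths)
    weights = np.array(genome.chrom_lengths, dtype=float) / total

    def place(width: int, tries: int = 10_000) -> GenomicInterval:
        for _ in range(tries):
            ci = rng.choice(len(genome.chrom_names), p=weights)
            chrom = genome.chrom_names[ci]
            clen = genome.chrom_lengths[ci]
            if clen <= width + 2:
                continue
            start = int(rng.integers(0, clen - width))
            ok = all(
                start - e >= min_separation or s - (start + width) >= min_separation
                for s, e in placed[chrom]
            )
            if ok:
                placed[chrom].append((start, start + width))
                return GenomicInterval(chrom, start, start + width)
        raise RuntimeError(
            "could not place all features: genome too small for the requested "
            "feature count and separation"
        )

    domains = []
    for i in range(n_domains):
        length = int(rng.integers(domain_length_range[0], domain_length_range[1] + 1))
        iv = place(length)
        domains.append(PlantedDomain(iv, domain_fold, f"domain_{i + 1}"))
    sites = []
    for i in range(n_sites):
        iv = place(2 * site_half_width)
        sites.append(
            PlantedSite(
                iv.chrom, iv.start + site_half_width, site_half_width, site_fold,
                f"site_{i + 1}",
            )
        )
    return SyntheticTruth(tuple(domains), tuple(sites), background_rate, seed)


def _enrichment_factors(genome: GenomeModel, truth: SyntheticTruth) -> dict[str, np.ndarray]:
    """Per-bin multiplicative enrichment; partial bins scale by covered fraction."""
    factors = {
        c: np.ones(genome.n_bins(c), dtype=float) for c in genome.chrom_names
    }
    b = genome.bin_size
    features = [(d.interval, d.fold, d.label) for d in truth.domains] + [
        (s.interval, s.fold, s.label or f"site@{s.position}") for s in truth.sites
    ]
    for iv, fold, label in features:
        genome.check_contains(iv, what=f"planted feature {label!r}")
        arr = factors[iv.chrom]
        first, last = iv.start // b, (iv.end - 1) // b
        edges = np.arange(first, last + 2) * b
        lo = np.maximum(edges[:-1], iv.start)
        hi = np.minimum(edges[1:], iv.end)
        bin_ends = np.minimum(edges[1:], genome.length_of(iv.chrom))
        widths = np.maximum(bin_ends - edges[:-1], 1)
        arr[first : last + 1] += (fold - 1.0) * (hi - lo) / widths
    return factors


def simulate_tracks(
    genome: GenomeModel,
    truth: SyntheticTruth,
    library_ratio: float = 1.0,
    nb_dispersion: float | None = None,
) -> tuple[BinnedTrack, BinnedTrack]:
    """Draw treatment and control tag-count tracks.

    Control bins are Poisson with mean ``background_rate * library_ratio``;
    treatment bins are Poisson with mean ``background_rate`` times the planted
    enrichment factor (1 outside features, the planted fold inside, the
    covered fraction in partially overlapped bins). A clipped last bin's mean
    scales with its width. With ``nb_dispersion`` set, counts are
    negative-binomial with that size parameter instead (overdispersed).
    """
    if library_ratio <= 0:
        raise ValueError("library_ratio must be positive")
    rng = derived_rng(truth.seed, "simulate_tracks")
    factors = _enrichment_factors(genome, truth)
    b = genome.bin_size
    t_counts: dict[str, np.ndarray] = {}
    c_counts: dict[str, np.ndarray] = {}

    def draw(lam: np.ndarray) -> np.ndarray:
        if nb_dispersion is None:
            return rng.poisson(lam).astype(float)
        size = nb_dispersion
        p = size / (size + lam)
        return rng.negative_binomial(size, p).astype(float)

    for chrom in genome.chrom_names:
        clen = genome.length_of(chrom)
        n = genome.n_bins(chrom)
        widths = np.minimum((np.arange(n) + 1) * b, clen) - np.arange(n) * b
        base = truth.background_rate * widths / b
        t_counts[chrom] = draw(base * factors[chrom])
        c_counts[chrom] = draw(base * library_ratio)
    return (
        BinnedTrack(genome, t_counts),
        BinnedTrack(genome, c_counts),
    )


def simulate_ct_table(
    design: Mapping[str, Mapping[str, float]],
    reference_genes,
    replicates: int = 3,
    noise_sd: float = 0.2,
    seed: int = 0,
    baseline_ct_range: tuple[float, float] = (18.0, 26.0),
) -> pd.DataFrame:
    """Well-level qPCR Ct table with known per-group per-gene fold changes.

    Ct = per-target baseline - log2(true fold) + Gaussian noise. Reference
    genes are forced to fold 1 in every group. Each group gets ``replicates``
    samples, each measuring every target once.
    """
    reference_genes = list(reference_genes)
    if not reference_genes:
        raise ValueError("at least one reference gene is required")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = derived_rng(seed, "simulate_ct_table")
    targets = sorted({t for g in design.values() for t in g} | set(reference_genes))
    baselines = {
        t: float(rng.uniform(*baseline_ct_range)) for t in targets
    }
    rows = []
    for group in design:
        folds = dict(design[group])
        for ref in reference_genes:
            folds[ref] = 1.0
        for t, f in folds.items():
            if f <= 0:
                raise ValueError(f"non-positive fold {f} for {t!r} in group {group!r}")
        for r in range(1, replicates + 1):
            sample = f"{group}_{r}"
            for t in targets:
                fold = folds.get(t, 1.0)
                ct = baselines[t] - math.log2(fold)
                if noise_sd > 0:
                    ct += float(rng.normal(0.0, noise_sd))
                rows.append((sample, group, t, r, ct))
    return pd.DataFrame(rows, columns=["sample", "group", "target", "replicate", "ct"])


def simulate_chip_qpcr(
    true_percent_input,
    input_fraction: float = 0.1,
    replicates: int = 3,
    noise_sd: float = 0.1,
    seed: int = 0,
    input_ct: float = 24.0,
) -> pd.DataFrame:
    """IP/input Ct pairs consistent with a known percent-input occupancy.

    ``true_percent_input`` may be a scalar or a mapping locus -> %. The pair
    satisfies percent = 100 * input_fraction * 2**(Ct_input - Ct_IP) before
    noise is added to both wells.
    """
    if not (0 < input_fraction <= 1):
        raise ValueError("input_fraction must be in (0, 1]")
    if isinstance(true_percent_input, Mapping):
        loci = dict(true_percent_input)
    else:
        loci = {"locus": float(true_percent_input)}
    for locus, pct in loci.items():
        if pct <= 0:
            raise ValueError(f"non-positive percent input for {locus!r}")
    rng = derived_rng(seed, "simulate_chip_qpcr")
    rows = []
    for locus, pct in sorted(loci.items()):
        ct_ip_true = input_ct - math.log2(pct / (100.0 * input_fraction))
        for r in range(1, replicates + 1):
            eps_in = float(rng.normal(0.0, noise_sd)) if noise_sd > 0 else 0.0
            eps_ip = float(rng.normal(0.0, noise_sd)) if noise_sd > 0 else 0.0
            rows.append((f"input_{r}", "input", locus, r, input_ct + eps_in))
            rows.append((f"IP_{r}", "IP", locus, r, ct_ip_true + eps_ip))
    return pd.DataFrame(rows, columns=["sample", "group", "target", "replicate", "ct"])


def write_fixtures(
    directory,
    genome: GenomeModel,
    truth: SyntheticTruth,
    treatment: BinnedTrack,
    control: BinnedTrack,
    expression_ct: pd.DataFrame | None = None,
    chip_ct: pd.DataFrame | None = None,
) -> list[dict]:
    """Write all pipeline inputs to ``directory`` and return a checksum manifest.

    Emits treatment/control bedGraph, a BED6 site file, the truth TSV, a
    chromosome-sizes TSV and the two Ct CSVs (empty tables when not given),
    plus a manifest.json listing every file with its sha256.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []

    p = directory / "treatment.bedgraph"
    write_bedgraph(treatment, p)
    paths.append(p)
    p = directory / "control.bedgraph"
    write_bedgraph(control, p)
    paths.append(p)

    p = directory / "sites.bed"
    write_bed(
        [s.interval for s in truth.sites],
        p,
        names=[s.label or f"site_{i+1}" for i, s in enumerate(truth.sites)],
        scores=[int(s.fold * 100) for s in truth.sites],
    )
    paths.append(p)

    p = directory / "truth.tsv"
    write_truth_tsv(truth.domains, truth.sites, p)
    paths.append(p)

    p = directory / "genome.tsv"
    with open(p, "w") as fh:
        fh.write("chrom\tlength\n")
        for name, length in zip(genome.chrom_names, genome.chrom_lengths):
            fh.write(f"{name}\t{length}\n")
    paths.append(p)

    empty = pd.DataFrame(columns=["sample", "group", "target", "replicate", "ct"])
    p = directory / "expression_ct.csv"
    (expression_ct if expression_ct is not None else empty).to_csv(p, index=False)
    paths.append(p)
    p = directory / "chip_qpcr_ct.csv"
    (chip_ct if chip_ct is not None else empty).to_csv(p, index=False)
    paths.append(p)

    return write_manifest(
        paths,
        directory / "manifest.json",
        meta={"background_rate": truth.background_rate, "seed": truth.seed,
              "bin_size": genome.bin_size},
    )
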