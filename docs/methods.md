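# Methods

## Signal model and normalization

All coverage is handled as fixed-width bin counts (default 150 bp, last bin
clipped at the chromosome end), standing in for the per-sample tag
directories of an aligned ChIP-seq experiment. Treatment/control comparison
uses depth normalization to a common library size (`scale_to`, default 10⁷
tags — the conventional tag-count normalization constant) followed by a
per-bin ratio with a pseudocount:

    s_i = (t_i · N/T + ψ) / (c_i · N/C + ψ),  ψ = 1.

The normalized signal is therefore fold enrichment over input, not
depth-normalized tags — consistent with aggregation profiles whose y axis is
fold enrichment of ChIP DNA relative to input DNA. The pseudocount sits on
the normalized scale, guaranteeing finite values over zero-input bins; at
realistic depths it is numerically negligible, so the ratio is effectively
scale-invariant (exactly scale-invariant when ψ = 0 and no bin is zero).

## Differential region finding

Candidate windows are `size` bp wide (default 150, assembled from whole
bins), slide at bin resolution, and are scored by the window-level
normalized fold. Two filters apply:

- fold ≥ 2.5 (the "peak filtering" threshold), and
- a Poisson upper-tail test of the window's treatment count against the
  depth-scaled control count, p < 10⁻⁴ by default (`max_poisson_p=None`
  disables it).

The Poisson filter is the default behavior of the tag-directory peak callers
this stage models, and it is statistically necessary at shallow coverage: at
10 tags/bin on both tracks, the fold filter alone passes ≈ 3% of pure
background bins (a Poisson(10) pair has heavy ratio tails), which chains
into spurious >1 kb "broad" regions; with the Poisson test the background
pass rate drops by ~1.5 orders of magnitude and spurious broad regions
essentially vanish.

Accepted windows are selected greedily by descending score; a window is
suppressed when its center lies strictly closer than `min_dist` (default
370 bp, center-to-center) to an accepted center. Ties break to the leftmost
coordinate, so output is unique and deterministic; the fold threshold is
monotone (raising it can only remove peaks).

## Broad regions and focus expansion

Peaks merge transitively when the edge-to-edge gap is ≤ 700 bp (inclusive:
"within 700 bp" reads as ≤); merged regions strictly longer than 1 kb
("longer than 1 kb" reads as >) become broad differential regions. Both
boundaries are covered by exact tests.

Expansion unions into a focus every bin whose normalized signal is strictly
greater than 1.5 and whose edge-to-edge distance to the focus is strictly
less than 1 kb; absorption closes the intervening gap, so the focus stays a
single interval and newly reachable bins join on later iterations. The
procedure runs to fixpoint (bounded by the number of above-threshold bins;
one wave absorbs everything reachable from the previous extent, so the
reported iteration count is the true chain depth). A bin within reach of two
foci joins both, and strictly overlapping foci coalesce — this makes the
result independent of processing order. A `single_pass` mode (one wave from
the original seed) exists for sensitivity analysis.

**Expansion bin width.** The expansion signal is computed on 1 kb bins by
default (tracks are re-binned mass-conservingly, then normalized), not on
the 150 bp calling bins. At 10 tags per 150 bp bin, the ratio of two
independent Poisson(10) counts exceeds 1.5 with probability ≈ 0.17, so
thresholding raw 150 bp bins lets foci percolate outward through background
(~1–3 kb of noise tail per side, which dilutes small domains below a 0.5
Jaccard against truth); at 1 kb (~67 tags) the background exceedance
probability falls to ≈ 0.01 and expansion tails are bounded by one bin. The
1 kb default matches the scale of the merge gap and the broad-region
threshold; the width is a parameter (`expansion_bin`) and can be set to the
track bin width.

## Aggregation profiles

Anchors are interval centers (strand ignored). Offsets step by
`profile_bin` (default the track bin width) symmetrically about 0, staying
strictly inside the half-open ±`flank` window; sites whose window leaves the
chromosome are dropped, not clipped, keeping per-offset n constant. The
profile value per offset is the ratio of cross-site means (pooled):
mean depth-normalized treatment over all sites divided by mean control, plus
the pseudocount in numerator and denominator — robust to individual
zero-control sites. The alternative estimator (mean of per-site ratios) is
available via `per_site_ratio=True` and differs on heterogeneous data; a
test pins the difference so the documented choice cannot silently regress.
`compare_profiles` pairs two profiles offset-by-offset and summarizes the
difference of means over the central ±250 bp.

## Scalar quantifications

- **Percent input**: 100 · f · 2^(Ct_input − Ct_IP) with input fraction
  f ∈ (0, 1], default 0.1 (one-tenth of pre-cleared chromatin reserved as
  input). Invariant under common Ct shifts; values above 100% are returned
  but flagged, since they indicate an inconsistent pair.
- **2^−ΔΔCt**: per sample ΔCt = Ct_target − mean(Ct of reference genes);
  group ΔCt averages replicates before differencing against the calibrator
  group (the classical formulation); fold = 2^−ΔΔCt exactly. Multiple
  reference genes (e.g. Gapdh and β-actin) combine by the arithmetic mean of
  their Ct, equivalent to the geometric mean of their expression; a test
  verifies refs at Ct 18 and 22 behave exactly like one ref at 20.
  Per-replicate folds are also emitted for error bars.
- **Top-k axon length**: mean of the k = 5 longest traced axons per nerve;
  fewer than k values fall back to the overall mean with a recorded warning.
- **DE counting**: genes with p < 0.05 split by log-fold-change sign;
  significant genes with exactly zero fold change are reported separately
  and counted in neither direction.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, with
defaults chosen as the study conditions all recovery statements refer to:
a 10 Mb single-chromosome genome at 150 bp bins; Poisson tag counts with
background 10 per bin on both tracks (a negative-binomial switch adds
overdispersion when wanted); 20 broad domains of 2–10 kb at fold 4;
50 point sites of ±150 bp at fold 3. Partial-overlap bins scale enrichment
by the covered fraction, avoiding edge artifacts in recovery scoring.
Features are placed uniformly with ≥ 30 kb separation, reflecting the
genomic sparsity of DSB domains and keeping planted features individually
resolvable. qPCR tables use Ct = baseline − log₂(fold) + N(0, σ) with
per-target baselines in 18–26 cycles, σ = 0.2 (expression) and 0.1 (ChIP),
3 replicates per group.

One global seed drives everything; each operation derives its own stream by
hashing its name (CRC-32) into a `SeedSequence`, so identical (parameters,
seed) give bit-identical outputs and adding a stage never perturbs another's
draws.

What the generator does **not** model: read-level data (fragment lengths,
mappability, GC bias), duplicate reads, copy-number or chromatin-state
covariates of real background, correlated noise between IP and input, and
qPCR efficiency ≠ 2. Passing recovery tests therefore demonstrates the
pipeline's logic and statistical behavior under idealized tag counts, not
performance on real libraries.

## Recovery scoring

Called foci are matched to planted domains greedily one-to-one by interval
Jaccard (|A∩B|/|A∪B|); sensitivity is the fraction of domains matched at
Jaccard ≥ 0.5, and a false focus overlaps no planted domain at all. With no
planted domains sensitivity is reported as NA.

## Numerical and interface choices

- Coordinates are 0-based half-open throughout (bedGraph/BED convention).
- bedGraph values are tags per `bin_size` bp, allocated to bins by overlap
  length; written files run-length-merge equal bins and rescale a clipped
  last bin so read-back is exact and mass is conserved.
- Problem sizes in tests: oracle equivalence runs 500 random instances per
  interval operation (≤ 200 intervals, quadratic references) and 200 random
  ≤ 100 kb genomes for the window-scan oracle; recovery runs the full 10 Mb
  study conditions.
- Configuration is one flat YAML file (`RunConfig`), dumped with sorted keys
  so write → read → write is byte-identical.

## Known limitations

- Windows slide at bin resolution; sub-bin window placement is out of scope.
- No FDR/significance testing between conditions at the focus level; the
  only filters are fold, Poisson enrichment and geometry.
- The percolation analysis above assumes independent Poisson background;
  overdispersed real data would need a wider expansion bin or a stricter
  signal threshold, which is why both are parameters.
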