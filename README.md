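# gammafoci

Analysis pipeline for **broad γH2AX ChIP-seq domains** around DNA
double-strand breaks (DSBs), built for a peripheral-nerve-injury study
design: a γH2AX ChIP sample from treated dorsal root ganglia is compared
against an input/control tag library to find *broad differential γH2AX
regions* and grow them into *expanded γH2AX foci*, profile γH2AX
fold-enrichment around CTCF binding sites, and compute the study's scalar
readouts (percent-input ChIP-qPCR occupancy, 2^−ΔΔCt expression folds, the
top-5 axon-length statistic, and p < 0.05 differential-expression counts).

Because γH2AX spreads over kilobase-scale domains rather than sharp summits,
the pipeline works on fixed-width coverage bins rather than read-level data,
and every stage can be driven by a synthetic-data generator that plants
domains and sites with known positions and fold enrichments, so recovery is
quantifiable.

## The pipeline

Given treatment counts `t_i` and control counts `c_i` in bins of width 150 bp
with library totals `T` and `C`, the depth-normalized fold enrichment is

    s_i = (t_i · N/T + ψ) / (c_i · N/C + ψ)

with a common scale `N = 10^7` tags and pseudocount `ψ = 1`.

1. **Differential region finding** — fixed 150 bp windows at ≥ 370 bp
   center-to-center spacing, kept when the window fold is ≥ 2.5 and the
   treatment count is Poisson-significantly above the depth-scaled control
   expectation (p < 10⁻⁴), selected greedily by descending fold.
2. **Merging** — peaks with edge-to-edge gap ≤ 700 bp are merged
   transitively.
3. **Broad regions** — merged regions strictly longer than 1 kb.
4. **Focus expansion** — bins whose normalized signal exceeds 1.5 and whose
   edge-to-edge distance to a current focus is < 1 kb are unioned into it
   (closing the gap), iterated to fixpoint; the expansion signal is computed
   on 1 kb bins to keep a 1.5-fold threshold meaningful at ~10 tags per
   150 bp bin.
5. **Aggregation** — mean fold enrichment (ratio of cross-site means) at
   each offset in a ±2 kb window around binding-site centers.
6. **Quantification** — percent input = 100 · f · 2^(Ct_input − Ct_IP) with
   input fraction `f` (default 1/10); 2^−ΔΔCt with multi-reference Ct
   averaging; top-k mean of traced axon lengths; DE up/down counts at
   p < 0.05.

## Worked example

```bash
python analysis/01_simulate.py      # fixtures with planted truth
python analysis/02_call_foci.py     # peaks -> broad regions -> foci -> recovery
python analysis/03_aggregate_sites.py
python analysis/04_quantify.py
```

The default run (10 Mb genome, Poisson background of 10 tags/bin, 20 planted
fold-4 domains of 2–10 kb, 50 fold-3 sites, seed 0) prints:

```
710 peaks -> 477 merged regions -> 27 broad (>1 kb) -> 21 expanded foci
recovery: sensitivity 1.00 at Jaccard >= 0.5, 1 false foci
per-domain Jaccard: median 0.91, min 0.68
```

so every planted domain is recovered by a focus sharing ≥ 50% of the union
of the two intervals, with one spurious focus from background noise. The
site aggregation reports

```
central fold: treated 2.94, sham 1.42 (summit difference 1.51)
```

— the planted fold-3 (treated) and fold-1.5 (sham) enrichments are read
directly off the profile summit. Quantification recovers the planted
percent-input occupancies (2.0% → 1.963%, 0.2% → 0.211%) and expression
folds (e.g. Atf3 3.0 → 3.27 at Ct noise 0.2 with 3 replicates).

The same stages are exposed as a CLI (`gammafoci simulate|callpeaks|foci|
aggregate|quant|run|score`) and as library functions under `gammafoci.*`.

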