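"""Independent naive reference implementations used as oracles.

These deliberately favor clarity over speed (quadratic scans, explicit
python loops) and share no code with the package's implementations.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def ref_merge(intervals: list[tuple[str, int, int]], max_gap: int) -> list[tuple[str, int, int]]:
    """Quadratic connected-components merge: gap <= max_gap links intervals."""
    n = len(intervals)
    adj = [[] for _ in range(n)]
    for i in range(n):
        ci, si, ei = intervals[i]
        for j in range(i + 1, n):
            cj, sj, ej = intervals[j]
            if ci != cj:
                continue
            gap = max(si, sj) - min(ei, ej)
            if gap <= max_gap:
                adj[i].append(j)
                adj[j].append(i)
    seen = [False] * n
    out = []
    for i in range(n):
        if seen[i]:
            continue
        stack, comp = [i], []
        seen[i] = True
        while stack:
            k = stack.pop()
            comp.append(k)
            for m in adj[k]:
                if not seen[m]:
                    seen[m] = True
                    stack.append(m)
        chrom = intervals[i][0]
        out.append(
            (chrom, min(intervals[k][1] for k in comp), max(intervals[k][2] for k in comp))
        )
    return sorted(out)


def ref_expand(
    seeds: list[tuple[str, int, int]],
    hot_bins: list[tuple[str, int, int]],
    max_gap: int,
) -> list[tuple[str, int, int]]:
    """Literal fixpoint expansion, one focus span per seed, then coalesce.

    Every hot bin strictly closer than max_gap to a focus is unioned into
    that focus (into every focus it is close to); iterated until nothing
    changes; strictly overlapping foci coalesce.
    """
    foci = [[c, s, e] for c, s, e in seeds]
    changed = True
    while changed:
        changed = False
        for f in foci:
            for c, s, e in hot_bins:
                if c != f[0]:
                    continue
                gap = max(f[1], s) - min(f[2], e)
                if gap < max_gap and not (s >= f[1] and e <= f[2]):
                    f[1] = min(f[1], s)
                    f[2] = max(f[2], e)
                    changed = True
    foci.sort()
    out = []
    for c, s, e in foci:
        if out and c == out[-1][0] and s < out[-1][2]:
            out[-1][2] = max(out[-1][2], e)
        else:
            out.append([c, s, e])
    return [tuple(f) for f in out]


def ref_find_regions(
    treatment,
    control,
    size: int,
    min_dist: int,
    fold: float,
    scale_to: float = 10_000_000.0,
    pseudocount: float = 1.0,
    max_poisson_p: float | None = 1e-4,
) -> list[tuple[str, int, int, float]]:
    """Exhaustive window scan + greedy non-maximum suppression."""
    b = treatment.bin_size
    w = -(-size // b)
    t_total = sum(float(a.sum()) for a in treatment.counts.values())
    c_total = sum(float(a.sum()) for a in control.counts.values())
    st, sc = scale_to / t_total, scale_to / c_total
    genome = treatment.genome
    candidates = []
    for ci, chrom in enumerate(genome.chrom_names):
        t = treatment.counts[chrom]
        c = control.counts[chrom]
        for i in range(t.size - w + 1):
            T = float(np.sum(t[i : i + w]))
            C = float(np.sum(c[i : i + w]))
            score = (T * st + pseudocount) / (C * sc + pseudocount)
            if score < fold:
                continue
            if max_poisson_p is not None:
                mu = max(C * t_total / c_total, 1e-12)
                if stats.poisson.sf(np.ceil(T) - 1, mu) >= max_poisson_p:
                    continue
            candidates.append((score, ci, i))
    candidates.sort(key=lambda x: (-x[0], x[1], x[2]))
    accepted = []
    result = []
    for score, ci, i in candidates:
        center = i * b + w * b / 2
        if any(cj == ci and abs(center - other) < min_dist for cj, other in accepted):
            continue
        accepted.append((ci, center))
        chrom = genome.chrom_names[ci]
        end = min(i * b + w * b, genome.length_of(chrom))
        result.append((chrom, i * b, end, score))
    return sorted(result)


def ref_jaccard(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    return inter / (a[1] - a[0] + b[1] - b[0] - inter)
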