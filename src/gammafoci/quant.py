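"""Scalar quantifications: percent-input ChIP-qPCR, 2^-ddCt expression,
top-k axon-length summary, and differential-expression counting.

Conventions
-----------
percent input
    occupancy % = 100 * input_fraction * 2**(Ct_input - Ct_IP), where
    ``input_fraction`` is the share of pre-cleared chromatin reserved as the
    input aliquot (default 0.1, one-tenth).
2^-ddCt
    per sample dCt = Ct_target - mean(Ct over reference genes); group dCt is
    the replicate mean; ddCt = group dCt - calibrator dCt; fold = 2**-ddCt.
    Multiple reference genes are combined by the arithmetic mean of their Ct
    (equivalent to the geometric mean of their expression).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CT_COLUMNS",
    "validate_ct_table",
    "percent_input",
    "percent_input_table",
    "OccupancyResult",
    "ddct",
    "ExpressionResult",
    "top_k_mean",
    "count_de",
    "DECounts",
]

CT_COLUMNS = ("sample", "group", "target", "replicate", "ct")


def validate_ct_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the well-level qPCR table contract and return it unchanged."""
    missing = [c for c in CT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"Ct table is missing columns: {missing}")
    ct = table["ct"].to_numpy(dtype=float)
    if not np.isfinite(ct).all() or (ct <= 0).any():
        raise ValueError("Ct values must be finite and > 0")
    dup = table.duplicated(subset=["sample", "target", "replicate"])
    if dup.any():
        rows = table.loc[dup, ["sample", "target", "replicate"]].iloc[0].tolist()
        raise ValueError(f"duplicate (sample, target, replicate) rows, e.g. {rows}")
    return table


# ---------------------------------------------------------------- percent input

@dataclass(frozen=True)
class OccupancyResult:
    locus: str
    group: str
    percent_input: float  # replicate mean, %
    replicate_values: tuple[float, ...]
    over_100: bool = False


def percent_input(ct_ip: float, ct_input: float, input_fraction: float = 0.1) -> float:
    """Percent-input occupancy from an IP/input Ct pair.

    Returns 100 * input_fraction * 2**(ct_input - ct_ip). Values above 100%
    are returned as computed (the caller may flag them); they indicate an
    inconsistent Ct pair or dilution.
    """
    if not (0 < input_fraction <= 1):
        raise ValueError("input_fraction must be in (0, 1]")
    if not (math.isfinite(ct_ip) and math.isfinite(ct_input)):
        raise ValueError("Ct values must be finite")
    return 100.0 * input_fraction * 2.0 ** (ct_input - ct_ip)


def percent_input_table(
    table: pd.DataFrame,
    input_fraction: float = 0.1,
    ip_group: str = "IP",
    input_group: str = "input",
) -> list[OccupancyResult]:
    """Pair IP and input wells by (target, replicate) and compute occupancy."""
    validate_ct_table(table)
    results = []
    for locus, sub in table.groupby("target", sort=True):
        ip = sub[sub["group"] == ip_group].set_index("replicate")["ct"]
        inp = sub[sub["group"] == input_group].set_index("replicate")["ct"]
        common = ip.index.intersection(inp.index)
        if common.empty:
            raise ValueError(f"no paired IP/input replicates for target {locus!r}")
        vals = tuple(
            percent_input(float(ip[r]), float(inp[r]), input_fraction) for r in common
        )
        mean = float(np.mean(vals))
        results.append(
            OccupancyResult(
                locus=str(locus),
                group=ip_group,
                percent_input=mean,
                replicate_values=vals,
                over_100=any(v > 100.0 for v in vals),
            )
        )
    return results


# --------------------------------------------------------------------- 2^-ddCt

@dataclass(frozen=True)
class ExpressionResult:
    target: str
    group: str
    delta_ct: float
    delta_delta_ct: float
    fold_change: float
    replicate_folds: tuple[float, ...] = field(default=())


def ddct(
    table: pd.DataFrame,
    target: str,
    reference_targets,
    calibrator_group: str,
) -> list[ExpressionResult]:
    """Relative expression of ``target`` per group by the 2^-ddCt method.

    dCt is averaged over replicates within each group before differencing
    against the calibrator group (the classical formulation); per-replicate
    folds (each replicate's dCt against the calibrator mean dCt) are also
    returned for error bars.
    """
    validate_ct_table(table)
    reference_targets = list(reference_targets)
    if not reference_targets:
        raise ValueError("at least one reference target is required")

    def sample_dct(sub: pd.DataFrame, sample: str) -> float:
        by_target = sub.groupby("target")["ct"].mean()
        for t in [target] + reference_targets:
            if t not in by_target.index:
                raise ValueError(f"sample {sample!r} is missing target {t!r}")
        ref_ct = float(np.mean([by_target[t] for t in reference_targets]))
        return float(by_target[target]) - ref_ct

    group_dcts: dict[str, list[float]] = {}
    for (group, sample), sub in table.groupby(["group", "sample"], sort=True):
        group_dcts.setdefault(str(group), []).append(sample_dct(sub, str(sample)))

    if calibrator_group not in group_dcts:
        raise ValueError(f"calibrator group {calibrator_group!r} not in table")
    calib_dct = float(np.mean(group_dcts[calibrator_group]))

    results = []
    for group, dcts in group_dcts.items():
        group_dct = float(np.mean(dcts))
        ddct_val = group_dct - calib_dct
        results.append(
            ExpressionResult(
                target=target,
                group=group,
                delta_ct=group_dct,
                delta_delta_ct=ddct_val,
                fold_change=2.0 ** (-ddct_val),
                replicate_folds=tuple(2.0 ** (-(d - calib_dct)) for d in dcts),
            )
        )
    return results


# ------------------------------------------------------------------ axon top-k

def top_k_mean(lengths, k: int = 5) -> float:
    """Mean of the k largest values (e.g. the five longest traced axons).

    With fewer than k values, returns the mean of all of them and records a
    warning.
    """
    arr = np.asarray(list(lengths), dtype=float)
    if arr.size == 0:
        raise ValueError("no lengths provided")
    if (arr < 0).any() or not np.isfinite(arr).all():
        raise ValueError("lengths must be finite and non-negative")
    if arr.size < k:
        warnings.warn(
            f"only {arr.size} values available for top-{k} mean; using all",
            stacklevel=2,
        )
        return float(arr.mean())
    return float(np.sort(arr)[-k:].mean())


# ------------------------------------------------------------------ DE counts

@dataclass(frozen=True)
class DECounts:
    n_up: int
    n_down: int
    n_zero_fold: int  # significant but direction-less; counted in neither


def count_de(
    table: pd.DataFrame,
    alpha: float = 0.05,
    p_col: str = "pvalue",
    lfc_col: str = "log2fc",
) -> DECounts:
    """Count differentially expressed genes at p < ``alpha``, split by sign."""
    for col in (p_col, lfc_col):
        if col not in table.columns:
            raise ValueError(f"differential table is missing column {col!r}")
    p = table[p_col].to_numpy(dtype=float)
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    lfc = table[lfc_col].to_numpy(dtype=float)
    sig = p < alpha
    return DECounts(
        n_up=int((sig & (lfc > 0)).sum()),
        n_down=int((sig & (lfc < 0)).sum()),
        n_zero_fold=int((sig & (lfc == 0)).sum()),
    )
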