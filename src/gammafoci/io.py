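"""Plain-text interval and table I/O (BED, truth TSV, manifests)."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .genome import GenomicInterval

__all__ = [
    "read_bed",
    "write_bed",
    "write_truth_tsv",
    "read_truth_tsv",
    "sha256_file",
    "write_manifest",
]

TRUTH_COLUMNS = ("kind", "chrom", "start", "end", "fold", "label")


def read_bed(path) -> list[GenomicInterval]:
    """Read intervals from a BED file (first three columns; extras ignored)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                out.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2])))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return out


def write_bed(records, path, *, names=None, scores=None) -> None:
    """Write intervals as BED6 (name, score clamped to [0, 1000], strand '.')."""
    records = [r.interval if hasattr(r, "interval") else r for r in records]
    with open(path, "w") as fh:
        for i, iv in enumerate(records):
            name = names[i] if names is not None else f"region_{i + 1}"
            score = 0 if scores is None else int(min(max(scores[i], 0), 1000))
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t.\n")


def write_truth_tsv(domains, sites, path) -> None:
    """Planted ground truth as a greppable tab-delimited table."""
    rows = []
    for d in domains:
        rows.append(
            ("domain", d.interval.chrom, d.interval.start, d.interval.end, d.fold, d.label)
        )
    for s in sites:
        rows.append(
            ("site", s.chrom, s.position - s.half_width, s.position + s.half_width,
             s.fold, s.label)
        )
    with open(path, "w") as fh:
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_truth_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in TRUTH_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: truth table is missing columns {missing}")
    return df


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(paths, out_path, meta: dict | None = None) -> list[dict]:
    """Checksum manifest over ``paths``; written as JSON, returned as a list."""
    entries = [
        {
            "path": str(Path(p).name),
            "sha256": sha256_file(p),
            "bytes": Path(p).stat().st_size,
        }
        for p in paths
    ]
    payload = {"files": entries}
    if meta:
        payload["meta"] = meta
    with open(out_path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return entries
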