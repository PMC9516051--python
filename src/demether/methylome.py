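"""Per-cytosine methylation maps: reading, merging, and pairwise intersection.

The exchange format is the 8-column CGmap dialect produced by bisulfite /
EM-seq callers::

    chrom  nuc(C|G)  pos(1-based)  context  dinucleotide  level  meth  total

Sites are kept per-cytosine per-strand (no symmetric-CpG collapsing).  The
floating-point ``level`` column of input files is never trusted: methylation
levels are always recomputed from the integer read counts, which are the
quantities that downstream count-weighted binning needs.

Coordinates are 1-based on disk (CGmap convention); every interval this
package emits is 0-based half-open (BED convention).  The conversion happens
only at I/O boundaries.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

CONTEXTS = ("CG", "CHG", "CHH")

_CGMAP_COLUMNS = [
    "chrom",
    "nuc",
    "pos",
    "context",
    "dinucleotide",
    "level",
    "meth",
    "total",
]


class CGmapError(ValueError):
    """Malformed or internally inconsistent CGmap content."""


@dataclass
class MethylomeMap:
    """All cytosine sites of one sample.

    ``sites`` holds one row per (chrom, pos) with columns
    chrom, pos (1-based), strand, context, dinucleotide, meth, total.
    """

    sample_id: str
    sites: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.sites
        if df.duplicated(["chrom", "pos"]).any():
            dup = df[df.duplicated(["chrom", "pos"])].iloc[0]
            raise CGmapError(
                f"duplicate site at {dup['chrom']}:{dup['pos']} in {self.sample_id}"
            )
        if (df["meth"] > df["total"]).any():
            bad = df[df["meth"] > df["total"]].iloc[0]
            raise CGmapError(
                f"meth > total at {bad['chrom']}:{bad['pos']} in {self.sample_id}"
            )
        bad_ctx = set(df["context"].unique()) - set(CONTEXTS)
        if bad_ctx:
            raise CGmapError(f"unknown context(s) {sorted(bad_ctx)} in {self.sample_id}")

    def __len__(self) -> int:
        return len(self.sites)

    def context(self, context: str) -> pd.DataFrame:
        """Rows of one sequence context."""
        _check_context(context)
        return self.sites[self.sites["context"] == context]

    def levels(self) -> pd.Series:
        """Per-site methylation level meth/total (NaN where total == 0)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            lv = self.sites["meth"] / self.sites["total"]
        return lv.where(self.sites["total"] > 0)


@dataclass
class PairedSiteTable:
    """Sites of one context covered (total > 0) in both of two samples.

    Columns: chrom, pos (1-based), meth_a, total_a, meth_b, total_b,
    sorted by (chrom, pos).
    """

    context: str
    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        _check_context(self.context)
        t = self.table
        if len(t) and ((t["total_a"] <= 0).any() or (t["total_b"] <= 0).any()):
            raise CGmapError("paired table contains uncovered sites")

    def __len__(self) -> int:
        return len(self.table)


def _check_context(context: str) -> None:
    if context not in CONTEXTS:
        raise ValueError(f"context must be one of {CONTEXTS}, got {context!r}")


def read_cgmap(path: str | Path | io.IOBase, sample_id: str | None = None) -> MethylomeMap:
    """Read an 8-column CGmap file into a :class:`MethylomeMap`.

    Strand is derived from the nucleotide column (C -> '+', G -> '-'); the
    level column is ignored and recomputed from the counts downstream.
    """
    name = getattr(path, "name", None) or str(path)
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=_CGMAP_COLUMNS,
            dtype={
                "chrom": str,
                "nuc": str,
                "pos": np.int64,
                "context": str,
                "dinucleotide": str,
                "level": float,
                "meth": np.int64,
                "total": np.int64,
            },
            comment=None,
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise CGmapError(f"malformed CGmap {name}: {exc}") from exc
    bad_nuc = ~df["nuc"].isin(["C", "G"])
    if bad_nuc.any():
        line = int(np.flatnonzero(bad_nuc.to_numpy())[0]) + 1
        raise CGmapError(f"{name} line {line}: nucleotide column must be C or G")
    if (df["meth"] < 0).any() or (df["total"] < df["meth"]).any():
        bad = (df["meth"] < 0) | (df["total"] < df["meth"])
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise CGmapError(f"{name} line {line}: requires 0 <= meth <= total")
    sites = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos": df["pos"],
            "strand": np.where(df["nuc"] == "C", "+", "-"),
            "context": df["context"],
            "dinucleotide": df["dinucleotide"],
            "meth": df["meth"],
            "total": df["total"],
        }
    ).sort_values(["chrom", "pos"], kind="stable", ignore_index=True)
    return MethylomeMap(sample_id or Path(name).stem, sites)


def write_cgmap(mmap: MethylomeMap, path: str | Path) -> None:
    """Write a map back to the 8-column CGmap dialect (counts round-trip exactly)."""
    s = mmap.sites
    with np.errstate(invalid="ignore", divide="ignore"):
        level = np.where(s["total"] > 0, s["meth"] / s["total"], np.nan)
    out = pd.DataFrame(
        {
            "chrom": s["chrom"],
            "nuc": np.where(s["strand"] == "+", "C", "G"),
            "pos": s["pos"],
            "context": s["context"],
            "dinucleotide": s["dinucleotide"],
            "level": np.round(level, 6),
            "meth": s["meth"],
            "total": s["total"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False, na_rep="nan")


def merge_replicates(maps: Sequence[MethylomeMap], sample_id: str | None = None) -> MethylomeMap:
    """Sum read counts across replicate maps, site by site.

    A site present in any input contributes (absence means zero coverage,
    not missing data).  Context and strand must agree wherever a position is
    shared between replicates.
    """
    if not maps:
        raise ValueError("merge_replicates requires at least one map")
    cat = pd.concat([m.sites for m in maps], ignore_index=True)
    grouped = cat.groupby(["chrom", "pos"], sort=True)
    meta = grouped[["strand", "context", "dinucleotide"]].agg(["first", "nunique"])
    for col in ("strand", "context"):
        if (meta[(col, "nunique")] > 1).any():
            key = meta.index[meta[(col, "nunique")] > 1][0]
            raise CGmapError(f"conflicting {col} at {key[0]}:{key[1]} across replicates")
    counts = grouped[["meth", "total"]].sum()
    sites = pd.DataFrame(
        {
            "chrom": counts.index.get_level_values(0),
            "pos": counts.index.get_level_values(1),
            "strand": meta[("strand", "first")].to_numpy(),
            "context": meta[("context", "first")].to_numpy(),
            "dinucleotide": meta[("dinucleotide", "first")].to_numpy(),
            "meth": counts["meth"].to_numpy(),
            "total": counts["total"].to_numpy(),
        }
    ).reset_index(drop=True)
    return MethylomeMap(sample_id or "+".join(m.sample_id for m in maps), sites)


def intersect_samples(a: MethylomeMap, b: MethylomeMap, context: str) -> PairedSiteTable:
    """Sites of one context covered (total > 0) in both samples.

    Mirrors per-context CGmap intersection: the output has one row per
    shared covered position, sorted by (chrom, pos).
    """
    _check_context(context)
    ca = a.context(context)
    cb = b.context(context)
    ca = ca[ca["total"] > 0]
    cb = cb[cb["total"] > 0]
    merged = ca.merge(
        cb[["chrom", "pos", "meth", "total"]],
        on=["chrom", "pos"],
        suffixes=("_a", "_b"),
        how="inner",
    )
    table = (
        merged[["chrom", "pos", "meth_a", "total_a", "meth_b", "total_b"]]
        .sort_values(["chrom", "pos"], kind="stable", ignore_index=True)
    )
    return PairedSiteTable(context, table)
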