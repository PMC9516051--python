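"""Threshold-based callers for 200-bp methylation regions.

All callers work on non-overlapping bins laid on a fixed grid anchored at
coordinate 0 of each chromosome.  A bin is *eligible* (a control region)
when both samples have at least ``min_count_c`` informative CG sites and at
least ``min_count_c`` informative CHG sites at a mean read depth of at
least ``min_cov`` per context.  Differentially methylated regions (DMRs)
are eligible bins whose count-weighted methylation level changes more than
two-fold *and* by more than 0.20 in the same direction in both the CG and
CHG contexts:

    hyper: v2 > fold * v1  and  v2 - v1 > min_abs_dif
    hypo:  v1 > fold * v2  and  v1 - v2 > min_abs_dif

(v1, v2 = bin levels in samples 1 and 2).  A zero denominator needs no
special case: with v1 = 0 the strict fold inequality reduces to v2 > 0, the
limit of the fold condition.  DMR thresholds are strict ("greater than");
the mCHH-region, CHG-UMR, eligibility and methylated-control thresholds are
inclusive ("at least").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .methylome import MethylomeMap, PairedSiteTable, _check_context

#: chromosome names kept when finalizing DMR sets; bins on scaffolds are dropped
DEFAULT_CHROMOSOMES = tuple(f"chr{i}" for i in range(1, 11))


@dataclass(frozen=True)
class DmrParams:
    """Parameters of the dual-context DMR caller."""

    bin_size: int = 200
    min_cov: float = 3.0          # mean read depth over a bin's informative sites
    min_count_c: int = 5          # informative cytosines per context per bin
    min_abs_dif: float = 0.20
    fold: float = 2.0             # relative-change factor (minRelDif 0.5 == 2x)
    chromosomes: tuple[str, ...] = DEFAULT_CHROMOSOMES

    def __post_init__(self) -> None:
        if self.bin_size <= 0 or self.min_cov <= 0 or self.min_count_c <= 0:
            raise ValueError("all thresholds must be strictly positive")
        if self.fold <= 1:
            raise ValueError("fold factor must exceed 1")


def bin_sites(table: PairedSiteTable, bin_size: int = 200) -> pd.DataFrame:
    """Aggregate a paired site table onto the fixed bin grid.

    Returns one row per non-empty bin: chrom, start, end, n_sites and the
    summed meth/total counts of both samples.  1-based site positions map to
    0-based grid bins, so position 200 falls in [0, 200) and 201 in [200, 400).
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    t = table.table
    if not len(t):
        return _empty_bins(["meth_a", "total_a", "meth_b", "total_b"])
    start = ((t["pos"] - 1) // bin_size) * bin_size
    g = t.groupby([t["chrom"], start], sort=True)
    agg = g[["meth_a", "total_a", "meth_b", "total_b"]].sum()
    agg["n_sites"] = g.size()
    out = agg.reset_index().rename(columns={"pos": "start"})
    out["end"] = out["start"] + bin_size
    cols = ["chrom", "start", "end", "n_sites", "meth_a", "total_a", "meth_b", "total_b"]
    return out[cols]


def bin_sites_single(mmap: MethylomeMap, context: str, bin_size: int = 200) -> pd.DataFrame:
    """Single-sample version of :func:`bin_sites` for one context.

    Only covered sites (total > 0) are informative.  Returns chrom, start,
    end, n_sites, meth, total per non-empty bin.
    """
    _check_context(context)
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    s = mmap.context(context)
    s = s[s["total"] > 0]
    if not len(s):
        return _empty_bins(["meth", "total"])
    start = ((s["pos"] - 1) // bin_size) * bin_size
    g = s.groupby([s["chrom"], start], sort=True)
    agg = g[["meth", "total"]].sum()
    agg["n_sites"] = g.size()
    out = agg.reset_index().rename(columns={"pos": "start"})
    out["end"] = out["start"] + bin_size
    return out[["chrom", "start", "end", "n_sites", "meth", "total"]]


def _empty_bins(count_cols: list[str]) -> pd.DataFrame:
    data: dict[str, pd.Series] = {"chrom": pd.Series(dtype=str)}
    for c in ("start", "end", "n_sites", *count_cols):
        data[c] = pd.Series(dtype=np.int64)
    return pd.DataFrame(data)


def _levels(bins: pd.DataFrame, sample: str) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        return (bins[f"meth_{sample}"] / bins[f"total_{sample}"]).to_numpy()


def eligible_bins(
    cg_bins: pd.DataFrame, chg_bins: pd.DataFrame, params: DmrParams = DmrParams()
) -> pd.DataFrame:
    """Bins with enough informative CG *and* CHG sites at depth in both samples.

    The result carries the four bin levels (v1_cg, v2_cg, v1_chg, v2_chg)
    used by the DMR and methylated-control callers downstream.
    """
    for bins, ctx in ((cg_bins, "cg"), (chg_bins, "chg")):
        if len(bins) and (bins["start"] % params.bin_size).any():
            raise ValueError(f"{ctx} bins are not on the bin_size={params.bin_size} grid")

    def _passing(bins: pd.DataFrame) -> pd.DataFrame:
        n = bins["n_sites"].to_numpy()
        ok = (
            (n >= params.min_count_c)
            & (bins["total_a"].to_numpy() / n >= params.min_cov)
            & (bins["total_b"].to_numpy() / n >= params.min_cov)
        )
        return bins[ok]

    cg = _passing(cg_bins)
    chg = _passing(chg_bins)
    merged = cg.merge(chg, on=["chrom", "start", "end"], suffixes=("_cg", "_chg"), how="inner")
    out = merged[["chrom", "start", "end"]].copy()
    for ctx in ("cg", "chg"):
        out[f"v1_{ctx}"] = merged[f"meth_a_{ctx}"] / merged[f"total_a_{ctx}"]
        out[f"v2_{ctx}"] = merged[f"meth_b_{ctx}"] / merged[f"total_b_{ctx}"]
    return out.sort_values(["chrom", "start"], kind="stable", ignore_index=True)


def call_context_dmrs(
    bins: pd.DataFrame, context: str, params: DmrParams = DmrParams()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-context DMR calls on eligibility-filtered bins.

    ``bins`` is the output of :func:`eligible_bins`; ``context`` selects the
    v1/v2 column pair.  Returns (hypo, hyper) subsets.
    """
    key = context.lower()
    if key not in ("cg", "chg"):
        raise ValueError("context must be CG or CHG")
    v1 = bins[f"v1_{key}"].to_numpy()
    v2 = bins[f"v2_{key}"].to_numpy()
    hyper = (v2 > params.fold * v1) & (v2 - v1 > params.min_abs_dif)
    hypo = (v1 > params.fold * v2) & (v1 - v2 > params.min_abs_dif)
    return bins[hypo].reset_index(drop=True), bins[hyper].reset_index(drop=True)


def combine_contexts(
    cg_dmrs: pd.DataFrame,
    chg_dmrs: pd.DataFrame,
    chromosomes: Sequence[str] = DEFAULT_CHROMOSOMES,
) -> pd.DataFrame:
    """Grid bins called as DMRs in both the CG and the CHG context.

    Because both inputs live on the same 200-bp grid, the interval
    intersection reduces to identity of (chrom, start).  Bins on sequences
    outside ``chromosomes`` (unplaced scaffolds) are discarded.
    """
    merged = cg_dmrs.merge(
        chg_dmrs[["chrom", "start", "end"]], on=["chrom", "start", "end"], how="inner"
    )
    merged = merged[merged["chrom"].isin(set(chromosomes))]
    return merged.sort_values(["chrom", "start"], kind="stable", ignore_index=True)


def call_dmrs(
    cg_table: PairedSiteTable,
    chg_table: PairedSiteTable,
    params: DmrParams = DmrParams(),
) -> dict[str, pd.DataFrame]:
    """End-to-end dual-context DMR calling for one sample pair.

    Returns a dict with the eligible control regions and the finalized
    hypo/hyper DMR sets (bins differential in both CG and CHG, scaffolds
    dropped from the DMR sets only).
    """
    cg_bins = bin_sites(cg_table, params.bin_size)
    chg_bins = bin_sites(chg_table, params.bin_size)
    eligible = eligible_bins(cg_bins, chg_bins, params)
    hypo_cg, hyper_cg = call_context_dmrs(eligible, "CG", params)
    hypo_chg, hyper_chg = call_context_dmrs(eligible, "CHG", params)
    return {
        "eligible": eligible,
        "hypo": combine_contexts(hypo_cg, hypo_chg, params.chromosomes),
        "hyper": combine_contexts(hyper_cg, hyper_chg, params.chromosomes),
    }


def find_methylated_regions(
    chh_bins: pd.DataFrame,
    min_count_c: int = 5,
    min_cov: float = 2.0,
    min_meth: float = 0.2,
    strict: bool = False,
) -> pd.DataFrame:
    """mCHH regions of one sample: enough covered CHH sites at depth, level >= 0.2.

    ``chh_bins`` comes from :func:`bin_sites_single`.  ``strict`` switches the
    level comparison from inclusive (default) to strictly greater.
    """
    n = chh_bins["n_sites"].to_numpy()
    level = chh_bins["meth"].to_numpy() / chh_bins["total"].to_numpy()
    ok = (n >= min_count_c) & (chh_bins["total"].to_numpy() / n >= min_cov)
    ok &= (level > min_meth) if strict else (level >= min_meth)
    out = chh_bins[ok].copy().reset_index(drop=True)
    out["level"] = out["meth"] / out["total"]
    return out


def find_unmethylated_regions(
    chg_bins: pd.DataFrame,
    min_count_c: int = 5,
    min_cov: float = 2.0,
    max_meth: float = 0.2,
    strict: bool = False,
) -> pd.DataFrame:
    """CHG-unmethylated regions (UMRs) — the euchromatin proxy track.

    Called on embryo mCHG because euchromatin is stably depleted of mCHG
    across tissues.  ``strict`` switches the level comparison from inclusive
    (default) to strictly less.
    """
    n = chg_bins["n_sites"].to_numpy()
    level = chg_bins["meth"].to_numpy() / chg_bins["total"].to_numpy()
    ok = (n >= min_count_c) & (chg_bins["total"].to_numpy() / n >= min_cov)
    ok &= (level < max_meth) if strict else (level <= max_meth)
    out = chg_bins[ok].copy().reset_index(drop=True)
    out["level"] = out["meth"] / out["total"]
    return out


def methylated_control_filter(eligible: pd.DataFrame, min_level: float = 0.2) -> pd.DataFrame:
    """Eligible regions with both mCG and mCHG >= ``min_level`` in at least one sample.

    These are the methylated control regions used as the comparison set when
    DMRs (which are methylated in at least one sample by construction) are
    profiled against annotations.
    """
    s1 = (eligible["v1_cg"] >= min_level) & (eligible["v1_chg"] >= min_level)
    s2 = (eligible["v2_cg"] >= min_level) & (eligible["v2_chg"] >= min_level)
    return eligible[s1 | s2].reset_index(drop=True)


def write_bed(regions: pd.DataFrame, path, level_cols: Sequence[str] | None = None) -> None:
    """Write region calls as BED3 (+ an optional comma-joined level column)."""
    out = regions[["chrom", "start", "end"]].copy()
    if level_cols and len(regions):
        out["name"] = regions[list(level_cols)].round(4).astype(str).agg(",".join, axis=1)
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    """Read BED3+ into a chrom/start/end frame (extra columns preserved)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df.columns = names[: df.shape[1]] + [f"col{i}" for i in range(6, df.shape[1])]
    df["chrom"] = df["chrom"].astype(str)
    return df
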