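"""Bulked-segregant mapping of a causal mutation from pooled variant tables.

The cross design (heterozygous mother x homozygous mutant father, mutant
homozygotes selected among progeny) predicts a genome-wide alternative
allele frequency of 0.75 in the selected pool, rising toward 1 at markers
linked to the causal locus.  Two per-record filter methods select
near-homozygous alternative variants; windowed scans of mean frequency and
variant density then localize the candidate region.

The variant table is the flat export of a two-bulk VCF with columns::

    CHROM POS REF ALT DP_wt AF_wt GQ_wt DP_mut AF_mut GQ_mut
    PL_homref_mut PL_het_mut PL_homalt_mut

(wt = the wild-type comparison bulk, mut = the combined mutant bulks).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = [
    "CHROM",
    "POS",
    "DP_wt",
    "AF_wt",
    "GQ_wt",
    "DP_mut",
    "AF_mut",
    "GQ_mut",
    "PL_homref_mut",
    "PL_het_mut",
    "PL_homalt_mut",
]


def read_variant_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"CHROM": str})
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"variant table missing columns: {sorted(missing)}")
    return df


def _complete(table: pd.DataFrame, cols: list[str]) -> tuple[pd.DataFrame, int]:
    ok = table[cols].notna().all(axis=1)
    return table[ok], int((~ok).sum())


def filter_variants_method1(table: pd.DataFrame) -> pd.DataFrame:
    """Likelihood-based filter for mutant-linked variants.

    Keeps records with (all bounds inclusive): zero alternative allele
    frequency in the wild-type bulk at depth 2-15; mutant-bulk depth 5-50;
    normalized Phred-scaled likelihood >= 400 for hom-ref and == 0 for
    hom-alt in the mutant bulks.  Records with missing fields are skipped
    (count available via :func:`skipped_records`).
    """
    cols = ["AF_wt", "DP_wt", "DP_mut", "PL_homref_mut", "PL_homalt_mut"]
    t, n_skipped = _complete(table, cols)
    keep = (
        (t["AF_wt"] == 0)
        & (t["DP_wt"] >= 2)
        & (t["DP_wt"] <= 15)
        & (t["DP_mut"] >= 5)
        & (t["DP_mut"] <= 50)
        & (t["PL_homref_mut"] >= 400)
        & (t["PL_homalt_mut"] == 0)
    )
    out = t[keep].reset_index(drop=True)
    out.attrs["n_skipped"] = n_skipped
    return out


def filter_variants_method2(table: pd.DataFrame) -> pd.DataFrame:
    """Genotype-quality filter for mutant-linked variants.

    Keeps records with GQ >= 20 in both bulks, wild-type depth 5-14
    (inclusive), mutant depth 6-49 (inclusive), and mutant alternative
    allele frequency strictly above 0.75.
    """
    cols = ["GQ_wt", "GQ_mut", "DP_wt", "DP_mut", "AF_mut"]
    t, n_skipped = _complete(table, cols)
    keep = (
        (t["GQ_wt"] >= 20)
        & (t["GQ_mut"] >= 20)
        & (t["DP_wt"] >= 5)
        & (t["DP_wt"] <= 14)
        & (t["DP_mut"] >= 6)
        & (t["DP_mut"] <= 49)
        & (t["AF_mut"] > 0.75)
    )
    out = t[keep].reset_index(drop=True)
    out.attrs["n_skipped"] = n_skipped
    return out


def window_scan(
    variants: pd.DataFrame,
    window: int = 1_000_000,
    step: int = 200_000,
    freq_col: str = "AF_mut",
    depth_weighted: bool = False,
) -> pd.DataFrame:
    """Sliding-window variant count, density and mean alt frequency.

    Windows start at multiples of ``step`` per chromosome and cover the
    last variant.  Mean frequency is unweighted across variants by default;
    ``depth_weighted`` weights by mutant-bulk depth.  Empty windows report
    NaN frequency, never 0.
    """
    if not (window >= step > 0):
        raise ValueError("require window >= step > 0")
    rows = []
    for chrom, g in variants.groupby("CHROM", sort=True):
        pos0 = g["POS"].to_numpy() - 1
        order = np.argsort(pos0, kind="stable")
        pos0 = pos0[order]
        freq = g[freq_col].to_numpy()[order]
        w = g["DP_mut"].to_numpy()[order].astype(float) if depth_weighted else np.ones(len(g))
        defined = ~np.isnan(freq)
        last = pos0.max() if len(g) else 0
        for wstart in range(0, int(last) + 1, step):
            wend = wstart + window
            i = np.searchsorted(pos0, wstart, side="left")
            j = np.searchsorted(pos0, wend, side="left")
            n = j - i
            ok = defined[i:j]
            if ok.any():
                mean_f = float(np.average(freq[i:j][ok], weights=w[i:j][ok]))
            else:
                mean_f = np.nan
            rows.append(
                {
                    "chrom": chrom,
                    "start": wstart,
                    "end": wend,
                    "n_variants": n,
                    "mean_freq": mean_f,
                    "density_per_mb": n / (window / 1e6),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class CandidateRegion:
    chrom: str
    start: int
    end: int
    n_windows: int
    pooled_freq: float


def candidate_region(
    stats: pd.DataFrame,
    background: float = 0.75,
    margin: float = 0.15,
    min_windows: int = 3,
) -> CandidateRegion | None:
    """Longest run of consecutive windows with mean frequency above background.

    A window qualifies when its mean frequency exceeds ``background +
    margin``.  Among maximal runs of >= ``min_windows`` consecutive
    qualifying windows (per chromosome, in scan order) the longest wins;
    ties break toward higher variant-pooled mean frequency, then leftmost
    coordinate.  Returns None when no run qualifies.
    """
    if not len(stats):
        raise ValueError("empty window stats")
    best: CandidateRegion | None = None
    for chrom, g in stats.groupby("chrom", sort=True):
        g = g.sort_values("start", kind="stable")
        qual = (g["mean_freq"] > background + margin).fillna(False).to_numpy()
        starts = g["start"].to_numpy()
        ends = g["end"].to_numpy()
        nvar = g["n_variants"].to_numpy()
        freq = np.nan_to_num(g["mean_freq"].to_numpy(), nan=0.0)
        i = 0
        while i < len(qual):
            if not qual[i]:
                i += 1
                continue
            j = i
            while j < len(qual) and qual[j]:
                j += 1
            if j - i >= min_windows:
                tot = nvar[i:j].sum()
                pooled = float((freq[i:j] * nvar[i:j]).sum() / tot) if tot else 0.0
                cand = CandidateRegion(
                    chrom=str(chrom),
                    start=int(starts[i]),
                    end=int(ends[j - 1]),
                    n_windows=j - i,
                    pooled_freq=pooled,
                )
                if _better(cand, best):
                    best = cand
            i = j
    return best


def _better(cand: CandidateRegion, best: CandidateRegion | None) -> bool:
    if best is None:
        return True
    key_c = (cand.n_windows, cand.pooled_freq, -cand.start)
    key_b = (best.n_windows, best.pooled_freq, -best.start)
    return key_c > key_b
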