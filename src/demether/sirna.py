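"""Small-RNA read classification and siRNA-region calling.

Reads arrive as aligned intervals (BED-like: chrom, start, end, length,
mapq, library_id, replicate_id).  siRNAs are 20-25 nt reads that do not
overlap housekeeping small-RNA loci (tRNA, 5S, NOR, miRNA) over at least
90% of their length.  Libraries are depth-matched by uniform subsampling
before region-level comparisons, and a region is an "siRNA region" when at
least 50 bp of it is spanned by the union of siRNA footprints.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .intervals import overlap_bp, overlap_select

READ_COLUMNS = ["chrom", "start", "end", "length", "mapq", "library_id", "replicate_id"]


def read_sirna_table(path) -> pd.DataFrame:
    """Read a BED-like small-RNA alignment table (TSV with header)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(READ_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"siRNA table missing columns: {sorted(missing)}")
    return df


def classify_sirnas(
    reads: pd.DataFrame,
    exclusion_loci: pd.DataFrame,
    min_len: int = 20,
    max_len: int = 25,
    excl_frac: float = 0.9,
) -> pd.DataFrame:
    """Length-filter reads and drop those inside housekeeping small-RNA loci.

    Keeps reads with min_len <= length <= max_len that overlap the union of
    ``exclusion_loci`` over less than ``excl_frac`` of their length.
    """
    in_window = (reads["length"] >= min_len) & (reads["length"] <= max_len)
    kept = reads[in_window]
    if len(exclusion_loci):
        kept = overlap_select(kept, exclusion_loci, excl_frac, invert=True)
    return kept.reset_index(drop=True)


def subsample_reads(reads: pd.DataFrame, n: int, seed: int) -> pd.DataFrame:
    """Uniform sample of ``n`` reads without replacement (fixed-seed reproducible)."""
    if n > len(reads):
        raise ValueError(
            f"cannot subsample {n} reads from a library of {len(reads)} "
            f"(short by {n - len(reads)})"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(reads), size=n, replace=False)
    return reads.iloc[np.sort(idx)].reset_index(drop=True)


def length_distribution(
    reads: pd.DataFrame, min_len: int = 20, max_len: int = 25
) -> pd.DataFrame:
    """Per-length read proportions with SEM across biological replicates.

    Proportions are computed within each replicate (summing to 1 over the
    length window), then averaged; SEM = sd / sqrt(r) with r replicates
    (0 when r == 1).
    """
    lengths = np.arange(min_len, max_len + 1)
    reps = sorted(reads["replicate_id"].unique())
    if not reps:
        raise ValueError("no replicates present")
    props = np.zeros((len(reps), len(lengths)))
    for ri, rep in enumerate(reps):
        sub = reads[reads["replicate_id"] == rep]
        counts = sub["length"].value_counts()
        tot = counts.reindex(lengths, fill_value=0).sum()
        if tot:
            props[ri] = counts.reindex(lengths, fill_value=0).to_numpy() / tot
    mean = props.mean(axis=0)
    sem = props.std(axis=0, ddof=1) / np.sqrt(len(reps)) if len(reps) > 1 else np.zeros(len(lengths))
    return pd.DataFrame({"length": lengths, "proportion": mean, "sem": sem})


def assign_reads_to_regions(
    reads: pd.DataFrame,
    regions: pd.DataFrame,
    frac: float = 0.9,
    unique_only: bool = False,
    min_mapq: int = 20,
) -> pd.DataFrame:
    """Reads overlapping >= ``frac`` of their length with the region union.

    ``unique_only`` restricts to alignments with MAPQ >= ``min_mapq``
    (the uniquely-mappable analysis mode); otherwise every alignment record
    is counted where it was placed.
    """
    pool = reads[reads["mapq"] >= min_mapq] if unique_only else reads
    if not len(regions):
        return pool.iloc[0:0].reset_index(drop=True)
    return overlap_select(pool, regions, frac).reset_index(drop=True)


def call_sirna_regions(
    regions: pd.DataFrame, reads: pd.DataFrame, min_span: int = 50
) -> pd.DataFrame:
    """Span each region with the union of read footprints; flag >= ``min_span`` bp.

    Coverage is a union, not a sum: stacking duplicate reads never changes
    a call.  Returns the regions with ``spanned_bp`` and ``has_sirna``.
    """
    out = regions.copy().reset_index(drop=True)
    out["spanned_bp"] = overlap_bp(out, reads)
    out["has_sirna"] = out["spanned_bp"] >= min_span
    return out
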