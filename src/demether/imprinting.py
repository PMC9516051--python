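"""Imprinting classification and expression categories for endosperm genes.

Endosperm is triploid with two maternal genomes and one paternal genome, so
a non-imprinted gene is expected to show a maternal read ratio of 2/3 at
allele-informative SNPs.  Maternally expressed genes (MEGs) are defined by
a maternal ratio above 0.9, paternally expressed genes (PEGs) below 0.1,
and everything callable in between is biallelic.  Genes without enough
informative reads are uncallable rather than biallelic.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import distance_to_nearest, overlap_bp

MEG_THRESHOLD = 0.9
PEG_THRESHOLD = 0.1

#: expected maternal ratio of a non-imprinted gene under 2m:1p genome dosage
BIALLELIC_EXPECTATION = 2.0 / 3.0


def maternal_ratio(counts: pd.DataFrame, min_informative: int = 10) -> pd.DataFrame:
    """Per-feature maternal ratio and MEG/PEG/biallelic/uncallable category.

    ``counts`` has feature_id, maternal_reads, paternal_reads and optionally
    a ``direction`` column for reciprocal crosses; counts are summed across
    directions before the ratio is taken.  Features with fewer than
    ``min_informative`` total reads are uncallable.
    """
    if min_informative < 1:
        raise ValueError("min_informative must be >= 1")
    agg = counts.groupby("feature_id", sort=True)[["maternal_reads", "paternal_reads"]].sum()
    total = agg["maternal_reads"] + agg["paternal_reads"]
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = agg["maternal_reads"] / total
    ratio = ratio.where(total > 0)
    category = np.select(
        [
            total < min_informative,
            ratio > MEG_THRESHOLD,
            ratio < PEG_THRESHOLD,
        ],
        ["uncallable", "MEG", "PEG"],
        default="biallelic",
    )
    return pd.DataFrame(
        {
            "feature_id": agg.index,
            "maternal_reads": agg["maternal_reads"].to_numpy(),
            "paternal_reads": agg["paternal_reads"].to_numpy(),
            "maternal_ratio": ratio.to_numpy(),
            "category": category,
        }
    ).reset_index(drop=True)


def category_dmr_overlap(
    calls: pd.DataFrame,
    features: pd.DataFrame,
    dmrs: pd.DataFrame,
    overlap_min_bp: int = 100,
    near_bp: int = 2000,
) -> pd.DataFrame:
    """Distance-to-DMR bins (overlap / within 2 kb / beyond 2 kb) per category.

    ``features`` maps feature_id to intervals.  A feature "overlaps" when at
    least ``overlap_min_bp`` of DMR bases fall inside it; otherwise it is
    binned by gap distance to the nearest DMR.  Returns one row per
    (category, distance_bin) with counts and within-category proportions.
    """
    feat = features.merge(calls[["feature_id", "category"]], on="feature_id", how="inner")
    if len(dmrs):
        ov = overlap_bp(feat, dmrs)
        dist = distance_to_nearest(feat, dmrs)
    else:
        ov = np.zeros(len(feat), dtype=int)
        dist = np.full(len(feat), np.inf)
    dist = np.where(np.isnan(dist), np.inf, dist)
    bin_label = np.select(
        [ov >= overlap_min_bp, dist <= near_bp],
        ["overlap", "near"],
        default="far",
    )
    feat = feat.assign(distance_bin=bin_label)
    counts = (
        feat.groupby(["category", "distance_bin"], sort=True)
        .size()
        .rename("n")
        .reset_index()
    )
    totals = counts.groupby("category")["n"].transform("sum")
    counts["proportion"] = counts["n"] / totals
    return counts


def classify_expression(
    rpm: pd.DataFrame,
    endosperm_libs: Sequence[str],
    on_rpm: float = 1.0,
    off_rpm: float = 0.5,
    constitutive_max_libs: int = 3,
    on_min_libs: int = 18,
    off_min_libs: int = 20,
) -> pd.Series:
    """Expression category per gene from a gene x library RPM matrix.

    Categories, assigned in precedence order:

    * ``constitutive_off`` — RPM > 1 in fewer than 3 of all libraries;
    * ``endosperm_on`` — RPM > 1 in at least 18 of the 21 endosperm libraries;
    * ``endosperm_off`` — RPM < 0.5 in at least 20 of the 21 endosperm libraries;
    * ``unclassified`` — the rest.

    Defaults mirror an atlas of 225 libraries with 21 endosperm libraries;
    the counts scale through the keyword thresholds for other designs.
    """
    endosperm_libs = list(endosperm_libs)
    missing = set(endosperm_libs) - set(rpm.columns)
    if missing:
        raise ValueError(f"endosperm libraries absent from matrix: {sorted(missing)}")
    n_on_all = (rpm > on_rpm).sum(axis=1)
    endo = rpm[endosperm_libs]
    n_on_endo = (endo > on_rpm).sum(axis=1)
    n_off_endo = (endo < off_rpm).sum(axis=1)
    category = np.select(
        [
            n_on_all < constitutive_max_libs,
            n_on_endo >= on_min_libs,
            n_off_endo >= off_min_libs,
        ],
        ["constitutive_off", "endosperm_on", "endosperm_off"],
        default="unclassified",
    )
    return pd.Series(category, index=rpm.index, name="expression_category")
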