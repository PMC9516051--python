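"""Characterization of region sets against genomic annotations.

Enrichment of DMRs over matched control regions for annotation overlap,
end-anchored (TSS / polyA / element-end) enrichment profiles, distance to
the nearest euchromatin region, methylation profiles over flanking DNA,
GC content, and degenerate-consensus motif matching.

Annotations are plain frames (chrom, start, end, strand, element_class,
family, ...); anchors are points with strand.  Enrichment statistics always
normalize by eligible control regions rather than by genome length, which
cancels the strong ascertainment bias of coverage-eligible bins.
"""

from __future__ import annotations

import re
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import reverse_complement

from .intervals import overlap_bp, overlap_select
from .methylome import MethylomeMap, PairedSiteTable


def element_enrichment(
    dmrs: pd.DataFrame,
    controls: pd.DataFrame,
    elements: pd.DataFrame,
    min_frac: float = 0.5,
) -> float | None:
    """Fold enrichment of element overlap among DMRs relative to controls.

    (proportion of DMRs overlapping an element by >= ``min_frac`` of their
    length) / (same proportion among control regions).  Returns None when
    no control region overlaps (the enrichment is undefined, not infinite).
    """
    if not len(dmrs) or not len(controls):
        raise ValueError("dmrs and controls must be non-empty")
    p_dmr = len(overlap_select(dmrs, elements, min_frac)) / len(dmrs)
    p_ctrl = len(overlap_select(controls, elements, min_frac)) / len(controls)
    if p_ctrl == 0:
        return None
    return p_dmr / p_ctrl


def _profile_counts(
    regions: pd.DataFrame,
    anchors: pd.DataFrame,
    window: int,
    bin_size: int,
) -> np.ndarray:
    """Count region-bin overlap events per anchor-relative 100-bp offset bin.

    A region is counted once per offset bin it touches (per anchor).  Minus
    strand anchors are mirrored so offsets run in transcript orientation.
    """
    nbins = 2 * window // bin_size
    counts = np.zeros(nbins, dtype=np.int64)
    if not len(regions) or not len(anchors):
        return counts
    for c, anc in anchors.groupby("chrom", sort=False):
        reg = regions[regions["chrom"] == c].sort_values("start")
        if not len(reg):
            continue
        rs = reg["start"].to_numpy()
        re_ = reg["end"].to_numpy()
        for apos, strand in zip(anc["pos"].to_numpy(), anc["strand"].to_numpy()):
            lo, hi = apos - window, apos + window
            i = np.searchsorted(re_, lo, side="right")
            j = np.searchsorted(rs, hi, side="left")
            for k in range(i, j):
                if strand == "-":
                    o0, o1 = apos - re_[k], apos - rs[k]
                else:
                    o0, o1 = rs[k] - apos, re_[k] - apos
                b0 = max(int(np.floor(o0 / bin_size)), -window // bin_size)
                b1 = min(int(np.ceil(o1 / bin_size)), window // bin_size)
                if b1 > b0:
                    counts[b0 + window // bin_size : b1 + window // bin_size] += 1
    return counts


def end_anchored_enrichment(
    dmrs: pd.DataFrame,
    controls: pd.DataFrame,
    anchors: pd.DataFrame,
    window: int = 3000,
    bin_size: int = 100,
) -> pd.DataFrame:
    """DMR/control overlap-count ratio per 100-bp bin around anchor points.

    ``anchors`` needs chrom, pos (0-based), strand.  Callers exclude
    solo-LTR elements from end anchors before calling.  Bins where no
    control overlaps get NaN enrichment (missing, never zero).
    """
    if window % bin_size:
        raise ValueError("window must be a multiple of bin_size")
    n_dmr = _profile_counts(dmrs, anchors, window, bin_size)
    n_ctl = _profile_counts(controls, anchors, window, bin_size)
    offsets = np.arange(-window, window, bin_size)
    with np.errstate(invalid="ignore", divide="ignore"):
        enr = np.where(n_ctl > 0, n_dmr / np.maximum(n_ctl, 1), np.nan)
    return pd.DataFrame(
        {"offset_bp": offsets, "n_query": n_dmr, "n_control": n_ctl, "enrichment": enr}
    )


def gene_anchors(genes: pd.DataFrame, which: str = "tss") -> pd.DataFrame:
    """TSS or polyA anchor points of stranded gene intervals."""
    if which not in ("tss", "polya"):
        raise ValueError("which must be 'tss' or 'polya'")
    plus = genes["strand"].to_numpy() == "+"
    at_start = plus if which == "tss" else ~plus
    pos = np.where(at_start, genes["start"].to_numpy(), genes["end"].to_numpy())
    return pd.DataFrame({"chrom": genes["chrom"], "pos": pos, "strand": genes["strand"]})


def element_end_anchors(elements: pd.DataFrame) -> pd.DataFrame:
    """5' and 3' end anchors of stranded elements (two rows per element)."""
    five = gene_anchors(elements, "tss")
    three = gene_anchors(elements, "polya")
    return pd.concat([five, three], ignore_index=True)


def flank_profile(
    regions: pd.DataFrame,
    methylome: MethylomeMap | PairedSiteTable | pd.DataFrame,
    context: str | None = None,
    sample: str = "a",
    flank: int = 3000,
    bin_size: int = 100,
    min_cov: int = 1,
    chunk: int = 2000,
) -> pd.DataFrame:
    """Mean methylation per 100-bp bin within and around each region.

    Offsets are relative to the region start; the interior of a 200-bp
    region occupies the two central bins [0,100) and [100,200).  Per region
    and bin the level is count-weighted over sites with coverage >=
    ``min_cov``; the profile value is the mean of those levels across
    regions, with ``n`` the number of contributing regions.  Bins with no
    covered site anywhere are missing (NaN), never zero.
    """
    sites = _site_frame(methylome, context, sample)
    reg_len = int((regions["end"] - regions["start"]).max()) if len(regions) else 0
    nbins = (2 * flank + reg_len) // bin_size
    sum_level = np.zeros(nbins)
    n_reg = np.zeros(nbins, dtype=np.int64)
    pos0 = sites["pos"].to_numpy() - 1  # 0-based site coordinate
    meth = sites["meth"].to_numpy()
    total = sites["total"].to_numpy()
    covered = total >= min_cov
    for c, reg in regions.groupby("chrom", sort=False):
        cmask = (sites["chrom"] == c).to_numpy() & covered
        if not cmask.any():
            continue
        p = pos0[cmask]
        order = np.argsort(p, kind="stable")
        p = p[order]
        m = meth[cmask][order]
        t = total[cmask][order]
        starts = reg["start"].to_numpy()
        for lo in range(0, len(starts), chunk):
            rstart = starts[lo : lo + chunk]
            i = np.searchsorted(p, rstart - flank, side="left")
            j = np.searchsorted(p, rstart + reg_len + flank, side="left")
            counts = j - i
            if counts.sum() == 0:
                continue
            ridx = np.repeat(np.arange(len(rstart)), counts)
            sidx = _ranges(i, j)
            off = p[sidx] - rstart[ridx] + flank
            b = off // bin_size
            flat = ridx * nbins + b
            msum = np.bincount(flat, weights=m[sidx], minlength=len(rstart) * nbins)
            tsum = np.bincount(flat, weights=t[sidx], minlength=len(rstart) * nbins)
            msum = msum.reshape(len(rstart), nbins)
            tsum = tsum.reshape(len(rstart), nbins)
            has = tsum > 0
            with np.errstate(invalid="ignore", divide="ignore"):
                lv = np.where(has, msum / np.maximum(tsum, 1), 0.0)
            sum_level += lv.sum(axis=0)
            n_reg += has.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        value = np.where(n_reg > 0, sum_level / np.maximum(n_reg, 1), np.nan)
    offsets = np.arange(-flank, -flank + nbins * bin_size, bin_size)
    return pd.DataFrame({"offset_bp": offsets, "value": value, "n": n_reg})


def _ranges(i: np.ndarray, j: np.ndarray) -> np.ndarray:
    """Concatenated arange(i[k], j[k]) for all k (empty ranges skipped)."""
    counts = j - i
    keep = counts > 0
    if not keep.any():
        return np.empty(0, dtype=np.int64)
    i2, j2, c2 = i[keep], j[keep], counts[keep]
    out = np.ones(int(c2.sum()), dtype=np.int64)
    first = np.cumsum(np.concatenate([[0], c2[:-1]]))
    out[first] = i2 - np.concatenate([[0], j2[:-1] - 1])
    return np.cumsum(out)


def _site_frame(
    methylome: MethylomeMap | PairedSiteTable | pd.DataFrame,
    context: str | None,
    sample: str,
) -> pd.DataFrame:
    if isinstance(methylome, MethylomeMap):
        s = methylome.context(context) if context else methylome.sites
        return s[["chrom", "pos", "meth", "total"]]
    if isinstance(methylome, PairedSiteTable):
        if sample not in ("a", "b"):
            raise ValueError("sample must be 'a' or 'b'")
        t = methylome.table
        return pd.DataFrame(
            {"chrom": t["chrom"], "pos": t["pos"], "meth": t[f"meth_{sample}"], "total": t[f"total_{sample}"]}
        )
    return methylome[["chrom", "pos", "meth", "total"]]


def gc_content(sequences: Iterable[str] | str) -> float:
    """(G+C) / (A+C+G+T) pooled over sequences; N bases are excluded.

    NaN when no unambiguous base is present.
    """
    if isinstance(sequences, str):
        sequences = [sequences]
    gc = acgt = 0
    for seq in sequences:
        s = seq.upper()
        gc += s.count("G") + s.count("C")
        acgt += sum(s.count(b) for b in "ACGT")
    return gc / acgt if acgt else float("nan")


def _iupac_regex(motif: str) -> str:
    parts = []
    for ch in motif.upper():
        if ch not in ambiguous_dna_values:
            raise ValueError(f"invalid IUPAC code {ch!r} in motif {motif!r}")
        vals = ambiguous_dna_values[ch]
        parts.append(vals if len(vals) == 1 else f"[{vals}]")
    return "".join(parts)


def iupac_motif_scan(
    sequences: Iterable[str] | str,
    motif: str,
    both_strands: bool = True,
) -> list[list[tuple[int, str]]]:
    """Exact degenerate-consensus matches of an IUPAC motif.

    Returns, per sequence, the 0-based start positions of every
    (possibly overlapping) match, with '+' or '-' for the strand.  Reverse
    strand hits are reported at their forward-strand start coordinate.
    """
    if isinstance(sequences, str):
        sequences = [sequences]
    fwd = re.compile(f"(?=({_iupac_regex(motif)}))")
    rev = re.compile(f"(?=({_iupac_regex(reverse_complement(motif))}))")
    out = []
    for seq in sequences:
        s = seq.upper()
        hits = [(m.start(), "+") for m in fwd.finditer(s)]
        if both_strands:
            hits += [(m.start(), "-") for m in rev.finditer(s)]
        out.append(sorted(hits))
    return out


def motif_presence(sequences: Iterable[str], motifs: Sequence[str]) -> np.ndarray:
    """Boolean per sequence: does any of the motifs match on either strand."""
    seqs = list(sequences)
    present = np.zeros(len(seqs), dtype=bool)
    for motif in motifs:
        hits = iupac_motif_scan(seqs, motif, both_strands=True)
        present |= np.array([len(h) > 0 for h in hits])
    return present


def read_gff3(path) -> pd.DataFrame:
    """Flatten a GFF3 file into a chrom/start/end frame (0-based half-open).

    Attribute keys become columns (ID, class, family, ...) so TE metadata
    like superfamily codes and solo-LTR naming survive the round trip.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    rows = []
    for feat in db.all_features():
        row = {
            "chrom": feat.seqid,
            "start": feat.start - 1,
            "end": feat.end,
            "strand": feat.strand or ".",
            "feature": feat.featuretype,
        }
        for key, vals in feat.attributes.items():
            row[key] = vals[0] if vals else ""
        rows.append(row)
    return pd.DataFrame(rows)


def fraction_beyond(distances: np.ndarray, cutoff: float = 2000.0) -> float:
    """Fraction of defined distances strictly greater than ``cutoff``."""
    d = np.asarray(distances, dtype=float)
    d = d[~np.isnan(d)]
    if not len(d):
        return float("nan")
    return float((d > cutoff).mean())
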