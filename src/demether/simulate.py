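"""Synthetic data with planted ground truth for every pipeline stage.

The generator emits the complete set of inputs the analysis consumes —
genome sequence and annotations, per-cytosine methylation maps for
wild-type endosperm, mutant endosperm and embryo (three biological
replicates each), small-RNA read tables, allele-count tables for
imprinting, and a two-bulk variant table for bulked-segregant mapping —
at desk scale, with the statistical structure the analysis assumes:

* a two-compartment methylome (euchromatin around genes, heterochromatin
  elsewhere) with binomial read sampling at Poisson coverage and a small
  enzymatic-conversion error;
* planted demethylated regions (truth 0.8 -> 0.05 in both mCG and mCHG in
  wild-type endosperm, high everywhere else) on the 200-bp caller grid;
* siRNA emission concentrated at annotated loci, doubled at demethylated
  regions in the mutant;
* maternal:paternal allele counts under triploid 2:1 dosage with planted
  MEGs and PEGs;
* a bulked-segregant cross (heterozygous mother x homozygous mutant
  father, mutant homozygotes selected) with Haldane recombination along a
  maize-like genetic map and binomial read sampling of the pooled bulks.

Every generator takes an explicit ``numpy.random.Generator`` and is
byte-reproducible for a fixed seed.  Defaults are deliberately desk-scale
(two 5-Mb chromosomes plus an unplaced scaffold; genome-wide counts from
the real organism are out of reach at this size).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .methylome import MethylomeMap

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class GenomePlan:
    chrom_lengths: tuple[tuple[str, int], ...] = (
        ("chr1", 5_000_000),
        ("chr2", 5_000_000),
        ("scaffold_282", 500_000),
    )
    gc: float = 0.47


@dataclass(frozen=True)
class AnnotationPlan:
    n_genes: int = 200
    gene_length: int = 2_000
    n_helitrons: int = 120           # DHH-superfamily family with planted motifs
    helitron_length: int = 1_000
    helitron_motif_fraction: float = 0.5
    n_gypsies: int = 60              # RLG family, some as solo LTRs
    gypsy_length: int = 5_000
    solo_ltr_fraction: float = 0.3
    solo_ltr_length: int = 1_000
    n_tandem: int = 20
    tandem_length: int = 2_000
    n_trna: int = 30
    trna_length: int = 80
    n_mirna: int = 10
    mirna_length: int = 150
    n_5s: int = 10
    fives_length: int = 120
    n_nor: int = 2
    nor_length: int = 5_000


@dataclass(frozen=True)
class MethylomePlan:
    n_replicates: int = 3
    coverage_per_replicate: float = 10.0   # merged mean depth = 30
    conversion_error: float = 0.005
    site_density: tuple[tuple[str, float], ...] = (("CG", 0.05), ("CHG", 0.05), ("CHH", 0.06))
    # (mCG, mCHG, mCHH) truth baselines per compartment
    heterochromatin: tuple[float, float, float] = (0.85, 0.75, 0.08)
    euchromatin: tuple[float, float, float] = (0.05, 0.02, 0.01)
    euchromatin_flank: int = 1_000


@dataclass(frozen=True)
class DmrPlan:
    n_dmrs: int = 300
    level_high: float = 0.80   # mCG/mCHG truth where methylation is retained
    level_low: float = 0.05    # truth in wild-type endosperm (demethylated)
    frac_in_helitrons: float = 0.4
    frac_near_genes: float = 0.3
    chromosomes: tuple[str, ...] = ("chr1", "chr2")
    n_chh_regions: int = 200
    chh_level: float = 0.4


@dataclass(frozen=True)
class SirnaPlan:
    n_replicates: int = 3
    dmr_rate_wt: float = 2.5             # expected reads per DMR locus, wild type
    mutant_multiplier: float = 2.0
    background_loci: int = 2_000
    background_rate: float = 1.0
    exclusion_rate: float = 200.0        # housekeeping loci emit abundantly
    length_probs: tuple[tuple[int, float], ...] = (
        (20, 0.04), (21, 0.16), (22, 0.10), (23, 0.05), (24, 0.60), (25, 0.05)
    )
    low_mapq_fraction: float = 0.2


@dataclass(frozen=True)
class ImprintingPlan:
    n_genes: int = 1_000
    meg_fraction: float = 0.05
    peg_fraction: float = 0.05
    mean_depth: int = 200
    p_biallelic: float = 2.0 / 3.0
    p_meg: float = 0.97
    p_peg: float = 0.03


@dataclass(frozen=True)
class BsaPlan:
    n_chromosomes: int = 10
    chrom_length: int = 5_000_000
    marker_spacing: int = 50_000
    genetic_length: float = 1.5          # Morgans per chromosome (maize-like)
    causal_chrom: str = "chr4"
    causal_pos: int = 4_800_000          # near the distal chromosome tip
    n_selected: int = 500
    depth_mut: float = 30.0
    depth_wt: float = 8.0
    error_rate: float = 0.001


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    genome: GenomePlan = GenomePlan()
    annotation: AnnotationPlan = AnnotationPlan()
    methylome: MethylomePlan = MethylomePlan()
    dmr: DmrPlan = DmrPlan()
    sirna: SirnaPlan = SirnaPlan()
    imprinting: ImprintingPlan = ImprintingPlan()
    bsa: BsaPlan = BsaPlan()

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------
# genome and annotation


@dataclass
class Annotation:
    """All annotated features of one synthetic genome."""

    chrom_lengths: dict[str, int]
    sequences: dict[str, str] = field(repr=False)
    genes: pd.DataFrame = field(repr=False)
    tes: pd.DataFrame = field(repr=False)
    tandem: pd.DataFrame = field(repr=False)
    exclusion: pd.DataFrame = field(repr=False)

    def euchromatin(self, flank: int = 1_000) -> pd.DataFrame:
        """Gene bodies with flanks — the low-methylation compartment."""
        from .intervals import merge_intervals

        g = self.genes.copy()
        g["start"] = np.maximum(g["start"] - flank, 0)
        g["end"] = g["end"] + flank
        return merge_intervals(g, 0)


class _Occupancy:
    """Rejection-sampling placement of non-overlapping features."""

    def __init__(self, chrom_lengths: dict[str, int]):
        self.lengths = chrom_lengths
        self.taken: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_lengths}

    def place(
        self,
        rng: np.random.Generator,
        n: int,
        length: int,
        chroms: list[str] | None = None,
        max_tries: int = 2_000,
    ) -> pd.DataFrame:
        chroms = chroms or list(self.lengths)
        weights = np.array([self.lengths[c] for c in chroms], dtype=float)
        weights /= weights.sum()
        rows = []
        for _ in range(n):
            for _try in range(max_tries):
                c = chroms[rng.choice(len(chroms), p=weights)]
                limit = self.lengths[c] - length
                if limit <= 0:
                    continue
                start = int(rng.integers(0, limit))
                if self._free(c, start, start + length):
                    self._insert(c, start, start + length)
                    rows.append((c, start, start + length))
                    break
            else:
                raise ValueError(
                    f"cannot place {n} features of length {length}: genome too full"
                )
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])

    def _free(self, c: str, s: int, e: int) -> bool:
        iv = self.taken[c]
        i = bisect.bisect_left(iv, (s, s))
        if i < len(iv) and iv[i][0] < e:
            return False
        if i > 0 and iv[i - 1][1] > s:
            return False
        return True

    def _insert(self, c: str, s: int, e: int) -> None:
        bisect.insort(self.taken[c], (s, e))


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p).astype(np.uint8)


#: PHERES1-binding consensus motifs planted into a subset of Helitron copies
PHE1_MOTIFS = ("TTWCCATATW", "CCAWAAATGG")


def make_genome_annotation(
    config: SimConfig, rng: np.random.Generator | None = None
) -> Annotation:
    """Random genome with non-overlapping genes, TEs, repeats and ncRNA loci.

    Helitron-family copies receive a planted PHE1-motif instance in a
    configured fraction of copies; gypsy copies are split into full-length
    elements and solo LTRs (flagged, shorter, excluded from end profiles).
    """
    rng = config.rng() if rng is None else rng
    gp, ap = config.genome, config.annotation
    lengths = dict(gp.chrom_lengths)
    seqs = {c: _random_sequence(rng, L, gp.gc) for c, L in lengths.items()}
    occ = _Occupancy(lengths)
    chroms = [c for c in lengths if not c.startswith("scaffold")]

    genes = occ.place(rng, ap.n_genes, ap.gene_length, chroms)
    genes["strand"] = np.where(rng.random(len(genes)) < 0.5, "+", "-")
    genes["feature_id"] = [f"gene{i:05d}" for i in range(len(genes))]

    hel = occ.place(rng, ap.n_helitrons, ap.helitron_length, chroms)
    hel["element_class"] = "DHH"
    hel["family"] = "DHH00002"
    hel["solo_ltr"] = False
    n_solo = int(round(ap.n_gypsies * ap.solo_ltr_fraction))
    gyp_full = occ.place(rng, ap.n_gypsies - n_solo, ap.gypsy_length, chroms)
    gyp_solo = occ.place(rng, n_solo, ap.solo_ltr_length, chroms)
    for df, solo in ((gyp_full, False), (gyp_solo, True)):
        df["element_class"] = "RLG"
        df["family"] = "RLG00001"
        df["solo_ltr"] = solo
    tes = pd.concat([hel, gyp_full, gyp_solo], ignore_index=True)
    tes["strand"] = np.where(rng.random(len(tes)) < 0.5, "+", "-")
    tes["feature_id"] = [f"te{i:05d}" for i in range(len(tes))]

    tandem = occ.place(rng, ap.n_tandem, ap.tandem_length, chroms)
    tandem["family"] = rng.choice(["knob180", "CentC", "TR-1"], size=len(tandem)).tolist()

    excl_parts = []
    for cls, n, length in (
        ("tRNA", ap.n_trna, ap.trna_length),
        ("miRNA", ap.n_mirna, ap.mirna_length),
        ("5S", ap.n_5s, ap.fives_length),
        ("NOR", ap.n_nor, ap.nor_length),
    ):
        part = occ.place(rng, n, length, chroms)
        part["element_class"] = cls
        excl_parts.append(part)
    exclusion = pd.concat(excl_parts, ignore_index=True)

    # plant a PHE1 motif inside a fraction of Helitron copies
    motif_flags = rng.random(len(hel)) < ap.helitron_motif_fraction
    for k in np.flatnonzero(motif_flags):
        row = hel.iloc[k]
        motif = PHE1_MOTIFS[int(rng.integers(0, 2))]
        inst = np.frombuffer(
            motif.replace("W", "AT"[int(rng.integers(0, 2))]).encode(), dtype=np.uint8
        )
        code = np.array([_BASES.tolist().index(b) for b in inst], dtype=np.uint8)
        offset = int(rng.integers(0, ap.helitron_length - len(motif)))
        seqs[row["chrom"]][row["start"] + offset : row["start"] + offset + len(motif)] = code
    tes["has_motif"] = False
    tes.loc[hel.index[motif_flags], "has_motif"] = True

    sequences = {c: _BASES[a].tobytes().decode() for c, a in seqs.items()}
    return Annotation(
        chrom_lengths=lengths,
        sequences=sequences,
        genes=genes[["chrom", "start", "end", "strand", "feature_id"]],
        tes=tes[
            ["chrom", "start", "end", "strand", "feature_id", "element_class", "family", "solo_ltr", "has_motif"]
        ],
        tandem=tandem,
        exclusion=exclusion,
    )


# ---------------------------------------------------------------------------
# planted regions and methylomes


def plant_regions(
    config: SimConfig, annotation: Annotation, rng: np.random.Generator
) -> dict[str, pd.DataFrame]:
    """Choose grid-aligned 200-bp bins for planted DMRs and mCHH regions.

    DMRs prefer Helitron copies and the heterochromatic margin upstream of
    genes, with the remainder scattered over heterochromatin, mirroring
    where endosperm demethylation concentrates.
    """
    dp = config.dmr
    bin_size = 200
    chosen: set[tuple[str, int]] = set()
    hel = annotation.tes[annotation.tes["family"] == "DHH00002"]
    hel = hel[hel["chrom"].isin(dp.chromosomes)].reset_index(drop=True)
    genes = annotation.genes[annotation.genes["chrom"].isin(dp.chromosomes)].reset_index(drop=True)
    euch = annotation.euchromatin(config.methylome.euchromatin_flank)

    n_hel = int(round(dp.n_dmrs * dp.frac_in_helitrons))
    n_gene = int(round(dp.n_dmrs * dp.frac_near_genes))
    # motif-carrying Helitron copies attract demethylation preferentially
    with_motif = hel[hel["has_motif"]].reset_index(drop=True)
    guard = 0
    while len(chosen) < n_hel and guard < 100_000:
        guard += 1
        pool = with_motif if (len(with_motif) and rng.random() < 0.7) else hel
        row = pool.iloc[int(rng.integers(0, len(pool)))]
        lo = (row["start"] // bin_size + 1) * bin_size
        hi = (row["end"] // bin_size - 1) * bin_size
        if hi <= lo:
            continue
        start = int(rng.integers(lo // bin_size, hi // bin_size)) * bin_size
        chosen.add((row["chrom"], start))
    while len(chosen) < n_hel + n_gene and guard < 200_000:
        guard += 1
        g = genes.iloc[int(rng.integers(0, len(genes)))]
        offset = int(rng.integers(1_400, 3_000))
        anchor = g["start"] - offset if g["strand"] == "+" else g["end"] + offset
        start = (int(anchor) // bin_size) * bin_size
        if not 0 <= start <= annotation.chrom_lengths[g["chrom"]] - bin_size:
            continue
        # a bin upstream of one gene can still fall inside a neighbor's
        # euchromatin; demethylation targets stay heterochromatic
        if _in_regions(np.array([start, start + bin_size - 1]), euch, g["chrom"]).any():
            continue
        chosen.add((g["chrom"], start))
    # remainder scattered over heterochromatin (demethylation needs methylation)
    while len(chosen) < dp.n_dmrs:
        c = dp.chromosomes[int(rng.integers(0, len(dp.chromosomes)))]
        start = int(rng.integers(0, annotation.chrom_lengths[c] // bin_size)) * bin_size
        if _in_regions(np.array([start, start + bin_size - 1]), euch, c).any():
            continue
        chosen.add((c, start))
    dmrs = pd.DataFrame(sorted(chosen), columns=["chrom", "start"])
    dmrs["end"] = dmrs["start"] + bin_size

    chh: set[tuple[str, int]] = set()
    while len(chh) < dp.n_chh_regions:
        c = dp.chromosomes[int(rng.integers(0, len(dp.chromosomes)))]
        start = int(rng.integers(0, annotation.chrom_lengths[c] // bin_size)) * bin_size
        if (c, start) not in chosen:
            chh.add((c, start))
    chh_df = pd.DataFrame(sorted(chh), columns=["chrom", "start"])
    chh_df["end"] = chh_df["start"] + bin_size
    return {"dmr": dmrs, "chh": chh_df}


def _in_regions(pos0: np.ndarray, regions: pd.DataFrame, chrom: str) -> np.ndarray:
    """Boolean membership of 0-based positions in a disjoint sorted region set."""
    reg = regions[regions["chrom"] == chrom].sort_values("start")
    if not len(reg):
        return np.zeros(len(pos0), dtype=bool)
    s = reg["start"].to_numpy()
    e = reg["end"].to_numpy()
    idx = np.searchsorted(s, pos0, side="right") - 1
    ok = idx >= 0
    return ok & (pos0 < e[np.maximum(idx, 0)])


def simulate_methylomes(
    config: SimConfig,
    annotation: Annotation,
    planted: dict[str, pd.DataFrame],
    rng: np.random.Generator,
    noise_free: bool = False,
) -> dict[str, list[MethylomeMap]]:
    """Replicate methylomes for wild-type endosperm, mutant endosperm, embryo.

    Per-site truth comes from the compartment baselines; planted DMR bins
    are demethylated (mCG/mCHG -> ``level_low``) in wild-type endosperm only,
    and planted mCHH-region bins are raised in both endosperm genotypes.
    Observed counts are Binomial(coverage, truth folded with the conversion
    error) at Poisson coverage.  ``noise_free`` fixes coverage at a constant
    high value and sets meth = round(truth * coverage) for limit checks.
    """
    mp = config.methylome
    dmrs, chh_regions = planted["dmr"], planted["chh"]
    euch = annotation.euchromatin(mp.euchromatin_flank)
    ctx_index = {"CG": 0, "CHG": 1, "CHH": 2}
    dinuc = {"CG": "CG", "CHG": "CA", "CHH": "CT"}
    samples = ("wt_endosperm", "mut_endosperm", "embryo")

    # site positions and per-sample truth, shared by all replicates
    frames_truth: list[pd.DataFrame] = []
    for chrom, length in annotation.chrom_lengths.items():
        # one draw per bp, partitioned into contexts, keeps sites disjoint
        u = rng.random(length)
        lo = 0.0
        for context, dens in mp.site_density:
            pos0 = np.flatnonzero((u >= lo) & (u < lo + dens))
            lo += dens
            if not len(pos0):
                continue
            k = ctx_index[context]
            base_h = mp.heterochromatin[k]
            base_e = mp.euchromatin[k]
            truth = np.where(_in_regions(pos0, euch, chrom), base_e, base_h)
            truth = np.repeat(truth[None, :], 3, axis=0)  # rows follow `samples`
            if context in ("CG", "CHG"):
                in_dmr = _in_regions(pos0, dmrs, chrom)
                truth[0, in_dmr] = config.dmr.level_low    # wild-type endosperm
                truth[1, in_dmr] = config.dmr.level_high
                truth[2, in_dmr] = config.dmr.level_high
            else:
                in_chh = _in_regions(pos0, chh_regions, chrom)
                truth[0, in_chh] = config.dmr.chh_level
                truth[1, in_chh] = config.dmr.chh_level
            strand = np.where(rng.random(len(pos0)) < 0.5, "+", "-")
            frames_truth.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": pos0 + 1,
                        "strand": strand,
                        "context": context,
                        "dinucleotide": dinuc[context],
                        "t_wt": truth[0],
                        "t_mut": truth[1],
                        "t_emb": truth[2],
                    }
                )
            )
    truth_df = pd.concat(frames_truth, ignore_index=True)
    truth_df = truth_df.sort_values(["chrom", "pos"], kind="stable", ignore_index=True)

    err = 0.0 if noise_free else mp.conversion_error
    out: dict[str, list[MethylomeMap]] = {s: [] for s in samples}
    truth_cols = {"wt_endosperm": "t_wt", "mut_endosperm": "t_mut", "embryo": "t_emb"}
    n_sites = len(truth_df)
    for sample in samples:
        truth = truth_df[truth_cols[sample]].to_numpy()
        p_obs = truth * (1 - err) + (1 - truth) * err
        for rep in range(mp.n_replicates):
            if noise_free:
                cov = np.full(n_sites, max(int(mp.coverage_per_replicate), 1) * 100)
                meth = np.rint(p_obs * cov).astype(np.int64)
            else:
                cov = rng.poisson(mp.coverage_per_replicate, size=n_sites)
                meth = rng.binomial(cov, p_obs)
            keep = cov > 0
            sites = pd.DataFrame(
                {
                    "chrom": truth_df["chrom"].to_numpy()[keep],
                    "pos": truth_df["pos"].to_numpy()[keep],
                    "strand": truth_df["strand"].to_numpy()[keep],
                    "context": truth_df["context"].to_numpy()[keep],
                    "dinucleotide": truth_df["dinucleotide"].to_numpy()[keep],
                    "meth": meth[keep],
                    "total": cov[keep],
                }
            )
            out[sample].append(MethylomeMap(f"{sample}_rep{rep + 1}", sites))
    return out


# ---------------------------------------------------------------------------
# small RNA libraries


def simulate_sirna_libraries(
    config: SimConfig,
    annotation: Annotation,
    dmrs: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Aligned small-RNA read tables for wild-type and mutant endosperm.

    Reads are emitted per locus with Poisson counts: housekeeping loci
    (tRNA/5S/NOR/miRNA) emit abundantly (these must be removed by the
    classifier), background heterochromatic loci emit at a low rate, and
    DMR loci emit at ``dmr_rate_wt`` in the wild type times
    ``mutant_multiplier`` in the mutant.  Lengths follow a 24-nt-dominated
    mix; a configured fraction of reads is tagged with low MAPQ to emulate
    multi-mappers.
    """
    sp = config.sirna
    lengths_mix = np.array([l for l, _ in sp.length_probs])
    probs = np.array([p for _, p in sp.length_probs])
    probs = probs / probs.sum()

    bg = _Occupancy(annotation.chrom_lengths)
    chroms = [c for c in annotation.chrom_lengths if not c.startswith("scaffold")]
    background = bg.place(rng, sp.background_loci, 200, chroms)

    loci = []
    for df, rate_wt, rate_mut in (
        (annotation.exclusion, sp.exclusion_rate, sp.exclusion_rate),
        (background, sp.background_rate, sp.background_rate),
        (dmrs, sp.dmr_rate_wt, sp.dmr_rate_wt * sp.mutant_multiplier),
    ):
        d = df[["chrom", "start", "end"]].copy()
        d["rate_wt"] = rate_wt
        d["rate_mut"] = rate_mut
        loci.append(d)
    loci_df = pd.concat(loci, ignore_index=True)

    tables = []
    for genotype in ("wt", "mut"):
        rates = loci_df[f"rate_{genotype}"].to_numpy()
        for rep in range(1, sp.n_replicates + 1):
            counts = rng.poisson(rates)
            total = int(counts.sum())
            li = np.repeat(np.arange(len(loci_df)), counts)
            lens = rng.choice(lengths_mix, size=total, p=probs)
            lstart = loci_df["start"].to_numpy()[li]
            lend = loci_df["end"].to_numpy()[li]
            span = np.maximum(lend - lstart - lens, 1)
            starts = lstart + (rng.random(total) * span).astype(np.int64)
            mapq = np.where(rng.random(total) < sp.low_mapq_fraction, 3, 42)
            tables.append(
                pd.DataFrame(
                    {
                        "chrom": loci_df["chrom"].to_numpy()[li],
                        "start": starts,
                        "end": starts + lens,
                        "length": lens,
                        "mapq": mapq,
                        "library_id": f"{genotype}_endosperm",
                        "replicate_id": f"{genotype}_rep{rep}",
                    }
                )
            )
    return pd.concat(tables, ignore_index=True)


# ---------------------------------------------------------------------------
# imprinting


def simulate_allele_counts(
    config: SimConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reciprocal-cross allele counts with planted MEGs and PEGs.

    Biallelic genes draw maternal reads at probability 2/3 (triploid 2:1
    dosage); MEGs at ``p_meg`` and PEGs at ``p_peg``.  Returns the counts
    table (one row per gene and cross direction) and the truth table.
    """
    ip = config.imprinting
    n = ip.n_genes
    n_meg = int(round(n * ip.meg_fraction))
    n_peg = int(round(n * ip.peg_fraction))
    categories = np.array(
        ["MEG"] * n_meg + ["PEG"] * n_peg + ["biallelic"] * (n - n_meg - n_peg)
    )
    rng.shuffle(categories)
    p = np.select(
        [categories == "MEG", categories == "PEG"],
        [ip.p_meg, ip.p_peg],
        default=ip.p_biallelic,
    )
    ids = np.array([f"gene{i:05d}" for i in range(n)])
    rows = []
    for direction in ("AxB", "BxA"):
        depth = rng.poisson(ip.mean_depth / 2, size=n)
        maternal = rng.binomial(depth, p)
        rows.append(
            pd.DataFrame(
                {
                    "feature_id": ids,
                    "maternal_reads": maternal,
                    "paternal_reads": depth - maternal,
                    "direction": direction,
                }
            )
        )
    counts = pd.concat(rows, ignore_index=True)
    truth = pd.DataFrame({"feature_id": ids, "true_category": categories})
    return counts, truth


# ---------------------------------------------------------------------------
# bulked-segregant cross


def simulate_bsa(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Two-bulk variant table from a selected bulked-segregant cross.

    Mother heterozygous (mutant-stock haplotype / reference haplotype)
    genome-wide, father homozygous mutant stock; progeny are selected for
    homozygosity of the mutant allele at the causal locus.  Marker alleles
    recombine along a Haldane map of ``genetic_length`` Morgans per
    chromosome.  The pooled mutant-bulk alternative allele frequency is
    therefore (1 + P(maternal allele is stock)) / 2: 0.75 genome-wide and
    1 - r/2 at recombination fraction r from the causal locus.  Read counts
    are Binomial at Poisson depth; GQ and PL fields come from a diploid
    binomial genotype-likelihood model of the counts.
    """
    bp = config.bsa
    markers = []
    for i in range(1, bp.n_chromosomes + 1):
        pos = np.arange(bp.marker_spacing // 2, bp.chrom_length, bp.marker_spacing)
        markers.append(pd.DataFrame({"CHROM": f"chr{i}", "POS": pos + 1}))
    mk = pd.concat(markers, ignore_index=True)

    # maternal gametes: Markov chain of haplotype origin along each chromosome
    maternal_alt = {}
    n_batch = int(bp.n_selected * 2.5)
    causal_alt = None
    for chrom, g in mk.groupby("CHROM", sort=False):
        pos0 = g["POS"].to_numpy() - 1
        gpos = pos0 / bp.chrom_length * bp.genetic_length
        r_adj = 0.5 * (1 - np.exp(-2 * np.diff(gpos)))
        state = rng.random(n_batch) < 0.5  # True = stock (alt) haplotype
        states = [state]
        for r in r_adj:
            flip = rng.random(n_batch) < r
            state = state ^ flip
            states.append(state)
        hap = np.column_stack(states)  # progeny x markers
        maternal_alt[chrom] = hap
        if chrom == bp.causal_chrom:
            # genotype at the causal position: nearest marker-linked simulation
            cg = bp.causal_pos / bp.chrom_length * bp.genetic_length
            k = int(np.argmin(np.abs(gpos - cg)))
            d = abs(gpos[k] - cg)
            r = 0.5 * (1 - np.exp(-2 * d))
            flip = rng.random(n_batch) < r
            causal_alt = hap[:, k] ^ flip

    selected = np.flatnonzero(causal_alt)
    if len(selected) < bp.n_selected:
        raise RuntimeError("selection batch too small; increase the batch factor")
    selected = selected[: bp.n_selected]

    rows = []
    for chrom, g in mk.groupby("CHROM", sort=False):
        hap = maternal_alt[chrom][selected]
        # pooled truth: father contributes an alt allele at every marker
        f_pool = (bp.n_selected + hap.sum(axis=0)) / (2 * bp.n_selected)
        p_read = f_pool * (1 - bp.error_rate) + (1 - f_pool) * bp.error_rate
        depth_mut = rng.poisson(bp.depth_mut, size=len(g))
        alt_mut = rng.binomial(depth_mut, p_read)
        depth_wt = rng.poisson(bp.depth_wt, size=len(g))
        alt_wt = rng.binomial(depth_wt, bp.error_rate)
        gq_mut, pls_mut = _genotype_quality(alt_mut, depth_mut, bp.error_rate)
        gq_wt, _ = _genotype_quality(alt_wt, depth_wt, bp.error_rate)
        with np.errstate(invalid="ignore", divide="ignore"):
            af_mut = np.where(depth_mut > 0, alt_mut / np.maximum(depth_mut, 1), np.nan)
            af_wt = np.where(depth_wt > 0, alt_wt / np.maximum(depth_wt, 1), np.nan)
        rows.append(
            pd.DataFrame(
                {
                    "CHROM": chrom,
                    "POS": g["POS"].to_numpy(),
                    "REF": "A",
                    "ALT": "G",
                    "DP_wt": depth_wt,
                    "AF_wt": af_wt,
                    "GQ_wt": gq_wt,
                    "DP_mut": depth_mut,
                    "AF_mut": af_mut,
                    "GQ_mut": gq_mut,
                    "PL_homref_mut": pls_mut[:, 0],
                    "PL_het_mut": pls_mut[:, 1],
                    "PL_homalt_mut": pls_mut[:, 2],
                    "true_freq": f_pool,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def _genotype_quality(
    alt: np.ndarray, depth: np.ndarray, error: float
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized Phred-scaled genotype likelihoods from allele counts.

    Diploid binomial model with allele probabilities (error, 1/2,
    1 - error) for hom-ref, het and hom-alt.  PLs are normalized so the
    best genotype has PL 0; GQ is the second-best PL, capped at 99.
    """
    ref = depth - alt
    p = np.array([error, 0.5, 1 - error])
    with np.errstate(divide="ignore"):
        ll = alt[:, None] * np.log10(p)[None, :] + ref[:, None] * np.log10(1 - p)[None, :]
    pl = -10 * (ll - ll.max(axis=1, keepdims=True))
    pl = np.rint(pl)
    pl = np.where(np.isfinite(pl), pl, 9999)
    gq = np.minimum(np.sort(pl, axis=1)[:, 1], 99).astype(np.int64)
    return gq, pl.astype(np.int64)


# ---------------------------------------------------------------------------
# expression matrix


def simulate_expression_matrix(
    config: SimConfig,
    rng: np.random.Generator,
    n_genes: int = 1_000,
    n_libraries: int = 225,
    n_endosperm: int = 21,
) -> tuple[pd.DataFrame, list[str], pd.Series]:
    """Gene x library RPM matrix with planted expression categories.

    A quarter of genes in each of: constitutive off (RPM ~ 0 everywhere),
    endosperm on (expressed everywhere incl. endosperm), endosperm off
    (expressed outside endosperm only), and mixed/unclassifiable noise.
    """
    libs = [f"endo{i:02d}" for i in range(n_endosperm)] + [
        f"lib{i:03d}" for i in range(n_libraries - n_endosperm)
    ]
    endo = libs[:n_endosperm]
    cats = rng.choice(
        ["constitutive_off", "endosperm_on", "endosperm_off", "unclassified"],
        size=n_genes,
    )
    rpm = np.zeros((n_genes, n_libraries))
    base = rng.gamma(2.0, 5.0, size=(n_genes, n_libraries))
    off = rng.uniform(0, 0.3, size=(n_genes, n_libraries))
    for i, cat in enumerate(cats):
        if cat == "constitutive_off":
            rpm[i] = off[i]
        elif cat == "endosperm_on":
            rpm[i] = base[i]
        elif cat == "endosperm_off":
            rpm[i] = base[i]
            rpm[i, :n_endosperm] = off[i, :n_endosperm]
        else:
            # bounce between thresholds so no rule fires cleanly
            rpm[i] = rng.uniform(0.4, 1.5, size=n_libraries)
    mat = pd.DataFrame(rpm, index=[f"gene{i:05d}" for i in range(n_genes)], columns=libs)
    truth = pd.Series(cats, index=mat.index, name="true_category")
    return mat, endo, truth


# ---------------------------------------------------------------------------
# file emission


def write_fasta(annotation: Annotation, path: str | Path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(seq), id=chrom, description="")
        for chrom, seq in annotation.sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def write_gff3(annotation: Annotation, path: str | Path) -> None:
    """Genes and TEs as GFF3 (gene / transposable_element features)."""
    rows = []
    for _, g in annotation.genes.iterrows():
        rows.append(
            (g["chrom"], "sim", "gene", g["start"] + 1, g["end"], ".", g["strand"], ".",
             f"ID={g['feature_id']}")
        )
    for _, t in annotation.tes.iterrows():
        name = t["feature_id"] + ("S" if t["solo_ltr"] else "")
        rows.append(
            (t["chrom"], "sim", "transposable_element", t["start"] + 1, t["end"], ".",
             t["strand"], ".",
             f"ID={name};class={t['element_class']};family={t['family']}")
        )
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")
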