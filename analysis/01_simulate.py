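"""Generate the synthetic dataset and write it in its exchange formats.

Builds the default desk-scale world (two 5-Mb chromosomes plus an unplaced
scaffold; 200 genes; Helitron and gypsy families; 300 planted demethylated
regions) and writes FASTA, GFF3, per-replicate CGmaps, the small-RNA read
table, the allele-count table and the two-bulk variant table under
scratch/sim/.  Large raw files live in scratch/ on purpose; downstream
analysis scripts regenerate the same world deterministically from the seed
instead of re-reading them, and results/ holds only summary tables.
"""

from pathlib import Path

import numpy as np

from demether import methylome, simulate

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "scratch" / "sim"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = simulate.SimConfig(seed=SEED)
    rng = cfg.rng()

    ann = simulate.make_genome_annotation(cfg, rng)
    simulate.write_fasta(ann, OUT / "genome.fa")
    simulate.write_gff3(ann, OUT / "annotation.gff3")
    ann.exclusion.to_csv(OUT / "exclusion_loci.bed", sep="\t", header=False, index=False)
    print(f"genome: {sum(ann.chrom_lengths.values()):,} bp across {len(ann.chrom_lengths)} sequences")
    print(f"annotated: {len(ann.genes)} genes, {len(ann.tes)} TEs, "
          f"{len(ann.tandem)} tandem arrays, {len(ann.exclusion)} housekeeping sRNA loci")

    planted = simulate.plant_regions(cfg, ann, rng)
    planted["dmr"].to_csv(OUT / "planted_dmrs.bed", sep="\t", header=False, index=False)
    planted["chh"].to_csv(OUT / "planted_chh_regions.bed", sep="\t", header=False, index=False)
    print(f"planted: {len(planted['dmr'])} demethylated bins, "
          f"{len(planted['chh'])} mCHH bins")

    maps = simulate.simulate_methylomes(cfg, ann, planted, rng)
    for sample, reps in maps.items():
        for m in reps:
            methylome.write_cgmap(m, OUT / f"{m.sample_id}.CGmap")
        print(f"{sample}: {len(reps)} replicates, ~{len(reps[0]):,} covered sites each")

    reads = simulate.simulate_sirna_libraries(cfg, ann, planted["dmr"], np.random.default_rng(SEED + 1))
    reads.to_csv(OUT / "sirna_reads.tsv", sep="\t", index=False)
    print(f"small RNA: {len(reads):,} aligned reads across {reads['replicate_id'].nunique()} libraries")

    counts, truth = simulate.simulate_allele_counts(cfg, np.random.default_rng(SEED + 3))
    counts.to_csv(OUT / "allele_counts.tsv", sep="\t", index=False)
    truth.to_csv(OUT / "allele_truth.tsv", sep="\t", index=False)

    var = simulate.simulate_bsa(cfg, np.random.default_rng(SEED + 4))
    var.to_csv(OUT / "bsa_variants.tsv", sep="\t", index=False)
    print(f"BSA: {len(var):,} markers over {var['CHROM'].nunique()} chromosomes")
    print(f"all files under {OUT}")


if __name__ == "__main__":
    main()
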