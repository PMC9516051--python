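"""Characterize DMRs against annotations and the methylome.

Computes, on the default synthetic world: element-overlap enrichment of
DMRs relative to methylated control regions (Helitrons should be enriched
because 40% of demethylated bins were planted inside them), end-anchored
profiles around gene TSS/polyA and gypsy ends (solo LTRs excluded),
distance from DMRs to the nearest euchromatin UMR, mCG flanking profiles
around DMRs vs controls (the planted V-shape), GC content of DMR vs
control sequence, and PHE1-motif enrichment among Helitron copies.
"""

from pathlib import Path

import pandas as pd

from demether import annostats, intervals, methylome, regions, simulate

SEED = 1
RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    cfg = simulate.SimConfig(seed=SEED)
    rng = cfg.rng()
    ann = simulate.make_genome_annotation(cfg, rng)
    planted = simulate.plant_regions(cfg, ann, rng)
    maps = simulate.simulate_methylomes(cfg, ann, planted, rng)
    mut = methylome.merge_replicates(maps["mut_endosperm"], "mut")
    wt = methylome.merge_replicates(maps["wt_endosperm"], "wt")
    res = regions.call_dmrs(
        methylome.intersect_samples(mut, wt, "CG"),
        methylome.intersect_samples(mut, wt, "CHG"),
    )
    dmrs = res["hypo"]
    controls = regions.methylated_control_filter(res["eligible"])
    print(f"{len(dmrs)} DMRs vs {len(controls)} methylated control regions")

    # 1. overlap enrichment per element class
    rows = []
    elements = {
        "gene": ann.genes,
        "helitron_DHH00002": ann.tes[ann.tes["family"] == "DHH00002"],
        "gypsy_RLG": ann.tes[ann.tes["element_class"] == "RLG"],
        "tandem_repeat": ann.tandem,
    }
    for name, el in elements.items():
        enr = annostats.element_enrichment(dmrs, controls, el)
        rows.append((name, "undefined" if enr is None else round(enr, 3)))
    enr_tab = pd.DataFrame(rows, columns=["element", "enrichment"])
    enr_tab.to_csv(RESULTS / "element_enrichment.tsv", sep="\t", index=False)
    print(enr_tab.to_string(index=False))

    # 2. end-anchored profiles (transcript orientation; solo LTRs excluded)
    tss = annostats.gene_anchors(ann.genes, "tss")
    gyp = ann.tes[(ann.tes["element_class"] == "RLG") & (~ann.tes["solo_ltr"])]
    for label, anchors in (
        ("tss", tss),
        ("polya", annostats.gene_anchors(ann.genes, "polya")),
        ("gypsy_ends", annostats.element_end_anchors(gyp)),
    ):
        prof = annostats.end_anchored_enrichment(dmrs, controls, anchors)
        prof.to_csv(RESULTS / f"end_profile_{label}.tsv", sep="\t", index=False)

    # 3. distance to nearest euchromatin
    umrs = regions.find_unmethylated_regions(
        regions.bin_sites_single(methylome.merge_replicates(maps["embryo"]), "CHG")
    )
    dist = intervals.distance_to_nearest(dmrs, umrs)
    frac_far = annostats.fraction_beyond(dist, 2_000)
    print(f"DMRs >2 kb from nearest euchromatin: {frac_far:.1%}")

    # 4. mCG flank profiles
    for name, regset in (("dmrs", dmrs), ("controls", controls)):
        prof = annostats.flank_profile(regset, wt, "CG")
        prof.to_csv(RESULTS / f"flank_mcg_wt_{name}.tsv", sep="\t", index=False)

    # 5. GC content
    seq = lambda df: [ann.sequences[r.chrom][r.start:r.end] for r in df.itertuples()]
    gc_dmr = annostats.gc_content(seq(dmrs))
    gc_ctrl = annostats.gc_content(seq(controls))
    print(f"GC content: {gc_dmr:.1%} in DMRs vs {gc_ctrl:.1%} in controls")

    # 6. PHE1 motifs in Helitron copies with vs without DMR overlap
    hel = elements["helitron_DHH00002"].reset_index(drop=True)
    with_dmr = intervals.overlap_bp(hel, dmrs) >= 100
    present = annostats.motif_presence(seq(hel), simulate.PHE1_MOTIFS)
    motif_tab = pd.DataFrame(
        {
            "group": ["with_dmr", "without_dmr"],
            "n": [int(with_dmr.sum()), int((~with_dmr).sum())],
            "motif_fraction": [present[with_dmr].mean(), present[~with_dmr].mean()],
        }
    )
    motif_tab.to_csv(RESULTS / "helitron_motifs.tsv", sep="\t", index=False)
    print(motif_tab.to_string(index=False))

    pd.DataFrame(
        [("frac_dmrs_beyond_2kb_euchromatin", round(frac_far, 4)),
         ("gc_dmrs", round(gc_dmr, 4)), ("gc_controls", round(gc_ctrl, 4))],
        columns=["quantity", "value"],
    ).to_csv(RESULTS / "dmr_characterization.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
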