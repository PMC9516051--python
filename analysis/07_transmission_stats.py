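"""Transmission genetics: the printed count tables re-tested.

Applies the package's exact tests to the published kernel counts: the
EMS-allele genotyping table (mottled vs solid kernels), the Ds-GFP
double-mutant transmission screens, the control segregation of two
unlinked Ds-GFP insertions against its 1/4 expectation, and the
1-defective:3-normal megagametophyte expectation from the cross model.
"""

from pathlib import Path

import pandas as pd

from demether import stats

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rows = []

    # genotyping of the EMS allele: 20/20 mottled vs 9/28 solid kernels
    p = stats.fisher_exact_2x2(20, 0, 9, 19)
    rows.append(("fisher_mottled_vs_solid", "p", p))
    print(f"EMS genotyping (20/20 vs 9/28): Fisher two-tailed p = {p:.3g}")

    # Ds-GFP screens: 6 of 5221 non-fluorescent (paternal double-mutant
    # transmission) vs the 81 of 355 control; expectation 1/4 without
    # gametophyte selection
    p_ctrl = stats.binomial_two_sided(81, 355, 0.25)
    p_screen = stats.binomial_two_sided(6, 5_221, 0.25)
    rows.append(("binomial_dsgfp_control_81_355_vs_quarter", "p", p_ctrl))
    rows.append(("binomial_dsgfp_screen_6_5221_vs_quarter", "p", p_screen))
    print(f"Ds-GFP control 81/355 vs 1/4 expectation: p = {p_ctrl:.3g} (consistent)")
    print(f"Ds-GFP screen 6/5221 vs 1/4 expectation: p = {p_screen:.3g} (selection!)")

    # cross-model expectations
    model = stats.CrossModel(
        loci=("mdr1", "dng102"),
        mother=stats.Parent((1, 1), (0, 0)),
        father=stats.Parent((0, 0), (0, 0)),
        map_distances=(None,),
    )
    probs = stats.phenotype_probabilities(
        model, lambda g: "defective" if g[0][0] == 1 and g[1][0] == 1 else "normal"
    )
    rows.append(("expected_defective_fraction", "probability", probs["defective"]))
    print(f"expected defective:normal kernels = "
          f"{probs['defective']:.2f}:{probs['normal']:.2f} (1:3)")

    gfp = stats.CrossModel(
        loci=("gfpA", "gfpB"),
        mother=stats.Parent((0, 0), (0, 0)),
        father=stats.Parent((1, 1), (0, 0)),
        map_distances=(None,),
    )
    dark = stats.phenotype_probabilities(
        gfp, lambda g: "dark" if g[0][1] == 0 and g[1][1] == 0 else "bright"
    )["dark"]
    rows.append(("expected_nonfluorescent_fraction", "probability", dark))
    print(f"expected non-fluorescent control kernels: {dark:.2f} (observed 81/355 = {81/355:.2f})")

    pd.DataFrame(rows, columns=["test", "kind", "value"]).to_csv(
        RESULTS / "transmission_stats.tsv", sep="\t", index=False
    )


if __name__ == "__main__":
    main()
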