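"""200-bp bin eligibility, DMR, mCHH-region, UMR and control callers."""

import numpy as np
import pandas as pd
import pytest

from demether import methylome, regions, simulate


def paired(rows, context="CG") -> methylome.PairedSiteTable:
    """rows: (chrom, pos, meth_a, total_a, meth_b, total_b)."""
    df = pd.DataFrame(rows, columns=["chrom", "pos", "meth_a", "total_a", "meth_b", "total_b"])
    return methylome.PairedSiteTable(context, df)


def single_bins(rows) -> pd.DataFrame:
    """rows: (chrom, start, n_sites, meth, total)."""
    df = pd.DataFrame(rows, columns=["chrom", "start", "n_sites", "meth", "total"])
    df["end"] = df["start"] + 200
    return df


class TestBinSites:
    def test_boundary_convention(self):
        t = paired([("chr1", 200, 1, 2, 1, 2), ("chr1", 201, 1, 2, 1, 2)])
        bins = regions.bin_sites(t, 200)
        assert list(bins["start"]) == [0, 200]
        assert (bins["n_sites"] == 1).all()

    def test_empty_table(self):
        t = paired([])
        assert len(regions.bin_sites(t)) == 0

    def test_hand_aggregation(self):
        rows = [("chr1", p, 1, 3, 2, 4) for p in (5, 50, 150, 199)]       # bin 0: 4 sites
        rows += [("chr1", p, 0, 2, 1, 1) for p in (201, 250, 399)]        # bin 200: 3 sites
        rows += [("chr2", p, 2, 2, 0, 5) for p in (1001, 1010, 1100, 1150, 1200)]  # bin 1000
        bins = regions.bin_sites(paired(rows), 200)
        assert len(bins) == 3
        b0 = bins[(bins.chrom == "chr1") & (bins.start == 0)].iloc[0]
        assert (b0.n_sites, b0.meth_a, b0.total_a, b0.meth_b, b0.total_b) == (4, 4, 12, 8, 16)
        b2 = bins[bins.chrom == "chr2"].iloc[0]
        assert (b2.start, b2.n_sites, b2.meth_a, b2.total_a) == (1000, 5, 10, 10)


class TestEligibility:
    def _bins(self, n_cg, cov_cg, n_chg=5, cov_chg=3):
        cg = [("chr1", p, 1, cov_cg, 1, cov_cg) for p in range(1, 1 + n_cg)]
        chg = [("chr1", p, 1, cov_chg, 1, cov_chg) for p in range(50, 50 + n_chg)]
        return (
            regions.bin_sites(paired(cg), 200),
            regions.bin_sites(paired(chg, "CHG"), 200),
        )

    def test_exactly_at_threshold_is_eligible(self):
        cg_bins, chg_bins = self._bins(n_cg=5, cov_cg=3)
        out = regions.eligible_bins(cg_bins, chg_bins)
        assert len(out) == 1

    def test_too_few_sites_fails_despite_depth(self):
        cg_bins, chg_bins = self._bins(n_cg=4, cov_cg=100)
        assert len(regions.eligible_bins(cg_bins, chg_bins)) == 0

    def test_low_mean_coverage_fails(self):
        cg_bins, chg_bins = self._bins(n_cg=5, cov_cg=2)
        assert len(regions.eligible_bins(cg_bins, chg_bins)) == 0

    def test_matches_brute_force_on_simulated_world(self, merged_pair):
        params = regions.DmrParams()
        cg_bins = regions.bin_sites(merged_pair["cg"])
        chg_bins = regions.bin_sites(merged_pair["chg"])
        got = regions.eligible_bins(cg_bins, chg_bins, params)
        expected = set()
        per_bin: dict[tuple, dict] = {}
        for ctx, tab in (("cg", merged_pair["cg"].table), ("chg", merged_pair["chg"].table)):
            for row in tab.itertuples():
                key = (row.chrom, (row.pos - 1) // 200 * 200)
                d = per_bin.setdefault(key, {"cg": [], "chg": []})
                d[ctx].append((row.meth_a, row.total_a, row.meth_b, row.total_b))
        for key, d in per_bin.items():
            ok = True
            for ctx in ("cg", "chg"):
                sites = d[ctx]
                n = len(sites)
                if n < params.min_count_c:
                    ok = False
                    break
                ta = sum(s[1] for s in sites)
                tb = sum(s[3] for s in sites)
                if ta / n < params.min_cov or tb / n < params.min_cov:
                    ok = False
                    break
            if ok:
                expected.add(key)
        assert set(zip(got["chrom"], got["start"])) == expected


class TestContextDmrs:
    def _eligible_frame(self, v1, v2):
        return pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [200],
             "v1_cg": [v1], "v2_cg": [v2], "v1_chg": [v1], "v2_chg": [v2]}
        )

    @pytest.mark.parametrize(
        "v1,v2,expect",
        [
            (0.10, 0.35, "hyper"),   # 3.5-fold, +0.25
            (0.40, 0.25, None),      # fold 1.6 < 2
            (0.0, 0.25, "hyper"),    # zero-denominator limit of the fold rule
            (0.35, 0.10, "hypo"),
            (0.25, 0.0, "hypo"),
            (0.10, 0.30, None),      # exactly +0.20 is not "greater than 20%"
            (0.5, 0.5, None),
        ],
    )
    def test_threshold_cases(self, v1, v2, expect):
        hypo, hyper = regions.call_context_dmrs(self._eligible_frame(v1, v2), "CG")
        got = "hypo" if len(hypo) else ("hyper" if len(hyper) else None)
        assert got == expect


class TestCombineContexts:
    def _f(self, pairs):
        df = pd.DataFrame(pairs, columns=["chrom", "start"])
        df["end"] = df["start"] + 200
        return df

    def test_set_intersection(self):
        cg = self._f([("chr1", 0), ("chr1", 400)])
        chg = self._f([("chr1", 400)])
        out = regions.combine_contexts(cg, chg)
        assert list(zip(out.chrom, out.start)) == [("chr1", 400)]

    def test_scaffold_bins_removed(self):
        cg = self._f([("scaffold_282", 0), ("chr2", 200)])
        out = regions.combine_contexts(cg, cg)
        assert list(out.chrom) == ["chr2"]

    def test_random_sets_match_brute_force(self):
        rng = np.random.default_rng(5)
        mk = lambda: self._f(
            {(f"chr{rng.integers(1, 4)}", int(rng.integers(0, 50)) * 200) for _ in range(40)}
        )
        cg, chg = mk(), mk()
        out = regions.combine_contexts(cg, chg, chromosomes=[f"chr{i}" for i in range(1, 4)])
        expected = set(zip(cg.chrom, cg.start)) & set(zip(chg.chrom, chg.start))
        assert set(zip(out.chrom, out.start)) == expected


class TestMrUmr:
    def test_mr_at_threshold(self):
        bins = single_bins([("chr1", 0, 5, 2, 10)])  # level exactly 0.2
        assert len(regions.find_methylated_regions(bins)) == 1

    def test_mr_below_threshold(self):
        bins = single_bins([("chr1", 0, 5, 19, 100)])
        assert len(regions.find_methylated_regions(bins)) == 0

    def test_umr_level_zero_reported(self):
        bins = single_bins([("chr1", 0, 6, 0, 18)])
        assert len(regions.find_unmethylated_regions(bins)) == 1

    def test_umr_too_few_sites(self):
        bins = single_bins([("chr1", 0, 4, 0, 18)])
        assert len(regions.find_unmethylated_regions(bins)) == 0

    def test_simulated_track_matches_brute_force(self, merged_pair):
        chh = regions.bin_sites_single(merged_pair["wt"], "CHH")
        got = regions.find_methylated_regions(chh)
        expect = chh[
            (chh.n_sites >= 5)
            & (chh.total / chh.n_sites >= 2)
            & (chh.meth / chh.total >= 0.2)
        ]
        assert set(zip(got.chrom, got.start)) == set(zip(expect.chrom, expect.start))


class TestMethylatedControls:
    def test_kept_when_one_sample_methylated(self):
        df = pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [200],
             "v1_cg": [0.9], "v1_chg": [0.8], "v2_cg": [0.0], "v2_chg": [0.0]}
        )
        assert len(regions.methylated_control_filter(df)) == 1

    def test_dropped_when_chg_fails_in_both(self):
        df = pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [200],
             "v1_cg": [0.9], "v1_chg": [0.1], "v2_cg": [0.9], "v2_chg": [0.1]}
        )
        assert len(regions.methylated_control_filter(df)) == 0

    def test_random_levels_match_predicate(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame(
            {"chrom": "chr1", "start": np.arange(100) * 200, "end": np.arange(100) * 200 + 200,
             "v1_cg": rng.random(100), "v1_chg": rng.random(100),
             "v2_cg": rng.random(100), "v2_chg": rng.random(100)}
        )
        got = regions.methylated_control_filter(df)
        exp = [
            i for i, r in df.iterrows()
            if (r.v1_cg >= 0.2 and r.v1_chg >= 0.2) or (r.v2_cg >= 0.2 and r.v2_chg >= 0.2)
        ]
        assert list(got["start"]) == list(df.loc[exp, "start"])


class TestPipelineProperties:
    def test_sample_swap_maps_hypo_onto_hyper(self, merged_pair):
        res = regions.call_dmrs(merged_pair["cg"], merged_pair["chg"])
        cg_sw = methylome.PairedSiteTable(
            "CG",
            merged_pair["cg"].table.rename(
                columns={"meth_a": "meth_b", "meth_b": "meth_a", "total_a": "total_b", "total_b": "total_a"}
            ),
        )
        chg_sw = methylome.PairedSiteTable(
            "CHG",
            merged_pair["chg"].table.rename(
                columns={"meth_a": "meth_b", "meth_b": "meth_a", "total_a": "total_b", "total_b": "total_a"}
            ),
        )
        swapped = regions.call_dmrs(cg_sw, chg_sw)
        assert set(zip(res["hypo"].chrom, res["hypo"].start)) == set(
            zip(swapped["hyper"].chrom, swapped["hyper"].start)
        )
        assert set(zip(res["hyper"].chrom, res["hyper"].start)) == set(
            zip(swapped["hypo"].chrom, swapped["hypo"].start)
        )

    def test_every_dmr_is_eligible(self, merged_pair):
        res = regions.call_dmrs(merged_pair["cg"], merged_pair["chg"])
        eligible = set(zip(res["eligible"].chrom, res["eligible"].start))
        for key in ("hypo", "hyper"):
            assert set(zip(res[key].chrom, res[key].start)) <= eligible

    def test_noise_free_identical_samples_give_zero_dmrs(self, small_cfg):
        rng = small_cfg.rng()
        ann = simulate.make_genome_annotation(small_cfg, rng)
        planted = simulate.plant_regions(small_cfg, ann, rng)
        maps = simulate.simulate_methylomes(small_cfg, ann, planted, rng, noise_free=True)
        mut = methylome.merge_replicates(maps["mut_endosperm"])
        res = regions.call_dmrs(
            methylome.intersect_samples(mut, mut, "CG"),
            methylome.intersect_samples(mut, mut, "CHG"),
        )
        assert len(res["hypo"]) == 0 and len(res["hyper"]) == 0
        assert len(res["eligible"]) > 0

    def test_raising_min_abs_dif_shrinks_dmr_set(self, merged_pair):
        loose = regions.call_dmrs(merged_pair["cg"], merged_pair["chg"], regions.DmrParams())
        tight = regions.call_dmrs(
            merged_pair["cg"], merged_pair["chg"], regions.DmrParams(min_abs_dif=0.5)
        )
        assert set(zip(tight["hypo"].chrom, tight["hypo"].start)) <= set(
            zip(loose["hypo"].chrom, loose["hypo"].start)
        )
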