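"""Bulked-segregant variant filters, window scans and candidate regions."""

import numpy as np
import pandas as pd
import pytest

from demether import bsa, simulate


def record(**kw) -> dict:
    base = dict(
        CHROM="chr1", POS=100, REF="A", ALT="G",
        DP_wt=10, AF_wt=0.0, GQ_wt=30,
        DP_mut=30, AF_mut=0.9, GQ_mut=30,
        PL_homref_mut=500, PL_het_mut=60, PL_homalt_mut=0,
    )
    base.update(kw)
    return base


def table(*rows) -> pd.DataFrame:
    return pd.DataFrame([record(**r) for r in rows])


def random_table(rng, n=400) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "CHROM": rng.choice(["chr1", "chr2"], n),
            "POS": rng.integers(1, 10_000_000, n),
            "REF": "A",
            "ALT": "G",
            "DP_wt": rng.integers(0, 25, n),
            "AF_wt": rng.choice([0.0, 0.0, 0.1, 0.5], n),
            "GQ_wt": rng.integers(0, 99, n),
            "DP_mut": rng.integers(0, 60, n),
            "AF_mut": rng.random(n),
            "GQ_mut": rng.integers(0, 99, n),
            "PL_homref_mut": rng.integers(0, 900, n),
            "PL_het_mut": rng.integers(0, 200, n),
            "PL_homalt_mut": rng.choice([0, 0, 40, 135], n),
        }
    )


class TestMethod1:
    def test_all_criteria_met(self):
        t = table(dict(AF_wt=0.0, DP_wt=10, DP_mut=30, PL_homref_mut=500, PL_homalt_mut=0))
        assert len(bsa.filter_variants_method1(t)) == 1

    def test_wt_depth_bound_is_inclusive(self):
        assert len(bsa.filter_variants_method1(table(dict(DP_wt=15)))) == 1
        assert len(bsa.filter_variants_method1(table(dict(DP_wt=16)))) == 0
        assert len(bsa.filter_variants_method1(table(dict(DP_wt=2)))) == 1
        assert len(bsa.filter_variants_method1(table(dict(DP_wt=1)))) == 0

    def test_missing_field_skipped_and_counted(self):
        t = table(dict(), dict(AF_wt=np.nan))
        out = bsa.filter_variants_method1(t)
        assert len(out) == 1
        assert out.attrs["n_skipped"] == 1

    def test_matches_brute_force(self):
        t = random_table(np.random.default_rng(0))
        got = bsa.filter_variants_method1(t)
        exp = [
            i for i, r in t.iterrows()
            if r.AF_wt == 0 and 2 <= r.DP_wt <= 15 and 5 <= r.DP_mut <= 50
            and r.PL_homref_mut >= 400 and r.PL_homalt_mut == 0
        ]
        assert got["POS"].tolist() == t.loc[exp, "POS"].tolist()


class TestMethod2:
    def test_all_criteria_met(self):
        t = table(dict(GQ_wt=30, GQ_mut=30, DP_wt=10, DP_mut=20, AF_mut=0.9))
        assert len(bsa.filter_variants_method2(t)) == 1

    def test_frequency_bound_is_strict(self):
        assert len(bsa.filter_variants_method2(table(dict(AF_mut=0.75)))) == 0
        assert len(bsa.filter_variants_method2(table(dict(AF_mut=0.7500001)))) == 1

    def test_depth_bounds(self):
        assert len(bsa.filter_variants_method2(table(dict(DP_wt=14)))) == 1
        assert len(bsa.filter_variants_method2(table(dict(DP_wt=15)))) == 0
        assert len(bsa.filter_variants_method2(table(dict(DP_mut=49)))) == 1
        assert len(bsa.filter_variants_method2(table(dict(DP_mut=50)))) == 0

    def test_matches_brute_force(self):
        t = random_table(np.random.default_rng(1))
        got = bsa.filter_variants_method2(t)
        exp = [
            i for i, r in t.iterrows()
            if r.GQ_wt >= 20 and r.GQ_mut >= 20 and 5 <= r.DP_wt <= 14
            and 6 <= r.DP_mut <= 49 and r.AF_mut > 0.75
        ]
        assert got["POS"].tolist() == t.loc[exp, "POS"].tolist()


class TestFilterProperties:
    def test_filters_commute_with_row_permutation(self):
        t = random_table(np.random.default_rng(2))
        shuffled = t.sample(frac=1, random_state=3).reset_index(drop=True)
        for f in (bsa.filter_variants_method1, bsa.filter_variants_method2):
            a = set(map(tuple, f(t)[["CHROM", "POS"]].to_numpy()))
            b = set(map(tuple, f(shuffled)[["CHROM", "POS"]].to_numpy()))
            assert a == b

    def test_widening_depth_bounds_grows_set(self):
        # widening is monotone: every method2 pass also passes with looser depth
        t = random_table(np.random.default_rng(4))
        narrow = bsa.filter_variants_method2(t)
        loose = t[
            (t.GQ_wt >= 20) & (t.GQ_mut >= 20) & (t.DP_wt >= 1) & (t.DP_wt <= 100)
            & (t.DP_mut >= 1) & (t.DP_mut <= 100) & (t.AF_mut > 0.75)
        ]
        assert set(narrow["POS"]) <= set(loose["POS"])


class TestWindowScan:
    def test_single_variant_mean(self):
        t = table(dict(POS=500, AF_mut=1.0))
        ws = bsa.window_scan(t, window=1000, step=1000)
        assert ws.iloc[0].mean_freq == pytest.approx(1.0)
        assert ws.iloc[0].n_variants == 1

    def test_constructed_window_means(self):
        rows = [dict(POS=p, AF_mut=f) for p, f in
                zip(range(100, 1100, 100), [0.1] * 5 + [0.9] * 5)]
        ws = bsa.window_scan(table(*rows), window=500, step=500)
        w0 = ws[ws.start == 0].iloc[0]
        assert w0.mean_freq == pytest.approx(0.1)  # POS 100..500 -> pos0 99..499
        assert w0.n_variants == 5
        w1 = ws[ws.start == 500].iloc[0]
        assert w1.mean_freq == pytest.approx(0.9)
        assert w1.n_variants == 5

    def test_empty_window_missing_mean(self):
        t = table(dict(POS=2_500, AF_mut=0.8))
        ws = bsa.window_scan(t, window=1000, step=1000)
        empty = ws[ws.start == 1000].iloc[0]
        assert empty.n_variants == 0 and np.isnan(empty.mean_freq)


class TestCandidateRegion:
    def _stats(self, freqs, chrom="chr1", n=10):
        return pd.DataFrame(
            {"chrom": chrom, "start": np.arange(len(freqs)) * 1000,
             "end": np.arange(len(freqs)) * 1000 + 1000,
             "n_variants": n, "mean_freq": freqs,
             "density_per_mb": n}
        )

    def test_flat_background_gives_none(self):
        assert bsa.candidate_region(self._stats([0.75] * 20)) is None

    def test_two_equal_runs_leftmost_wins(self):
        freqs = [0.75] * 3 + [0.95] * 3 + [0.75] * 3 + [0.95] * 3 + [0.75] * 3
        cand = bsa.candidate_region(self._stats(freqs))
        assert cand.start == 3000

    def test_planted_peak_contains_causal_locus(self):
        cfg = simulate.SimConfig(seed=0)
        tab = simulate.simulate_bsa(cfg, np.random.default_rng(123))
        ws = bsa.window_scan(tab)
        cand = bsa.candidate_region(ws)
        assert cand is not None
        assert cand.chrom == cfg.bsa.causal_chrom
        assert cand.start <= cfg.bsa.causal_pos <= cand.end


class TestSimulatedCross:
    def test_unlinked_frequency_near_three_quarters(self):
        cfg = simulate.SimConfig(seed=0)
        tab = simulate.simulate_bsa(cfg, np.random.default_rng(7))
        unlinked = tab[tab.CHROM != cfg.bsa.causal_chrom]
        assert abs(unlinked.true_freq.mean() - 0.75) < 0.01

    def test_complete_linkage_frequency_one(self):
        cfg = simulate.SimConfig(seed=0)
        tab = simulate.simulate_bsa(cfg, np.random.default_rng(7))
        bp = cfg.bsa
        near = tab[(tab.CHROM == bp.causal_chrom)
                   & (abs(tab.POS - bp.causal_pos) < bp.marker_spacing)]
        assert near.true_freq.min() > 0.98

    def test_linked_marker_matches_closed_form(self):
        # selection on the maternal allele makes the pooled truth 1 - r/2
        cfg = simulate.SimConfig(
            seed=0, bsa=simulate.BsaPlan(n_selected=4000)
        )
        tab = simulate.simulate_bsa(cfg, np.random.default_rng(11))
        bp = cfg.bsa
        chrom = tab[tab.CHROM == bp.causal_chrom]
        d_morgan = (
            abs(chrom.POS - 1 - bp.causal_pos) / bp.chrom_length * bp.genetic_length
        )
        r = 0.5 * (1 - np.exp(-2 * d_morgan))
        expected = 1 - r / 2
        se = np.sqrt(0.25 / (2 * bp.n_selected))  # binomial bound on the pooled truth
        assert (abs(chrom.true_freq - expected) < 5 * se + 0.01).all()
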