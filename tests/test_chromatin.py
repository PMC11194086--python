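"""Interval rules vs brute-force oracles, differential regions, PWM scanning."""

import itertools

import numpy as np
import pandas as pd
import pytest

from senoscore import chromatin, syndata
from senoscore.chromatin import (
    PWM,
    _PWM_SCALE,
    boundary_upregulation_test,
    call_active_promoters,
    call_enhancers,
    categorize_ctcf_sites,
    correlate_change,
    differential_region_test,
    link_nearest_gene,
    promoter_windows,
    scan_pwm,
    size_factors_median_of_ratios,
)


def _bed(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def _tss(rows):
    return pd.DataFrame(rows, columns=["gene", "chrom", "tss", "strand"])


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------


def oracle_overlap(a_start, a_end, b_start, b_end):
    return max(a_start, b_start) < min(a_end, b_end)


def oracle_active(tss_row, peaks, window=2000):
    lo, hi = tss_row["tss"] - window, tss_row["tss"] + window
    for mark in ("H3K27ac", "ATAC", "H3K4me3"):
        df = peaks[mark]
        ok = any(
            r["chrom"] == tss_row["chrom"] and oracle_overlap(lo, hi, r["start"], r["end"])
            for _, r in df.iterrows()
        )
        if not ok:
            return False
    return True


def oracle_nearest(element, tss):
    mid = (element["start"] + element["end"]) // 2
    sub = tss[tss["chrom"] == element["chrom"]]
    if sub.empty:
        return "none"
    d = (sub["tss"] - mid).abs()
    best = sub.assign(d=d).sort_values(["d", "tss", "gene"], kind="mergesort")
    return best.iloc[0]["gene"]


class TestPromoters:
    def test_example_all_marks_within_window(self):
        tss = _tss([("g1", "chr1", 10_000, "+")])
        peaks = {
            "H3K27ac": _bed([("chr1", 9_500, 9_600, "a")]),
            "ATAC": _bed([("chr1", 10_100, 10_200, "b")]),
            "H3K4me3": _bed([("chr1", 8_200, 8_300, "c")]),
        }
        out = call_active_promoters(tss, peaks)
        assert out["active"].iloc[0]

    def test_missing_mark_inactive(self):
        tss = _tss([("g1", "chr1", 10_000, "+")])
        peaks = {
            "H3K27ac": _bed([("chr1", 9_500, 9_600, "a")]),
            "ATAC": _bed([("chr1", 10_100, 10_200, "b")]),
            "H3K4me3": _bed([("chr1", 50_000, 50_300, "c")]),
        }
        assert not call_active_promoters(tss, peaks)["active"].iloc[0]

    def test_half_open_boundary(self):
        # peak starting exactly at tss + 2000 does not overlap [tss-2k, tss+2k)
        tss = _tss([("g1", "chr1", 10_000, "+")])
        base = {
            "H3K27ac": _bed([("chr1", 9_000, 9_100, "a")]),
            "ATAC": _bed([("chr1", 9_000, 9_100, "b")]),
        }
        touching = dict(base, H3K4me3=_bed([("chr1", 12_000, 12_100, "c")]))
        inside = dict(base, H3K4me3=_bed([("chr1", 11_999, 12_100, "c")]))
        assert not call_active_promoters(tss, touching)["active"].iloc[0]
        assert call_active_promoters(tss, inside)["active"].iloc[0]

    def test_out_of_bounds_tss_rejected(self):
        tss = _tss([("g1", "chr1", 99_999_999, "+")])
        peaks = {m: _bed([("chr1", 0, 100, "x")]) for m in
                 ("H3K27ac", "ATAC", "H3K4me3")}
        out = call_active_promoters(tss, peaks, chrom_sizes={"chr1": 1_000_000})
        assert out["rejected"].iloc[0] and not out["active"].iloc[0]

    def test_matches_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            tss = _tss([(f"g{i}", "chr1", int(rng.integers(5_000, 95_000)), "+")
                        for i in range(8)])
            peaks = {
                m: _bed([("chr1", s, s + int(rng.integers(100, 3_000)), f"{m}{j}")
                         for j, s in enumerate(
                             rng.integers(0, 100_000, rng.integers(1, 10)))])
                for m in ("H3K27ac", "ATAC", "H3K4me3")
            }
            out = call_active_promoters(tss, peaks)
            for _, row in out.iterrows():
                assert row["active"] == oracle_active(row, peaks)

    def test_invariant_to_peak_splitting(self):
        tss = _tss([("g1", "chr1", 10_000, "+")])
        whole = {m: _bed([("chr1", 9_000, 11_000, "x")]) for m in
                 ("H3K27ac", "ATAC", "H3K4me3")}
        split = {m: _bed([("chr1", 9_000, 10_000, "x1"), ("chr1", 10_000, 11_000, "x2")])
                 for m in ("H3K27ac", "ATAC", "H3K4me3")}
        assert (call_active_promoters(tss, whole)["active"].iloc[0]
                == call_active_promoters(tss, split)["active"].iloc[0])


class TestEnhancers:
    def test_rule_application(self):
        k27 = _bed([("chr1", 100, 200, "e1")])
        k4 = _bed([("chr1", 150, 250, "m1")])
        out = call_enhancers(k27, k4, _bed([]))
        assert len(out) == 1
        assert (out.iloc[0]["start"], out.iloc[0]["end"]) == (100, 200)

    def test_inside_promoter_excluded(self):
        k27 = _bed([("chr1", 100, 200, "e1")])
        k4 = _bed([("chr1", 150, 250, "m1")])
        out = call_enhancers(k27, k4, _bed([("chr1", 0, 500, "p")]))
        assert len(out) == 0

    def test_no_k4me1_no_enhancer(self):
        out = call_enhancers(_bed([("chr1", 100, 200, "e1")]),
                             _bed([("chr2", 100, 200, "m")]), _bed([]))
        assert len(out) == 0

    def test_planted_landscape_perfect_recovery(self, small_landscape):
        land = small_landscape
        proms = call_active_promoters(land.tss_table, land.peaks,
                                      chrom_sizes=land.chrom_sizes)
        enh = call_enhancers(land.peaks["H3K27ac"], land.peaks["H3K4me1"],
                             promoter_windows(proms))
        truth_names = {n for n in land.peaks["H3K27ac"]["name"]
                       if n.startswith("enh_")}
        called = set(enh["name"])
        assert called == truth_names  # recall = precision = 1


class TestNearestGene:
    def test_tie_break_and_containment(self):
        tss = _tss([("b", "chr1", 900, "+"), ("a", "chr1", 1_100, "+")])
        el = _bed([("chr1", 950, 1_050, "e")])  # midpoint 1000, equidistant
        out = link_nearest_gene(el, tss)
        assert out["nearest_gene"].iloc[0] == "b"  # smaller coordinate wins
        contain = link_nearest_gene(_bed([("chr1", 890, 910, "e")]), tss)
        assert contain["distance"].iloc[0] == 0

    def test_chrom_without_tss(self):
        out = link_nearest_gene(_bed([("chrX", 0, 10, "e")]),
                                _tss([("a", "chr1", 5, "+")]))
        assert out["nearest_gene"].iloc[0] == "none"

    def test_matches_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            tss = _tss([(f"g{i}", "chr1", int(p), "+") for i, p in
                        enumerate(rng.integers(0, 50_000, 12))])
            els = _bed([("chr1", int(s), int(s) + 100, f"e{j}") for j, s in
                        enumerate(rng.integers(0, 50_000, 15))])
            out = link_nearest_gene(els, tss)
            for (_, el), got in zip(els.iterrows(), out["nearest_gene"]):
                assert got == oracle_nearest(el, tss)


class TestDifferentialRegions:
    def test_size_factor_example(self):
        counts = pd.DataFrame({"s1": [10, 20], "s2": [20, 40]}, index=["r1", "r2"])
        sf = size_factors_median_of_ratios(counts)
        np.testing.assert_allclose(sf, [np.sqrt(0.5), np.sqrt(2.0)], atol=1e-4)
        assert np.prod(sf) == pytest.approx(1.0, abs=1e-12)

    def test_size_factors_multiply_to_one(self, small_landscape):
        sf = size_factors_median_of_ratios(small_landscape.region_counts)
        assert np.prod(sf) == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_region_untested(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(rng.poisson(30, (20, 6)),
                              columns=[f"s{i}" for i in range(6)])
        counts.iloc[0] = 0
        cond = pd.Series(["a"] * 3 + ["b"] * 3, index=counts.columns,
                         name="condition")
        res = differential_region_test(counts, cond)
        assert not res.table["tested"].iloc[0]
        assert res.table["class"].iloc[0] == "unchanged"

    def test_planted_fold_changes_detected(self):
        rng = np.random.default_rng(3)
        l2fc = np.zeros(400)
        l2fc[:40] = 2.0
        counts, cond, _ = syndata.simulate_region_counts(
            l2fc, n_reps=3, depth=50, dispersion=0.05, rng=rng)
        df = pd.DataFrame(counts, index=[f"r{i}" for i in range(400)],
                          columns=cond.index)
        res = differential_region_test(df, cond)
        called = res.table["class"].to_numpy() != "unchanged"
        assert called[:40].mean() >= 0.8
        assert called[40:].sum() <= 0.1 * max(called.sum(), 1)

    def test_single_condition_rejected(self):
        counts = pd.DataFrame(np.ones((3, 4)), columns=list("abcd"))
        cond = pd.Series(["x"] * 4, index=counts.columns, name="condition")
        with pytest.raises(ValueError):
            differential_region_test(counts, cond)


class TestPWM:
    def test_null_distribution_sums_to_one(self):
        pwm = PWM.from_counts(syndata.SYNTHETIC_CTCF_PFM)
        pmf, _ = pwm.null_distribution()
        assert abs(pmf.sum() - 1.0) < 1e-9

    @pytest.mark.parametrize("width", [2, 4, 6, 8])
    def test_threshold_matches_exhaustive_enumeration(self, width):
        rng = np.random.default_rng(width)
        counts = pd.DataFrame(rng.integers(1, 60, (4, width)),
                              index=list("ACGT"))
        pwm = PWM.from_counts(counts)
        for pmax in (1e-1, 1e-2, 1e-3):
            t_dp = pwm.score_threshold(pmax)
            # enumerate all 4^width k-mers with their background probabilities
            scores, probs = [], []
            for kmer in itertools.product(range(4), repeat=width):
                scores.append(sum(pwm.int_scores[b, j] for j, b in enumerate(kmer)))
                probs.append(np.prod(pwm.background[list(kmer)]))
            scores = np.array(scores)
            probs = np.array(probs)
            order = np.argsort(scores)
            uniq = np.unique(scores)
            sf = {s: probs[scores >= s].sum() for s in uniq}
            passing = [s for s in uniq if sf[s] <= pmax]
            t_enum = min(passing) if passing else int(uniq.max()) + 1
            assert t_dp == t_enum

    def test_threshold_monotone_in_pvalue(self):
        pwm = PWM.from_counts(syndata.SYNTHETIC_CTCF_PFM)
        ts = [pwm.score_threshold(p) for p in (1e-2, 1e-4, 1e-6)]
        assert ts[0] <= ts[1] <= ts[2]

    def test_background_pwm_scores_zero(self):
        counts = pd.DataFrame(np.ones((4, 5)), index=list("ACGT"))
        pwm = PWM.from_counts(counts)
        assert np.all(pwm.int_scores == 0)
        scan = scan_pwm({"s": "ACGTACGTAC"}, pwm, pvalue_max=0.5)
        assert scan["best_score"].iloc[0] == 0.0

    def test_reverse_complement_symmetry(self):
        pwm = PWM.from_counts(syndata.SYNTHETIC_CTCF_PFM)
        probs = pwm.probs
        consensus = "".join("ACGT"[i] for i in np.argmax(probs, axis=0))
        rc = syndata._revcomp(consensus)
        pad = "TTTTT"
        scan = scan_pwm({"fwd": pad + consensus + pad, "rev": pad + rc + pad}, pwm)
        assert scan.loc["fwd", "passed"] and scan.loc["rev", "passed"]
        assert scan.loc["fwd", "best_score"] == scan.loc["rev", "best_score"]

    def test_short_sequence_flagged(self):
        pwm = PWM.from_counts(syndata.SYNTHETIC_CTCF_PFM)
        scan = scan_pwm({"tiny": "ACG"}, pwm)
        assert scan.loc["tiny", "too_short"] and not scan.loc["tiny", "passed"]

    def test_n_bases_score_background(self):
        pwm = PWM.from_counts(syndata.SYNTHETIC_CTCF_PFM)
        w = pwm.width
        scan = scan_pwm({"nn": "N" * (w + 4)}, pwm, pvalue_max=0.5)
        assert scan.loc["nn", "best_score"] == 0.0


class TestCategorize:
    def _promoters(self, entries):
        return pd.DataFrame(
            [{"gene": g, "chrom": "chr1", "tss": t, "strand": "+",
              "window_start": t - 2000, "window_end": t + 2000, "active": True}
             for g, t in entries])

    def test_promoter_precedence(self):
        sites = _bed([("chr1", 9_900, 10_100, "s1")])
        cat = categorize_ctcf_sites(
            sites, self._promoters([("g1", 10_000)]), _bed([]),
            _tss([("g1", "chr1", 10_000, "+")]), _bed([]))
        assert cat.loc["s1", "category"] == "promoter"
        assert cat.loc["s1", "linked_gene"] == "g1"

    def test_intervening_rule_and_sidedness(self):
        proms = self._promoters([("g1", 600_000)])
        tss = _tss([("g1", "chr1", 600_000, "+")])
        enh = _bed([("chr1", 449_000, 451_000, "e1")])
        # enhancer at -50 kb, promoter at +100 kb from the site midpoint
        mid_site = _bed([("chr1", 499_900, 500_100, "s1")])
        cat = categorize_ctcf_sites(mid_site, proms, enh, tss, _bed([]))
        assert cat.loc["s1", "category"] == "enhancer_promoter_intervening"
        # same side: both enhancer and promoter to the right -> not intervening
        left_site = _bed([("chr1", 399_900, 400_100, "s2")])
        cat2 = categorize_ctcf_sites(left_site, proms, enh, tss, _bed([]))
        assert cat2.loc["s2", "category"] != "enhancer_promoter_intervening"

    def test_boundary_flag_retained_with_intervening(self):
        proms = self._promoters([("g1", 600_000)])
        tss = _tss([("g1", "chr1", 600_000, "+")])
        enh = _bed([("chr1", 449_000, 451_000, "e1")])
        tads = _bed([("chr1", 495_000, 505_000, "b1")])
        site = _bed([("chr1", 499_900, 500_100, "s1")])
        cat = categorize_ctcf_sites(site, proms, enh, tss, tads)
        assert cat.loc["s1", "category"] == "enhancer_promoter_intervening"
        assert cat.loc["s1", "boundary_flag"]

    def test_planted_landscape_categories_exact(self, small_landscape):
        land = small_landscape
        proms = call_active_promoters(land.tss_table, land.peaks,
                                      chrom_sizes=land.chrom_sizes)
        enh = call_enhancers(land.peaks["H3K27ac"], land.peaks["H3K4me1"],
                             promoter_windows(proms))
        cat = categorize_ctcf_sites(land.ctcf_sites, proms, enh,
                                    land.tss_table, land.tad_boundaries)
        truth = land.ctcf_truth
        assert (cat["category"] == truth["category"]).all()


class TestBoundaryTest:
    def test_planted_coupling_strongly_significant(self):
        land = syndata.generate_regulatory_landscape(
            syndata.LandscapeConfig(seed=3, n_boundary_sites=100, coupling=0.9))
        truth = land.ctcf_truth
        cat = pd.DataFrame({
            "boundary_flag": truth["category"] == "tad_boundary",
            "linked_gene": truth["linked_gene"]})
        change = truth["planted_log2fc"]
        up = set(land.gene_truth.index[land.gene_truth["upregulated"]])
        res = boundary_upregulation_test(cat, change, up,
                                         set(land.gene_truth.index))
        assert res["p"] < 1e-6

    def test_extreme_case_closed_form(self):
        cat = pd.DataFrame({"boundary_flag": [True, True],
                            "linked_gene": ["a", "b"]}, index=["s1", "s2"])
        change = pd.Series([-1.0, -1.0], index=["s1", "s2"])
        res = boundary_upregulation_test(cat, change, {"a", "b"},
                                         {"a", "b", "c", "d"})
        # P(both draws in the 2 upregulated of 4) = 1/C(4,2)
        assert res["p"] == pytest.approx(1 / 6, abs=1e-12)

    def test_empty_foreground_rejected(self):
        cat = pd.DataFrame({"boundary_flag": [False], "linked_gene": ["a"]},
                           index=["s1"])
        with pytest.raises(ValueError):
            boundary_upregulation_test(cat, pd.Series([-1.0], index=["s1"]),
                                       {"a"}, {"a", "b"})


class TestCorrelateChange:
    def test_perfect_correlations(self):
        x = pd.Series([1.0, 2.0, 3.0, 4.0])
        assert correlate_change(x, x)["r"] == pytest.approx(1.0)
        assert correlate_change(x, -x)["r"] == pytest.approx(-1.0)

    def test_zero_variance_flagged(self):
        x = pd.Series([1.0, 2.0, 3.0])
        out = correlate_change(x, pd.Series([5.0, 5.0, 5.0]))
        assert not out["defined"]
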