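"""Methylation fractions, Fisher/Wilcoxon exact tests, gene and panel calls."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from fibroprog.methylome import (CpGSite, PanelDef, fisher_exact_2x2,
                                 gene_meth_status, meth_pct, read_panels,
                                 site_differential, summarize_panel,
                                 wilcoxon_paired, write_cpg_table,
                                 read_cpg_table)


def site(meth_veh, total_veh, meth_edc, total_edc, pos=100):
    return CpGSite("chr1", pos, meth_veh, total_veh, meth_edc, total_edc)


def brute_force_wilcoxon(diffs):
    """Two-sided exact signed-rank p by enumerating all sign patterns."""
    d = np.asarray([x for x in diffs if x != 0], dtype=float)
    n = len(d)
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product((0, 1), repeat=n):
        ws.append(sum(r for s, r in zip(signs, ranks) if s))
    ws = np.asarray(ws)
    lower = (ws <= w_obs + 1e-9).mean()
    upper = (ws >= w_obs - 1e-9).mean()
    return min(1.0, 2 * min(lower, upper))


class TestMethPct:
    def test_simple_fractions(self):
        assert meth_pct(5, 10) == 0.5
        assert meth_pct(0, 500) == 0.0

    def test_sub_floor_frequency_reported_zero(self):
        # 1 methylated read in 2000 is below the 0.1% reporting floor
        assert meth_pct(1, 2000) == 0.0
        assert meth_pct(2, 2000) == pytest.approx(0.001)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            meth_pct(0, 0)

    def test_coverage_rule_defines_analyzable(self):
        assert not site(3, 4, 5, 10).analyzable
        assert not site(3, 10, 2, 4).analyzable
        assert site(3, 5, 2, 5).analyzable


class TestFisherExact:
    def test_balanced_table_null(self):
        odds, p = fisher_exact_2x2([[5, 5], [5, 5]])
        assert odds == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_diagonal_table_enumeration(self):
        _, p = fisher_exact_2x2([[5, 0], [0, 5]])
        assert p == pytest.approx(2 / 252, rel=1e-9)

    def test_antidiagonal_20_reads(self):
        _, p = fisher_exact_2x2([[0, 10], [10, 0]])
        assert p == pytest.approx(2 / math.comb(20, 10), rel=1e-9)

    def test_transpose_preserves_p(self, rng):
        for _ in range(50):
            a, b, c, d = rng.integers(0, 20, 4)
            _, p1 = fisher_exact_2x2([[a, b], [c, d]])
            _, p2 = fisher_exact_2x2([[a, c], [b, d]])
            assert p1 == pytest.approx(p2, rel=1e-9)

    def test_zero_margin_gives_unit_p(self):
        _, p = fisher_exact_2x2([[0, 0], [3, 4]])
        assert p == 1.0

    def test_matches_scipy_on_random_tables(self, rng):
        for _ in range(1000):
            a, b, c, d = (int(x) for x in rng.integers(0, 30, 4))
            _, p = fisher_exact_2x2([[a, b], [c, d]])
            ref = stats.fisher_exact([[a, b], [c, d]]).pvalue
            assert p == pytest.approx(ref, rel=1e-7, abs=1e-12)


class TestSiteDifferential:
    def test_identical_proportions_null(self):
        delta, p = site_differential(site(5, 10, 5, 10))
        assert delta == 0.0 and p == pytest.approx(1.0)

    def test_hypo_direction_is_negative_delta(self):
        delta, _ = site_differential(site(9, 10, 2, 10))
        assert delta < 0

    def test_low_coverage_rejected(self):
        with pytest.raises(ValueError):
            site_differential(site(1, 2, 5, 10))


class TestGeneMethStatus:
    @pytest.mark.parametrize(
        "deltas,threshold,expected",
        [
            ((-0.40, -0.35, 0.00), 0.33, "hypo"),
            ((-0.40, +0.40), 0.33, "mixed"),
            ((-0.10, +0.10), 0.33, "none"),
            ((+0.40, +0.05), 0.33, "hyper"),
            ((-0.20, +0.05), 0.10, "hypo"),
            ((), 0.33, "none"),
        ],
    )
    def test_threshold_rules(self, deltas, threshold, expected):
        # sites with exact deltas: veh at 0.5, edc at 0.5 + delta
        sites = [
            CpGSite("chr1", i, 50, 100, int(round((0.5 + d) * 100)), 100)
            for i, d in enumerate(deltas)
        ]
        status = gene_meth_status("g", sites, threshold)
        assert status.status == expected
        assert status.n_sites == len(deltas)

    def test_unanalyzable_sites_ignored(self):
        sites = [CpGSite("chr1", 1, 4, 4, 0, 4)]  # below 5x both ways
        assert gene_meth_status("g", sites, 0.33).status == "none"


class TestWilcoxon:
    def test_all_positive_n5(self):
        w, p = wilcoxon_paired([1, 2, 3, 4, 5], [0, 0, 0, 0, 0])
        assert w == 15
        assert p == pytest.approx(2 / 32)

    def test_identical_vectors_null(self):
        assert wilcoxon_paired([1, 2, 3], [1, 2, 3]) == (0.0, 1.0)

    def test_negating_differences_preserves_p(self, rng):
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        _, p1 = wilcoxon_paired(x, y)
        _, p2 = wilcoxon_paired(y, x)
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_exact_matches_enumeration_with_ties(self, rng):
        for _ in range(60):
            n = int(rng.integers(2, 10))
            d = rng.integers(-4, 5, n)
            x = d.astype(float)
            y = np.zeros(n)
            if (x == 0).all():
                continue
            _, p = wilcoxon_paired(x, y)
            assert p == pytest.approx(brute_force_wilcoxon(x), rel=1e-9)

    def test_exact_matches_scipy_without_ties(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 15))
            x = rng.normal(size=n)
            y = np.zeros(n)
            _, p = wilcoxon_paired(x, y)
            ref = stats.wilcoxon(x, method="exact", alternative="two-sided").pvalue
            assert p == pytest.approx(ref, rel=1e-9)

    def test_normal_approximation_for_large_n(self, rng):
        x = rng.normal(0.2, 1.0, size=60)
        y = np.zeros(60)
        _, p = wilcoxon_paired(x, y)
        ref = stats.wilcoxon(x, correction=False, method="approx",
                             alternative="two-sided").pvalue
        assert p == pytest.approx(ref, rel=1e-6)


class TestPanels:
    def make_panel(self, n=19):
        return PanelDef("Pgr", "chr1", tuple(range(100, 100 + n * 50, 50)))

    def sites_with_calls(self, panel, n_hypo):
        """High-coverage sites: the first n_hypo strongly hypo, the rest null."""
        sites = []
        for i, pos in enumerate(panel.positions):
            if i < n_hypo:
                sites.append(CpGSite(panel.chrom, pos, 160, 200, 60, 200))
            else:
                sites.append(CpGSite(panel.chrom, pos, 100, 200, 100, 200))
        return sites

    def test_seven_of_nineteen_hypo_is_36_8_pct(self):
        panel = self.make_panel(19)
        report = summarize_panel(panel, self.sites_with_calls(panel, 7))
        assert report.n_hypo == 7
        assert report.pct_hypo == 36.8

    def test_full_panel_hypo_is_100_pct(self):
        panel = self.make_panel(14)
        report = summarize_panel(panel, self.sites_with_calls(panel, 14))
        assert report.pct_hypo == 100.0

    def test_no_calls_zero_pct(self):
        panel = self.make_panel(10)
        report = summarize_panel(panel, self.sites_with_calls(panel, 0))
        assert report.pct_hypo == 0.0 and report.n_hypo == 0

    def test_missing_sites_noted_and_excluded(self):
        panel = self.make_panel(5)
        sites = self.sites_with_calls(panel, 5)[:3]
        report = summarize_panel(panel, sites)
        assert set(report.missing) == set(panel.positions[3:])
        assert report.n_hypo == 3
        assert report.pct_hypo == round(100 * 3 / 5, 1)

    def test_percent_invariant_to_site_order(self):
        panel = self.make_panel(12)
        sites = self.sites_with_calls(panel, 5)
        fwd = summarize_panel(panel, sites)
        rev = summarize_panel(panel, sites[::-1])
        assert fwd.pct_hypo == rev.pct_hypo
        assert fwd.wilcoxon_p == pytest.approx(rev.wilcoxon_p)

    def test_positions_must_increase(self):
        with pytest.raises(ValueError):
            PanelDef("g", "chr1", (5, 5, 6))


class TestCpGIO:
    def test_round_trip(self, tmp_path, rng):
        sites = [
            CpGSite("chr1", int(p), int(m), int(t + m), int(m2), int(t2 + m2))
            for p, m, t, m2, t2 in zip(
                range(0, 500, 50), rng.integers(0, 10, 10), rng.integers(0, 20, 10),
                rng.integers(0, 10, 10), rng.integers(0, 20, 10))
        ]
        write_cpg_table(sites, tmp_path / "cpg.tsv")
        assert read_cpg_table(tmp_path / "cpg.tsv") == sites

    def test_panel_reader_groups_by_gene(self, tmp_path):
        path = tmp_path / "panels.tsv"
        path.write_text(
            "gene\tchrom\tpos\nEsr1\tchr1\t10\nEsr1\tchr1\t60\nPgr\tchr8\t5\n"
        )
        panels = read_panels(path)
        assert panels["Esr1"].size == 2 and panels["Pgr"].size == 1
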