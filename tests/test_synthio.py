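"""Planted-truth generator: determinism, planted effects, recoverable signal."""

import numpy as np
import pytest

from fibroprog.methylome import PanelDef
from fibroprog.synthio import (SimConfig, make_genes, make_genome, plant_truth,
                               simulate_chip_windows, simulate_panel,
                               simulate_rnaseq, simulate_rrbs, read_truth,
                               write_truth)


def small_config(**kw):
    defaults = dict(n_genes=100, n_erg=10, rna_depth=500_000, seed=11)
    defaults.update(kw)
    return SimConfig(**defaults)


class TestPlantTruth:
    def test_fraction_zero_all_null(self):
        cfg = small_config(fraction_de=0.0)
        truth = plant_truth(make_genes(cfg), cfg)
        assert all(t.de_log2fc == 0 and t.chip_effect == 1 and t.meth_delta == 0
                   for t in truth)

    def test_rounding_rule_half_up_half_down(self):
        cfg = small_config(fraction_de=0.3)
        truth = plant_truth(make_genes(cfg), cfg)
        ups = sum(t.de_log2fc > 0 for t in truth)
        downs = sum(t.de_log2fc < 0 for t in truth)
        assert (ups, downs) == (15, 15)

    def test_odd_count_ties_to_up(self):
        cfg = small_config(n_genes=90, fraction_de=0.3)  # 27 DE genes
        truth = plant_truth(make_genes(cfg), cfg)
        ups = sum(t.de_log2fc > 0 for t in truth)
        downs = sum(t.de_log2fc < 0 for t in truth)
        assert (ups, downs) == (14, 13)

    def test_same_seed_identical_truth(self):
        cfg = small_config()
        genes = make_genes(cfg)
        assert plant_truth(genes, cfg) == plant_truth(genes, cfg)

    def test_concordant_effects_agree_with_expression_direction(self):
        cfg = small_config(n_genes=400, fraction_de=0.5,
                           fraction_concordant_chip=1.0,
                           fraction_concordant_meth=1.0)
        truth = plant_truth(make_genes(cfg), cfg)
        for t in truth:
            if t.de_log2fc > 0:
                assert t.chip_effect > 1 and t.meth_delta < 0
            elif t.de_log2fc < 0:
                assert t.chip_effect < 1 and t.meth_delta > 0


class TestRNASeq:
    def test_planted_fold_change_recovered_at_depth(self):
        cfg = small_config(n_genes=200, fraction_de=0.5, de_log2fc=1.0,
                           rna_depth=10_000_000, dispersion=0.0)
        genes = make_genes(cfg)
        truth = plant_truth(genes, cfg)
        cm = simulate_rnaseq(genes, truth, cfg)
        counts = cm.counts
        # planted means satisfy E[EDC] = E[VEH] * 2^lfc on the raw scale
        errors = []
        for t in truth:
            if t.de_log2fc == 0:
                continue
            a = counts.loc[t.gene_id, "EDC_1"]
            b = counts.loc[t.gene_id, "VEH_1"]
            if a > 0 and b > 0:
                errors.append(np.log2(a / b) - t.de_log2fc)
        assert abs(np.mean(errors)) < 0.05

    def test_null_genes_centered_on_zero(self):
        cfg = small_config(n_genes=300, fraction_de=0.0, rna_depth=5_000_000)
        genes = make_genes(cfg)
        truth = plant_truth(genes, cfg)
        counts = simulate_rnaseq(genes, truth, cfg).counts
        libs = counts.sum(axis=0)
        ratios = np.log2(
            (counts["EDC_1"] + 0.5) / libs["EDC_1"]
        ) - np.log2((counts["VEH_1"] + 0.5) / libs["VEH_1"])
        assert abs(ratios.mean()) < 0.05

    def test_depth_scaling_of_totals(self):
        for depth in (1_000_000, 4_000_000):
            cfg = small_config(rna_depth=depth)
            genes = make_genes(cfg)
            truth = plant_truth(genes, cfg)
            total = simulate_rnaseq(genes, truth, cfg).counts["VEH_1"].sum()
            assert abs(total - depth) / depth < 0.05

    def test_replicates_shape(self):
        cfg = small_config(replicates=3)
        genes = make_genes(cfg)
        cm = simulate_rnaseq(genes, plant_truth(genes, cfg), cfg)
        assert cm.counts.shape == (100, 6)
        assert cm.conditions == ["VEH"] * 3 + ["EDC"] * 3


class TestChipWindows:
    def test_planted_promoter_ratio_recovered(self):
        cfg = small_config(n_genes=50, fraction_de=1.0,
                           fraction_concordant_chip=1.0, chip_effect=3.0,
                           chip_background=200.0, peak_height=10.0)
        genes = make_genes(cfg)
        truth = plant_truth(genes, cfg)
        track = simulate_chip_windows(make_genome(cfg), genes, truth, cfg)
        by_gene = {t.gene_id: t for t in truth}
        ratios = []
        for gene in genes:
            t = by_gene[gene.gene_id]
            if t.chip_effect <= 1:
                continue
            w = gene.tss // cfg.window_size
            edc = track.edc[gene.chrom][w]
            veh = track.veh[gene.chrom][w]
            # subtract flat background before comparing peak rates
            ratios.append((edc - 200.0) / (veh - 200.0))
        assert np.mean(ratios) == pytest.approx(3.0, rel=0.05)

    def test_null_effect_tracks_exchangeable(self):
        cfg = small_config(fraction_de=0.0)
        genes = make_genes(cfg)
        truth = plant_truth(genes, cfg)
        track = simulate_chip_windows(make_genome(cfg), genes, truth, cfg)
        tot_v = sum(v.sum() for v in track.veh.values())
        tot_e = sum(v.sum() for v in track.edc.values())
        assert abs(tot_v - tot_e) / tot_v < 0.05

    def test_zero_background_zero_outside_peaks(self):
        cfg = small_config(chip_background=0.0)
        genes = make_genes(cfg)
        truth = plant_truth(genes, cfg)
        track = simulate_chip_windows(make_genome(cfg), genes, truth, cfg)
        assert sum(v.sum() for v in track.veh.values()) == 0


class TestRRBS:
    def test_null_deltas_centered_on_zero(self):
        cfg = small_config(fraction_de=0.0, cpg_coverage=100)
        genes = make_genes(cfg)
        sites = simulate_rrbs(genes, plant_truth(genes, cfg), cfg)
        deltas = [s.delta for s in sites if s.analyzable]
        assert abs(np.mean(deltas)) < 0.02

    def test_planted_delta_recovered_at_coverage(self):
        cfg = small_config(n_genes=60, fraction_de=1.0,
                           fraction_concordant_meth=1.0, meth_delta=0.25,
                           cpg_coverage=500)
        genes = make_genes(cfg)
        truth = plant_truth(genes, cfg)
        sites = simulate_rrbs(genes, truth, cfg)
        up_genes = {t.gene_id for t in truth if t.de_log2fc > 0}
        by_gene: dict[str, list] = {}
        from fibroprog.methylome import assign_sites_to_promoters
        mapping = assign_sites_to_promoters(sites, genes, cfg.promoter_flank)
        hypo_deltas = [s.delta for g in up_genes for s in mapping[g]]
        # binomial standard error at 500x is ~0.02; clipping pulls slightly up
        assert np.mean(hypo_deltas) == pytest.approx(-0.25, abs=0.03)

    def test_sites_per_promoter(self):
        cfg = small_config(cpgs_per_promoter=14)
        genes = make_genes(cfg)
        sites = simulate_rrbs(genes, plant_truth(genes, cfg), cfg)
        assert len(sites) == 14 * len(genes)


class TestPanelSim:
    def panel(self, n=14):
        return PanelDef("Esr1", "chr1", tuple(range(1000, 1000 + 40 * n, 40)))

    def test_panel_size_respected(self):
        sites = simulate_panel(self.panel(14), [-0.25] * 14, 500, seed=42)
        assert len(sites) == 14
        assert [s.pos for s in sites] == list(self.panel(14).positions)

    def test_null_deltas_give_null_panel(self):
        sites = simulate_panel(self.panel(10), [0.0] * 10, 500, seed=1)
        deltas = [s.delta for s in sites]
        assert abs(np.mean(deltas)) < 0.05

    def test_wrong_delta_count_rejected(self):
        with pytest.raises(ValueError, match="deltas"):
            simulate_panel(self.panel(14), [-0.25] * 10, 500, seed=1)

    def test_out_of_range_delta_rejected(self):
        with pytest.raises(ValueError):
            simulate_panel(self.panel(2), [-1.5, 0.0], 500, seed=1)

    def test_clipping_bounds_levels(self):
        sites = simulate_panel(self.panel(14), [-0.95] * 14, 500, seed=3,
                               meth_base=0.2)
        for s in sites:
            assert s.pct_edc == pytest.approx(0.0, abs=0.02)


class TestDeterminism:
    def test_identical_config_bit_identical_outputs(self):
        cfg = small_config()
        genes = make_genes(cfg)
        truth = plant_truth(genes, cfg)
        cm1 = simulate_rnaseq(genes, truth, cfg)
        cm2 = simulate_rnaseq(genes, truth, cfg)
        assert cm1.counts.equals(cm2.counts)
        t1 = simulate_chip_windows(make_genome(cfg), genes, truth, cfg)
        t2 = simulate_chip_windows(make_genome(cfg), genes, truth, cfg)
        for c in t1.genome.chrom_names:
            np.testing.assert_array_equal(t1.edc[c], t2.edc[c])
        assert simulate_rrbs(genes, truth, cfg) == simulate_rrbs(genes, truth, cfg)

    def test_different_seeds_differ(self):
        cfg1, cfg2 = small_config(seed=1), small_config(seed=2)
        genes = make_genes(cfg1)
        cm1 = simulate_rnaseq(genes, plant_truth(genes, cfg1), cfg1)
        cm2 = simulate_rnaseq(genes, plant_truth(genes, cfg2), cfg2)
        assert not cm1.counts.equals(cm2.counts)

    def test_truth_table_round_trip(self, tmp_path):
        cfg = small_config()
        genes = make_genes(cfg)
        truth = plant_truth(genes, cfg)
        write_truth(truth, tmp_path / "truth.tsv")
        assert read_truth(tmp_path / "truth.tsv") == truth
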