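"""Tri-omics direction-concordance classification and gene-set statistics.

Each differentially expressed gene is classified per epigenetic layer
against its expression direction: the "expected" mark is promoter-mark
enrichment or promoter hypo-methylation for an upregulated gene (symmetric
for downregulated), "opposite" is the reverse, "mixed" means the layer shows
both directions, and "none" means no mark.  Summary tables report category
counts and percentages per expression direction, the estrogen-responsive
gene (ERG) dysregulation tally, hypergeometric over-representation, and the
Fisher association between expression direction and mark status.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import chromstate as cs
from . import diffchip, diffexpr, methylome, synthio
from .config import dump_config, load_config
from .genome import write_bed
from .methylome import fisher_exact_2x2

logger = logging.getLogger(__name__)

CHIP_STATUSES = {"enriched", "reduced", "both", "none"}
METH_STATUSES = {"hypo", "hyper", "mixed", "none"}
CATEGORIES = ("expected", "opposite", "mixed", "none")


@dataclass(frozen=True)
class ConcordanceRecord:
    """Per-gene expression direction, layer statuses, and derived categories."""

    gene_id: str
    de_direction: str  # up / down
    chip_status: str
    meth_status: str
    chip_category: str
    meth_category: str


@dataclass
class ORAResult:
    """Hypergeometric over-representation of a gene set within a gene list."""

    set_name: str
    universe: int  # N
    list_size: int  # n
    set_size: int  # K
    overlap: int  # k
    p: float  # P(X >= k)
    enrichment: float  # (k/n) / (K/N)


def classify_gene(de_dir: str, chip_status: str, meth_status: str,
                  gene_id: str = "") -> ConcordanceRecord:
    """Assign expected/opposite/mixed/none categories for both layers."""
    if de_dir not in {"up", "down"}:
        raise ValueError(f"de_dir must be up or down, got {de_dir!r}")
    if chip_status not in CHIP_STATUSES:
        raise ValueError(f"unknown chip status {chip_status!r}")
    if meth_status not in METH_STATUSES:
        raise ValueError(f"unknown methylation status {meth_status!r}")

    if chip_status == "both":
        chip_cat = "mixed"
    elif chip_status == "none":
        chip_cat = "none"
    elif (de_dir == "up") == (chip_status == "enriched"):
        chip_cat = "expected"
    else:
        chip_cat = "opposite"

    if meth_status == "mixed":
        meth_cat = "mixed"
    elif meth_status == "none":
        meth_cat = "none"
    elif (de_dir == "up") == (meth_status == "hypo"):
        meth_cat = "expected"
    else:
        meth_cat = "opposite"

    return ConcordanceRecord(gene_id, de_dir, chip_status, meth_status,
                             chip_cat, meth_cat)


def summarize_concordance(records: Sequence[ConcordanceRecord], threshold: float
                          ) -> dict[str, dict]:
    """Category counts and percentages per expression direction.

    Returns {direction: {"n": total, "chip": {cat: {count, pct}}, "meth":
    {...}, "overlap": genes with both a chip and a methylation mark}}.
    Percentages are count/total*100 to 2 decimals.
    """
    if not records:
        raise ValueError("no concordance records to summarize")
    out: dict[str, dict] = {}
    for direction in ("up", "down"):
        recs = [r for r in records if r.de_direction == direction]
        if not recs:
            continue
        total = len(recs)
        entry: dict = {"n": total, "threshold": threshold}
        for layer, attr in (("chip", "chip_category"), ("meth", "meth_category")):
            layer_counts = {}
            for cat in CATEGORIES:
                count = sum(1 for r in recs if getattr(r, attr) == cat)
                layer_counts[cat] = {
                    "count": count,
                    "pct": round(100.0 * count / total, 2),
                }
            entry[layer] = layer_counts
        entry["overlap"] = sum(
            1 for r in recs if r.chip_status != "none" and r.meth_status != "none"
        )
        out[direction] = entry
    return out


def erg_summary(de_results: pd.DataFrame, erg_set: set[str]) -> tuple[int, int, int]:
    """Counts of dysregulated ERGs: (n_up, n_down, n_total)."""
    if not erg_set:
        raise ValueError("empty ERG set")
    present = [g for g in erg_set if g in de_results.index]
    absent = erg_set - set(present)
    if absent:
        logger.info("%d ERGs not in the expression table (counted as not detected)",
                    len(absent))
    directions = de_results.loc[present, "direction"]
    n_up = int((directions == "up").sum())
    n_down = int((directions == "down").sum())
    return n_up, n_down, n_up + n_down


def ora_hypergeom(gene_list: set[str], gene_set: set[str], universe: set[str],
                  set_name: str = "") -> ORAResult:
    """Hypergeometric upper-tail over-representation p-value.

    p = P(X >= k) where k genes of the list of size n fall in the set of
    size K drawn from a universe of size N.
    """
    if not universe:
        raise ValueError("empty universe")
    extra_list = gene_list - universe
    extra_set = gene_set - universe
    if extra_list or extra_set:
        logger.warning("clipping %d list / %d set genes outside the universe",
                       len(extra_list), len(extra_set))
    glist = gene_list & universe
    gset = gene_set & universe
    n_universe, n_list, n_set = len(universe), len(glist), len(gset)
    k = len(glist & gset)
    p = float(stats.hypergeom.sf(k - 1, n_universe, n_set, n_list))
    p = min(1.0, max(p, np.nextafter(0, 1)))
    if n_list == 0 or n_set == 0:
        enrichment = 0.0
    else:
        enrichment = (k / n_list) / (n_set / n_universe)
    return ORAResult(set_name, n_universe, n_list, n_set, k, p, enrichment)


def integration_fisher(de_dirs: Mapping[str, str], mark_present: Mapping[str, bool]
                       ) -> tuple[float, float]:
    """Fisher exact association of expression direction with mark presence.

    The 2x2 table is (up, down) x (mark, no mark) over the genes present in
    both mappings; degenerate margins yield p = 1.
    """
    shared = [g for g in de_dirs if g in mark_present and de_dirs[g] in {"up", "down"}]
    if not shared:
        raise ValueError("no genes shared between expression and mark tables")
    a = sum(1 for g in shared if de_dirs[g] == "up" and mark_present[g])
    b = sum(1 for g in shared if de_dirs[g] == "up" and not mark_present[g])
    c = sum(1 for g in shared if de_dirs[g] == "down" and mark_present[g])
    d = sum(1 for g in shared if de_dirs[g] == "down" and not mark_present[g])
    return fisher_exact_2x2([[a, b], [c, d]])


def build_concordance(de_results: pd.DataFrame,
                      chip_status: Mapping[str, str],
                      meth_status: Mapping[str, str]) -> list[ConcordanceRecord]:
    """Classify every differentially expressed gene (ns genes are excluded)."""
    records = []
    for gene_id, row in de_results.iterrows():
        if row["direction"] not in {"up", "down"}:
            continue
        records.append(
            classify_gene(
                row["direction"],
                chip_status.get(gene_id, "none"),
                meth_status.get(gene_id, "none"),
                gene_id=str(gene_id),
            )
        )
    return records


def evaluate_recovery(truth: Sequence[synthio.TruthRecord],
                      de_results: pd.DataFrame,
                      chip_status: Mapping[str, str],
                      records: Sequence[ConcordanceRecord]) -> dict:
    """Planted-truth recovery metrics for a synthetic run.

    Reports expression-call sensitivity and false-direction rate, promoter
    mark sensitivity among genes with a planted mark effect, and the
    recovered expected-mark percentages among up/down genes per layer.
    """
    by_gene = {t.gene_id: t for t in truth}
    de_true = [t for t in truth if t.de_log2fc != 0]
    called = de_results[de_results["direction"].isin(["up", "down"])]
    hits = 0
    wrong_direction = 0
    for t in de_true:
        if t.gene_id in called.index:
            want = "up" if t.de_log2fc > 0 else "down"
            if called.loc[t.gene_id, "direction"] == want:
                hits += 1
            else:
                wrong_direction += 1
    de_sensitivity = hits / len(de_true) if de_true else float("nan")

    chip_true = [t for t in truth if t.chip_effect != 1.0]
    chip_hits = 0
    chip_wrong = 0
    for t in chip_true:
        status = chip_status.get(t.gene_id, "none")
        want = "enriched" if t.chip_effect > 1 else "reduced"
        if status == want:
            chip_hits += 1
        elif status in {"enriched", "reduced"}:
            chip_wrong += 1
    chip_sensitivity = chip_hits / len(chip_true) if chip_true else float("nan")

    recovered: dict[str, dict[str, float]] = {}
    for direction in ("up", "down"):
        recs = [r for r in records if r.de_direction == direction]
        if recs:
            recovered[direction] = {
                "chip_expected_pct": round(
                    100.0 * sum(r.chip_category == "expected" for r in recs) / len(recs), 2),
                "meth_expected_pct": round(
                    100.0 * sum(r.meth_category == "expected" for r in recs) / len(recs), 2),
            }
    planted_chip = [t.chip_concordant for t in truth if t.chip_concordant is not None]
    planted_meth = [t.meth_concordant for t in truth if t.meth_concordant is not None]
    return {
        "de_sensitivity": de_sensitivity,
        "de_false_direction": wrong_direction,
        "chip_sensitivity": chip_sensitivity,
        "chip_false_direction": chip_wrong,
        "recovered": recovered,
        "planted_chip_concordance_pct": round(100.0 * np.mean(planted_chip), 2)
        if planted_chip else float("nan"),
        "planted_meth_concordance_pct": round(100.0 * np.mean(planted_meth), 2)
        if planted_meth else float("nan"),
    }


def default_panel_path() -> Path:
    return Path(__file__).parent / "data" / "erg_panels_synthetic.tsv"


def run_pipeline(config: Mapping | str | Path | None, outdir: str | Path,
                 panel_path: str | Path | None = None) -> dict:
    """Run the full synthetic tri-omics pipeline and write every report.

    ``config`` may be a loaded configuration mapping, a YAML path, or None
    for all defaults.  Returns the summary dictionary (also written as
    ``summary.json``).  Deterministic given the configuration.
    """
    if config is None or isinstance(config, (str, Path)):
        cfg = load_config(config)
    else:
        cfg = load_config(None, overrides=config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dump_config(cfg, outdir / "effective_config.yaml")

    summary: dict = {"seed": cfg["seed"]}
    t0 = time.time()

    # --- synthesis ---------------------------------------------------------
    sim = synthio.SimConfig.from_mapping(cfg["synth"], cfg["seed"])
    genome = synthio.make_genome(sim)
    genes = synthio.make_genes(sim)
    truth = synthio.plant_truth(genes, sim)
    counts = synthio.simulate_rnaseq(genes, truth, sim)
    track = synthio.simulate_chip_windows(genome, genes, truth, sim)
    sites = synthio.simulate_rrbs(genes, truth, sim, genome)

    write_bed(outdir / "genes.bed", genes)
    synthio.write_truth(truth, outdir / "truth.tsv")
    counts.to_tsv(outdir / "counts.tsv")
    diffchip.write_bedgraph(track.veh, genome, sim.window_size, outdir / "chip_veh.bedgraph")
    diffchip.write_bedgraph(track.edc, genome, sim.window_size, outdir / "chip_edc.bedgraph")
    methylome.write_cpg_table(sites, outdir / "cpg.tsv")
    logger.info("synthesis done in %.1fs", time.time() - t0)

    # --- differential expression ------------------------------------------
    t0 = time.time()
    de_cfg = cfg["diffexpr"]
    detected = diffexpr.filter_detected(counts, de_cfg["min_total"])
    de = diffexpr.de_test(detected, de_cfg["dispersion"])
    de = diffexpr.call_de(de, de_cfg["fc_cut"], de_cfg["fdr_cut"])
    diffexpr.write_de_table(de, outdir / "de.tsv")
    summary["n_genes"] = len(genes)
    summary["n_detected"] = len(detected.gene_ids)
    summary["n_up"] = int((de["direction"] == "up").sum())
    summary["n_down"] = int((de["direction"] == "down").sum())
    summary["n_de"] = summary["n_up"] + summary["n_down"]
    logger.info("diffexpr done in %.1fs", time.time() - t0)

    # --- differential mark windows ----------------------------------------
    t0 = time.time()
    dc_cfg = cfg["diffchip"]
    regions = diffchip.scan_windows(track, dc_cfg["fc_cut"], dc_cfg["fdr_cut"])
    diffchip.write_regions_bed(regions, outdir / "diff_regions.bed")
    tss_map = diffchip.annotate_tss(regions, genes, dc_cfg["tss_max_dist"])
    chip_status = {
        g.gene_id: diffchip.gene_mark_status(g, regions, dc_cfg["gene_flank"], genome).status
        for g in genes
    }
    summary["n_diff_regions"] = len(regions)
    summary["n_enriched_regions"] = sum(r.direction == "enriched" for r in regions)
    summary["n_reduced_regions"] = sum(r.direction == "reduced" for r in regions)
    summary["n_genes_with_tss_region"] = len(tss_map)
    logger.info("diffchip done in %.1fs", time.time() - t0)

    # --- chromatin states --------------------------------------------------
    ch_cfg = cfg["chromstate"]
    if ch_cfg["enabled"]:
        t0 = time.time()
        binary = cs.binarize(track, "veh", ch_cfg["p_cut"])
        model = cs.fit_hmm(binary, ch_cfg["n_states"], seed=cfg["seed"],
                           n_restarts=ch_cfg["n_restarts"], tol=ch_cfg["tol"],
                           max_iter=ch_cfg["max_iter"])
        path = cs.decode(model, binary)
        cs.write_states_bed(path, genome, sim.window_size, model.n_states,
                            outdir / "states.bed")
        cs.write_model_tsv(model, outdir / "hmm_model.tsv")
        enrich = cs.state_enrichment(path, regions, genome, sim.window_size,
                                     model.n_states)
        with open(outdir / "state_enrichment.tsv", "w") as handle:
            handle.write("state\tlabel\tgenome_bp\tdiff_bp\todds_ratio\tdefined\n")
            for e in enrich:
                handle.write(
                    f"{e.state + 1}\t{e.label}\t{e.genome_bp}\t{e.diff_bp}\t"
                    f"{e.odds_ratio:.6g}\t{int(e.defined)}\n"
                )
        summary["hmm_log_likelihood"] = round(model.log_likelihood, 3)
        summary["state_odds_ratios"] = {
            e.label: round(e.odds_ratio, 4) for e in enrich
        }
        logger.info("chromstate done in %.1fs", time.time() - t0)

    # --- methylome ----------------------------------------------------------
    t0 = time.time()
    me_cfg = cfg["methylome"]
    analyzable = [s for s in sites if s.analyzable]
    rows = []
    for s in analyzable:
        delta, p = methylome.site_differential(s)
        rows.append((s.chrom, s.pos, f"{s.pct_veh:.6g}", f"{s.pct_edc:.6g}",
                     f"{delta:.6g}", f"{p:.6g}"))
    pd.DataFrame(
        rows, columns=["chrom", "pos", "pct_veh", "pct_edc", "delta", "p"]
    ).to_csv(outdir / "cpg_differential.tsv", sep="\t", index=False)
    by_promoter = methylome.assign_sites_to_promoters(
        analyzable, genes, me_cfg["promoter_flank"]
    )
    meth_status_by_t: dict[float, dict[str, str]] = {}
    for threshold in me_cfg["thresholds"]:
        meth_status_by_t[threshold] = {
            g.gene_id: methylome.gene_meth_status(
                g.gene_id, by_promoter.get(g.gene_id, []), threshold
            ).status
            for g in genes
        }
    summary["n_cpg_sites"] = len(sites)
    summary["n_analyzable_cpgs"] = len(analyzable)

    # targeted panels
    panels = methylome.read_panels(panel_path or default_panel_path())
    panel_dir = outdir / "panels"
    panel_dir.mkdir(exist_ok=True)
    panel_summaries = {}
    for name, panel in panels.items():
        psites = synthio.simulate_panel(
            panel, [sim.panel_delta] * panel.size, sim.panel_coverage,
            cfg["seed"], sim.meth_base, sim.meth_concentration,
        )
        report = methylome.summarize_panel(panel, psites)
        table = report.table.copy()
        for col in ("pct_veh", "pct_edc", "delta", "p"):
            table[col] = table[col].map(lambda v: f"{v:.6g}")
        table.to_csv(panel_dir / f"{name}.tsv", sep="\t", index=False)
        panel_summaries[name] = {
            "size": report.panel_size,
            "n_hypo": report.n_hypo,
            "n_hyper": report.n_hyper,
            "pct_hypo": report.pct_hypo,
            "wilcoxon_p": round(report.wilcoxon_p, 6),
        }
    summary["panels"] = panel_summaries
    logger.info("methylome done in %.1fs", time.time() - t0)

    # --- integration --------------------------------------------------------
    t0 = time.time()
    threshold = cfg["integrate"]["threshold"]
    concord_summaries = {}
    records_at_default: list[ConcordanceRecord] = []
    for t_cut in me_cfg["thresholds"]:
        records = build_concordance(de, chip_status, meth_status_by_t[t_cut])
        if t_cut == threshold:
            records_at_default = records
        label = f"{int(round(t_cut * 100))}"
        if records:
            concord_summaries[label] = summarize_concordance(records, t_cut)
            for direction in ("up", "down"):
                recs = [r for r in records if r.de_direction == direction]
                if not recs:
                    continue
                pd.DataFrame(
                    [
                        (r.gene_id, r.de_direction, r.chip_status, r.meth_status,
                         r.chip_category, r.meth_category)
                        for r in recs
                    ],
                    columns=["gene_id", "de_direction", "chip_status",
                             "meth_status", "chip_category", "meth_category"],
                ).to_csv(outdir / f"concordance_{direction}_{label}.tsv",
                         sep="\t", index=False)
    summary["concordance"] = concord_summaries

    erg_set = {g.gene_id for g in genes if "ERG" in g.gene_sets}
    if erg_set:
        n_up, n_down, n_total = erg_summary(de, erg_set)
        summary["erg"] = {"n_up": n_up, "n_down": n_down, "n_total": n_total}
        de_genes = set(de[de["direction"].isin(["up", "down"])].index)
        universe = set(de.index)
        ora = ora_hypergeom(de_genes, erg_set, universe, "ERG")
        summary["ora_erg"] = {
            "universe": ora.universe, "list": ora.list_size, "set": ora.set_size,
            "overlap": ora.overlap, "p": float(f"{ora.p:.6g}"),
            "enrichment": round(ora.enrichment, 4),
        }

    de_dirs = {str(g): d for g, d in de["direction"].items() if d in {"up", "down"}}
    chip_present = {g: chip_status.get(g, "none") != "none" for g in de_dirs}
    meth_present = {
        g: meth_status_by_t[threshold].get(g, "none") != "none" for g in de_dirs
    }
    if de_dirs:
        or_chip, p_chip = integration_fisher(de_dirs, chip_present)
        or_meth, p_meth = integration_fisher(de_dirs, meth_present)
        summary["fisher_chip"] = {"odds_ratio": round(or_chip, 4),
                                  "p": float(f"{p_chip:.6g}")}
        summary["fisher_meth"] = {"odds_ratio": round(or_meth, 4),
                                  "p": float(f"{p_meth:.6g}")}

    summary["recovery"] = evaluate_recovery(truth, de, chip_status, records_at_default)
    logger.info("integration done in %.1fs", time.time() - t0)

    with open(outdir / "summary.json", "w") as handle:
        json.dump(summary, handle, indent=2, sort_keys=True)
        handle.write("\n")
    return summary
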