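"""Seeded tri-omics simulator with planted per-gene ground truth.

The generator emulates the two-condition (EDC-exposed vs vehicle) pooled
design: per-gene RNA read counts with planted log2 fold changes, TSS-proximal
H3K4me3 window signal with planted enriched/reduced promoters, and per-CpG
bisulfite counts with planted hypo/hyper methylation deltas.  Effects across
the three layers are drawn to agree with the expression direction
("expected mark": up + mark enrichment, up + hypo-methylation) with
configurable probability, so the direction-concordance classification has a
recoverable truth.  Identical configuration (including seed) reproduces
bit-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import rng_for
from .diffchip import WindowTrack
from .diffexpr import EDC, VEH, CountMatrix
from .genome import GeneModel, GenomeSpec
from .methylome import CpGSite, PanelDef

logger = logging.getLogger(__name__)


@dataclass
class SimConfig:
    """All knobs of the tri-omics generator.

    Fractions are probabilities in [0, 1]; depths are total reads (RNA),
    background reads per window (ChIP), and mean per-site coverage (CpG).
    The negative binomial uses Var = mu + dispersion * mu^2; methylation
    levels are Beta-distributed around ``meth_base`` with the given
    concentration (higher = tighter).
    """

    n_genes: int = 2000
    n_erg: int = 50
    fraction_de: float = 0.25
    fraction_concordant_chip: float = 0.8
    fraction_concordant_meth: float = 0.6
    de_log2fc: float = 1.5
    chip_effect: float = 3.0
    meth_delta: float = 0.4
    rna_depth: int = 10_000_000
    chip_background: float = 5.0
    peak_height: float = 10.0
    cpg_coverage: int = 30
    cpgs_per_promoter: int = 14
    replicates: int = 1
    dispersion: float = 0.01
    meth_base: float = 0.5
    meth_concentration: float = 30.0
    window_size: int = 1000
    promoter_flank: int = 1000
    gene_length: int = 4000
    gene_spacing: int = 20000
    n_chroms: int = 2
    panel_delta: float = -0.25
    panel_coverage: int = 500
    seed: int = 1

    def __post_init__(self) -> None:
        for name in ("fraction_de", "fraction_concordant_chip", "fraction_concordant_meth"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.rna_depth <= 0 or self.cpg_coverage <= 0:
            raise ValueError("sequencing depths must be positive")
        if self.chip_background < 0:
            raise ValueError("chip_background must be non-negative")
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")
        if self.replicates < 1:
            raise ValueError("need at least one replicate per condition")
        if abs(self.meth_delta) > 1:
            raise ValueError("|meth_delta| must be <= 1")
        if self.chip_effect <= 0:
            raise ValueError("chip_effect must be positive")
        if not 0 < self.meth_base < 1:
            raise ValueError("meth_base must lie in (0, 1)")

    @classmethod
    def from_mapping(cls, synth: dict, seed: int) -> "SimConfig":
        known = {f.name for f in fields(cls)}
        kwargs = {k: v for k, v in synth.items() if k in known}
        unknown = set(synth) - known
        if unknown:
            raise ValueError(f"unknown simulation keys: {sorted(unknown)}")
        return cls(seed=seed, **kwargs)


@dataclass(frozen=True)
class TruthRecord:
    """Planted per-gene effects across the three layers.

    ``de_log2fc`` is 0 for null genes; ``chip_effect`` is the multiplicative
    EDC/VEH signal ratio at the gene's promoter peak (1 = null);
    ``meth_delta`` is the planted EDC - VEH methylation difference at
    promoter CpGs (0 = null).  The concordance flags record whether each
    epigenetic effect was drawn to agree in the expected direction with the
    expression change (None for non-DE genes).
    """

    gene_id: str
    de_log2fc: float
    chip_effect: float
    meth_delta: float
    chip_concordant: bool | None
    meth_concordant: bool | None

    def __post_init__(self) -> None:
        if abs(self.meth_delta) > 1:
            raise ValueError("|meth_delta| must be <= 1")
        if self.chip_effect <= 0:
            raise ValueError("chip_effect must be positive")


def make_genome(config: SimConfig) -> GenomeSpec:
    """A compact synthetic genome sized to hold the configured genes."""
    per_chrom = -(-config.n_genes // config.n_chroms)
    length = (per_chrom + 1) * config.gene_spacing
    return GenomeSpec({f"chr{i + 1}": length for i in range(config.n_chroms)})


def make_genes(config: SimConfig) -> list[GeneModel]:
    """Genes on a regular grid, alternating strand, with an ERG subset.

    The first ``n_erg`` genes in a seeded random order carry the "ERG" set
    label (the estrogen-responsive gene membership used downstream).
    """
    genome = make_genome(config)
    rng = rng_for("genes", config.seed)
    erg_idx = set(
        rng.choice(config.n_genes, size=min(config.n_erg, config.n_genes),
                   replace=False).tolist()
    )
    genes = []
    per_chrom = -(-config.n_genes // config.n_chroms)
    width = len(str(config.n_genes))
    for i in range(config.n_genes):
        chrom = f"chr{i // per_chrom + 1}"
        slot = i % per_chrom
        start = slot * config.gene_spacing + config.gene_spacing // 2
        end = start + config.gene_length
        strand = "+" if i % 2 == 0 else "-"
        sets = frozenset({"ERG"}) if i in erg_idx else frozenset()
        genes.append(GeneModel(f"g{i + 1:0{width}d}", chrom, start, end, strand, sets))
    assert all(g.end <= genome.length(g.chrom) for g in genes)
    return genes


def plant_truth(genes: Sequence[GeneModel], config: SimConfig) -> list[TruthRecord]:
    """Draw the planted truth table.

    Exactly round(fraction_de * n_genes) genes are differentially expressed,
    half up and half down (ties to up).  Among DE genes each epigenetic layer
    agrees with the expression direction with its configured concordance
    probability and is opposite otherwise.  Null genes carry null effects.
    """
    rng = rng_for("truth", config.seed)
    n = len(genes)
    n_de = int(round(config.fraction_de * n))
    if config.fraction_de > 0 and n_de < 1:
        logger.warning("fraction_de * n_genes < 1; planting zero DE genes")
    de_idx = rng.choice(n, size=n_de, replace=False)
    n_up = -(-n_de // 2)  # ties to up
    up = set(de_idx[:n_up].tolist())
    down = set(de_idx[n_up:].tolist())

    records = []
    for i, gene in enumerate(genes):
        if i in up or i in down:
            sign = 1.0 if i in up else -1.0
            lfc = sign * config.de_log2fc
            chip_conc = bool(rng.random() < config.fraction_concordant_chip)
            meth_conc = bool(rng.random() < config.fraction_concordant_meth)
            # expected mark: up -> promoter mark enriched, promoter hypo-methylated
            chip_sign = sign if chip_conc else -sign
            meth_sign = -sign if meth_conc else sign
            chip = config.chip_effect ** chip_sign
            meth = meth_sign * abs(config.meth_delta)
            records.append(TruthRecord(gene.gene_id, lfc, chip, meth, chip_conc, meth_conc))
        else:
            records.append(TruthRecord(gene.gene_id, 0.0, 1.0, 0.0, None, None))
    return records


def simulate_rnaseq(genes: Sequence[GeneModel], truth: Sequence[TruthRecord],
                    config: SimConfig) -> CountMatrix:
    """Negative-binomial RNA counts with planted fold changes.

    Gene base abundances are log-normal; the vehicle library is scaled to the
    configured depth and the exposed condition multiplies each gene's mean by
    2^de_log2fc.  Columns are VEH_1..r then EDC_1..r.
    """
    by_gene = {t.gene_id: t for t in truth}
    missing = [g.gene_id for g in genes if g.gene_id not in by_gene]
    if missing:
        raise ValueError(f"truth table missing genes: {missing[:3]}...")
    rng = rng_for("rnaseq", config.seed)
    n = len(genes)
    base = rng.lognormal(mean=0.0, sigma=1.5, size=n)
    lfc = np.array([by_gene[g.gene_id].de_log2fc for g in genes])
    mu_veh = base / base.sum() * config.rna_depth
    mu_edc = mu_veh * np.exp2(lfc)

    def draw(mu: np.ndarray) -> np.ndarray:
        if config.dispersion <= 1e-12:
            return rng.poisson(mu)
        r = 1.0 / config.dispersion
        return rng.negative_binomial(r, r / (r + mu))

    cols, conds, data = [], [], []
    for rep in range(config.replicates):
        cols.append(f"VEH_{rep + 1}")
        conds.append(VEH)
        data.append(draw(mu_veh))
    for rep in range(config.replicates):
        cols.append(f"EDC_{rep + 1}")
        conds.append(EDC)
        data.append(draw(mu_edc))
    df = pd.DataFrame(
        np.column_stack(data), index=[g.gene_id for g in genes], columns=cols
    )
    return CountMatrix(df, conds)


def promoter_bounds(gene: GeneModel, flank: int, genome: GenomeSpec) -> tuple[int, int]:
    """TSS ± flank, clipped to the chromosome."""
    lo = max(0, gene.tss - flank)
    hi = min(genome.length(gene.chrom), gene.tss + flank)
    return lo, hi


def simulate_chip_windows(genome: GenomeSpec, genes: Sequence[GeneModel],
                          truth: Sequence[TruthRecord], config: SimConfig
                          ) -> WindowTrack:
    """Poisson window counts: flat background plus promoter peaks.

    Windows overlapping a gene's TSS ± promoter_flank carry a peak of rate
    background * peak_height in the vehicle track; the exposed track scales
    each gene's peak by its planted chip_effect.  Overlapping promoters sum
    their peak signal (with a warning).  Counts are independent Poisson draws
    across windows.
    """
    by_gene = {t.gene_id: t for t in truth}
    rng = rng_for("chip", config.seed)
    w = config.window_size
    lam_veh: dict[str, np.ndarray] = {}
    lam_edc: dict[str, np.ndarray] = {}
    claimed: dict[str, np.ndarray] = {}
    for chrom in genome.chrom_names:
        n_win = -(-genome.length(chrom) // w)
        lam_veh[chrom] = np.full(n_win, float(config.chip_background))
        lam_edc[chrom] = np.full(n_win, float(config.chip_background))
        claimed[chrom] = np.zeros(n_win, dtype=bool)
    peak = config.chip_background * config.peak_height
    overlap_warned = False
    for gene in genes:
        effect = by_gene[gene.gene_id].chip_effect
        lo, hi = promoter_bounds(gene, config.promoter_flank, genome)
        first, last = lo // w, (hi - 1) // w
        idx = np.arange(first, last + 1)
        if claimed[gene.chrom][idx].any() and not overlap_warned:
            logger.warning("overlapping gene promoters: peak signals summed")
            overlap_warned = True
        claimed[gene.chrom][idx] = True
        lam_veh[gene.chrom][idx] += peak
        lam_edc[gene.chrom][idx] += peak * effect
    veh = {c: rng.poisson(lam_veh[c]) for c in genome.chrom_names}
    edc = {c: rng.poisson(lam_edc[c]) for c in genome.chrom_names}
    return WindowTrack(genome, w, veh, edc)


def _beta_params(mean: float, concentration: float) -> tuple[float, float]:
    return mean * concentration, (1.0 - mean) * concentration


def simulate_rrbs(genes: Sequence[GeneModel], truth: Sequence[TruthRecord],
                  config: SimConfig, genome: GenomeSpec | None = None
                  ) -> list[CpGSite]:
    """Binomial bisulfite counts at promoter CpGs with planted deltas.

    Per site the vehicle methylation level is Beta-distributed around
    ``meth_base``; the exposed level adds the gene's planted delta, clipped
    to [0, 1].  Coverage is Poisson around ``cpg_coverage`` per condition.
    Sites are placed evenly across each promoter (TSS ± promoter_flank).
    """
    if genome is None:
        genome = make_genome(config)
    by_gene = {t.gene_id: t for t in truth}
    rng = rng_for("rrbs", config.seed)
    a, b = _beta_params(config.meth_base, config.meth_concentration)
    sites: list[CpGSite] = []
    for gene in genes:
        delta = by_gene[gene.gene_id].meth_delta
        lo, hi = promoter_bounds(gene, config.promoter_flank, genome)
        k = config.cpgs_per_promoter
        positions = np.linspace(lo, hi - 1, num=k).round().astype(int)
        level_veh = rng.beta(a, b, size=k)
        level_edc = np.clip(level_veh + delta, 0.0, 1.0)
        cov_veh = rng.poisson(config.cpg_coverage, size=k)
        cov_edc = rng.poisson(config.cpg_coverage, size=k)
        meth_veh = rng.binomial(cov_veh, level_veh)
        meth_edc = rng.binomial(cov_edc, level_edc)
        for j in range(k):
            sites.append(
                CpGSite(gene.chrom, int(positions[j]), int(meth_veh[j]),
                        int(cov_veh[j]), int(meth_edc[j]), int(cov_edc[j]))
            )
    return sites


def simulate_panel(panel: PanelDef, deltas: Sequence[float], coverage: int,
                   seed: int, meth_base: float = 0.5,
                   meth_concentration: float = 30.0) -> list[CpGSite]:
    """Targeted amplicon counts at the exact panel positions.

    ``deltas`` gives the planted EDC - VEH methylation difference per site
    (one value per panel position, each in [-1, 1]).
    """
    if len(deltas) != panel.size:
        raise ValueError(
            f"panel {panel.gene}: {panel.size} sites but {len(deltas)} deltas"
        )
    deltas = np.asarray(deltas, dtype=float)
    if (np.abs(deltas) > 1).any():
        raise ValueError("planted deltas must lie in [-1, 1]")
    rng = rng_for(f"panel:{panel.gene}", seed)
    a, b = _beta_params(meth_base, meth_concentration)
    k = panel.size
    level_veh = rng.beta(a, b, size=k)
    level_edc = np.clip(level_veh + deltas, 0.0, 1.0)
    cov_veh = rng.poisson(coverage, size=k)
    cov_edc = rng.poisson(coverage, size=k)
    meth_veh = rng.binomial(cov_veh, level_veh)
    meth_edc = rng.binomial(cov_edc, level_edc)
    return [
        CpGSite(panel.chrom, pos, int(meth_veh[j]), int(cov_veh[j]),
                int(meth_edc[j]), int(cov_edc[j]))
        for j, pos in enumerate(panel.positions)
    ]


TRUTH_COLUMNS = ["gene_id", "de_log2fc", "chip_effect", "meth_delta",
                 "chip_concordant", "meth_concordant"]


def write_truth(truth: Iterable[TruthRecord], path: str | Path) -> None:
    rows = []
    for t in truth:
        rows.append(
            (t.gene_id, f"{t.de_log2fc:.17g}", f"{t.chip_effect:.17g}",
             f"{t.meth_delta:.17g}",
             "." if t.chip_concordant is None else str(int(t.chip_concordant)),
             "." if t.meth_concordant is None else str(int(t.meth_concordant)))
        )
    pd.DataFrame(rows, columns=TRUTH_COLUMNS).to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> list[TruthRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for row in df.itertuples(index=False):
        out.append(
            TruthRecord(
                row.gene_id, float(row.de_log2fc), float(row.chip_effect),
                float(row.meth_delta),
                None if row.chip_concordant == "." else bool(int(row.chip_concordant)),
                None if row.meth_concordant == "." else bool(int(row.meth_concordant)),
            )
        )
    return out
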