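"""Per-CpG methylation quantification, differential calls, and the exact
tests used to compare methylation between conditions.

Genome-wide (RRBS-style) sites carry methylated/total read counts for both
conditions and are analyzable only at a minimum of 5x coverage in both
samples.  Differential direction is expressed as delta = EDC - VEH
methylation fraction, so hypo-methylation in the exposed condition gives a
negative delta.  Gene-level status uses per-site deltas against an absolute
threshold (10 / 33 / 50 percentage points); targeted amplicon panels are
summarized site by site with a Fisher exact call and a paired Wilcoxon
signed-rank test across the panel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GeneModel

#: minimum per-condition coverage for a site to be analyzable
MIN_COVERAGE = 5
#: reportable-percentage floor: variant frequencies below 0.1% are called 0
PCT_FLOOR = 0.001


@dataclass(frozen=True)
class CpGSite:
    """One CpG with methylated/total read counts in both conditions."""

    chrom: str
    pos: int
    meth_veh: int
    total_veh: int
    meth_edc: int
    total_edc: int

    def __post_init__(self) -> None:
        for meth, total in ((self.meth_veh, self.total_veh), (self.meth_edc, self.total_edc)):
            if meth < 0 or total < 0 or meth > total:
                raise ValueError(
                    f"site {self.chrom}:{self.pos}: need 0 <= meth <= total"
                )

    @property
    def analyzable(self) -> bool:
        return self.total_veh >= MIN_COVERAGE and self.total_edc >= MIN_COVERAGE

    @property
    def pct_veh(self) -> float:
        return meth_pct(self.meth_veh, self.total_veh)

    @property
    def pct_edc(self) -> float:
        return meth_pct(self.meth_edc, self.total_edc)

    @property
    def delta(self) -> float:
        return self.pct_edc - self.pct_veh


@dataclass(frozen=True)
class PanelDef:
    """A targeted bisulfite amplicon panel: gene symbol plus ordered CpG positions."""

    gene: str
    chrom: str
    positions: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.positions:
            raise ValueError(f"panel {self.gene}: empty position list")
        if any(b <= a for a, b in zip(self.positions, self.positions[1:])):
            raise ValueError(f"panel {self.gene}: positions must strictly increase")

    @property
    def size(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class GeneMethStatus:
    """Gene-level promoter methylation call at one delta threshold."""

    gene_id: str
    threshold: float
    status: str  # hypo / hyper / mixed / none
    n_sites: int


def meth_pct(meth: int, total: int, floor: float = PCT_FLOOR) -> float:
    """Methylation fraction meth/total, with frequencies below ``floor`` set to 0."""
    if total <= 0:
        raise ValueError("total must be positive")
    if meth < 0 or meth > total:
        raise ValueError("need 0 <= meth <= total")
    pct = meth / total
    return 0.0 if 0 < pct < floor else pct


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> tuple[float, float]:
    """Fisher's exact test on a 2x2 table of non-negative integers.

    Two-sided p sums the probabilities of all tables with the observed
    margins whose conditional (hypergeometric) probability does not exceed
    the observed one (with a small relative slack for floating-point ties).
    The odds ratio is the sample odds ratio with a Haldane 0.5 correction
    applied when any cell is zero.  A zero margin yields p = 1.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("cells must be non-negative")
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2
    if min(a, b, c, d) == 0:
        oa, ob, oc, od = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        oa, ob, oc, od = float(a), float(b), float(c), float(d)
    odds = (oa * od) / (ob * oc)
    if row1 == 0 or row2 == 0 or col1 == 0 or col1 == n:
        return odds, 1.0
    lo, hi = max(0, col1 - row2), min(col1, row1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, row1, col1)
    p_obs = pmf[a - lo]
    p = float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-7)].sum()))
    return odds, p


def site_differential(site: CpGSite) -> tuple[float, float]:
    """Per-site methylation difference and two-sided Fisher exact p.

    The 2x2 table is meth/unmeth by condition; delta = EDC - VEH fraction
    (negative means hypo-methylation in the exposed condition).
    """
    if not site.analyzable:
        raise ValueError(
            f"site {site.chrom}:{site.pos} below {MIN_COVERAGE}x in one condition"
        )
    _, p = fisher_exact_2x2(
        [
            [site.meth_edc, site.total_edc - site.meth_edc],
            [site.meth_veh, site.total_veh - site.meth_veh],
        ]
    )
    return site.delta, p


def gene_meth_status(gene_id: str, sites: Iterable[CpGSite], threshold: float = 0.33
                     ) -> GeneMethStatus:
    """Promoter methylation status at an absolute delta threshold.

    hypo: at least one analyzable site with delta <= -threshold and none with
    delta >= +threshold; hyper symmetric; mixed when both occur; none
    otherwise (including no analyzable sites).
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    deltas = [s.delta for s in sites if s.analyzable]
    has_hypo = any(d <= -threshold for d in deltas)
    has_hyper = any(d >= threshold for d in deltas)
    if has_hypo and has_hyper:
        status = "mixed"
    elif has_hypo:
        status = "hypo"
    elif has_hyper:
        status = "hyper"
    else:
        status = "none"
    return GeneMethStatus(gene_id, threshold, status, len(deltas))


def wilcoxon_paired(x: Sequence[float], y: Sequence[float],
                    exact_max_n: int = 25) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired observations.

    Zero differences are dropped; ties in |d| receive midranks.  The p-value
    is exact (distribution of the positive-rank sum over all sign patterns)
    for n <= ``exact_max_n``, else a normal approximation with tie
    correction.  All-zero differences give (0, 1).
    """
    if len(x) != len(y):
        raise ValueError("paired vectors must have equal length")
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 0.0, 1.0
    ranks = stats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        p = _wilcoxon_exact_p(ranks, w_pos)
    else:
        mean = n * (n + 1) / 4.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
        z = (w_pos - mean) / math.sqrt(var)
        p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    return w_pos, p


def _wilcoxon_exact_p(ranks: np.ndarray, w_pos: float) -> float:
    """Exact two-sided p by dynamic programming over doubled (integer) ranks.

    Enumerating the 2^n sign patterns is equivalent to convolving the
    distribution of the positive-rank sum one rank at a time; midranks are
    half-integers, so everything is doubled to stay on an integer grid.
    """
    doubled = np.rint(2 * ranks).astype(np.int64)
    total = int(doubled.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = dist + shifted
    dist /= 2.0 ** len(doubled)
    w2 = int(round(2 * w_pos))
    lower = dist[: w2 + 1].sum()
    upper = dist[w2:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


@dataclass
class PanelReport:
    """Site-by-site summary of a targeted panel plus panel-level statistics."""

    gene: str
    table: pd.DataFrame  # per-site: pos, pct_veh, pct_edc, delta, p, call
    n_hypo: int
    n_hyper: int
    panel_size: int
    pct_hypo: float  # 100 * n_hypo / panel_size, 1 decimal
    wilcoxon_w: float
    wilcoxon_p: float
    missing: tuple[int, ...] = ()


def summarize_panel(panel: PanelDef, sites: Iterable[CpGSite],
                    alpha: float = 0.05) -> PanelReport:
    """Per-site percent methylation, hypo/hyper calls, and panel summary.

    A site is called hypo when its Fisher exact p < ``alpha`` and delta < 0
    (hyper symmetric).  Percent-of-panel-hypo uses the full panel size as
    denominator, reported to one decimal.  A paired Wilcoxon signed-rank
    test compares VEH and EDC levels across the covered sites.
    """
    by_pos = {s.pos: s for s in sites if s.chrom == panel.chrom}
    rows = []
    missing = []
    for pos in panel.positions:
        site = by_pos.get(pos)
        if site is None or not site.analyzable:
            missing.append(pos)
            continue
        delta, p = site_differential(site)
        if p < alpha and delta < 0:
            call = "hypo"
        elif p < alpha and delta > 0:
            call = "hyper"
        else:
            call = "ns"
        rows.append(
            {
                "pos": pos,
                "pct_veh": site.pct_veh,
                "pct_edc": site.pct_edc,
                "delta": delta,
                "p": p,
                "call": call,
            }
        )
    table = pd.DataFrame(rows, columns=["pos", "pct_veh", "pct_edc", "delta", "p", "call"])
    n_hypo = int((table["call"] == "hypo").sum()) if len(table) else 0
    n_hyper = int((table["call"] == "hyper").sum()) if len(table) else 0
    pct_hypo = round(100.0 * n_hypo / panel.size, 1)
    if len(table):
        w, wp = wilcoxon_paired(table["pct_edc"].tolist(), table["pct_veh"].tolist())
    else:
        w, wp = 0.0, 1.0
    return PanelReport(
        gene=panel.gene,
        table=table,
        n_hypo=n_hypo,
        n_hyper=n_hyper,
        panel_size=panel.size,
        pct_hypo=pct_hypo,
        wilcoxon_w=w,
        wilcoxon_p=wp,
        missing=tuple(missing),
    )


def assign_sites_to_promoters(sites: Iterable[CpGSite], genes: Iterable[GeneModel],
                              flank: int = 1000) -> dict[str, list[CpGSite]]:
    """Group CpG sites by the gene whose TSS ± flank contains them."""
    sites = list(sites)
    out: dict[str, list[CpGSite]] = {}
    for gene in genes:
        lo, hi = gene.tss - flank, gene.tss + flank
        hits = [s for s in sites if s.chrom == gene.chrom and lo <= s.pos < hi]
        if hits:
            out[gene.gene_id] = hits
    return out


CPG_COLUMNS = ["chrom", "pos", "meth_veh", "total_veh", "meth_edc", "total_edc"]


def read_cpg_table(path: str | Path) -> list[CpGSite]:
    df = pd.read_csv(path, sep="\t")
    missing = set(CPG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"CpG table missing columns: {sorted(missing)}")
    return [
        CpGSite(row.chrom, int(row.pos), int(row.meth_veh), int(row.total_veh),
                int(row.meth_edc), int(row.total_edc))
        for row in df.itertuples(index=False)
    ]


def write_cpg_table(sites: Iterable[CpGSite], path: str | Path) -> None:
    rows = [
        (s.chrom, s.pos, s.meth_veh, s.total_veh, s.meth_edc, s.total_edc)
        for s in sites
    ]
    pd.DataFrame(rows, columns=CPG_COLUMNS).to_csv(path, sep="\t", index=False)


def read_panels(path: str | Path) -> dict[str, PanelDef]:
    """Read panel site definitions (columns: gene, chrom, pos) into PanelDefs."""
    df = pd.read_csv(path, sep="\t")
    missing = {"gene", "chrom", "pos"} - set(df.columns)
    if missing:
        raise ValueError(f"panel table missing columns: {sorted(missing)}")
    panels: dict[str, PanelDef] = {}
    for gene, grp in df.groupby("gene", sort=False):
        chroms = grp["chrom"].unique()
        if len(chroms) != 1:
            raise ValueError(f"panel {gene}: sites on multiple chromosomes")
        positions = tuple(sorted(int(p) for p in grp["pos"]))
        panels[str(gene)] = PanelDef(str(gene), str(chroms[0]), positions)
    return panels
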