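"""Sliding-window differential H3K4me3 enrichment, region merging, and gene
assignment.

Windows tiling the genome are tested with a 2x2 G-test (log-likelihood ratio
chi-square) on read counts versus total mapped reads per condition, fold
changes are computed on reads-per-million with a half-read pseudocount, and
windows passing both the fold-change (>=1.5x) and FDR (q < 0.01) cuts are
merged into differential regions by direction.  Regions within 3 kb of a TSS
annotate the gene; gene-level mark status uses the gene body plus a 10-kb
flank.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from scipy import special, stats

from .genome import GeneModel, GenomeSpec, Region, distance_to_tss, gene_window

#: pseudocount in reads applied to each condition before rpm fold change
FC_PSEUDOCOUNT = 0.5


@dataclass
class WindowTrack:
    """Fixed-width genome bins with integer read counts for VEH and EDC.

    Bins tile each chromosome left to right; the last bin may be clipped by
    the chromosome end.  ``total_veh`` / ``total_edc`` are total mapped reads
    used for rpm normalization (defaults: the track sums).
    """

    genome: GenomeSpec
    window_size: int
    veh: dict[str, np.ndarray]
    edc: dict[str, np.ndarray]
    total_veh: float | None = None
    total_edc: float | None = None

    def __post_init__(self) -> None:
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")
        for chrom in self.genome.chrom_names:
            n_expect = -(-self.genome.length(chrom) // self.window_size)
            for name, track in (("veh", self.veh), ("edc", self.edc)):
                if chrom not in track:
                    raise ValueError(f"{name} track missing chromosome {chrom}")
                if len(track[chrom]) != n_expect:
                    raise ValueError(
                        f"{name}:{chrom} has {len(track[chrom])} windows, "
                        f"expected {n_expect}"
                    )
                if (track[chrom] < 0).any():
                    raise ValueError("window counts must be non-negative")
        if self.total_veh is None:
            self.total_veh = float(sum(v.sum() for v in self.veh.values()))
        if self.total_edc is None:
            self.total_edc = float(sum(v.sum() for v in self.edc.values()))

    def window_region(self, chrom: str, index: int) -> Region:
        start = index * self.window_size
        end = min(start + self.window_size, self.genome.length(chrom))
        return Region(chrom, start, end)

    def n_windows(self, chrom: str) -> int:
        return len(self.veh[chrom])


@dataclass(frozen=True)
class DiffRegion:
    """A merged differential interval with direction, fold change and q-value."""

    region: Region
    direction: str  # "enriched" or "reduced", EDC vs VEH
    fold_change: float  # rpm ratio EDC/VEH, pseudocounted; extremal over windows
    g_stat: float
    p: float
    q: float

    def __post_init__(self) -> None:
        if self.direction not in {"enriched", "reduced"}:
            raise ValueError(f"bad direction {self.direction!r}")


@dataclass(frozen=True)
class GeneMarkStatus:
    """Gene-level H3K4me3 call from differential regions near/within the gene."""

    gene_id: str
    status: str  # enriched / reduced / both / none
    region_ids: tuple[int, ...] = field(default_factory=tuple)


def gtest_2x2(a: int, b: int, na: float, nb: float) -> tuple[float, float]:
    """Likelihood-ratio G-test on the 2x2 table [[a, Na-a], [b, Nb-b]].

    G = 2 * sum O*ln(O/E) with expecteds from the margins; zero cells
    contribute nothing.  p is the chi-square (1 df) upper tail.  An empty
    observation (a + b = 0) returns (0, 1) by convention.
    """
    if na <= 0 or nb <= 0:
        raise ValueError("totals must be positive")
    if a < 0 or b < 0 or a > na or b > nb:
        raise ValueError("counts must satisfy 0 <= a <= Na, 0 <= b <= Nb")
    if a + b == 0:
        return 0.0, 1.0
    obs = np.array([[a, na - a], [b, nb - b]], dtype=float)
    total = obs.sum()
    expect = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
    g = 2.0 * special.xlogy(obs, np.divide(
        obs, expect, out=np.ones_like(obs), where=obs > 0
    )).sum()
    g = max(0.0, float(g))
    return g, float(stats.chi2.sf(g, df=1))


def _gtest_vectorized(a: np.ndarray, b: np.ndarray, na: float, nb: float
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized G-test over many windows sharing the same margins Na, Nb."""
    cells = np.stack([a, na - a, b, nb - b], axis=1).astype(float)
    row = np.stack([a + b, (na - a) + (nb - b)], axis=1)
    col = np.array([na, nb], dtype=float)
    total = na + nb
    expect = np.stack(
        [
            row[:, 0] * col[0] / total,
            row[:, 1] * col[0] / total,
            row[:, 0] * col[1] / total,
            row[:, 1] * col[1] / total,
        ],
        axis=1,
    )
    ratio = np.divide(cells, expect, out=np.ones_like(cells), where=cells > 0)
    g = 2.0 * special.xlogy(cells, ratio).sum(axis=1)
    g = np.maximum(g, 0.0)
    return g, stats.chi2.sf(g, df=1)


def scan_windows(track: WindowTrack, fc_cut: float = 1.5, fdr_cut: float = 0.01
                 ) -> list[DiffRegion]:
    """Scan all windows, BH-adjust, and merge significant windows into regions.

    Only windows with at least one read in either condition enter the test
    and the FDR adjustment.  A window is significant when q < ``fdr_cut`` and
    its pseudocounted rpm fold change is >= ``fc_cut`` in one direction;
    adjacent or overlapping significant windows of the same direction merge,
    keeping the extremal fold change and the minimal q.
    """
    from .diffexpr import bh_adjust

    if fc_cut < 1:
        raise ValueError("fc_cut must be >= 1")
    na, nb = float(track.total_edc), float(track.total_veh)
    if na <= 0 or nb <= 0:
        return []

    chroms, idxs, a_all, b_all = [], [], [], []
    for chrom in track.genome.chrom_names:
        edc = track.edc[chrom]
        veh = track.veh[chrom]
        testable = (edc + veh) > 0
        where = np.nonzero(testable)[0]
        chroms.extend([chrom] * len(where))
        idxs.append(where)
        a_all.append(edc[where])
        b_all.append(veh[where])
    if not chroms:
        return []
    idx = np.concatenate(idxs)
    a = np.concatenate(a_all).astype(np.int64)
    b = np.concatenate(b_all).astype(np.int64)

    g, p = _gtest_vectorized(a, b, na, nb)
    q = bh_adjust(p)
    # rpm fold change EDC/VEH with half-read pseudocount
    fc = ((a + FC_PSEUDOCOUNT) / na) / ((b + FC_PSEUDOCOUNT) / nb)
    sig = (q < fdr_cut) & ((fc >= fc_cut) | (fc <= 1.0 / fc_cut))

    regions: list[DiffRegion] = []
    order = np.lexsort((idx, np.array([track.genome.chrom_names.index(c) for c in chroms])))
    current: dict | None = None
    for j in order:
        if not sig[j]:
            continue
        chrom = chroms[j]
        w = track.window_region(chrom, int(idx[j]))
        direction = "enriched" if fc[j] >= fc_cut else "reduced"
        joined = (
            current is not None
            and current["chrom"] == chrom
            and current["direction"] == direction
            and w.start <= current["end"]  # adjacent or overlapping
        )
        if joined:
            current["end"] = max(current["end"], w.end)
            if direction == "enriched":
                current["fc"] = max(current["fc"], float(fc[j]))
            else:
                current["fc"] = min(current["fc"], float(fc[j]))
            if q[j] < current["q"]:
                current["q"], current["p"], current["g"] = float(q[j]), float(p[j]), float(g[j])
        else:
            if current is not None:
                regions.append(_close_region(current))
            current = {
                "chrom": chrom, "start": w.start, "end": w.end,
                "direction": direction, "fc": float(fc[j]),
                "g": float(g[j]), "p": float(p[j]), "q": float(q[j]),
            }
    if current is not None:
        regions.append(_close_region(current))
    return regions


def _close_region(acc: dict) -> DiffRegion:
    return DiffRegion(
        Region(acc["chrom"], acc["start"], acc["end"]),
        acc["direction"], acc["fc"], acc["g"], acc["p"], acc["q"],
    )


def annotate_tss(regions: Iterable[DiffRegion], genes: Iterable[GeneModel],
                 max_dist: int = 3000) -> dict[str, list[DiffRegion]]:
    """Map gene_id to the differential regions within ``max_dist`` of its TSS."""
    regions = list(regions)
    out: dict[str, list[DiffRegion]] = {}
    for gene in genes:
        hits = [r for r in regions if distance_to_tss(r.region, gene) <= max_dist]
        if hits:
            out[gene.gene_id] = hits
    return out


def gene_mark_status(gene: GeneModel, regions: Iterable[DiffRegion],
                     flank: int = 10000, genome: GenomeSpec | None = None
                     ) -> GeneMarkStatus:
    """Mark status from significant regions overlapping gene body ± flank."""
    window = gene_window(gene, flank, genome)
    directions: set[str] = set()
    hit_ids: list[int] = []
    for i, reg in enumerate(regions):
        if window.overlaps(reg.region):
            directions.add(reg.direction)
            hit_ids.append(i)
    if directions == {"enriched", "reduced"}:
        status = "both"
    elif directions:
        status = directions.pop()
    else:
        status = "none"
    return GeneMarkStatus(gene.gene_id, status, tuple(hit_ids))


def write_regions_bed(regions: Iterable[DiffRegion], path: str | Path) -> None:
    """Write regions as BED6+ with fold_change, G, p, q extra columns.

    Score is -10*log10(q) capped at 1000, rounded to an integer.
    """
    with open(path, "w") as handle:
        for reg in regions:
            score = 1000 if reg.q <= 0 else min(1000, int(round(-10 * np.log10(reg.q))))
            handle.write(
                f"{reg.region.chrom}\t{reg.region.start}\t{reg.region.end}\t"
                f"{reg.direction}\t{score}\t.\t{reg.fold_change:.6g}\t"
                f"{reg.g_stat:.6g}\t{reg.p:.6g}\t{reg.q:.6g}\n"
            )


def read_bedgraph(path: str | Path, genome: GenomeSpec, window_size: int
                  ) -> dict[str, np.ndarray]:
    """Read a fixed-width-bin bedGraph into per-chromosome count arrays."""
    counts = {
        chrom: np.zeros(-(-genome.length(chrom) // window_size), dtype=np.int64)
        for chrom in genome.chrom_names
    }
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track")):
                continue
            chrom, start_s, end_s, value_s = line.split()[:4]
            start = int(start_s)
            if start % window_size != 0:
                raise ValueError(
                    f"line {lineno}: bin start {start} not aligned to {window_size}"
                )
            counts[chrom][start // window_size] = int(round(float(value_s)))
    return counts


def write_bedgraph(track: Mapping[str, np.ndarray], genome: GenomeSpec,
                   window_size: int, path: str | Path) -> None:
    """Write per-window counts as bedGraph; zero windows are omitted."""
    with open(path, "w") as handle:
        for chrom in genome.chrom_names:
            values = track[chrom]
            for i in np.nonzero(values)[0]:
                start = int(i) * window_size
                end = min(start + window_size, genome.length(chrom))
                handle.write(f"{chrom}\t{start}\t{end}\t{int(values[i])}\n")
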