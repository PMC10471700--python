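"""Differential gene expression on read counts for a two-condition contrast.

The design this pipeline serves contrasts a single pooled library per
condition (EDC-exposed vs vehicle), so the default test is an exact
conditional binomial test: conditioned on the total count of a gene across
the two libraries, the EDC count is Binomial(total, N_EDC/(N_EDC+N_VEH))
under the null of equal relative abundance.  When replicates are available a
per-gene negative-binomial likelihood-ratio test at fixed dispersion is used
instead.  Fold-change and FDR cutoffs default to twofold and q < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

VEH = "VEH"
EDC = "EDC"

#: pseudocount (reads) added to both conditions before fold-change estimation
PSEUDOCOUNT = 0.5


@dataclass
class CountMatrix:
    """Integer gene-by-sample counts with a condition label per sample."""

    counts: pd.DataFrame  # index: gene_id, columns: sample names
    conditions: list[str]  # parallel to columns, each VEH or EDC

    def __post_init__(self) -> None:
        if len(self.conditions) != self.counts.shape[1]:
            raise ValueError("one condition label per sample column required")
        bad = set(self.conditions) - {VEH, EDC}
        if bad:
            raise ValueError(f"unknown condition labels: {sorted(bad)}")
        if VEH not in self.conditions or EDC not in self.conditions:
            raise ValueError("need at least one sample per condition")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        self.counts = self.counts.rename_axis("gene_id")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    def library_sizes(self) -> np.ndarray:
        return self.counts.to_numpy().sum(axis=0).astype(float)

    def condition_columns(self, condition: str) -> list[str]:
        return [c for c, k in zip(self.counts.columns, self.conditions) if k == condition]

    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.columns = [f"{cond}:{name}" for name, cond in zip(out.columns, self.conditions)]
        out.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col="gene_id")
        conditions, names = [], []
        for col in df.columns:
            cond, _, name = col.partition(":")
            conditions.append(cond)
            names.append(name or col)
        df.columns = names
        return cls(df, conditions)


def filter_detected(counts: CountMatrix, min_total: int = 10) -> CountMatrix:
    """Keep genes whose summed count across all samples is at least ``min_total``."""
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    keep = counts.counts.sum(axis=1) >= min_total
    return CountMatrix(counts.counts.loc[keep], list(counts.conditions))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, order-preserving with the input."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _binom_exact_two_sided(a: int, t: int, p0: float) -> float:
    """Two-sided exact binomial p: sum of outcome probabilities <= P(observed)."""
    if t == 0:
        return 1.0
    k = np.arange(t + 1)
    pmf = stats.binom.pmf(k, t, p0)
    # relative slack guards against ties lost to floating point
    return float(min(1.0, pmf[pmf <= pmf[a] * (1 + 1e-7)].sum()))


def _nb_loglik(counts: np.ndarray, mu: np.ndarray, phi: float) -> float:
    """Negative-binomial log-likelihood with Var = mu + phi*mu^2."""
    if phi <= 0:
        return float(stats.poisson.logpmf(counts, mu).sum())
    r = 1.0 / phi
    return float(
        (
            special.gammaln(counts + r)
            - special.gammaln(r)
            - special.gammaln(counts + 1)
            + r * np.log(r / (r + mu))
            + counts * np.log(mu / (r + mu))
        ).sum()
    )


def _nb_mle_rate(counts: np.ndarray, libsizes: np.ndarray, phi: float) -> float:
    """MLE of a common per-read rate for NB counts with library-size offsets."""
    total = counts.sum()
    if total == 0:
        return 0.0
    rate0 = total / libsizes.sum()  # Poisson MLE; exact when libsizes equal
    if phi <= 0 or np.allclose(libsizes, libsizes[0]):
        return rate0

    def negll(log_rate: float) -> float:
        return -_nb_loglik(counts, np.exp(log_rate) * libsizes, phi)

    res = optimize.minimize_scalar(
        negll, bracket=(np.log(rate0) - 1.0, np.log(rate0) + 1.0), method="brent",
        options={"xtol": 1e-10},
    )
    return float(np.exp(res.x))


def de_test(counts: CountMatrix, dispersion: float = 0.01) -> pd.DataFrame:
    """Per-gene differential test, EDC vs VEH.

    Returns a DataFrame indexed by gene_id with columns log2fc, p, q,
    direction (direction is 'ns' until :func:`call_de` is applied).

    With one sample per condition, an exact conditional binomial test; with
    replicates, a likelihood-ratio test of a shared versus per-condition
    negative-binomial mean at the given fixed dispersion (chi-square, 1 df).
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    veh_cols = counts.condition_columns(VEH)
    edc_cols = counts.condition_columns(EDC)
    mat = counts.counts
    lib = mat.sum(axis=0).astype(float)
    if (lib <= 0).any():
        raise ValueError("all library sizes must be positive")
    n_veh = float(lib[veh_cols].sum())
    n_edc = float(lib[edc_cols].sum())
    a = mat[edc_cols].sum(axis=1).to_numpy(dtype=np.int64)  # EDC totals
    b = mat[veh_cols].sum(axis=1).to_numpy(dtype=np.int64)  # VEH totals

    log2fc = np.log2((a + PSEUDOCOUNT) / n_edc) - np.log2((b + PSEUDOCOUNT) / n_veh)

    unreplicated = len(veh_cols) == 1 and len(edc_cols) == 1
    if unreplicated:
        p0 = n_edc / (n_edc + n_veh)
        totals = a + b
        pvals = np.ones(len(mat))
        for i, (ai, ti) in enumerate(zip(a, totals)):
            if ti > 0:
                pvals[i] = _binom_exact_two_sided(int(ai), int(ti), p0)
    else:
        lib_v = lib[veh_cols].to_numpy()
        lib_e = lib[edc_cols].to_numpy()
        lib_all = np.concatenate([lib_v, lib_e])
        cv = mat[veh_cols].to_numpy(dtype=np.int64)
        ce = mat[edc_cols].to_numpy(dtype=np.int64)
        pvals = np.ones(len(mat))
        for i in range(len(mat)):
            row_v, row_e = cv[i], ce[i]
            row_all = np.concatenate([row_v, row_e])
            rate0 = _nb_mle_rate(row_all, lib_all, dispersion)
            rate_v = _nb_mle_rate(row_v, lib_v, dispersion)
            rate_e = _nb_mle_rate(row_e, lib_e, dispersion)
            ll0 = _nb_loglik(row_all, np.maximum(rate0 * lib_all, 1e-300), dispersion)
            ll1 = _nb_loglik(row_v, np.maximum(rate_v * lib_v, 1e-300), dispersion) + \
                _nb_loglik(row_e, np.maximum(rate_e * lib_e, 1e-300), dispersion)
            lrt = max(0.0, 2.0 * (ll1 - ll0))
            pvals[i] = float(stats.chi2.sf(lrt, df=1))

    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "p": pvals,
            "q": bh_adjust(pvals),
            "direction": "ns",
        },
        index=mat.index,
    )


def call_de(results: pd.DataFrame, fc_cut: float = 2.0, fdr_cut: float = 0.05) -> pd.DataFrame:
    """Label each gene up / down / ns at a fold-change and FDR cutoff.

    ``up`` requires log2fc >= log2(fc_cut) and q < fdr_cut; ``down`` is
    symmetric; everything else is ``ns``.
    """
    if fc_cut < 1:
        raise ValueError("fc_cut must be >= 1")
    out = results.copy()
    lfc_cut = np.log2(fc_cut)
    sig = out["q"] < fdr_cut
    out["direction"] = "ns"
    out.loc[sig & (out["log2fc"] >= lfc_cut), "direction"] = "up"
    out.loc[sig & (out["log2fc"] <= -lfc_cut), "direction"] = "down"
    return out


def write_de_table(results: pd.DataFrame, path: str | Path) -> None:
    out = results.copy()
    out["log2fc"] = out["log2fc"].map(lambda v: f"{v:.6g}")
    out["p"] = out["p"].map(lambda v: f"{v:.6g}")
    out["q"] = out["q"].map(lambda v: f"{v:.6g}")
    out.to_csv(path, sep="\t", index_label="gene_id")


def read_de_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")
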