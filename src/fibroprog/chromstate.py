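"""Single-mark chromatin-state segmentation and per-state enrichment.

The mark signal is first binarized per bin against a genome-wide Poisson
background (the standard first step of emission-based segmentation), then a
hidden Markov model with Bernoulli emissions is fitted by Baum–Welch with
seeded random restarts.  States are relabeled in decreasing order of their
emission probability so that state 1 is always the most signal-rich, and are
annotated from that ranking.  Differential regions are scored per state with
a Haldane-corrected odds ratio against the cumulative genomic size of the
state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .diffchip import DiffRegion, WindowTrack
from .genome import GenomeSpec

logger = logging.getLogger(__name__)


@dataclass
class BinaryTrack:
    """Per-bin 0/1 mark presence tiling the genome."""

    genome: GenomeSpec
    bin_size: int
    bins: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        for chrom in self.genome.chrom_names:
            if chrom not in self.bins:
                raise ValueError(f"binary track missing chromosome {chrom}")
            arr = np.asarray(self.bins[chrom])
            if not np.isin(arr, (0, 1)).all():
                raise ValueError("binary track values must be 0 or 1")
            self.bins[chrom] = arr.astype(np.int8)

    def sequences(self) -> list[np.ndarray]:
        return [self.bins[c] for c in self.genome.chrom_names]

    @property
    def n_bins(self) -> int:
        return sum(len(v) for v in self.bins.values())


@dataclass
class HMMModel:
    """Bernoulli-emission HMM: initial distribution, transitions, P(signal=1)."""

    pi: np.ndarray  # (S,)
    transitions: np.ndarray  # (S, S), rows sum to 1
    emissions: np.ndarray  # (S,), probability of emitting 1
    log_likelihood: float = float("nan")

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.transitions = np.asarray(self.transitions, dtype=float)
        self.emissions = np.asarray(self.emissions, dtype=float)
        if not np.allclose(self.transitions.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition rows must sum to 1")
        if not np.isclose(self.pi.sum(), 1.0, atol=1e-9):
            raise ValueError("initial distribution must sum to 1")
        if ((self.emissions < 0) | (self.emissions > 1)).any():
            raise ValueError("emission probabilities must lie in [0, 1]")

    @property
    def n_states(self) -> int:
        return len(self.pi)


@dataclass(frozen=True)
class StateEnrichment:
    """Odds-ratio enrichment of differential regions within one state."""

    state: int
    label: str
    genome_bp: int
    diff_bp: int
    odds_ratio: float
    defined: bool = True  # False when no differential bp exists at all


def poisson_threshold(lam: float, p_cut: float = 1e-4) -> int:
    """Smallest count c with Poisson upper tail P(X >= c; lam) < p_cut."""
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if lam == 0:
        return 1
    # P(X >= c) = sf(c - 1); start near the bulk and walk up
    c = max(1, int(lam))
    while stats.poisson.sf(c - 1, lam) >= p_cut:
        c += 1
    while c > 1 and stats.poisson.sf(c - 2, lam) < p_cut:
        c -= 1
    return c


def binarize(track: WindowTrack, condition: str = "edc", p_cut: float = 1e-4
             ) -> BinaryTrack:
    """Binarize one condition of a window track against a Poisson background.

    The background rate is the genome-wide mean count per bin; a bin scores 1
    when its count is extreme enough that the Poisson upper tail falls below
    ``p_cut``.
    """
    counts = {"veh": track.veh, "edc": track.edc}[condition]
    total = sum(float(v.sum()) for v in counts.values())
    n_bins = sum(len(v) for v in counts.values())
    lam = total / n_bins
    if total == 0:
        logger.warning("binarize: all-zero track; returning all-zero bins")
        bins = {c: np.zeros(len(v), dtype=np.int8) for c, v in counts.items()}
        return BinaryTrack(track.genome, track.window_size, bins)
    c_min = poisson_threshold(lam, p_cut)
    bins = {c: (v >= c_min).astype(np.int8) for c, v in counts.items()}
    return BinaryTrack(track.genome, track.window_size, bins)


def _forward_backward(seq: np.ndarray, pi: np.ndarray, a: np.ndarray,
                      e: np.ndarray):
    """Scaled forward-backward pass for one 0/1 sequence.

    Returns (loglik, gamma (T,S), xi_sum (S,S), emission-weighted counts).
    Scaling by the per-step normalizer is algebraically equivalent to
    log-space recursion and keeps the pass O(T S^2).
    """
    t_len = len(seq)
    s = len(pi)
    b = np.where(seq[:, None] == 1, e[None, :], 1.0 - e[None, :])
    alpha = np.empty((t_len, s))
    scale = np.empty(t_len)
    cur = pi * b[0]
    scale[0] = cur.sum()
    alpha[0] = cur / scale[0]
    for t in range(1, t_len):
        cur = (alpha[t - 1] @ a) * b[t]
        z = cur.sum()
        scale[t] = z
        alpha[t] = cur / z
    beta = np.empty((t_len, s))
    beta[-1] = 1.0
    at = a  # row-stochastic
    for t in range(t_len - 2, -1, -1):
        beta[t] = (at @ (b[t + 1] * beta[t + 1])) / scale[t + 1]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    weighted = (b[1:] * beta[1:]) / scale[1:, None]
    xi_sum = a * (alpha[:-1].T @ weighted)
    loglik = float(np.log(scale).sum())
    return loglik, gamma, xi_sum


def _em_step(seqs: Sequence[np.ndarray], pi, a, e):
    s = len(pi)
    ll = 0.0
    pi_acc = np.zeros(s)
    xi_acc = np.zeros((s, s))
    gamma_acc = np.zeros(s)
    gamma_tail = np.zeros(s)  # gamma summed over t < T-1 (transition denominators)
    ones_acc = np.zeros(s)
    for seq in seqs:
        llk, gamma, xi = _forward_backward(seq, pi, a, e)
        ll += llk
        pi_acc += gamma[0]
        xi_acc += xi
        gamma_acc += gamma.sum(axis=0)
        gamma_tail += gamma[:-1].sum(axis=0)
        ones_acc += gamma[seq == 1].sum(axis=0)
    new_pi = pi_acc / pi_acc.sum()
    new_a = xi_acc / np.maximum(gamma_tail[:, None], 1e-300)
    new_a /= new_a.sum(axis=1, keepdims=True)
    new_e = np.clip(ones_acc / np.maximum(gamma_acc, 1e-300), 1e-6, 1 - 1e-6)
    return ll, new_pi, new_a, new_e


def fit_hmm(binary: BinaryTrack, n_states: int, seed: int = 0,
            n_restarts: int = 5, tol: float = 1e-6, max_iter: int = 500
            ) -> HMMModel:
    """Fit a Bernoulli-emission HMM by Baum–Welch with seeded random restarts.

    The best model over restarts (by log-likelihood) is returned, with states
    relabeled in decreasing emission-probability order.  ``n_states=1`` has
    the closed form: emission = empirical frequency of 1s.
    """
    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    seqs = [np.asarray(s, dtype=np.int8) for s in binary.sequences() if len(s) > 0]
    n_bins = sum(len(s) for s in seqs)
    if n_states > n_bins:
        raise ValueError(f"n_states={n_states} exceeds number of bins {n_bins}")
    if n_states == 1:
        freq = sum(int(s.sum()) for s in seqs) / n_bins
        e = np.clip(np.array([freq]), 1e-6, 1 - 1e-6)
        ll = float(n_bins * (freq * np.log(e[0]) + (1 - freq) * np.log(1 - e[0])))
        return HMMModel(np.array([1.0]), np.array([[1.0]]), e, ll)

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x6D6D]))
    best: HMMModel | None = None
    for _ in range(n_restarts):
        pi = rng.dirichlet(np.ones(n_states))
        a = rng.dirichlet(np.ones(n_states) * 5.0, size=n_states)
        a = 0.5 * a + 0.5 * np.eye(n_states)  # bias toward persistence
        a /= a.sum(axis=1, keepdims=True)
        e = np.sort(rng.uniform(0.02, 0.98, size=n_states))[::-1]
        prev_ll = -np.inf
        for _iter in range(max_iter):
            ll, pi, a, e = _em_step(seqs, pi, a, e)
            if ll - prev_ll < tol and _iter > 0:
                break
            prev_ll = ll
        if best is None or ll > best.log_likelihood:
            best = _relabel(HMMModel(pi, a, e, ll))
    assert best is not None
    return best


def _relabel(model: HMMModel) -> HMMModel:
    """Relabel states in decreasing emission-probability order."""
    order = np.argsort(-model.emissions, kind="mergesort")
    return HMMModel(
        model.pi[order],
        model.transitions[np.ix_(order, order)],
        model.emissions[order],
        model.log_likelihood,
    )


def log_likelihood(model: HMMModel, binary: BinaryTrack) -> float:
    """Total data log-likelihood under the model (forward algorithm)."""
    total = 0.0
    for seq in binary.sequences():
        if len(seq) == 0:
            continue
        ll, _, _ = _forward_backward(seq, model.pi, model.transitions, model.emissions)
        total += ll
    return total


def decode(model: HMMModel, binary: BinaryTrack) -> dict[str, np.ndarray]:
    """Viterbi state path per chromosome; ties resolve to the lowest state index."""
    out: dict[str, np.ndarray] = {}
    log_pi = np.log(np.maximum(model.pi, 1e-300))
    log_a = np.log(np.maximum(model.transitions, 1e-300))
    e = model.emissions
    for chrom in binary.genome.chrom_names:
        seq = binary.bins[chrom]
        t_len = len(seq)
        if t_len == 0:
            out[chrom] = np.zeros(0, dtype=np.int32)
            continue
        log_b = np.where(
            seq[:, None] == 1,
            np.log(np.maximum(e, 1e-300))[None, :],
            np.log(np.maximum(1 - e, 1e-300))[None, :],
        )
        s = model.n_states
        delta = log_pi + log_b[0]
        back = np.zeros((t_len, s), dtype=np.int32)
        for t in range(1, t_len):
            cand = delta[:, None] + log_a
            # argmax over predecessors; np.argmax returns the lowest index on ties
            back[t] = np.argmax(cand, axis=0)
            delta = cand[back[t], np.arange(s)] + log_b[t]
        path = np.empty(t_len, dtype=np.int32)
        path[-1] = int(np.argmax(delta))
        for t in range(t_len - 2, -1, -1):
            path[t] = back[t + 1][path[t + 1]]
        out[chrom] = path
    return out


def state_labels(n_states: int) -> list[str]:
    """Annotation labels by emission rank, strongest signal first."""
    if n_states == 1:
        return ["uniform"]
    labels = ["active-high"]
    labels += [f"intermediate-{i}" for i in range(1, n_states - 1)]
    labels.append("quiescent")
    return labels


def state_enrichment(path: dict[str, np.ndarray], diff_regions: Iterable[DiffRegion],
                     genome: GenomeSpec, bin_size: int, n_states: int
                     ) -> list[StateEnrichment]:
    """Per-state odds ratio of differential bp versus state genomic size.

    For each state: a = differential bp inside, b = differential bp in other
    states, c = non-differential bp inside, d = elsewhere; OR = (a d)/(b c)
    with a 0.5-bp Haldane correction on zero cells.  With no differential bp
    at all, odds ratios are reported as 0 and flagged undefined.
    """
    labels = state_labels(n_states)
    state_bp = np.zeros(n_states, dtype=np.int64)
    for chrom in genome.chrom_names:
        p = path[chrom]
        clen = genome.length(chrom)
        for i, s in enumerate(p):
            start = i * bin_size
            state_bp[s] += min(bin_size, clen - start)
    diff_bp = np.zeros(n_states, dtype=np.int64)
    for reg in diff_regions:
        chrom = reg.region.chrom
        p = path[chrom]
        first = reg.region.start // bin_size
        last = (reg.region.end - 1) // bin_size
        for i in range(first, last + 1):
            bin_start = i * bin_size
            bin_end = min(bin_start + bin_size, genome.length(chrom))
            ov = min(reg.region.end, bin_end) - max(reg.region.start, bin_start)
            if ov > 0:
                diff_bp[p[i]] += ov
    total_diff = int(diff_bp.sum())
    total_bp = int(state_bp.sum())
    out = []
    for s in range(n_states):
        if total_diff == 0:
            out.append(StateEnrichment(s, labels[s], int(state_bp[s]), 0, 0.0, False))
            continue
        a = float(diff_bp[s])
        b = float(total_diff - diff_bp[s])
        c = float(state_bp[s] - diff_bp[s])
        d = float((total_bp - total_diff) - c)
        if min(a, b, c, d) == 0:
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        out.append(
            StateEnrichment(s, labels[s], int(state_bp[s]), int(diff_bp[s]),
                            (a * d) / (b * c), True)
        )
    return out


def write_states_bed(path_by_chrom: dict[str, np.ndarray], genome: GenomeSpec,
                     bin_size: int, n_states: int, path: str | Path) -> None:
    """Write the decoded segmentation as BED4, merging runs of one state."""
    labels = state_labels(n_states)
    with open(path, "w") as handle:
        for chrom in genome.chrom_names:
            p = path_by_chrom[chrom]
            if len(p) == 0:
                continue
            run_start = 0
            for i in range(1, len(p) + 1):
                if i == len(p) or p[i] != p[run_start]:
                    start = run_start * bin_size
                    end = min(i * bin_size, genome.length(chrom))
                    handle.write(f"{chrom}\t{start}\t{end}\t{labels[p[run_start]]}\n")
                    run_start = i


def write_model_tsv(model: HMMModel, path: str | Path) -> None:
    """Write emissions and transitions as one TSV."""
    with open(path, "w") as handle:
        handle.write("state\tlabel\tinitial\temission\t" +
                     "\t".join(f"to_state_{j + 1}" for j in range(model.n_states)) + "\n")
        labels = state_labels(model.n_states)
        for i in range(model.n_states):
            row = "\t".join(f"{model.transitions[i, j]:.6g}" for j in range(model.n_states))
            handle.write(
                f"{i + 1}\t{labels[i]}\t{model.pi[i]:.6g}\t{model.emissions[i]:.6g}\t{row}\n"
            )
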