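"""Hidden-Markov LOD scan contrasting pooled allele frequencies.

The statistic follows the Multipool idea: along each contig, model the
(unobserved) designated-founder frequency in the segregant population,
discretized to j/N, as a Markov chain whose transitions encode
recombination; the emission marginalizes the binomial sampling of the
finite pool (N haplotypes) from that frequency followed by binomial read
sampling, so finite-pool composition noise is part of the measurement
model rather than signal.  For each genomic bin x the LOD is the
log10 ratio between (i) the two pools evolving independently and (ii) a
tied model in which a single state is drawn at x from the stationary prior
and shared by both pools, the dynamics being otherwise independent:

    LOD(x) = log10 L_high + log10 L_low - log10 L_tied(x)
           = -log10( sum_j gamma_high,x(j) * gamma_low,x(j) / pi(j) )

where gamma are the smoothed state posteriors from forward-backward and
pi the prior.  This is an independent re-implementation of the published
tool's model class, not a bit-level clone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .synthcross import haldane_switch_prob

LOD_CAP = 1_000.0  # file-output stand-in for the +infinity sentinel


@dataclass
class LodModelParams:
    """Model settings: pool haplotype count, bin width, recombination, error.

    ``N`` is the number of haplotypes per pool (20 strains each contributing
    one haplotype per sub-genome).  ``prior`` defaults to Binomial(N, 0.5),
    the stationary distribution of the transition kernel: pools of random
    segregants are unbiased a priori.
    """

    N: int = 20
    res_bp: int = 100
    bp_per_cM: float = 2_500.0
    eps: float = 0.002
    prior: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.res_bp < 1:
            raise ValueError("res_bp must be >= 1")
        if not (0 <= self.eps < 0.5):
            raise ValueError("eps must be in [0, 0.5)")
        if self.prior is None:
            self.prior = stats.binom.pmf(np.arange(self.N + 1), self.N, 0.5)
        else:
            self.prior = np.asarray(self.prior, dtype=float)
            if self.prior.shape != (self.N + 1,):
                raise ValueError(f"prior must have length N+1 = {self.N + 1}")
            if not np.isclose(self.prior.sum(), 1.0):
                raise ValueError("prior must sum to 1")

    @property
    def states(self) -> np.ndarray:
        return np.arange(self.N + 1)


@dataclass
class BinnedCounts:
    """Aggregated (a, depth) per fixed-width bin along one contig."""

    contig: str
    res_bp: int
    a: np.ndarray
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=np.int64)
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if self.a.shape != self.depth.shape:
            raise ValueError("a and depth must have equal length")
        if (self.a > self.depth).any():
            raise ValueError("designated-allele count exceeds depth in a bin")

    @property
    def n_bins(self) -> int:
        return len(self.a)

    @property
    def starts(self) -> np.ndarray:
        """1-based bp start of each bin."""
        return np.arange(self.n_bins, dtype=np.int64) * self.res_bp + 1

    @property
    def ends(self) -> np.ndarray:
        return (np.arange(self.n_bins, dtype=np.int64) + 1) * self.res_bp

    @property
    def mids(self) -> np.ndarray:
        return (self.starts + self.ends) / 2.0


def bin_counts(
    track: pd.DataFrame,
    res_bp: int,
    contig_lengths: Mapping[str, int] | None = None,
) -> dict[str, BinnedCounts]:
    """Aggregate a marker count track into fixed-width bins per contig.

    A marker at 1-based position p lands in bin floor((p-1)/res_bp); empty
    bins are carried with (0, 0) so the chain's grid is uniform.  The grid
    extends to the contig length when provided, else to the last marker.
    """
    out: dict[str, BinnedCounts] = {}
    contigs = (
        list(contig_lengths) if contig_lengths is not None
        else sorted(track["contig"].unique())
    )
    for contig in contigs:
        sub = track.loc[track["contig"] == contig]
        if contig_lengths is not None:
            n_bins = max(1, int(np.ceil(contig_lengths[contig] / res_bp)))
        elif sub.empty:
            continue
        else:
            n_bins = int((sub["pos"].max() - 1) // res_bp) + 1
        a = np.zeros(n_bins, dtype=np.int64)
        d = np.zeros(n_bins, dtype=np.int64)
        if not sub.empty:
            idx = ((sub["pos"].to_numpy() - 1) // res_bp).astype(np.int64)
            np.add.at(a, idx, sub["a"].to_numpy())
            np.add.at(d, idx, sub["depth"].to_numpy())
        out[contig] = BinnedCounts(contig=contig, res_bp=res_bp, a=a, depth=d)
    return out


def transition_matrix(d_bp: float, params: LodModelParams) -> np.ndarray:
    """Recombination kernel over a physical distance, (N+1)x(N+1).

    Each pooled haplotype independently "forgets" its origin over d bp with
    probability rho = 1 - exp(-2c) (c in Morgans), redrawing a fresh
    Bernoulli(0.5); the net origin-switch probability is rho/2, the Haldane
    map function.  From state j the next count is
    Binomial(j, 1 - rho/2) + Binomial(N - j, rho/2).  Rows sum to 1, the
    stationary distribution is Binomial(N, 0.5), and at infinite distance
    every row reaches it (rho -> 1).
    """
    if d_bp < 0:
        raise ValueError("distance must be >= 0")
    N = params.N
    rho = 2.0 * float(haldane_switch_prob(d_bp, params.bp_per_cM))
    T = np.zeros((N + 1, N + 1))
    for j in range(N + 1):
        keep = stats.binom.pmf(np.arange(j + 1), j, 1.0 - rho / 2.0)
        gain = stats.binom.pmf(np.arange(N - j + 1), N - j, rho / 2.0)
        T[j, :] = np.convolve(keep, gain)[: N + 1]
    # guard against convolution round-off
    T[T < 0] = 0.0
    T /= T.sum(axis=1, keepdims=True)
    return T


def _pool_sampling_weights(params: LodModelParams) -> np.ndarray:
    """W[j, k] = Binom(k; N, j/N): probability the finite pool holds k
    designated haplotypes when the underlying segregant frequency is j/N."""
    N = params.N
    frac = params.states / N
    return stats.binom.pmf(np.arange(N + 1)[None, :], N, frac[:, None])


def emission(a: int, depth: int, j: int, params: LodModelParams) -> float:
    """Likelihood of observing (a, depth) reads given state j.

    The state is the underlying segregant-population frequency j/N; the
    finite pool of N haplotypes is a binomial sample from it, and reads a
    binomial sample from the pool with per-read error eps.  Marginalizing
    the unobserved pool composition k:

        P(a | j) = sum_k Binom(k; N, j/N) * Binom(a; depth, q_k),
        q_k = (k/N)(1 - eps) + (1 - k/N) eps.

    Accounting for the pool-sampling step is what keeps random composition
    divergence between small pools from masquerading as linkage signal.
    """
    if a > depth:
        raise ValueError("a must not exceed depth")
    if depth == 0:
        return 1.0
    N = params.N
    w = stats.binom.pmf(np.arange(N + 1), N, j / N)
    frac = np.arange(N + 1) / N
    q = frac * (1.0 - params.eps) + (1.0 - frac) * params.eps
    return float(w @ stats.binom.pmf(a, depth, q))


def _emission_matrix(binned: BinnedCounts, params: LodModelParams) -> np.ndarray:
    """n_bins x (N+1) pool-marginalized emission likelihoods; empty bins emit 1."""
    frac = params.states / params.N
    q = frac * (1.0 - params.eps) + (1.0 - frac) * params.eps
    a = binned.a[:, None]
    d = binned.depth[:, None]
    read_lik = stats.binom.pmf(a, d, q[None, :])  # n_bins x (N+1 compositions)
    E = read_lik @ _pool_sampling_weights(params).T
    E[binned.depth == 0, :] = 1.0
    return E


@dataclass
class ForwardBackwardResult:
    """Smoothed posteriors gamma (rows sum to 1) and log10 data likelihood.

    The unnormalized smoothed marginal of the model is u_x(j) =
    gamma[x, j] * L; ``ok`` is False when the data are impossible under the
    model (some bin had zero total emission mass), in which case the
    log-likelihood is -inf and gamma is undefined.
    """

    gamma: np.ndarray
    log10_likelihood: float
    ok: bool = True


def forward_backward(
    binned: BinnedCounts, params: LodModelParams
) -> ForwardBackwardResult:
    """Scaled forward-backward over the uniform bin grid."""
    if binned.n_bins < 1:
        raise ValueError("need at least one bin")
    E = _emission_matrix(binned, params)
    n, S = E.shape
    T = transition_matrix(float(binned.res_bp), params) if n > 1 else None
    alpha = np.zeros((n, S))
    c = np.zeros(n)
    a0 = params.prior * E[0]
    c[0] = a0.sum()
    if c[0] == 0:
        return ForwardBackwardResult(np.full((n, S), np.nan), -np.inf, ok=False)
    alpha[0] = a0 / c[0]
    for x in range(1, n):
        ax = (alpha[x - 1] @ T) * E[x]
        c[x] = ax.sum()
        if c[x] == 0:
            return ForwardBackwardResult(np.full((n, S), np.nan), -np.inf, ok=False)
        alpha[x] = ax / c[x]
    beta = np.zeros((n, S))
    beta[n - 1] = 1.0
    for x in range(n - 2, -1, -1):
        beta[x] = (T @ (E[x + 1] * beta[x + 1])) / c[x + 1]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    return ForwardBackwardResult(gamma, float(np.log10(c).sum()), ok=True)


def posterior_mean_frequency(fb: ForwardBackwardResult, params: LodModelParams) -> np.ndarray:
    """Per-bin posterior mean of j/N (the pool allele frequency estimate)."""
    return fb.gamma @ (params.states / params.N)


def contrast_lod(
    high: BinnedCounts, low: BinnedCounts, params: LodModelParams
) -> pd.DataFrame:
    """Per-bin LOD contrasting independent vs tied pool frequencies.

    Returns columns contig, bin_start, bin_end, mid, lod, f_high, f_low.
    A bin where the tied likelihood is exactly zero (possible only with
    eps = 0) carries LOD = +inf as a sentinel.
    """
    if high.n_bins != low.n_bins or high.res_bp != low.res_bp:
        raise ValueError("high/low pools must share the same bin grid")
    if high.contig != low.contig:
        raise ValueError("high/low pools are on different contigs")
    fb_h = forward_backward(high, params)
    fb_l = forward_backward(low, params)
    if not (fb_h.ok and fb_l.ok):
        raise ValueError(
            f"contig {high.contig}: data impossible under the model "
            "(zero emission mass; raise eps)"
        )
    tie = (fb_h.gamma * fb_l.gamma / params.prior[None, :]).sum(axis=1)
    with np.errstate(divide="ignore"):
        lod = -np.log10(tie)
    return pd.DataFrame(
        {
            "contig": high.contig,
            "bin_start": high.starts,
            "bin_end": high.ends,
            "mid": high.mids,
            "lod": lod,
            "f_high": posterior_mean_frequency(fb_h, params),
            "f_low": posterior_mean_frequency(fb_l, params),
        }
    )


def scan(
    track_high: pd.DataFrame,
    track_low: pd.DataFrame,
    params: LodModelParams,
    contig_lengths: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Bin both pool tracks on a common grid and contrast every contig."""
    bh = bin_counts(track_high, params.res_bp, contig_lengths)
    bl = bin_counts(track_low, params.res_bp, contig_lengths)
    frames = []
    for contig in sorted(set(bh) | set(bl)):
        if contig not in bh or contig not in bl:
            # one pool has no data on this contig: align grids with zeros
            have = bh.get(contig) or bl.get(contig)
            empty = BinnedCounts(
                contig, have.res_bp,
                np.zeros(have.n_bins, int), np.zeros(have.n_bins, int),
            )
            h = bh.get(contig, empty)
            l = bl.get(contig, empty)
        else:
            h, l = bh[contig], bl[contig]
            if h.n_bins != l.n_bins:
                n = max(h.n_bins, l.n_bins)
                h = _pad(h, n)
                l = _pad(l, n)
        frames.append(contrast_lod(h, l, params))
    if not frames:
        return pd.DataFrame(
            columns=["contig", "bin_start", "bin_end", "mid", "lod", "f_high", "f_low"]
        )
    return pd.concat(frames, ignore_index=True)


def _pad(b: BinnedCounts, n_bins: int) -> BinnedCounts:
    if b.n_bins >= n_bins:
        return b
    pad = n_bins - b.n_bins
    return BinnedCounts(
        b.contig, b.res_bp,
        np.concatenate([b.a, np.zeros(pad, int)]),
        np.concatenate([b.depth, np.zeros(pad, int)]),
    )
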