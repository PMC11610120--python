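"""Exhaustive reference computations for the LOD hidden-Markov model.

Brute-force summation over all (N+1)^n_bins state paths, feasible only for
tiny pools and a handful of bins.  Used to validate the forward-backward
recursion and the tied-model contrast; deliberately shares no code path
with :mod:`hybridqtl.lodscan` beyond the model parameter container.
"""

from __future__ import annotations

import itertools

import numpy as np

from .lodscan import BinnedCounts, LodModelParams, emission, transition_matrix


def enumerate_chain(
    binned: BinnedCounts, params: LodModelParams
) -> tuple[float, np.ndarray]:
    """Total likelihood and unnormalized smoothed marginals by enumeration.

    Returns (L, M) where M[x, s] = sum of path weights over all state paths
    passing through state s at bin x; each column of M sums to L and
    M[x, s] equals the model's u_x(s) = gamma[x, s] * L.
    """
    n = binned.n_bins
    S = params.N + 1
    T = transition_matrix(float(binned.res_bp), params)
    a, d = binned.a, binned.depth
    L = 0.0
    M = np.zeros((n, S))
    for path in itertools.product(range(S), repeat=n):
        w = params.prior[path[0]] * emission(int(a[0]), int(d[0]), path[0], params)
        for x in range(1, n):
            w *= T[path[x - 1], path[x]] * emission(
                int(a[x]), int(d[x]), path[x], params
            )
        L += w
        for x, s in enumerate(path):
            M[x, s] += w
    return L, M


def enumerate_tied_likelihood(
    high: BinnedCounts, low: BinnedCounts, params: LodModelParams, x: int
) -> float:
    """Tied-model likelihood at bin x by enumeration.

    Generative tie: one state s ~ prior at bin x is shared by both pools,
    whose chains are otherwise independent.  Equals
    sum_s M_high[x, s] * M_low[x, s] / prior(s) with M from
    :func:`enumerate_chain` (the chain marginal at x under a stationary
    start is the prior).
    """
    _, mh = enumerate_chain(high, params)
    _, ml = enumerate_chain(low, params)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(
            params.prior > 0, mh[x] * ml[x] / params.prior, 0.0
        )
    return float(terms.sum())


def enumerate_lod(
    high: BinnedCounts, low: BinnedCounts, params: LodModelParams, x: int
) -> float:
    """LOD(x) = log10(L_high * L_low) - log10(L_tied(x)) by enumeration."""
    lh, _ = enumerate_chain(high, params)
    ll, _ = enumerate_chain(low, params)
    lt = enumerate_tied_likelihood(high, low, params, x)
    if lt == 0.0:
        return np.inf
    return float(np.log10(lh) + np.log10(ll) - np.log10(lt))
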