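"""HMM LOD scan: binning, kernel, emission, forward-backward, contrast."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.special import logsumexp

from hybridqtl import bruteforce
from hybridqtl.lodscan import (
    BinnedCounts, LodModelParams, bin_counts, contrast_lod, emission,
    forward_backward, transition_matrix, scan,
)


def _binned(a, d, res_bp=100, contig="c"):
    return BinnedCounts(contig=contig, res_bp=res_bp, a=np.array(a), depth=np.array(d))


class TestBinCounts:
    def _track(self, rows):
        return pd.DataFrame(rows, columns=["contig", "pos", "a", "depth"])

    def test_markers_share_bin_and_sum(self):
        out = bin_counts(self._track([("c", 50, 3, 10), ("c", 90, 2, 10)]), 100)
        assert out["c"].n_bins == 1
        assert out["c"].a[0] == 5 and out["c"].depth[0] == 20

    def test_totals_conserved_with_empty_bins(self):
        track = self._track([("c", 50, 3, 10), ("c", 950, 2, 12)])
        out = bin_counts(track, 100, {"c": 1000})
        assert out["c"].n_bins == 10
        assert out["c"].a.sum() == 5 and out["c"].depth.sum() == 22

    def test_position_100_lands_in_first_bin(self):
        out = bin_counts(self._track([("c", 100, 1, 1)]), 100)
        assert out["c"].n_bins == 1

    def test_grid_extends_to_contig_length(self):
        out = bin_counts(self._track([("c", 100, 1, 1)]), 100, {"c": 1234})
        assert out["c"].n_bins == 13


class TestTransitionMatrix:
    def test_zero_distance_is_identity(self):
        T = transition_matrix(0.0, LodModelParams(N=5))
        assert np.allclose(T, np.eye(6))

    def test_infinite_distance_reaches_stationary(self):
        params = LodModelParams(N=4)
        T = transition_matrix(1e12, params)
        target = stats.binom.pmf(np.arange(5), 4, 0.5)
        assert np.allclose(T, np.tile(target, (5, 1)), atol=1e-12)

    def test_hand_expanded_row_n2(self):
        # redraw probability 1/2: from j=2 the next count is Binomial(2, 3/4),
        # i.e. (1/16, 6/16, 9/16).  rho = 1 - exp(-2c) = 1/2 at c = ln(2)/2.
        params = LodModelParams(N=2, bp_per_cM=2500.0)
        d = np.log(2) / 2 * 100 * params.bp_per_cM
        T = transition_matrix(d, params)
        assert np.allclose(T[2], [1 / 16, 6 / 16, 9 / 16])

    def test_negative_distance_raises(self):
        with pytest.raises(ValueError):
            transition_matrix(-1.0, LodModelParams(N=2))

    @given(st.integers(1, 8), st.floats(0, 1e6))
    @settings(max_examples=50, deadline=None)
    def test_rows_are_stochastic(self, N, d):
        T = transition_matrix(d, LodModelParams(N=N))
        assert np.allclose(T.sum(axis=1), 1.0)
        assert (T >= 0).all()


class TestEmission:
    def test_edge_states_deterministic(self):
        params = LodModelParams(N=3, eps=0.0)
        assert emission(7, 7, 3, params) == pytest.approx(1.0)
        assert emission(1, 5, 0, params) == 0.0

    def test_half_frequency_symmetric(self):
        params = LodModelParams(N=2, eps=0.01)
        assert emission(3, 10, 1, params) == pytest.approx(emission(7, 10, 1, params))

    def test_empty_bin_emits_one(self):
        assert emission(0, 0, 1, LodModelParams(N=2)) == 1.0

    def test_count_exceeding_depth_raises(self):
        with pytest.raises(ValueError):
            emission(5, 3, 1, LodModelParams(N=2))


class TestForwardBackward:
    def test_single_empty_bin_returns_prior(self):
        params = LodModelParams(N=3)
        fb = forward_backward(_binned([0], [0]), params)
        assert fb.log10_likelihood == pytest.approx(0.0)  # L = 1
        assert np.allclose(fb.gamma[0], params.prior)

    def test_two_state_hand_enumeration(self):
        # N=1, eps=0, one bin with (a=1, d=1): L = 0.5, smoothed mass on j=1
        params = LodModelParams(N=1, eps=0.0)
        fb = forward_backward(_binned([1], [1]), params)
        assert 10 ** fb.log10_likelihood == pytest.approx(0.5)
        assert np.allclose(fb.gamma[0], [0.0, 1.0])

    def test_impossible_data_flagged(self):
        params = LodModelParams(N=1, eps=0.0)
        fb = forward_backward(_binned([1, 0], [1, 1], res_bp=0), params)
        # res 0 -> identity transitions; (1,1) then (0,1) is impossible
        assert not fb.ok and fb.log10_likelihood == -np.inf

    def test_smoothed_marginals_sum_to_one_everywhere(self):
        rng = np.random.default_rng(0)
        d = rng.integers(0, 30, size=50)
        a = rng.binomial(d, 0.4)
        fb = forward_backward(_binned(a, d, res_bp=500), LodModelParams(N=4))
        assert np.allclose(fb.gamma.sum(axis=1), 1.0, atol=1e-12)

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(42)
        for N in (1, 2, 3):
            params = LodModelParams(N=N, res_bp=700)
            for _ in range(5):
                n_bins = rng.integers(2, 5)
                d = rng.integers(0, 6, size=n_bins)
                a = np.array([rng.integers(0, di + 1) for di in d])
                b = _binned(a, d, res_bp=700)
                fb = forward_backward(b, params)
                L, M = bruteforce.enumerate_chain(b, params)
                assert 10 ** fb.log10_likelihood == pytest.approx(L, rel=1e-9)
                assert np.allclose(fb.gamma * L, M, rtol=1e-9, atol=1e-300)

    def test_scaled_recursion_agrees_with_log_space(self):
        """Per-bin scaling matches an independent logsumexp forward pass on a
        10,000-bin track."""
        rng = np.random.default_rng(3)
        n = 10_000
        d = rng.poisson(8, size=n)
        a = rng.binomial(d, 0.5)
        params = LodModelParams(N=6, res_bp=100)
        b = _binned(a, d)
        fb = forward_backward(b, params)

        from hybridqtl.lodscan import _emission_matrix

        E = _emission_matrix(b, params)
        logT = np.log(transition_matrix(100.0, params))
        la = np.log(params.prior) + np.log(E[0])
        for x in range(1, n):
            la = logsumexp(la[:, None] + logT, axis=0) + np.log(E[x])
        log10_L = logsumexp(la) / np.log(10)
        assert fb.log10_likelihood == pytest.approx(log10_L, abs=1e-9)


class TestContrastLod:
    def test_agreeing_pools_single_bin(self):
        params = LodModelParams(N=1, eps=0.0)
        out = contrast_lod(_binned([1], [1]), _binned([1], [1]), params)
        assert out.loc[0, "lod"] == pytest.approx(-np.log10(2))

    def test_contradicting_pools_infinite_sentinel(self):
        params = LodModelParams(N=1, eps=0.0)
        out = contrast_lod(_binned([1], [1]), _binned([0], [1]), params)
        assert np.isinf(out.loc[0, "lod"])

    def test_identical_data_never_positive(self):
        rng = np.random.default_rng(7)
        for N in (1, 2):
            params = LodModelParams(N=N, eps=0.01, res_bp=300)
            for _ in range(5):
                n_bins = rng.integers(1, 4)
                d = rng.integers(0, 5, size=n_bins)
                a = np.array([rng.integers(0, di + 1) for di in d])
                out = contrast_lod(_binned(a, d, 300), _binned(a, d, 300), params)
                assert (out["lod"] <= 1e-12).all()

    def test_tied_likelihood_matches_enumeration(self):
        rng = np.random.default_rng(5)
        for N in (1, 2, 3):
            params = LodModelParams(N=N, eps=0.05, res_bp=400)
            for _ in range(3):
                n_bins = int(rng.integers(2, 5))
                dh = rng.integers(0, 5, size=n_bins)
                ah = np.array([rng.integers(0, x + 1) for x in dh])
                dl = rng.integers(0, 5, size=n_bins)
                al = np.array([rng.integers(0, x + 1) for x in dl])
                bh, bl = _binned(ah, dh, 400), _binned(al, dl, 400)
                out = contrast_lod(bh, bl, params)
                for x in range(n_bins):
                    assert out.loc[x, "lod"] == pytest.approx(
                        bruteforce.enumerate_lod(bh, bl, params, x), rel=1e-9
                    )

    def test_finite_with_positive_error_rate(self):
        params = LodModelParams(N=2, eps=0.002)
        out = contrast_lod(_binned([20], [20]), _binned([0], [20]), params)
        assert np.isfinite(out.loc[0, "lod"])

    def test_posterior_frequencies_within_unit_interval(self):
        rng = np.random.default_rng(1)
        d = rng.poisson(30, 40)
        params = LodModelParams(N=10, res_bp=1000)
        out = contrast_lod(
            _binned(rng.binomial(d, 0.8), d, 1000),
            _binned(rng.binomial(d, 0.2), d, 1000),
            params,
        )
        for col in ("f_high", "f_low"):
            assert out[col].between(0, 1).all()

    def test_grid_mismatch_raises(self):
        params = LodModelParams(N=1)
        with pytest.raises(ValueError, match="grid"):
            contrast_lod(_binned([1], [1]), _binned([1, 0], [1, 1]), params)

    def test_monotone_in_planted_frequency_gap(self):
        """Widening the between-pool frequency gap never lowers the peak."""
        rng = np.random.default_rng(11)
        params = LodModelParams(N=20, res_bp=5000, bp_per_cM=2500 / 6)
        n_bins, depth = 40, 500
        noise = rng.normal(0, 0.01, size=(2, n_bins))
        peaks = []
        for gap in np.arange(0.1, 0.95, 0.2):
            fh, fl = 0.5 + gap / 2, 0.5 - gap / 2
            d = np.full(n_bins, depth)
            ah = np.clip((d * (fh + noise[0])).astype(int), 0, depth)
            al = np.clip((d * (fl + noise[1])).astype(int), 0, depth)
            out = contrast_lod(_binned(ah, d, 5000), _binned(al, d, 5000), params)
            peaks.append(out["lod"].max())
        assert all(b >= a - 1e-9 for a, b in zip(peaks, peaks[1:]))


class TestScan:
    def test_multi_contig_tracks(self):
        track = pd.DataFrame(
            {
                "contig": ["c1", "c1", "c2"],
                "pos": [50, 150, 70],
                "a": [5, 6, 2],
                "depth": [10, 10, 10],
            }
        )
        params = LodModelParams(N=2, res_bp=100)
        out = scan(track, track, params, {"c1": 200, "c2": 100})
        assert set(out["contig"]) == {"c1", "c2"}
        assert (out["lod"] <= 1e-12).all()  # identical pools
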