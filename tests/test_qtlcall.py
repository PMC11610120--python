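"""QTL interval calling, support intervals, trend check, gene annotation."""

import numpy as np
import pandas as pd
import pytest

from hybridqtl.qtlcall import (
    QtlCallParams, QtlInterval, annotate_genes, call_intervals,
    opposite_trend, support_bins, support_interval, to_bed,
)


def _track(lods, res=100, contig="c", f_high=0.9, f_low=0.1):
    n = len(lods)
    starts = np.arange(n) * res + 1
    return pd.DataFrame(
        {
            "contig": contig,
            "bin_start": starts,
            "bin_end": starts + res - 1,
            "mid": starts + (res - 1) / 2,
            "lod": lods,
            "f_high": f_high,
            "f_low": f_low,
        }
    )


def _params(**kw):
    return QtlCallParams(**kw)


class TestCallIntervals:
    def test_25kb_run_called(self):
        lods = [0.0] * 10 + [6.0] * 250 + [0.0] * 10
        out = call_intervals(_track(lods), _params())
        assert len(out) == 1
        iv = out[0]
        assert iv.run_end - iv.run_start + 1 == 25_000
        assert iv.peak_lod == 6.0

    def test_10kb_run_below_span_not_called(self):
        lods = [0.0] * 10 + [6.0] * 100 + [0.0] * 10
        assert call_intervals(_track(lods), _params()) == []

    def test_runs_split_by_subthreshold_bin_tested_separately(self):
        lods = [6.0] * 250 + [4.0] + [6.0] * 100 + [0.0] * 5
        out = call_intervals(_track(lods), _params())
        # first run 25 kb qualifies; second (10 kb) does not
        assert len(out) == 1
        assert out[0].run_start == 1

    def test_peak_tie_goes_leftmost(self):
        lods = [0.0] * 5 + [7.0] * 300 + [0.0] * 5
        out = call_intervals(_track(lods), _params())
        assert out[0].peak_pos == out[0].run_start + 49  # first bin's midpoint

    def test_opposite_trend_required(self):
        lods = [6.0] * 250
        track = _track(lods, f_high=0.9, f_low=0.7)  # same side of 0.5
        assert call_intervals(track, _params()) == []
        kept = call_intervals(
            track, _params(require_opposite_trend=False)
        )
        assert len(kept) == 1

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(4)
        lods = np.abs(rng.normal(4, 2, size=600)).round(2)
        base = call_intervals(_track(list(lods)), _params())
        looser_lod = call_intervals(_track(list(lods)), _params(min_lod=4))
        looser_span = call_intervals(
            _track(list(lods)), _params(min_span_bp=10_000)
        )
        def spans(ivs):
            return {(iv.run_start, iv.run_end) for iv in ivs}
        # every original run survives (possibly widened) under looser settings
        assert len(looser_lod) >= len(base)
        assert len(looser_span) >= len(base)
        for s, e in spans(base):
            assert any(s2 <= s and e2 >= e for s2, e2 in spans(looser_lod))
            assert (s, e) in spans(looser_span)


class TestSupportInterval:
    def test_flat_track_spans_whole_contig(self):
        track = _track([6.0] * 300)
        start, end = support_interval(track, 150)
        assert (start, end) == (1, 30_000)

    def test_triangular_peak_crosses_at_five_kb(self):
        """LOD 8 at the peak falling linearly to cross 7 at +/- 5 kb."""
        res = 100
        n = 300
        peak_idx = 150
        mids = np.arange(n) * res + 1 + (res - 1) / 2
        peak_mid = mids[peak_idx]
        lods = 8.0 - np.abs(mids - peak_mid) / 5_000.0
        track = _track(list(lods))
        start, end = support_interval(track, peak_idx)
        assert start == pytest.approx(peak_mid - 5_000, abs=1.0)
        assert end == pytest.approx(peak_mid + 5_000, abs=1.0)

    def test_peak_at_contig_edge_is_one_sided(self):
        lods = list(np.linspace(8, 0, 100))
        track = _track(lods)
        start, end = support_interval(track, 0)
        assert start == 1
        assert end < 10_000

    def test_support_contains_peak_and_peak_is_run_max(self):
        rng = np.random.default_rng(9)
        lods = list(np.abs(rng.normal(5, 2, size=500)))
        for iv in call_intervals(_track(lods), _params(min_span_bp=1_000)):
            assert iv.support_start <= iv.peak_pos <= iv.support_end
            run = [
                l for s, l in zip(
                    np.arange(500) * 100 + 1, lods
                ) if iv.run_start <= s <= iv.run_end
            ]
            assert iv.peak_lod == max(run)

    def test_support_bins_widest_contiguous_range(self):
        lods = np.array([0, 5, 6, 7, 6.5, 5.5, 0], dtype=float)
        assert support_bins(lods, 3, drop=1.0) == (2, 4)


class TestOppositeTrend:
    @pytest.mark.parametrize(
        "fh,fl,expected",
        [(0.9, 0.1, True), (0.9, 0.7, False), (0.5, 0.1, False), (0.3, 0.7, True)],
    )
    def test_straddle_rule(self, fh, fl, expected):
        assert opposite_trend(fh, fl) is expected


class TestAnnotation:
    def _interval(self, start, end):
        return QtlInterval(
            condition="drug", sub_genome="Scer", contig="c",
            run_start=start, run_end=end, peak_pos=(start + end) // 2,
            peak_lod=8.0, support_start=start, support_end=end,
            f_high=0.9, f_low=0.1,
        )

    def test_overlap_conventions(self):
        genes = pd.DataFrame(
            {
                "contig": ["c", "c", "c", "c"],
                "start": [1_100, 900, 2_000, 5_000],
                "end": [1_500, 1_000, 2_400, 6_000],
                "gene_id": ["inside", "edge", "tail_overlap", "outside"],
            }
        )
        got = annotate_genes(self._interval(1_000, 2_000), genes)
        assert got == ["edge", "inside", "tail_overlap"]  # sorted by start

    def test_missing_contig_yields_empty(self):
        genes = pd.DataFrame(
            {"contig": ["other"], "start": [1], "end": [10], "gene_id": ["g"]}
        )
        assert annotate_genes(self._interval(1, 100), genes) == []

    def test_bed_export_is_zero_based_half_open(self):
        bed = to_bed([self._interval(1_000, 2_000)])
        assert bed.loc[0, "chromStart"] == 999
        assert bed.loc[0, "chromEnd"] == 2_000
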