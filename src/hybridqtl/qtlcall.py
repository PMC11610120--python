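"""QTL interval calling from LOD tracks.

The reporting rule: a QTL is a maximal run of bins with LOD >= 5 whose bp
span is at least 20 kb, reported with a 1-LOD support interval around the
run's peak.  The support interval may extend beyond the LOD>=5 run (the
drop is relative to the peak, which can exceed 6), and intervals whose
posterior pool frequencies do not straddle 0.5 in opposite directions at
the peak can optionally be discarded (the "diametrically opposite trend"
requirement).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

QTL_COLUMNS = [
    "condition", "sub_genome", "contig", "run_start", "run_end",
    "peak_pos", "peak_lod", "support_start", "support_end",
    "f_high", "f_low", "genes",
]


@dataclass
class QtlCallParams:
    min_lod: float = 5.0
    min_span_bp: int = 20_000
    support_drop: float = 1.0
    require_opposite_trend: bool = True

    def __post_init__(self) -> None:
        if self.min_lod <= 0:
            raise ValueError("min_lod must be > 0")
        if self.support_drop <= 0:
            raise ValueError("support_drop must be > 0")
        if self.min_span_bp < 1:
            raise ValueError("min_span_bp must be >= 1")


@dataclass
class QtlInterval:
    condition: str
    sub_genome: str
    contig: str
    run_start: int
    run_end: int
    peak_pos: int
    peak_lod: float
    support_start: int
    support_end: int
    f_high: float
    f_low: float
    genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (self.support_start <= self.peak_pos <= self.support_end):
            raise ValueError("support interval must contain the peak")

    def to_row(self) -> dict:
        d = {k: getattr(self, k) for k in QTL_COLUMNS[:-1]}
        d["genes"] = ";".join(self.genes)
        return d


def intervals_to_frame(intervals: list[QtlInterval]) -> pd.DataFrame:
    return pd.DataFrame(
        [iv.to_row() for iv in intervals], columns=QTL_COLUMNS
    )


def support_bins(
    lod: np.ndarray, peak_idx: int, drop: float = 1.0
) -> tuple[int, int]:
    """Widest contiguous bin-index range around the peak with
    LOD >= peak - drop; bounded by the track ends."""
    thresh = lod[peak_idx] - drop
    lo = peak_idx
    while lo > 0 and lod[lo - 1] >= thresh:
        lo -= 1
    hi = peak_idx
    while hi < len(lod) - 1 and lod[hi + 1] >= thresh:
        hi += 1
    return lo, hi


def support_interval(
    track: pd.DataFrame, peak_idx: int, drop: float = 1.0
) -> tuple[int, int]:
    """1-LOD support interval in bp around the peak bin.

    The interval runs between the points where the LOD profile crosses
    peak - drop on either side of the peak, found by linear interpolation
    between bin midpoints (a triangular peak of height 8 crossing 7 at
    +/- 5 kb yields exactly peak +/- 5 kb).  Where the profile never drops
    below the threshold the interval is bounded by the track's outer bin
    edges.  ``track`` is one contig's bins, sorted; columns bin_start,
    bin_end, mid, lod.
    """
    lod = track["lod"].to_numpy()
    mids = track["mid"].to_numpy()
    thresh = lod[peak_idx] - drop
    lo, hi = support_bins(lod, peak_idx, drop)
    if lo > 0:
        # lod[lo-1] < thresh <= lod[lo]: interpolate the crossing
        frac = (lod[lo] - thresh) / (lod[lo] - lod[lo - 1])
        start = int(round(mids[lo] - frac * (mids[lo] - mids[lo - 1])))
    else:
        start = int(track["bin_start"].iloc[0])
    if hi < len(lod) - 1:
        frac = (lod[hi] - thresh) / (lod[hi] - lod[hi + 1])
        end = int(round(mids[hi] + frac * (mids[hi + 1] - mids[hi])))
    else:
        end = int(track["bin_end"].iloc[-1])
    return start, end


def opposite_trend(f_high: float, f_low: float) -> bool:
    """True iff the two pools' posterior frequencies straddle 0.5."""
    return (f_high - 0.5) * (f_low - 0.5) < 0


def call_intervals(
    track: pd.DataFrame,
    params: QtlCallParams,
    condition: str = "",
    sub_genome: str = "",
) -> list[QtlInterval]:
    """Apply the LOD >= min_lod over >= min_span_bp rule per contig.

    ``track`` columns: contig, bin_start, bin_end, mid, lod, f_high, f_low
    (bins sorted within contig).  The run span is measured between the
    outer bp edges of its first and last bin; the peak is the max-LOD bin
    (leftmost on ties); the support interval is the 1-LOD drop region,
    which may extend beyond the run.  Intervals failing the opposite-trend
    check are dropped when required (and logged).
    """
    out: list[QtlInterval] = []
    for contig, sub in track.groupby("contig", sort=True):
        sub = sub.sort_values("bin_start", kind="mergesort").reset_index(drop=True)
        lod = sub["lod"].to_numpy()
        above = lod >= params.min_lod
        if not above.any():
            continue
        edges = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
        for start, stop in zip(edges[::2], edges[1::2]):  # [start, stop) runs
            run = sub.iloc[start:stop]
            run_start = int(run["bin_start"].iloc[0])
            run_end = int(run["bin_end"].iloc[-1])
            if run_end - run_start + 1 < params.min_span_bp:
                continue
            rel_peak = int(np.argmax(run["lod"].to_numpy()))
            peak_idx = start + rel_peak
            s_start, s_end = support_interval(sub, peak_idx, params.support_drop)
            f_high = float(sub["f_high"].iloc[peak_idx])
            f_low = float(sub["f_low"].iloc[peak_idx])
            iv = QtlInterval(
                condition=condition,
                sub_genome=sub_genome,
                contig=contig,
                run_start=run_start,
                run_end=run_end,
                peak_pos=int(sub["mid"].iloc[peak_idx]),
                peak_lod=float(lod[peak_idx]),
                support_start=s_start,
                support_end=s_end,
                f_high=f_high,
                f_low=f_low,
            )
            if params.require_opposite_trend and not opposite_trend(f_high, f_low):
                logger.info(
                    "dropping %s:%d-%d (no opposite trend: f_high=%.3f f_low=%.3f)",
                    contig, iv.support_start, iv.support_end, f_high, f_low,
                )
                continue
            out.append(iv)
    return out


def load_gene_table(gff_path: str | Path) -> pd.DataFrame:
    """Gene features (contig, start, end, gene_id) from a GFF3 file."""
    db = gffutils.create_db(
        str(gff_path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    rows = []
    for feat in db.features_of_type("gene"):
        gid = feat.attributes.get("Name", feat.attributes.get("ID", [feat.id]))[0]
        rows.append((feat.seqid, feat.start, feat.end, gid))
    return pd.DataFrame(rows, columns=["contig", "start", "end", "gene_id"])


def annotate_genes(
    interval: QtlInterval, genes: pd.DataFrame
) -> list[str]:
    """Genes overlapping the support interval by >= 1 bp (1-based inclusive),
    sorted by start.  ``genes`` is the frame from :func:`load_gene_table`."""
    sub = genes.loc[genes["contig"] == interval.contig]
    if sub.empty:
        logger.warning("contig %s absent from annotation", interval.contig)
        return []
    hit = sub.loc[
        (sub["end"] >= interval.support_start)
        & (sub["start"] <= interval.support_end)
    ].sort_values("start", kind="mergesort")
    return hit["gene_id"].tolist()


def annotate_all(
    intervals: list[QtlInterval], genes: pd.DataFrame
) -> list[QtlInterval]:
    for iv in intervals:
        iv.genes = annotate_genes(iv, genes)
    return intervals


def to_bed(intervals: list[QtlInterval]) -> pd.DataFrame:
    """Support intervals as BED (0-based half-open)."""
    return pd.DataFrame(
        {
            "chrom": [iv.contig for iv in intervals],
            "chromStart": [iv.support_start - 1 for iv in intervals],
            "chromEnd": [iv.support_end for iv in intervals],
            "name": [
                f"{iv.condition}_{iv.sub_genome}_{iv.contig}_{iv.peak_pos}"
                for iv in intervals
            ],
        }
    )
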