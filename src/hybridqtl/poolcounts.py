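"""Per-marker founder-allele counting in pooled sequencing data.

Pool VCF records are matched to the founder-diagnostic marker panel by
(contig, position) and by allele identity; the count of the *designated*
founder's allele is AO when that founder carries the marker's alternate
allele and RO otherwise, so every track is oriented consistently along a
sub-genome regardless of which founder happened to be alternate at a site.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import pysam

from .markers import MarkerPanel

COUNT_COLUMNS = [
    "contig", "pos", "sub_genome", "condition", "pool",
    "ro", "ao", "a", "depth", "freq",
]


def default_designated(panel: MarkerPanel) -> dict[str, str]:
    """Alt-richer founder per sub-genome (the non-reference-like strain)."""
    out = {}
    for sub in panel.contig_map.sub_genomes:
        counts = panel.for_sub_genome(sub)["alt_founder"].value_counts()
        fa, fb = panel.contig_map.founders_of(sub)
        if counts.empty:
            out[sub] = fb
            continue
        top = counts.index[np.argmax(counts.to_numpy())]
        # deterministic tie-break: founder_b (conventionally the non-reference)
        if len(counts) == 2 and counts.iloc[0] == counts.iloc[1]:
            top = fb
        out[sub] = top
    return out


def _read_pool_vcf(path: str | Path) -> pd.DataFrame:
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            alts = rec.alts or ()
            if len(alts) != 1:
                continue  # pooled counts only meaningful for bi-allelic records
            call = rec.samples[samples[0]] if samples else None
            ro = call.get("RO") if call else None
            ao = call.get("AO") if call else None
            if isinstance(ao, tuple):
                ao = ao[0]
            if ro is None or ao is None:
                continue
            rows.append((rec.chrom, rec.pos, rec.ref, alts[0], int(ro), int(ao)))
    return pd.DataFrame(rows, columns=["contig", "pos", "ref", "alt", "ro", "ao"])


def count_alleles(
    pool_vcf: str | Path | pd.DataFrame,
    panel: MarkerPanel,
    designated: Mapping[str, str] | None = None,
    min_depth: int = 10,
    condition: str = "",
    pool: str = "",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Oriented designated-founder allele counts at each marker.

    ``pool_vcf`` may be a VCF path or an already-parsed DataFrame with
    columns contig, pos, ref, alt, ro, ao.  Markers with no pool record,
    mismatched alleles, or depth below ``min_depth`` are dropped and
    tallied in the returned report.
    """
    if len(panel) == 0:
        raise ValueError("empty marker panel")
    pool_df = (
        pool_vcf if isinstance(pool_vcf, pd.DataFrame) else _read_pool_vcf(pool_vcf)
    )
    unknown = set(pool_df["contig"]) - set(panel.contig_map.contigs)
    if unknown:
        raise ValueError(f"pool VCF contigs absent from contig map: {sorted(unknown)}")
    if designated is None:
        designated = default_designated(panel)
    for sub, founder in designated.items():
        if founder not in panel.contig_map.founders_of(sub):
            raise ValueError(
                f"designated founder {founder!r} is not a founder of {sub!r}"
            )
    merged = panel.df.merge(
        pool_df, on=["contig", "pos"], how="left", suffixes=("", "_pool")
    )
    report = {"absent": 0, "allele_mismatch": 0, "low_depth": 0}
    absent = merged["ro"].isna()
    report["absent"] = int(absent.sum())
    merged = merged.loc[~absent].copy()
    mismatch = (merged["ref"] != merged["ref_pool"]) | (
        merged["alt"] != merged["alt_pool"]
    )
    report["allele_mismatch"] = int(mismatch.sum())
    merged = merged.loc[~mismatch].copy()
    merged["depth"] = merged["ro"].astype(int) + merged["ao"].astype(int)
    shallow = merged["depth"] < min_depth
    report["low_depth"] = int(shallow.sum())
    merged = merged.loc[~shallow].copy()
    des = merged["sub_genome"].map(dict(designated))
    merged["a"] = np.where(
        merged["alt_founder"] == des, merged["ao"], merged["ro"]
    ).astype(int)
    merged["freq"] = merged["a"] / merged["depth"]
    merged["condition"] = condition
    merged["pool"] = pool
    track = (
        merged[COUNT_COLUMNS]
        .sort_values(["contig", "pos"], kind="mergesort")
        .reset_index(drop=True)
    )
    report_df = pd.DataFrame(sorted(report.items()), columns=["reason", "count"])
    return track, report_df


def observed_frequency(track: pd.DataFrame) -> pd.Series:
    """Per-marker designated-allele frequency a/depth (for plotting/QC)."""
    if track.empty:
        return pd.Series(dtype=float, name="freq")
    return (track["a"] / track["depth"]).rename("freq")
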