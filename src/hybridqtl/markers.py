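"""Founder-diagnostic marker derivation for hybrid sub-genomes.

In an inter-species hybrid, each sub-genome (the chromosome complement
contributed by one parental species) descends from exactly two founder
strains.  A *marker* is a bi-allelic SNP site at which one founder carries
the reference allele and the other a single alternate allele, with adequate
read depth in both haploid founder calls.  Pooled reads at such sites can be
assigned a parental origin, which is what the downstream allele-frequency
contrast needs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import pysam

NUCLEOTIDES = frozenset("ACGT")

CONTIG_MAP_COLUMNS = ["contig", "length", "sub_genome", "founder_a", "founder_b"]
MARKER_COLUMNS = ["contig", "pos", "sub_genome", "ref", "alt", "alt_founder"]


@dataclass(frozen=True)
class ContigMap:
    """Contig -> (length, sub-genome, founder pair) lookup table."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(CONTIG_MAP_COLUMNS) - set(self.df.columns)
        if missing:
            raise ValueError(f"contig map missing columns: {sorted(missing)}")
        if self.df["contig"].duplicated().any():
            dupes = self.df.loc[self.df["contig"].duplicated(), "contig"].tolist()
            raise ValueError(f"duplicate contigs in map: {dupes}")
        if (self.df["length"] <= 0).any():
            raise ValueError("all contig lengths must be > 0")

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, int, str, str, str]]
    ) -> "ContigMap":
        return cls(pd.DataFrame(list(records), columns=CONTIG_MAP_COLUMNS))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ContigMap":
        return cls(pd.read_csv(path, sep="\t", dtype={"contig": str}))

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @property
    def contigs(self) -> list[str]:
        return self.df["contig"].tolist()

    def has_contig(self, contig: str) -> bool:
        return contig in set(self.df["contig"])

    def sub_genome_of(self, contig: str) -> str:
        row = self.df.loc[self.df["contig"] == contig]
        if row.empty:
            raise KeyError(f"contig {contig!r} absent from contig map")
        return row["sub_genome"].iloc[0]

    def length_of(self, contig: str) -> int:
        row = self.df.loc[self.df["contig"] == contig]
        if row.empty:
            raise KeyError(f"contig {contig!r} absent from contig map")
        return int(row["length"].iloc[0])

    def founders_of(self, sub_genome: str) -> tuple[str, str]:
        rows = self.df.loc[self.df["sub_genome"] == sub_genome]
        if rows.empty:
            raise KeyError(f"sub-genome {sub_genome!r} absent from contig map")
        pairs = set(zip(rows["founder_a"], rows["founder_b"]))
        if len(pairs) != 1:
            raise ValueError(
                f"sub-genome {sub_genome!r} has inconsistent founder pairs: {pairs}"
            )
        return next(iter(pairs))

    @property
    def sub_genomes(self) -> list[str]:
        return sorted(self.df["sub_genome"].unique())

    def contigs_of(self, sub_genome: str) -> list[str]:
        return self.df.loc[self.df["sub_genome"] == sub_genome, "contig"].tolist()


@dataclass
class MarkerPanel:
    """Sorted founder-diagnostic markers plus the contig map they refer to.

    ``df`` columns: contig, pos (1-based), sub_genome, ref, alt, alt_founder
    where ``alt_founder`` names the founder strain carrying the alternate
    allele (the other founder of that sub-genome carries the reference).
    """

    df: pd.DataFrame
    contig_map: ContigMap

    def __post_init__(self) -> None:
        missing = set(MARKER_COLUMNS) - set(self.df.columns)
        if missing:
            raise ValueError(f"marker table missing columns: {sorted(missing)}")
        self.df = (
            self.df.sort_values(["contig", "pos"], kind="mergesort")
            .reset_index(drop=True)
        )
        if self.df.duplicated(["contig", "pos"]).any():
            raise ValueError("duplicate (contig, pos) in marker panel")
        unknown = set(self.df["contig"]) - set(self.contig_map.contigs)
        if unknown:
            raise ValueError(f"marker contigs absent from contig map: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.df)

    def for_sub_genome(self, sub_genome: str) -> pd.DataFrame:
        return self.df.loc[self.df["sub_genome"] == sub_genome].reset_index(drop=True)

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, contig_map: ContigMap) -> "MarkerPanel":
        df = pd.read_csv(path, sep="\t", dtype={"contig": str})
        return cls(df, contig_map)


def load_founder_variants(
    vcf_paths: Mapping[str, str | Path], contig_map: ContigMap
) -> pd.DataFrame:
    """Read per-founder haploid-call VCFs into a long site table.

    Keeps SNP records only (reference and every alternate a single
    nucleotide); indels and MNPs are dropped and counted.  Multi-allelic
    SNP records are retained but flagged.  Monomorphic reference records
    (ALT = ".") are kept so founder depth at non-variant sites is known.

    Returns a DataFrame with columns
    contig, pos, founder, ref, called, depth, multiallelic, n_alts
    plus a ``.attrs["rejections"]`` dict of per-reason drop counts.
    """
    rows: list[tuple] = []
    rejections: dict[str, int] = {"not_snp": 0, "het_call": 0}
    known = set(contig_map.contigs)
    for founder, path in vcf_paths.items():
        with pysam.VariantFile(str(path)) as vcf:
            if len(vcf.header.samples) != 1:
                raise ValueError(
                    f"founder VCF {path} must contain exactly one sample"
                )
            sample = vcf.header.samples[0]
            for rec in vcf:
                if rec.chrom not in known:
                    raise ValueError(
                        f"contig {rec.chrom!r} in {path} absent from contig map"
                    )
                alts = [a for a in (rec.alts or ())]
                if len(rec.ref) != 1 or rec.ref not in NUCLEOTIDES:
                    rejections["not_snp"] += 1
                    continue
                if any(len(a) != 1 or a not in NUCLEOTIDES for a in alts):
                    rejections["not_snp"] += 1
                    continue
                call = rec.samples[sample]
                gt = call.get("GT")
                alleles = [g for g in (gt or ()) if g is not None]
                if len(set(alleles)) > 1:
                    # haploid founder calls cannot be heterozygous
                    rejections["het_call"] += 1
                    continue
                idx = alleles[0] if alleles else 0
                called = rec.ref if idx == 0 else alts[idx - 1]
                depth = call.get("DP")
                if depth is None:
                    ro = call.get("RO") or 0
                    ao = call.get("AO") or 0
                    if isinstance(ao, tuple):
                        ao = sum(x or 0 for x in ao)
                    depth = ro + ao
                rows.append(
                    (
                        rec.chrom,
                        rec.pos,
                        founder,
                        rec.ref,
                        called,
                        int(depth),
                        len(alts) > 1,
                        len(alts),
                    )
                )
    df = pd.DataFrame(
        rows,
        columns=[
            "contig",
            "pos",
            "founder",
            "ref",
            "called",
            "depth",
            "multiallelic",
            "n_alts",
        ],
    )
    df.attrs["rejections"] = rejections
    return df


def derive_markers(
    sites: pd.DataFrame, contig_map: ContigMap, min_depth: int = 10
) -> tuple[MarkerPanel, pd.DataFrame]:
    """Derive founder-diagnostic bi-allelic markers from founder site calls.

    A site on a contig of sub-genome S (founders A, B) becomes a marker iff

    * both A and B have depth >= ``min_depth`` at it (a missing call counts
      as depth 0),
    * exactly one founder carries a single alternate allele and the other
      carries the reference, and
    * the site is bi-allelic across the two founders.

    Returns the panel and a rejection report (reason, count).
    """
    counts: dict[str, int] = {
        "low_depth": 0,
        "non_segregating": 0,
        "tri_allelic": 0,
        "multi_allelic_record": 0,
    }
    marker_rows: list[tuple] = []
    if not sites.empty:
        for (contig, pos), grp in sites.groupby(["contig", "pos"], sort=True):
            sub = contig_map.sub_genome_of(contig)
            fa, fb = contig_map.founders_of(sub)
            by_founder = {r.founder: r for r in grp.itertuples()}
            ra, rb = by_founder.get(fa), by_founder.get(fb)
            depth_a = ra.depth if ra is not None else 0
            depth_b = rb.depth if rb is not None else 0
            if depth_a < min_depth or depth_b < min_depth:
                counts["low_depth"] += 1
                continue
            if ra.multiallelic or rb.multiallelic:
                counts["multi_allelic_record"] += 1
                continue
            if ra.ref != rb.ref:
                counts["tri_allelic"] += 1
                continue
            ref = ra.ref
            a_alt, b_alt = ra.called != ref, rb.called != ref
            if a_alt == b_alt:
                if a_alt and ra.called != rb.called:
                    counts["tri_allelic"] += 1
                else:
                    counts["non_segregating"] += 1
                continue
            alt_founder, alt = (fa, ra.called) if a_alt else (fb, rb.called)
            marker_rows.append((contig, pos, sub, ref, alt, alt_founder))
    panel_df = pd.DataFrame(marker_rows, columns=MARKER_COLUMNS)
    report = pd.DataFrame(
        sorted(counts.items()), columns=["reason", "count"]
    )
    return MarkerPanel(panel_df, contig_map), report
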