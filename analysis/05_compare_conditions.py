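"""Pleiotropy, cross-sub-genome sharing, and summary counts.

Groups QTL intervals that overlap across drug conditions (pleiotropic
regions), finds same-condition intervals on the two sub-genomes that share
ortholog-paired genes, and tabulates interval counts and lengths per
condition and sub-genome.
"""

from pathlib import Path

import pandas as pd

from hybridqtl import crosscompare
from hybridqtl.qtlcall import QtlInterval

SCRATCH = Path("scratch/synthetic_study")
RESULTS = Path("results/tables")


def _load_intervals() -> list[QtlInterval]:
    df = pd.read_csv(RESULTS / "qtl_calls.tsv", sep="\t")
    out = []
    for row in df.itertuples():
        out.append(
            QtlInterval(
                condition=row.condition, sub_genome=row.sub_genome,
                contig=row.contig, run_start=row.run_start, run_end=row.run_end,
                peak_pos=row.peak_pos, peak_lod=row.peak_lod,
                support_start=row.support_start, support_end=row.support_end,
                f_high=row.f_high, f_low=row.f_low,
                genes=str(row.genes).split(";") if pd.notna(row.genes) and row.genes else [],
            )
        )
    return out


def main() -> None:
    intervals = _load_intervals()
    groups = crosscompare.pleiotropic_groups(intervals)
    pd.DataFrame([g.to_row() for g in groups]).to_csv(
        RESULTS / "pleiotropic_regions.tsv", sep="\t", index=False
    )
    print(f"{len(groups)} pleiotropic region(s):")
    for g in groups:
        print(f"  {g.sub_genome} {g.contig}:{g.start}-{g.end} "
              f"shared by {', '.join(g.conditions)} "
              f"({len(g.shared_genes)} shared genes)")

    orth = pd.read_csv(SCRATCH / "orthologs.tsv", sep="\t")
    ia = [iv for iv in intervals if iv.sub_genome == "Scer"]
    ib = [iv for iv in intervals if iv.sub_genome == "Skud"]
    shared_rows = []
    for cond in sorted({iv.condition for iv in intervals}):
        for sq in crosscompare.shared_across_subgenomes(ia, ib, orth, cond):
            shared_rows.append(sq.to_row())
    shared = pd.DataFrame(
        shared_rows, columns=["condition", "sub_genome_a", "region_a",
                              "sub_genome_b", "region_b", "orthologs"]
    )
    shared.to_csv(RESULTS / "shared_subgenome_qtls.tsv", sep="\t", index=False)
    print(f"\n{len(shared)} QTL pair(s) shared across sub-genomes "
          f"(by ortholog content, not coordinates):")
    if len(shared):
        print(shared[["condition", "region_a", "region_b"]].to_string(index=False))

    summary = crosscompare.summarize_counts(intervals)
    summary.to_csv(RESULTS / "qtl_summary_counts.tsv", sep="\t", index=False)
    print("\nper condition x sub-genome summary "
          "(support-interval lengths in kb):")
    print(summary.round(2).to_string(index=False))


if __name__ == "__main__":
    main()
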