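"""Pool sequencing, marker derivation, and oriented allele counting.

Derives the founder-diagnostic marker panel from the founder VCFs (depth
>= 10, bi-allelic, one founder reference / one alternate), simulates pooled
sequencing of each selected 20-strain pool, and converts the pool VCFs into
designated-founder allele counts per marker, per sub-genome.
"""

from pathlib import Path

import pandas as pd

from hybridqtl import poolcounts, synthcross as sc
from hybridqtl.markers import ContigMap, derive_markers, load_founder_variants

import importlib
import sys

sys.path.insert(0, str(Path(__file__).resolve().parent))
sim_mod = importlib.import_module("01_simulate_cross")

SCRATCH = Path("scratch/synthetic_study")
RESULTS = Path("results/tables")


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    cmap = ContigMap.from_tsv(SCRATCH / "contig_map.tsv")
    founders = {
        f: SCRATCH / f"founder_{f}.vcf"
        for sub in cmap.sub_genomes for f in cmap.founders_of(sub)
    }
    sites = load_founder_variants(founders, cmap)
    panel, rejections = derive_markers(sites, cmap, min_depth=10)
    panel.to_tsv(SCRATCH / "markers.tsv")
    print(f"derived {len(panel)} markers from {len(sites)} founder calls; "
          f"rejections: {dict(zip(rejections['reason'], rejections['count']))}")

    # sequence the selected pools (synthetic stand-in for the Illumina step)
    config = sim_mod.CONFIG
    panel_truth, _ = sc.sim_founder_markers(config)
    progeny = {p.id: p for p in sc.sim_progeny(panel_truth, config)}
    pools = pd.read_csv(SCRATCH / "pools.tsv", sep="\t")
    designated = poolcounts.default_designated(panel)
    print(f"designated (alt-richer) founder per sub-genome: {designated}")

    frames = []
    for (cond, label), grp in pools.groupby(["condition", "pool"]):
        members = [progeny[s] for s in grp["strain"]]
        reads = sc.sim_pool_reads(members, panel, config, f"{cond}_{label}")
        vcf = SCRATCH / f"pool_{cond}_{label}.vcf"
        sc.write_pool_vcf(reads, panel, f"{cond}_{label}", vcf)
        track, report = poolcounts.count_alleles(
            vcf, panel, designated, min_depth=10, condition=cond, pool=label
        )
        frames.append(track)
    counts = pd.concat(frames, ignore_index=True)
    counts.to_csv(SCRATCH / "counts.tsv", sep="\t", index=False)
    by_pool = counts.groupby(["condition", "pool"]).agg(
        markers=("pos", "size"), mean_depth=("depth", "mean"),
        mean_freq=("freq", "mean"),
    ).round(3)
    by_pool.to_csv(RESULTS / "pool_count_summary.tsv", sep="\t")
    print("\nper-pool counting summary:")
    print(by_pool.to_string())
    print(f"\ncounts -> {SCRATCH / 'counts.tsv'}")


if __name__ == "__main__":
    main()
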