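"""Simulate the synthetic F12 hybrid study.

Builds a two-sub-genome hybrid cross (one 1 Mb contig per parental species,
founder pairs OS104/OS253 and IF01802/OS575), 228 diploid F12 progeny, and
colony-size phenotypes for three antifungal-like conditions plus the YPD
control.  The planted architecture deliberately mirrors the features the
downstream comparisons look for:

* a pleiotropic region on the S. cerevisiae contig (~520 kb) affecting
  fluconazole and micafungin,
* a condition-specific locus (~200 kb, fluconazole only), and
* a flucytosine locus present at homologous positions on BOTH sub-genomes,
  so the two intervals share ortholog-paired genes.

Outputs (founder VCFs, phenotype TSV, contig map, GFF3, orthologs, truth)
go to scratch/synthetic_study/.
"""

from pathlib import Path

import pandas as pd

from hybridqtl import synthcross as sc
from hybridqtl.synthcross import Qtl, SimConfig, TraitModel

SCRATCH = Path("scratch/synthetic_study")
SEED = 42

CONFIG = SimConfig(
    seed=SEED,
    n_progeny=228,
    contigs=[("Sc_chrI", 1_000_000, "Scer"), ("Sk_chrI", 1_000_000, "Skud")],
    read_depth=100.0,
)

TRAITS = [
    TraitModel(
        condition="fluconazole",
        qtls=[Qtl("Sc_chrI", 520_000, 12.0, "OS253"),
              Qtl("Sc_chrI", 200_000, 9.0, "OS104")],
        noise_sd=6.0,
    ),
    TraitModel(
        condition="flucytosine",
        qtls=[Qtl("Sc_chrI", 600_000, 12.0, "OS253"),
              Qtl("Sk_chrI", 600_000, 12.0, "OS575")],
        noise_sd=6.0,
    ),
    TraitModel(
        condition="micafungin",
        qtls=[Qtl("Sc_chrI", 520_000, 12.0, "OS253")],
        noise_sd=6.0,
    ),
    TraitModel(condition="YPD", qtls=[], noise_sd=6.0),
]


def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    panel, alleles = sc.sim_founder_markers(CONFIG)
    progeny = sc.sim_progeny(panel, CONFIG)
    print(f"simulated {len(panel)} founder-diagnostic markers "
          f"across {len(CONFIG.contigs)} contigs and {len(progeny)} F12 progeny")

    pheno = pd.concat(
        [sc.sim_phenotypes(progeny, t, CONFIG) for t in TRAITS], ignore_index=True
    )
    pheno.to_csv(SCRATCH / "pheno.tsv", sep="\t", index=False)

    sc.write_founder_vcfs(panel, CONFIG, SCRATCH)
    CONFIG.contig_map().to_tsv(SCRATCH / "contig_map.tsv")
    genes = sc.sim_genes(CONFIG)
    sc.write_gff3(genes, SCRATCH / "genes.gff3")
    sc.make_ortholog_table(genes, "Scer", "Skud").to_csv(
        SCRATCH / "orthologs.tsv", sep="\t", index=False
    )
    truth = pd.concat([t.truth_frame() for t in TRAITS if t.qtls], ignore_index=True)
    truth.to_csv(SCRATCH / "truth.tsv", sep="\t", index=False)
    print(f"planted {len(truth)} QTLs:")
    print(truth.to_string(index=False))
    print(f"wrote inputs to {SCRATCH}/")


if __name__ == "__main__":
    main()
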