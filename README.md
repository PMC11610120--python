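# hybridqtl

Pooled-segregant QTL mapping for inter-species hybrid yeast.

Inter-species *Saccharomyces* hybrids (e.g. *S. cerevisiae* × *S.
kudriavzevii*) carry one chromosome complement — a **sub-genome** — from each
parental species, and each sub-genome descends from a pair of founder
strains.  After many rounds of intercrossing (an F12 population), colony
size under an antifungal drug is a quantitative trait, and sequencing pools
of the best and worst progeny turns allele-frequency contrast between the
pools into a genetic map of the trait.  `hybridqtl` implements the full
desk-side arc of such a study:

1. **phenoscreen** — colony-size replicate QC (values beyond 1.25 × IQR of
   the four technical replicates are excluded; type-7 quartiles), per-strain
   medians and normalization to the YPD control, dispersion (quartile
   coefficient of dispersion), and two-tailed selection of the 20 best and
   20 worst strains per condition.
2. **markers** — founder-diagnostic marker derivation from per-founder
   haploid-call VCFs: bi-allelic SNP sites where one founder of a
   sub-genome is reference and the other carries a single alternate, with
   read depth ≥ 10 in both.
3. **poolcounts** — matching pool VCF records (RO/AO observation counts) to
   the marker panel and orienting every count to a designated founder.
4. **lodscan** — a hidden-Markov contrast scan in the Multipool family.
   The hidden state is the designated-founder frequency in the segregant
   population, discretized to j/N for a pool of N = 20 haplotypes.
   Transitions encode recombination (per-lineage origin decorrelation by
   the Haldane map function); the emission marginalizes the binomial
   sampling of the finite pool and of the reads.  For each genomic bin *x*,

   LOD(*x*) = log₁₀ L_indep − log₁₀ L_tied(*x*)
            = −log₁₀ Σⱼ γ_high(j) γ_low(j) / π(j),

   where γ are smoothed forward–backward posteriors and π = Binomial(N, ½)
   is the stationary prior shared at the tied bin.
5. **qtlcall** — the reporting rule: maximal runs with LOD ≥ 5 spanning
   ≥ 20 kb, a 1-LOD support interval around the peak (interpolated
   crossings), a requirement that the pools' posterior frequencies straddle
   0.5 in opposite directions, and GFF3 gene annotation.
6. **crosscompare** — pleiotropic regions (coordinate overlap of support
   intervals across drug conditions) and QTLs shared between sub-genomes
   (ortholog gene content, never coordinates).
7. **rhagrowth** — logistic growth-curve fits
   N(t) = K / (1 + ((K−N₀)/N₀) e^(−rt)) with derived T_mid and integral
   area, and pooled-variance Student's *t* comparisons of
   reciprocal-hemizygote allele groups.
8. **synthcross** — a synthetic F12 generator (recombinant haplotype
   mosaics, planted additive QTLs, replicate noise with outliers, pooled
   binomial reads) emitting the same VCF/TSV/GFF3 formats the real pipeline
   consumes, so every stage is exercisable without external data.
9. **pipeline** — orchestration of all stages over plain-text
   intermediates, with a manifest of parameters, row counts and checksums.

## Worked example

The numbered scripts under `analysis/` run a complete synthetic study
(two 1 Mb sub-genome contigs, 228 progeny, five planted QTLs):

```bash
python analysis/01_simulate_cross.py
python analysis/02_phenotype_pools.py
python analysis/03_sequence_and_count.py
python analysis/04_scan_and_call.py
python analysis/05_compare_conditions.py
python analysis/06_growth_validation.py
```

`04_scan_and_call.py` prints the calls:

```
5 QTL intervals called:
  condition sub_genome  contig  support_start  support_end  peak_pos  peak_lod  f_high  f_low
fluconazole       Scer Sc_chrI         197797       209620    205400      8.95    0.79   0.23
fluconazole       Scer Sc_chrI         516126       524573    522600      9.76    0.16   0.75
flucytosine       Scer Sc_chrI         597761       605663    600600      9.84    0.16   0.76
flucytosine       Skud Sk_chrI         596088       604822    600600      7.19    0.75   0.23
 micafungin       Scer Sc_chrI         515194       523439    517400     10.12    0.26   0.86

planted-QTL recovery: 5/5 planted loci fall inside a called run for their condition
```

Every called interval brackets a planted locus, the high/low posterior
frequencies sit on opposite sides of 0.5 (the designated founder is
enriched in one pool and depleted in the other), and `05_compare_conditions.py`
then reports the planted structure:

```
1 pleiotropic region(s):
  Scer Sc_chrI:516126-523439 shared by fluconazole, micafungin (4 shared genes)
1 QTL pair(s) shared across sub-genomes (by ortholog content, not coordinates):
  flucytosine Sc_chrI:597761-605663  Sk_chrI:596088-604822
```

`06_growth_validation.py` fits the growth curves of simulated
reciprocal hemizygotes and finds the allele effect on the integral area
(t = 21.5, p ≈ 1e-9).  Small summary tables land in `results/tables/`;
bulky intermediates stay under `scratch/`.

A `hybridqtl` CLI exposes the same stages
(`simulate`, `phenotype`, `markers`, `counts`, `scan`, `call`, `compare`,
`growth`, `run-all`); see `hybridqtl --help`.

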