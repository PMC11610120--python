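# Methods

## The mapping problem

A diploid inter-species hybrid carries one haploid complement per parental
species.  In an F12 intercross population each such complement is a mosaic
of the two founder strains of that sub-genome, with breakpoint density
accumulated over twelve meioses.  Selecting the 20 highest- and 20
lowest-fitness strains and sequencing each pool turns trait association
into allele-frequency divergence between pools along the genome.  The
pipeline scores that divergence with a hidden-Markov likelihood-ratio
statistic and reports QTL intervals under a fixed rule (LOD ≥ 5 sustained
over ≥ 20 kb, 1-LOD support interval, opposite frequency trend).

## The contrast model

For a pool of N haploid complements (default N = 20), the hidden state at
bin *x* is the designated-founder frequency in the segregant population,
discretized to j/N, j = 0…N.

* **Prior / stationary distribution.** π = Binomial(N, ½): pools of random
  segregants are unbiased a priori.
* **Transitions.** Over a physical gap of d bp, each lineage independently
  "forgets" its founder origin with probability ρ = 1 − e^(−2c)
  (c = d / (100 · bp_per_cM) Morgans) and redraws Bernoulli(½); the net
  origin-switch probability is ρ/2, the Haldane map function.  From state
  j the next count is Binomial(j, 1 − ρ/2) + Binomial(N − j, ρ/2).  The
  kernel's stationary distribution is π and a single step at infinite
  distance reaches it.  The simpler parameterization that redraws with the
  Haldane probability itself caps at a half and can never decorrelate a
  single step fully, which contradicts the stationarity limit; ρ is the
  physically consistent choice.
* **Emission.** A bin with aggregated counts (a, d) given state j:

      P(a | j) = Σₖ Binom(k; N, j/N) · Binom(a; d, q_k),
      q_k = (k/N)(1 − ε) + (1 − k/N) ε.

  The inner binomial is read sampling with per-read error ε (default
  0.002); the outer sum marginalizes the composition k of the finite pool.
  This finite-pool term is essential: two pools of 20 drawn from the same
  population differ in composition by σ ≈ 0.11 in frequency at every
  locus, and at depth ~100 per marker that divergence is fully resolvable.
  A model that treats the pool composition itself as the state therefore
  assigns enormous LOD to plain sampling noise (measured on null
  simulations: maximum LOD ≈ 45 with a third of the genome above 5).  With
  the marginalized emission the same null simulations stay below LOD ≈ 4
  genome-wide.  Empty bins emit 1.
* **LOD.** With smoothed posteriors γ from scaled forward–backward and
  total likelihoods L per pool, the tied model draws one state from π at
  the test bin, shared by both pools, dynamics otherwise independent:

      L_tied(x) = Σⱼ u_high(j) · u_low(j) / π(j),   u = γ·L
      LOD(x)    = log₁₀(L_high · L_low) − log₁₀ L_tied(x)
                = −log₁₀ Σⱼ γ_high(j) γ_low(j) / π(j).

  With ε = 0 a contradiction between pools can make L_tied exactly zero;
  the LOD is then reported as +∞ and capped at 1000 in file output so
  downstream interval logic has an orderable value.  The implementation is
  validated against exhaustive enumeration over all (N+1)^bins state paths
  for N ≤ 3 and ≤ 4 bins (relative error < 1e-9, `bruteforce` module) and
  against an independent log-space forward pass on 10,000-bin tracks.

## Scan resolution and map density

`LodModelParams` defaults are conservative and generic (bin 100 bp,
2,500 bp/cM — the order of the yeast genome-wide average — ε = 0.002,
N = 20).  For an F12 design the pipeline derives two settings from the
generator configuration (`pipeline.recommended_scan_params`):

* the kernel uses the **effective** map density `bp_per_cM /
  map_expansion` (≈ 417 bp/cM at the defaults), because the pooled
  haplotypes are F12 recombinants whose origin tracts decay at the
  expanded rate;
* the bin width is set to ~1/8 of the effective Morgan length (5,000 bp at
  the defaults).  The emission marginalizes the pool composition
  independently per bin, which is accurate when a bin holds about one
  effective composition draw; much finer bins pseudo-replicate the
  pool-sampling noise across the many bins inside one linkage block and
  inflate null LOD (measured: res 2,500 pushes null maxima to ≈ 7 with
  occasional spurious calls, res 5,000 keeps 20/20 null runs call-free),
  while much coarser bins degrade peak localization.

## Interval calling

Runs of consecutive bins with LOD ≥ `min_lod` (default 5) qualify when
their outer bp span is at least `min_span_bp` (default 20,000) — span is
measured on the run, not the support interval.  The peak is the maximal
bin (leftmost on ties).  The 1-LOD support interval ends where the profile
crosses peak − 1, located by linear interpolation between bin midpoints
(a triangular peak of height 8 crossing 7 at ±5 kb yields exactly ±5 kb);
it may extend beyond the LOD ≥ 5 run, since the drop is relative to a peak
that can exceed 6.  Intervals whose posterior pool frequencies do not
straddle 0.5 in opposite directions at the peak are discarded by default.
Genes overlap an interval if they share ≥ 1 bp, 1-based inclusive.

## Synthetic cross generator

The generator emulates the study design: 228 diploid F12 progeny, one
recombinant haplotype per sub-genome (two founders per sub-genome — the
tetraploid intermediate is collapsed to what the marker contrast can see),
four technical colony-size replicates, and two-tailed pools of 20.

* **Mosaics.** Two-state Markov chains over the marker grid; switch
  probability per gap from the Haldane function at `map_expansion` × the
  nominal map distance.  The multiplier (default 6.0, the advanced-
  intercross expectation of g/2 for g = 12 meioses) replaces explicit
  pedigree simulation: only the marginal breakpoint density matters to the
  inference being tested.  Breakpoints sit midway between flanking markers.
* **Phenotypes.** true = baseline + Σ effect·[origin = advantaged founder]
  + N(0, noise_sd); each replicate multiplies by LogNormal(0,
  replicate_cv), with probability `outlier_rate` additionally by
  Uniform(3, 10), floored at zero.  Defaults: baseline 100 (arbitrary
  colony-size units), noise_sd 6, replicate_cv 0.10, outlier_rate 0.01 —
  replicate scatter of ~10% with rare gross outliers is typical of
  high-throughput colony imaging.  A planted effect of 12 against this
  noise puts the extreme pools near designated-allele frequencies
  0.9/0.1 at the locus.
* **Pool reads.** Depth ~ Poisson(read_depth, default 100 per marker);
  designated-allele count Binomial(depth, f(1−ε) + (1−f)ε) at the pool's
  true haplotype frequency f.
* **Founder VCFs.** Markers every ~500 bp (exponential spacing).  The
  alternate-carrying founder gets a variant record; the other founder gets
  a monomorphic reference record (ALT=".") so its depth at the site is
  encoded — real callers rarely emit these, but the marker stage treats a
  missing call as depth 0, and the round-trip property (derived panel ==
  simulated panel at uniform depth) needs both founders' depths visible.
* **Determinism.** Every stage draws from
  `default_rng([seed, stage_id, crc32(label)])`, so stages are
  independently reproducible and identical configurations produce
  byte-identical files.

What the generator does **not** emulate: read-level artefacts (FASTQ,
alignment, duplicates), mapping bias between sub-genomes, structural
variation, segregation distortion, plate spatial effects, and
linkage-disequilibrium structure beyond the single-multiplier breakpoint
model.  Passing tests on synthetic data therefore demonstrate the
inference machinery, not robustness to alignment-era artefacts.

## Growth-curve validation

Logistic fits use bounded least squares on N(t) = K / (1 + ((K−N₀)/N₀)
e^(−rt)), initialized at K₀ = max density, N₀ from the first positive
observation, r₀ from the early log-linear slope.  Derived metrics use the
closed forms T_mid = ln((K−N₀)/N₀)/r ("the time at which the population
reaches half of K"; the phrase "reaches 1/K" occasionally seen for this
quantity is read as K/2, the convention of the standard growth-curve
packages) and auc_l = (K/r)·ln((K + N₀(e^(rT) − 1))/K) with T the last
observed time.  Group comparisons use the equal-variance two-sample
Student's t (configurable to Welch); zero pooled variance with equal means
returns t = 0, p = 1, with unequal means it is flagged degenerate.

## Calibration measurements

All computed by the test suite and `scripts/acceptance.py` on the planted
single-QTL design (228 progeny, 1 Mb contig, markers every ~500 bp, pools
of 20 at ≈ 0.9/0.1, depth 100, 20 seeded runs):

* null design (no planted effect): zero QTL calls in 20/20 runs;
* planted design: exactly one QTL called in 20/20 runs;
* the planted position falls inside the 1-LOD support interval in ~15/20
  runs.  The support intervals are 8–15 kb wide while the peak's
  positional scatter has a 1–3 kb tail beyond them: at this LOD scale
  (peaks ≈ 8–16) a 1-LOD drop is roughly a 75–85% positional interval for
  20-haplotype pools, not a 95% one.  Users who need calibrated coverage
  should widen the drop (e.g. 2-LOD) via `QtlCallParams.support_drop`.

## Known limitations

* The LOD statistic is a re-implementation of the Multipool model class,
  not a byte-level clone of the published tool; absolute LOD values depend
  on bin width and map-density settings, which are explicit parameters.
* With 20-strain pools, regions of genuine random composition divergence
  can approach the calling threshold; the 20 kb span and opposite-trend
  rules remove most but drift-driven calls cannot be excluded in
  principle at this pool size.
* Pleiotropy grouping is purely coordinate-based and sharing purely
  ortholog-based; partial overlaps of long intervals can chain distinct
  loci into one group (the group span is then flagged as a union).
* The logistic fit assumes a single growth phase; diauxic or lagged
  curves are fit poorly and only flagged through residual diagnostics.
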