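"""Synthetic F12 hybrid cross generator.

Emulates the study design this pipeline targets: a diploid inter-species
hybrid population (one recombinant haploid complement per parental species,
i.e. one haplotype per sub-genome), phenotyped as colony sizes with four
technical replicates, and sequenced as pooled extreme-tail selections.

The twelve meiotic cycles are modelled phenomenologically: haplotypes are
two-state Markov mosaics over the founder pair, with switch probability per
inter-marker gap given by the Haldane map function at a map distance
inflated by a single ``map_expansion`` multiplier.  Only the marginal
breakpoint density matters to the inference being exercised, so explicit
multi-generation pedigree simulation is deliberately avoided.

Determinism: every stage draws from ``default_rng([seed, stage_id, extra])``
where ``stage_id`` is fixed per operation (see ``_STAGE``) and ``extra``
is a CRC32 of any distinguishing label (condition, pool name), so stages
are independently reproducible from the single config seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .markers import ContigMap, MarkerPanel, MARKER_COLUMNS
from . import vcfio

_STAGE = {"markers": 0, "progeny": 1, "phenotypes": 2, "pool_reads": 3, "genes": 4}

_DEFAULT_CONTIGS = [
    ("Sc_chrI", 1_000_000, "Scer"),
    ("Sk_chrI", 1_000_000, "Skud"),
]
_DEFAULT_FOUNDERS = {"Scer": ("OS104", "OS253"), "Skud": ("IF01802", "OS575")}

_BASES = np.array(list("ACGT"))


def _crc(label: str) -> int:
    return zlib.crc32(label.encode()) & 0x7FFFFFFF


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic cross.

    Defaults follow the experimental design being emulated: 228 F12 diploid
    progeny, pools of 20 extremes, ~500 bp marker spacing, pooled depth 100.
    """

    seed: int = 0
    n_progeny: int = 228
    contigs: Sequence[tuple[str, int, str]] = field(
        default_factory=lambda: list(_DEFAULT_CONTIGS)
    )
    founders: dict[str, tuple[str, str]] = field(
        default_factory=lambda: dict(_DEFAULT_FOUNDERS)
    )
    marker_spacing_bp: float = 500.0
    bp_per_cM: float = 2_500.0
    map_expansion: float = 6.0
    read_depth: float = 100.0
    seq_error: float = 0.002
    founder_depth: int = 30
    replicate_cv: float = 0.10
    outlier_rate: float = 0.01
    pool_size: int = 20

    def __post_init__(self) -> None:
        if self.n_progeny < 2 * self.pool_size:
            raise ValueError(
                f"n_progeny ({self.n_progeny}) must be >= 2 * pool_size "
                f"({2 * self.pool_size})"
            )
        if not self.contigs:
            raise ValueError("at least one contig required")
        for name, length, sub in self.contigs:
            if length <= 0:
                raise ValueError(f"contig {name!r} has non-positive length")
            if sub not in self.founders:
                raise ValueError(f"contig {name!r}: unknown sub-genome {sub!r}")
        if not (0 <= self.seq_error < 0.5):
            raise ValueError("seq_error must be in [0, 0.5)")
        if self.map_expansion < 1:
            raise ValueError("map_expansion must be >= 1")
        if self.marker_spacing_bp <= 0 or self.bp_per_cM <= 0:
            raise ValueError("spacings must be positive")

    def rng(self, stage: str, extra: str = "") -> np.random.Generator:
        return np.random.default_rng(
            [self.seed, _STAGE[stage], _crc(extra)] if extra else
            [self.seed, _STAGE[stage]]
        )

    def contig_map(self) -> ContigMap:
        rows = []
        for name, length, sub in self.contigs:
            fa, fb = self.founders[sub]
            rows.append((name, length, sub, fa, fb))
        return ContigMap.from_records(rows)


@dataclass(frozen=True)
class Qtl:
    contig: str
    pos: int
    effect: float
    advantaged: str  # founder label whose allele raises the phenotype


@dataclass
class TraitModel:
    """Ground-truth additive trait architecture for one condition."""

    condition: str = "drug"
    qtls: Sequence[Qtl] = field(default_factory=list)
    baseline: float = 100.0
    noise_sd: float = 6.0

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (self.condition, q.contig, q.pos, q.effect, q.advantaged)
                for q in self.qtls
            ],
            columns=["condition", "contig", "pos", "effect", "advantaged"],
        )


@dataclass
class ProgenyGenome:
    """One diploid hybrid: a haplotype mosaic per contig (one per sub-genome).

    ``mosaics[contig] = (starts, labels)`` where ``starts`` are 1-based
    segment start positions (first is always 1) and ``labels`` the founder
    of origin per segment; segments tile the contig without gaps.
    """

    id: str
    mosaics: dict[str, tuple[np.ndarray, np.ndarray]]

    def origin_at(self, contig: str, positions: np.ndarray | int) -> np.ndarray:
        starts, labels = self.mosaics[contig]
        idx = np.searchsorted(starts, np.atleast_1d(positions), side="right") - 1
        return labels[idx]


def haldane_switch_prob(
    d_bp: np.ndarray | float, bp_per_cM: float, map_expansion: float = 1.0
) -> np.ndarray | float:
    """Founder-origin switch probability over a physical gap (Haldane)."""
    c = map_expansion * np.asarray(d_bp, dtype=float) / (100.0 * bp_per_cM)
    return 0.5 * (1.0 - np.exp(-2.0 * c))


def sim_founder_markers(config: SimConfig) -> tuple[MarkerPanel, pd.DataFrame]:
    """Draw marker positions and founder alleles.

    Positions have exponential spacing (mean ``marker_spacing_bp``) per
    contig; each marker gets distinct ref/alt nucleotides and a uniformly
    chosen alternate-carrying founder.  Returns the panel plus a long
    founder-allele table (contig, pos, founder, allele).
    """
    rng = config.rng("markers")
    rows, allele_rows = [], []
    for name, length, sub in config.contigs:
        n_draw = int(np.ceil(length / config.marker_spacing_bp * 2)) + 50
        gaps = rng.exponential(config.marker_spacing_bp, size=n_draw)
        pos = np.unique(np.floor(np.cumsum(gaps)).astype(np.int64) + 1)
        pos = pos[(pos >= 1) & (pos <= length)]
        fa, fb = config.founders[sub]
        for p in pos:
            ref, alt = rng.choice(_BASES, size=2, replace=False)
            alt_founder = fa if rng.random() < 0.5 else fb
            rows.append((name, int(p), sub, ref, alt, alt_founder))
            ref_founder = fb if alt_founder == fa else fa
            allele_rows.append((name, int(p), alt_founder, alt))
            allele_rows.append((name, int(p), ref_founder, ref))
    panel = MarkerPanel(pd.DataFrame(rows, columns=MARKER_COLUMNS), config.contig_map())
    alleles = pd.DataFrame(allele_rows, columns=["contig", "pos", "founder", "allele"])
    return panel, alleles


def sim_progeny(panel: MarkerPanel, config: SimConfig) -> list[ProgenyGenome]:
    """Simulate recombinant haplotype mosaics for every progeny.

    Two-state Markov chain over the marker grid: origin at the leftmost
    marker is Bernoulli(0.5); between markers d bp apart the origin switches
    with the Haldane probability at ``map_expansion`` times the nominal map
    distance.  Breakpoints are placed midway between flanking markers.
    """
    rng = config.rng("progeny")
    n = config.n_progeny
    mosaics: list[dict[str, tuple[np.ndarray, np.ndarray]]] = [
        {} for _ in range(n)
    ]
    for name, length, sub in config.contigs:
        fa, fb = config.founders[sub]
        founder_arr = np.array([fa, fb])
        mk = panel.df.loc[panel.df["contig"] == name, "pos"].to_numpy()
        if mk.size == 0:
            origin = (rng.random(n) < 0.5).astype(np.int8)
            for i in range(n):
                mosaics[i][name] = (
                    np.array([1], dtype=np.int64),
                    founder_arr[[origin[i]]],
                )
            continue
        r = haldane_switch_prob(np.diff(mk), config.bp_per_cM, config.map_expansion)
        init = rng.random(n) < 0.5
        switches = rng.random((n, mk.size - 1)) < r
        flips = np.concatenate(
            [np.zeros((n, 1), bool), np.logical_xor.accumulate(switches, axis=1)],
            axis=1,
        )
        states = (init[:, None] ^ flips).astype(np.int8)  # n x m, 0=fa 1=fb
        mids = (mk[:-1] + mk[1:]) // 2
        for i in range(n):
            s = states[i]
            change = np.flatnonzero(s[:-1] != s[1:])
            starts = np.concatenate(([1], mids[change] + 1)).astype(np.int64)
            labels = founder_arr[np.concatenate(([s[0]], s[change + 1]))]
            mosaics[i][name] = (starts, labels)
    return [
        ProgenyGenome(id=f"P{i:04d}", mosaics=m) for i, m in enumerate(mosaics)
    ]


def _qtl_genotypes(
    progeny: Sequence[ProgenyGenome], trait: TraitModel, config: SimConfig
) -> np.ndarray:
    """n_progeny x n_qtls indicator of carrying the advantaged allele."""
    known = {name for name, _, _ in config.contigs}
    geno = np.zeros((len(progeny), len(trait.qtls)))
    for j, q in enumerate(trait.qtls):
        if q.contig not in known:
            raise ValueError(f"QTL contig {q.contig!r} not among simulated contigs")
        for i, p in enumerate(progeny):
            geno[i, j] = p.origin_at(q.contig, q.pos)[0] == q.advantaged
    return geno


def sim_phenotypes(
    progeny: Sequence[ProgenyGenome], trait: TraitModel, config: SimConfig
) -> pd.DataFrame:
    """Colony-size table (strain, condition, rep1..rep4).

    True value = baseline + sum of carried QTL effects + N(0, noise_sd);
    each replicate multiplies it by LogNormal(0, replicate_cv), with an
    ``outlier_rate`` chance of a further uniform 3-10x inflation, floored
    at zero.
    """
    rng = config.rng("phenotypes", trait.condition)
    geno = _qtl_genotypes(progeny, trait, config)
    effects = np.array([q.effect for q in trait.qtls])
    true = trait.baseline + (geno @ effects if effects.size else 0.0)
    true = true + rng.normal(0.0, trait.noise_sd, size=len(progeny))
    n = len(progeny)
    mult = (
        np.exp(rng.normal(0.0, config.replicate_cv, size=(n, 4)))
        if config.replicate_cv > 0
        else np.ones((n, 4))
    )
    is_outlier = rng.random((n, 4)) < config.outlier_rate
    mult = np.where(is_outlier, mult * rng.uniform(3.0, 10.0, size=(n, 4)), mult)
    reps = np.maximum(true[:, None] * mult, 0.0)
    out = pd.DataFrame(
        {
            "strain": [p.id for p in progeny],
            "condition": trait.condition,
            "rep1": reps[:, 0],
            "rep2": reps[:, 1],
            "rep3": reps[:, 2],
            "rep4": reps[:, 3],
        }
    )
    return out


def sim_pool_reads(
    pool_members: Sequence[ProgenyGenome],
    panel: MarkerPanel,
    config: SimConfig,
    pool_label: str = "pool",
) -> pd.DataFrame:
    """Pooled read counts at every marker.

    At each marker the true alternate-founder frequency f is the fraction of
    member haplotypes whose origin is the marker's alt-carrying founder;
    depth ~ Poisson(read_depth) and the alternate-observation count
    AO ~ Binomial(depth, f(1-eps) + (1-f)eps), RO the remainder.

    Returns columns contig, pos, ref, alt, ro, ao, true_alt_freq.
    """
    if len(pool_members) == 0:
        raise ValueError("empty pool")
    rng = config.rng("pool_reads", pool_label)
    eps = config.seq_error
    frames = []
    for contig in panel.contig_map.contigs:
        sub = panel.df.loc[panel.df["contig"] == contig]
        if sub.empty:
            continue
        pos = sub["pos"].to_numpy()
        alt_founder = sub["alt_founder"].to_numpy()
        carries = np.stack(
            [p.origin_at(contig, pos) == alt_founder for p in pool_members]
        )
        f = carries.mean(axis=0)
        depth = rng.poisson(config.read_depth, size=pos.size)
        q = f * (1.0 - eps) + (1.0 - f) * eps
        ao = rng.binomial(depth, q)
        frames.append(
            pd.DataFrame(
                {
                    "contig": contig,
                    "pos": pos,
                    "ref": sub["ref"].to_numpy(),
                    "alt": sub["alt"].to_numpy(),
                    "ro": depth - ao,
                    "ao": ao,
                    "true_alt_freq": f,
                }
            )
        )
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["contig", "pos", "ref", "alt", "ro", "ao", "true_alt_freq"]
    )


def write_founder_vcfs(
    panel: MarkerPanel, config: SimConfig, outdir: str | Path
) -> dict[str, Path]:
    """One VCF per founder over that founder's sub-genome markers.

    The alternate-carrying founder gets a variant record (GT=1, AO=depth);
    the other founder gets a monomorphic reference record (ALT=".", GT=0)
    so its depth at the site is represented.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cmap = panel.contig_map
    paths: dict[str, Path] = {}
    for sub in cmap.sub_genomes:
        for founder in cmap.founders_of(sub):
            recs = []
            for contig in cmap.contigs_of(sub):
                for row in panel.df.loc[panel.df["contig"] == contig].itertuples():
                    alt = row.alt if row.alt_founder == founder else None
                    recs.append((contig, int(row.pos), row.ref, alt, config.founder_depth))
            path = outdir / f"founder_{founder}.vcf"
            vcfio.write_founder_vcf(path, founder, recs, cmap)
            paths[founder] = path
    return paths


def write_pool_vcf(
    counts: pd.DataFrame, panel: MarkerPanel, pool_name: str, path: str | Path
) -> Path:
    vcfio.write_pool_vcf(path, pool_name, counts, panel.contig_map)
    return Path(path)


def sim_genes(config: SimConfig, gene_span: int = 1_200, gap: int = 800) -> pd.DataFrame:
    """Synthetic gene features tiling each contig (for annotation tests)."""
    rows = []
    for name, length, sub in config.contigs:
        i = 0
        start = 1 + gap // 2
        while start + gene_span - 1 <= length:
            rows.append(
                (name, start, start + gene_span - 1, "+", f"{sub}_G{i:05d}", sub)
            )
            start += gene_span + gap
            i += 1
    return pd.DataFrame(
        rows, columns=["contig", "start", "end", "strand", "gene_id", "sub_genome"]
    )


def write_gff3(genes: pd.DataFrame, path: str | Path) -> Path:
    lines = ["##gff-version 3"]
    for row in genes.itertuples():
        lines.append(
            f"{row.contig}\thybridqtl\tgene\t{row.start}\t{row.end}\t.\t"
            f"{row.strand}\t.\tID={row.gene_id};Name={row.gene_id}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
    return Path(path)


def make_ortholog_table(genes: pd.DataFrame, sub_a: str, sub_b: str) -> pd.DataFrame:
    """Index-paired synthetic orthologs between two sub-genomes' gene sets."""
    ga = genes.loc[genes["sub_genome"] == sub_a, "gene_id"].tolist()
    gb = genes.loc[genes["sub_genome"] == sub_b, "gene_id"].tolist()
    n = min(len(ga), len(gb))
    return pd.DataFrame({"gene_a": ga[:n], "gene_b": gb[:n]})
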