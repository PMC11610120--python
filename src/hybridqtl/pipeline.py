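"""End-to-end orchestration: simulate -> phenotype -> pools -> markers ->
counts -> scan -> call -> compare, over plain TSV/VCF intermediates.

Every stage reads and writes files under one output directory, so runs are
diffable, resumable from any intermediate, and checksum-stable; the run
manifest records parameters, per-stage row counts and output checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import crosscompare, phenoscreen, poolcounts, qtlcall, synthcross
from .lodscan import LOD_CAP, LodModelParams, scan
from .markers import ContigMap, MarkerPanel, derive_markers, load_founder_variants
from .qtlcall import QtlCallParams, QtlInterval, annotate_all, intervals_to_frame
from .synthcross import Qtl, SimConfig, TraitModel

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Single-document configuration for a full pipeline run."""

    seed: int = 0
    out_dir: str | Path = "run"
    control_condition: str = "YPD"
    pool_size: int = 20
    sim: SimConfig | None = None
    traits: Sequence[TraitModel] = field(default_factory=list)
    markers_min_depth: int = 10
    counts_min_depth: int = 10
    scan_params: LodModelParams = field(default_factory=LodModelParams)
    call_params: QtlCallParams = field(default_factory=QtlCallParams)
    # external inputs, used when sim is None
    pheno_tsv: str | None = None
    founder_vcfs: dict[str, str] = field(default_factory=dict)
    contig_map_tsv: str | None = None
    pool_vcfs: dict[tuple[str, str], str] = field(default_factory=dict)
    gff: str | None = None
    orthologs_tsv: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim = None
        traits: list[TraitModel] = []
        if "simulate" in raw:
            s = dict(raw["simulate"])
            trait_specs = s.pop("traits", [])
            s["contigs"] = [tuple(c) for c in s.get("contigs", [])] or None
            if s["contigs"] is None:
                s.pop("contigs")
            sim = SimConfig(seed=raw.get("seed", 0), **s)
            for t in trait_specs:
                traits.append(
                    TraitModel(
                        condition=t["condition"],
                        qtls=[Qtl(*q) for q in t.get("qtls", [])],
                        baseline=t.get("baseline", 100.0),
                        noise_sd=t.get("noise_sd", 6.0),
                    )
                )
        scan_params = LodModelParams(**raw.get("scan", {}))
        call_params = QtlCallParams(**raw.get("call", {}))
        return cls(
            seed=raw.get("seed", 0),
            out_dir=raw.get("out_dir", "run"),
            control_condition=raw.get("control", "YPD"),
            pool_size=raw.get("pool_size", 20),
            sim=sim,
            traits=traits,
            markers_min_depth=raw.get("markers", {}).get("min_depth", 10),
            counts_min_depth=raw.get("counts", {}).get("min_depth", 10),
            scan_params=scan_params,
            call_params=call_params,
            pheno_tsv=raw.get("pheno_tsv"),
            founder_vcfs=raw.get("founder_vcfs", {}),
            contig_map_tsv=raw.get("contig_map"),
            gff=raw.get("gff"),
            orthologs_tsv=raw.get("orthologs"),
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def recommended_scan_params(sim: SimConfig, N: int | None = None) -> LodModelParams:
    """Scan settings matched to an F12 synthetic design.

    The chain's recombination kernel gets the *effective* map density
    (``bp_per_cM / map_expansion``): the pooled haplotypes are F12
    recombinants, so their founder-origin tracts decay at the expanded
    rate.  The bin width is set to about one eighth of the resulting mean
    linkage-block length (one Morgan of effective map), so that one bin
    holds approximately one effective draw of the pool composition — much
    finer and the pool-sampling noise is pseudo-replicated across bins,
    which inflates and sharpens LOD under the null; much coarser and
    peak localization degrades.
    """
    eff_bp_per_cM = sim.bp_per_cM / sim.map_expansion
    block_bp = 100.0 * eff_bp_per_cM  # one Morgan of effective map
    res = max(100, int(round(block_bp / 8.0 / 100.0)) * 100)
    return LodModelParams(
        N=N if N is not None else sim.pool_size,
        res_bp=res,
        bp_per_cM=eff_bp_per_cM,
        eps=sim.seq_error,
    )


def single_qtl_design(
    seed: int,
    effect: float = 12.0,
    qtl_pos: int | None = None,
    contig_length: int = 1_000_000,
    read_depth: float = 100.0,
    n_progeny: int = 228,
    condition: str = "drug",
) -> RunConfig:
    """The planted-single-QTL synthetic study design.

    One 1 Mb contig, markers every ~500 bp, 228 progeny, pools of 20,
    pooled depth 100; the planted additive effect (default 12 size units
    against noise_sd 6 plus replicate noise) puts the extreme pools near
    designated-allele frequencies of ~0.9 / ~0.1 at the locus.  An effect
    of 0 gives the matching null design.  When ``qtl_pos`` is omitted the
    locus is drawn per seed from the central 40-80% of the contig, so it
    holds no special alignment to any bin grid.
    """
    sim = SimConfig(
        seed=seed,
        n_progeny=n_progeny,
        contigs=[("Sc_chrI", contig_length, "Scer")],
        read_depth=read_depth,
    )
    if qtl_pos is None:
        qtl_pos = int(
            np.random.default_rng([seed, 99]).integers(
                int(0.3 * contig_length), int(0.7 * contig_length)
            )
        )
    qtls = [Qtl("Sc_chrI", qtl_pos, effect, "OS253")] if effect != 0 else []
    trait = TraitModel(condition=condition, qtls=qtls, baseline=100.0, noise_sd=6.0)
    return RunConfig(
        seed=seed, sim=sim, traits=[trait],
        scan_params=recommended_scan_params(sim),
    )


def planted_recovery_trial(
    seed: int, effect: float = 12.0, out_dir: str | Path | None = None
) -> dict[str, Any]:
    """One end-to-end run of the planted-single-QTL design.

    Returns the number of QTL calls, whether the planted position fell
    inside the (single) call's 1-LOD support interval, and the planted
    position itself.  With ``effect=0`` this is a null run and ``covered``
    is None.
    """
    import tempfile

    cfg = single_qtl_design(seed=seed, effect=effect)
    with tempfile.TemporaryDirectory() as tmp:
        cfg.out_dir = Path(out_dir) if out_dir is not None else Path(tmp) / "run"
        run_all(cfg)
        qtl = pd.read_csv(Path(cfg.out_dir) / "qtl.tsv", sep="\t")
        truth = pd.read_csv(Path(cfg.out_dir) / "truth.tsv", sep="\t")
    planted = int(truth["pos"].iloc[0]) if len(truth) else None
    covered = None
    if planted is not None:
        covered = bool(
            len(qtl) == 1
            and qtl["support_start"].iloc[0] <= planted <= qtl["support_end"].iloc[0]
        )
    return {"n_qtl": int(len(qtl)), "covered": covered, "planted": planted}


def run_all(config: RunConfig) -> dict[str, Any]:
    """Execute every stage; returns the run manifest (also written as JSON)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "seed": config.seed,
        "stages": {},
        "outputs": {},
        "parameters": {
            "pool_size": config.pool_size,
            "markers_min_depth": config.markers_min_depth,
            "counts_min_depth": config.counts_min_depth,
            "scan": {
                "N": config.scan_params.N,
                "res_bp": config.scan_params.res_bp,
                "bp_per_cM": config.scan_params.bp_per_cM,
                "eps": config.scan_params.eps,
            },
            "call": vars(config.call_params),
        },
    }

    def record(stage: str, name: str, df: pd.DataFrame, path: Path) -> None:
        df.to_csv(path, sep="\t", index=False)
        manifest["stages"].setdefault(stage, {})[name] = len(df)
        manifest["outputs"][str(path.name)] = _sha256(path)

    # --- stage: simulate -------------------------------------------------
    progeny_by_id: dict[str, synthcross.ProgenyGenome] = {}
    if config.sim is not None:
        sim = config.sim
        panel_truth, _ = synthcross.sim_founder_markers(sim)
        progeny = synthcross.sim_progeny(panel_truth, sim)
        progeny_by_id = {p.id: p for p in progeny}
        traits = list(config.traits)
        if not any(t.condition == config.control_condition for t in traits):
            traits.append(
                TraitModel(condition=config.control_condition, qtls=[],
                           baseline=traits[0].baseline if traits else 100.0,
                           noise_sd=traits[0].noise_sd if traits else 6.0)
            )
        pheno = pd.concat(
            [synthcross.sim_phenotypes(progeny, t, sim) for t in traits],
            ignore_index=True,
        )
        founder_paths = synthcross.write_founder_vcfs(panel_truth, sim, out)
        cmap = sim.contig_map()
        cmap.to_tsv(out / "contig_map.tsv")
        manifest["outputs"]["contig_map.tsv"] = _sha256(out / "contig_map.tsv")
        genes = synthcross.sim_genes(sim)
        synthcross.write_gff3(genes, out / "genes.gff3")
        manifest["outputs"]["genes.gff3"] = _sha256(out / "genes.gff3")
        subs = cmap.sub_genomes
        orth = (
            synthcross.make_ortholog_table(genes, subs[0], subs[1])
            if len(subs) >= 2
            else pd.DataFrame(columns=["gene_a", "gene_b"])
        )
        record("simulate", "orthologs", orth, out / "orthologs.tsv")
        truth_frames = [t.truth_frame() for t in traits if t.qtls]
        truth = (
            pd.concat(truth_frames, ignore_index=True)
            if truth_frames
            else TraitModel().truth_frame()
        )
        record("simulate", "truth", truth, out / "truth.tsv")
        record("simulate", "phenotypes", pheno, out / "pheno.tsv")
        config = _materialize(config, out, founder_paths)
    else:
        if not (config.pheno_tsv and config.founder_vcfs and config.contig_map_tsv):
            raise ValueError(
                "stage simulate disabled: pheno_tsv, founder_vcfs and "
                "contig_map are required inputs"
            )

    # --- stage: phenotype ------------------------------------------------
    pheno = pd.read_csv(config.pheno_tsv, sep="\t")
    summary = phenoscreen.summarize(pheno, control=config.control_condition)
    record("phenotype", "summary", summary, out / "pheno_summary.tsv")
    conditions = sorted(
        c for c in summary["condition"].unique() if c != config.control_condition
    )
    if not conditions:
        raise ValueError(
            "stage phenotype: no non-control conditions in the phenotype table"
        )
    pools: dict[str, phenoscreen.PoolAssignment] = {}
    pool_frames = []
    for cond in conditions:
        pools[cond] = phenoscreen.select_pools(summary, cond, n=config.pool_size)
        pool_frames.append(pools[cond].to_frame())
    record(
        "phenotype", "pools",
        pd.concat(pool_frames, ignore_index=True) if pool_frames
        else pd.DataFrame(columns=["condition", "pool", "strain"]),
        out / "pools.tsv",
    )

    # --- stage: markers --------------------------------------------------
    cmap = ContigMap.from_tsv(config.contig_map_tsv)
    sites = load_founder_variants(config.founder_vcfs, cmap)
    panel, rejections = derive_markers(sites, cmap, min_depth=config.markers_min_depth)
    record("markers", "panel", panel.df, out / "markers.tsv")
    record("markers", "rejections", rejections, out / "marker_rejections.tsv")
    if len(panel) == 0:
        raise RuntimeError("stage markers: derived an empty marker panel")

    # --- stage: pool sequencing (synthetic) ------------------------------
    if config.sim is not None:
        for cond in conditions:
            for label, members in (
                ("high", pools[cond].high_pool),
                ("low", pools[cond].low_pool),
            ):
                reads = synthcross.sim_pool_reads(
                    [progeny_by_id[s] for s in members],
                    panel,
                    config.sim,
                    pool_label=f"{cond}_{label}",
                )
                path = out / f"pool_{cond}_{label}.vcf"
                synthcross.write_pool_vcf(reads, panel, f"{cond}_{label}", path)
                manifest["outputs"][path.name] = _sha256(path)
                config.pool_vcfs[(cond, label)] = str(path)

    # --- stage: counts ---------------------------------------------------
    designated = poolcounts.default_designated(panel)
    count_frames = []
    for (cond, label), path in sorted(config.pool_vcfs.items()):
        track, report = poolcounts.count_alleles(
            path, panel, designated,
            min_depth=config.counts_min_depth, condition=cond, pool=label,
        )
        if track.empty:
            raise RuntimeError(
                f"stage counts: no usable markers in pool VCF {path}"
            )
        count_frames.append(track)
    counts = pd.concat(count_frames, ignore_index=True)
    record("counts", "counts", counts, out / "counts.tsv")

    # --- stage: scan + call ----------------------------------------------
    gene_table = (
        qtlcall.load_gene_table(config.gff) if config.gff
        else pd.DataFrame(columns=["contig", "start", "end", "gene_id"])
    )
    all_intervals: list[QtlInterval] = []
    lod_frames = []
    for cond in conditions:
        for sub in cmap.sub_genomes:
            lengths = {c: cmap.length_of(c) for c in cmap.contigs_of(sub)}
            th = counts.query(
                "condition == @cond and pool == 'high' and sub_genome == @sub"
            )
            tl = counts.query(
                "condition == @cond and pool == 'low' and sub_genome == @sub"
            )
            if th.empty and tl.empty:
                continue
            lod = scan(th, tl, config.scan_params, contig_lengths=lengths)
            lod["condition"] = cond
            lod["sub_genome"] = sub
            lod_frames.append(lod)
            ivs = qtlcall.call_intervals(
                lod, config.call_params, condition=cond, sub_genome=sub
            )
            all_intervals.extend(annotate_all(ivs, gene_table))
    lod_all = pd.concat(lod_frames, ignore_index=True)
    lod_all["lod"] = lod_all["lod"].clip(upper=LOD_CAP)
    record("scan", "lod", lod_all, out / "lod.tsv")
    qtl_df = intervals_to_frame(all_intervals)
    record("call", "qtl", qtl_df, out / "qtl.tsv")

    # --- stage: compare --------------------------------------------------
    groups = crosscompare.pleiotropic_groups(all_intervals)
    record(
        "compare", "pleiotropy",
        pd.DataFrame([g.to_row() for g in groups],
                     columns=["sub_genome", "contig", "start", "end",
                              "conditions", "genes", "span_is_union"]),
        out / "pleiotropy.tsv",
    )
    orth = (
        pd.read_csv(config.orthologs_tsv, sep="\t")
        if config.orthologs_tsv
        else pd.DataFrame(columns=["gene_a", "gene_b"])
    )
    shared_rows = []
    subs = cmap.sub_genomes
    if len(subs) >= 2 and not orth.empty:
        a_sub, b_sub = subs[0], subs[1]
        for cond in conditions:
            ia = [iv for iv in all_intervals if iv.sub_genome == a_sub]
            ib = [iv for iv in all_intervals if iv.sub_genome == b_sub]
            for sq in crosscompare.shared_across_subgenomes(ia, ib, orth, cond):
                shared_rows.append(sq.to_row())
    record(
        "compare", "shared",
        pd.DataFrame(shared_rows, columns=["condition", "sub_genome_a", "region_a",
                                           "sub_genome_b", "region_b", "orthologs"]),
        out / "shared.tsv",
    )
    record("compare", "summary", crosscompare.summarize_counts(all_intervals),
           out / "qtl_summary.tsv")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _materialize(
    config: RunConfig, out: Path, founder_paths: dict[str, Path]
) -> RunConfig:
    """Point the downstream stages at the files the simulate stage wrote."""
    config.pheno_tsv = str(out / "pheno.tsv")
    config.founder_vcfs = {k: str(v) for k, v in founder_paths.items()}
    config.contig_map_tsv = str(out / "contig_map.tsv")
    config.gff = str(out / "genes.gff3")
    config.orthologs_tsv = str(out / "orthologs.tsv")
    return config
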