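"""Synthetic cross generator: markers, mosaics, phenotypes, pooled reads."""

import numpy as np
import pandas as pd
import pytest

from hybridqtl import synthcross as sc
from hybridqtl.markers import load_founder_variants, derive_markers
from hybridqtl.synthcross import (
    ProgenyGenome, Qtl, SimConfig, TraitModel, haldane_switch_prob,
)


class TestConfigValidation:
    def test_pool_size_bound(self):
        with pytest.raises(ValueError, match="n_progeny"):
            SimConfig(n_progeny=10, pool_size=20)

    @pytest.mark.parametrize("kw", [
        {"seq_error": 0.6}, {"map_expansion": 0.5},
        {"contigs": [("c", -5, "Scer")]},
    ])
    def test_invalid_fields(self, kw):
        with pytest.raises(ValueError):
            SimConfig(**kw)


class TestFounderMarkers:
    def test_positions_bounded_sorted_unique(self):
        cfg = SimConfig(contigs=[("c", 10_000, "Scer")], marker_spacing_bp=500)
        panel, alleles = sc.sim_founder_markers(cfg)
        pos = panel.df["pos"].to_numpy()
        assert 5 <= len(pos) <= 60  # ~20 expected
        assert pos.min() >= 1 and pos.max() <= 10_000
        assert (np.diff(pos) > 0).all()
        # founder allele table lists both founders at every marker
        assert len(alleles) == 2 * len(pos)

    def test_deterministic_under_seed(self):
        cfg = SimConfig(contigs=[("c", 10_000, "Scer")], seed=3)
        p1, _ = sc.sim_founder_markers(cfg)
        p2, _ = sc.sim_founder_markers(cfg)
        pd.testing.assert_frame_equal(p1.df, p2.df)

    def test_degenerate_spacing(self):
        cfg = SimConfig(contigs=[("c", 10_000, "Scer")], marker_spacing_bp=1e9)
        panel, _ = sc.sim_founder_markers(cfg)
        assert len(panel) <= 1


class TestProgenyMosaics:
    def test_haldane_limits(self):
        assert haldane_switch_prob(0.0, 2500.0) == 0.0
        assert haldane_switch_prob(1e12, 2500.0) == pytest.approx(0.5)

    def test_zero_recombination_limit(self):
        cfg = SimConfig(
            contigs=[("c", 50_000, "Scer")], bp_per_cM=1e13, map_expansion=1.0,
            n_progeny=40,
        )
        panel, _ = sc.sim_founder_markers(cfg)
        progeny = sc.sim_progeny(panel, cfg)
        for p in progeny:
            starts, labels = p.mosaics["c"]
            assert len(labels) == 1  # one founder genome-wide

    def test_segments_tile_contig(self, small_config):
        panel, _ = sc.sim_founder_markers(small_config)
        for p in sc.sim_progeny(panel, small_config)[:10]:
            starts, labels = p.mosaics["chrA"]
            assert starts[0] == 1
            assert (np.diff(starts) > 0).all()
            # adjacent segments always switch founder
            assert all(labels[i] != labels[i + 1] for i in range(len(labels) - 1))

    def test_founder_origin_frequency_near_half(self):
        cfg = SimConfig(
            contigs=[("c", 20_000, "Scer")], n_progeny=500, seed=5
        )
        panel, _ = sc.sim_founder_markers(cfg)
        progeny = sc.sim_progeny(panel, cfg)
        pos = panel.df["pos"].to_numpy()[::10]
        for x in pos:
            freq = np.mean(
                [p.origin_at("c", x)[0] == "OS253" for p in progeny]
            )
            assert abs(freq - 0.5) <= 3 * np.sqrt(0.25 / 500)

    def test_switch_rate_matches_haldane(self):
        """Empirical switch rate across 1,000 haplotypes within 3 SE of the
        map function at the expanded distance."""
        cfg = SimConfig(
            contigs=[("c", 30_000, "Scer")], n_progeny=1000, seed=9,
            marker_spacing_bp=2_000,
        )
        panel, _ = sc.sim_founder_markers(cfg)
        progeny = sc.sim_progeny(panel, cfg)
        pos = panel.df["pos"].to_numpy()
        origins = np.stack([p.origin_at("c", pos) for p in progeny])
        for i in range(len(pos) - 1):
            r_hat = np.mean(origins[:, i] != origins[:, i + 1])
            r = haldane_switch_prob(
                pos[i + 1] - pos[i], cfg.bp_per_cM, cfg.map_expansion
            )
            se = np.sqrt(r * (1 - r) / 1000)
            assert abs(r_hat - r) <= 3 * se + 1e-12


class TestPhenotypes:
    def test_noise_free_bimodality(self, small_config):
        cfg = small_config
        cfg.replicate_cv = 0.0
        cfg.outlier_rate = 0.0
        panel, _ = sc.sim_founder_markers(cfg)
        progeny = sc.sim_progeny(panel, cfg)
        trait = TraitModel(
            condition="drug", qtls=[Qtl("chrA", 50_000, 7.0, "OS253")],
            baseline=100.0, noise_sd=0.0,
        )
        pheno = sc.sim_phenotypes(progeny, trait, cfg)
        values = np.unique(pheno[["rep1", "rep2", "rep3", "rep4"]].to_numpy())
        assert set(np.round(values, 9)) == {100.0, 107.0}

    def test_zero_effect_uncorrelated_with_genotype(self):
        cfg = SimConfig(contigs=[("c", 20_000, "Scer")], n_progeny=500, seed=2)
        panel, _ = sc.sim_founder_markers(cfg)
        progeny = sc.sim_progeny(panel, cfg)
        trait = TraitModel(
            condition="drug", qtls=[Qtl("c", 10_000, 0.0, "OS253")], noise_sd=5.0
        )
        pheno = sc.sim_phenotypes(progeny, trait, cfg)
        geno = np.array([p.origin_at("c", 10_000)[0] == "OS253" for p in progeny])
        med = pheno[["rep1", "rep2", "rep3", "rep4"]].median(axis=1)
        assert abs(np.corrcoef(geno, med)[0, 1]) < 0.15

    def test_four_replicates_per_row(self, small_config, single_qtl_trait):
        panel, _ = sc.sim_founder_markers(small_config)
        progeny = sc.sim_progeny(panel, small_config)
        pheno = sc.sim_phenotypes(progeny, single_qtl_trait, small_config)
        assert list(pheno.columns) == [
            "strain", "condition", "rep1", "rep2", "rep3", "rep4"
        ]
        assert len(pheno) == small_config.n_progeny
        assert pheno[["rep1", "rep2", "rep3", "rep4"]].notna().all().all()

    def test_unknown_qtl_contig_raises(self, small_config):
        panel, _ = sc.sim_founder_markers(small_config)
        progeny = sc.sim_progeny(panel, small_config)
        trait = TraitModel(qtls=[Qtl("nope", 1, 1.0, "OS253")])
        with pytest.raises(ValueError, match="nope"):
            sc.sim_phenotypes(progeny, trait, small_config)


def _fixed_progeny(panel, labels):
    """Progeny each carrying a single founder genome-wide."""
    out = []
    for i, lab in enumerate(labels):
        mosaics = {
            c: (np.array([1]), np.array([lab])) for c in panel.contig_map.contigs
        }
        out.append(ProgenyGenome(id=f"F{i}", mosaics=mosaics))
    return out


class TestPoolReads:
    def test_fixed_pool_all_designated(self, small_config):
        cfg = small_config
        cfg.seq_error = 0.0
        panel, _ = sc.sim_founder_markers(cfg)
        # every member is pure OS253: at markers where OS253 is alt, ao=d
        members = _fixed_progeny(panel, ["OS253"] * 20)
        reads = sc.sim_pool_reads(members, panel, cfg)
        alt_is_253 = panel.df["alt_founder"].to_numpy() == "OS253"
        assert (reads.loc[alt_is_253, "ro"] == 0).all()
        assert (reads.loc[~alt_is_253, "ao"] == 0).all()
        assert (reads["true_alt_freq"] == alt_is_253.astype(float)).all()

    def test_empty_pool_raises(self, small_config):
        panel, _ = sc.sim_founder_markers(small_config)
        with pytest.raises(ValueError, match="empty pool"):
            sc.sim_pool_reads([], panel, small_config)

    def test_mean_frequency_half_at_depth_50(self):
        cfg = SimConfig(
            contigs=[("c", 500_000, "Scer")], read_depth=50, seed=21,
            n_progeny=40,
        )
        panel, _ = sc.sim_founder_markers(cfg)  # ~1000 markers
        members = _fixed_progeny(panel, ["OS253"] * 10 + ["OS104"] * 10)
        reads = sc.sim_pool_reads(members, panel, cfg)
        assert len(reads) > 700
        assert abs((reads["ao"] / (reads["ro"] + reads["ao"])).mean() - 0.5) < 0.02


class TestVcfRoundTrip:
    def test_founder_panel_round_trip(self, small_config, tmp_path):
        panel, _ = sc.sim_founder_markers(small_config)
        paths = sc.write_founder_vcfs(panel, small_config, tmp_path)
        sites = load_founder_variants(paths, panel.contig_map)
        derived, report = derive_markers(sites, panel.contig_map, min_depth=10)
        pd.testing.assert_frame_equal(
            derived.df, panel.df, check_dtype=False
        )

    def test_empty_panel_writes_header_only(self, small_config, tmp_path):
        panel, _ = sc.sim_founder_markers(small_config)
        panel.df = panel.df.iloc[0:0]
        paths = sc.write_founder_vcfs(panel, small_config, tmp_path)
        text = list(paths.values())[0].read_text()
        assert all(line.startswith("#") for line in text.strip().splitlines())
        sites = load_founder_variants(paths, panel.contig_map)
        assert sites.empty

    def test_pool_counts_survive_round_trip(self, small_config, tmp_path):
        from hybridqtl.poolcounts import _read_pool_vcf

        panel, _ = sc.sim_founder_markers(small_config)
        row = panel.df.iloc[0]
        counts = pd.DataFrame(
            {"contig": [row.contig], "pos": [row.pos], "ref": [row.ref],
             "alt": [row.alt], "ro": [12], "ao": [8]}
        )
        path = tmp_path / "pool.vcf"
        sc.write_pool_vcf(counts, panel, "pool", path)
        back = _read_pool_vcf(path)
        assert back.loc[0, "ro"] == 12 and back.loc[0, "ao"] == 8

    def test_byte_identical_outputs_under_same_config(self, small_config, tmp_path):
        panel, _ = sc.sim_founder_markers(small_config)
        a, b = tmp_path / "a", tmp_path / "b"
        pa = sc.write_founder_vcfs(panel, small_config, a)
        pb = sc.write_founder_vcfs(panel, small_config, b)
        for k in pa:
            assert pa[k].read_bytes() == pb[k].read_bytes()


class TestGenesAndOrthologs:
    def test_gff_and_ortholog_table(self, two_subgenome_config, tmp_path):
        genes = sc.sim_genes(two_subgenome_config)
        assert (genes["end"] > genes["start"]).all()
        path = sc.write_gff3(genes, tmp_path / "genes.gff3")
        from hybridqtl.qtlcall import load_gene_table

        table = load_gene_table(path)
        assert len(table) == len(genes)
        orth = sc.make_ortholog_table(genes, "Scer", "Skud")
        assert not orth.empty
        assert orth["gene_a"].str.startswith("Scer").all()
        assert orth["gene_b"].str.startswith("Skud").all()
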