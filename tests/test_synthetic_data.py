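from __future__ import annotations

import numpy as np
import pytest

from snpchrom.genomic_io import GenomicSite
from snpchrom.snp_catalog import NINE_CATEGORIES
from snpchrom.synthetic_data import (
    SimulationConfig,
    make_genome,
    plant_mutation_sites,
    plant_snps,
    simulate_dataset,
    simulate_gc_biased_tags,
    simulate_hm_tags,
    simulate_methylation,
    simulate_nucleosome_tags,
    uniform_snp_positions,
)


def small_config(**overrides):
    defaults = dict(
        genome_length=120_000,
        master_seed=1,
        mutation_n_sites=500,
        mutation_half_window=1000,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


class TestConfig:
    def test_substitution_probs_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SimulationConfig(substitution_probs={"A/G": 0.5, "C/T": 0.4})

    def test_from_dict_rejects_unknown_keys(self):
        with pytest.raises(ValueError, match="unknown"):
            SimulationConfig.from_dict({"not_a_knob": 1})

    def test_closed_form_folds(self):
        cfg = small_config(
            mutation_snp_density=0.004,
            mutation_p_enrich=0.8 * 0.004,
            mutation_p_deplete=0.5,
        )
        assert cfg.expected_fold_flank == pytest.approx(1.4)
        assert cfg.expected_fold_center == pytest.approx(0.5)


class TestMakeGenome:
    def test_all_gc(self):
        cfg = small_config(gc_by_class={k: 1.0 for k in
                          ["exon", "utr5", "utr3", "intron", "near_gene_5",
                           "near_gene_3", "intergenic"]})
        genome, _ = make_genome(cfg)
        seq = genome.sequences[cfg.chrom]
        assert set(seq) <= {"G", "C"}

    def test_deterministic_for_seed(self):
        cfg = small_config()
        g1, _ = make_genome(cfg)
        g2, _ = make_genome(cfg)
        assert g1.sequences == g2.sequences

    def test_realized_gc_within_3se(self):
        cfg = small_config()
        genome, annotation = make_genome(cfg)
        seq = genome.sequences[cfg.chrom]
        iv = annotation.regions["intron"][0]
        target = cfg.gc_by_class["intron"]
        sub = seq[iv.start : iv.end]
        gc = sum(b in "GC" for b in sub) / len(sub)
        se = np.sqrt(target * (1 - target) / len(sub))
        assert abs(gc - target) < 3.5 * se

    def test_annotation_covers_all_classes(self):
        _, annotation = make_genome(small_config())
        for region in ("exon", "intron", "utr5", "utr3", "near_gene_5",
                       "near_gene_3", "intergenic"):
            assert annotation.total_length(region) > 0

    def test_sinusoidal_gc(self):
        cfg = small_config(gc_sinusoid=(0.5, 0.3, 5000))
        genome, _ = make_genome(cfg)
        seq = genome.sequences[cfg.chrom]
        # quarter-period windows at the crest and trough differ strongly
        crest = seq[1000:1500]
        trough = seq[3500:4000]
        gc = lambda s: sum(b in "GC" for b in s) / len(s)
        assert gc(crest) - gc(trough) > 0.3


class TestPlantSnps:
    def test_zero_density_empty(self):
        cfg = small_config(snp_density={})
        genome, annotation = make_genome(cfg)
        records, risk = plant_snps(cfg, genome, annotation, np.random.default_rng(0))
        assert records == [] and risk == []

    def test_reference_allele_matches_genome(self):
        cfg = small_config()
        genome, annotation = make_genome(cfg)
        records, _ = plant_snps(cfg, genome, annotation, np.random.default_rng(0))
        seq = genome.sequences[cfg.chrom]
        for rec in records[:200]:
            if rec.observed_alleles is not None:
                assert rec.observed_alleles[0] == seq[rec.site.pos]

    def test_coding_snps_inside_exons(self):
        cfg = small_config()
        genome, annotation = make_genome(cfg)
        records, _ = plant_snps(cfg, genome, annotation, np.random.default_rng(0))
        exons = annotation.regions["exon"]
        for rec in records:
            if rec.func_category == "coding_synonymous":
                assert any(iv.start <= rec.site.pos < iv.end for iv in exons)

    def test_categories_are_canonical(self):
        cfg = small_config()
        genome, annotation = make_genome(cfg)
        records, _ = plant_snps(cfg, genome, annotation, np.random.default_rng(0))
        assert {r.func_category for r in records} <= set(NINE_CATEGORIES)


class TestNucleosomeTags:
    def test_zero_coverage_and_background_empty(self):
        cfg = small_config(coverage_per_dyad=0.0, nucleosome_background_rate=0.0)
        genome, annotation = make_genome(cfg)
        records, risk = plant_snps(cfg, genome, annotation, np.random.default_rng(0))
        tags = simulate_nucleosome_tags(cfg, genome, records, np.random.default_rng(0))
        assert tags.total_tag_count == 0

    def test_tags_within_genome(self):
        cfg = small_config()
        data = simulate_dataset(cfg)
        L = cfg.genome_length
        for iv in data.nucleosome_tags.intervals[:500]:
            assert 0 <= iv.start < iv.end <= L


class TestHmTags:
    def test_zero_baseline_and_background_empty(self):
        cfg = small_config(hm_baseline=0.0, hm_background_rate=0.0)
        data = simulate_dataset(cfg)
        for tags in data.hm_tags.values():
            assert tags.total_tag_count == 0

    def test_one_tagset_per_mark(self):
        cfg = small_config()
        data = simulate_dataset(cfg)
        assert set(data.hm_tags) == set(cfg.hm_types)


class TestMutationModel:
    def test_uniform_positions_density(self):
        cfg = small_config(genome_length=500_000, mutation_snp_density=0.01)
        pos = uniform_snp_positions(cfg, np.random.default_rng(0))
        se = np.sqrt(0.01 * 0.99 * 500_000)
        assert abs(len(pos) - 5000) < 4 * se

    def test_depletion_probability_one_removes_all(self):
        cfg = small_config(
            genome_length=500_000,
            mutation_n_sites=2000,
            mutation_p_deplete=1.0,
            mutation_p_enrich=0.0,
            mutation_snp_density=0.01,
        )
        rng = np.random.default_rng(0)
        bg = uniform_snp_positions(cfg, rng)
        muts, snps = plant_mutation_sites(cfg, bg, rng)
        assert not np.isin(snps, muts).any()

    def test_enrichment_adds_at_plus_minus_one(self):
        cfg = small_config(
            genome_length=500_000,
            mutation_n_sites=2000,
            mutation_p_deplete=0.0,
            mutation_p_enrich=1.0,
            mutation_snp_density=0.0,
        )
        rng = np.random.default_rng(0)
        muts, snps = plant_mutation_sites(cfg, np.empty(0, dtype=np.int64), rng)
        assert len(snps) == 2000
        offsets = np.abs(snps[:, None] - muts[None, :]).min(axis=1)
        assert set(offsets.tolist()) <= {0, 1}  # 0 only via adjacent mutations


class TestMethylation:
    def test_levels_clipped(self):
        cfg = small_config(meth_sd=60.0)
        data = simulate_dataset(cfg)
        levels = [lvl for _, lvl in data.methylation.sites]
        assert levels and min(levels) >= 0.0 and max(levels) <= 100.0

    def test_identical_class_means_symmetric(self):
        cfg = small_config(meth_class_means={"neutral": 60.0, "risk": 60.0})
        data = simulate_dataset(cfg)
        levels = np.array([lvl for _, lvl in data.methylation.sites])
        assert abs(levels.mean() - 60.0) < 2.0


class TestGcBiasedTags:
    def test_density_follows_gc_weight(self):
        cfg = small_config(genome_length=200_000, gc_sinusoid=(0.5, 0.25, 5000))
        rng = np.random.default_rng(3)
        genome, _ = make_genome(cfg, rng)
        tags = simulate_gc_biased_tags(genome, cfg.chrom, rng, n_tags=20_000,
                                       peak_gc=0.54, width=0.05)
        assert tags.total_tag_count == 40_000  # one pair per dyad
        strands = {iv.strand for iv in tags.intervals}
        assert strands == {"+", "-"}


class TestFullDataset:
    def test_full_determinism(self):
        cfg = small_config()
        d1 = simulate_dataset(cfg)
        d2 = simulate_dataset(cfg)
        assert d1.genome.sequences == d2.genome.sequences
        assert d1.snps == d2.snps
        assert d1.nucleosome_tags.intervals == d2.nucleosome_tags.intervals
        assert np.array_equal(d1.mutation_sites, d2.mutation_sites)
        assert np.array_equal(d1.mutation_snp_positions, d2.mutation_snp_positions)
        assert d1.methylation.sites == d2.methylation.sites

    def test_write_outputs_round_trip(self, tmp_path):
        from snpchrom.genomic_io import (
            read_genome_fasta,
            read_methylation_table,
            read_site_table,
            read_snp_table,
            read_tag_bed,
        )

        cfg = small_config()
        data = simulate_dataset(cfg, outdir=tmp_path)
        genome = read_genome_fasta(tmp_path / "genome.fa")
        assert genome.sequences == data.genome.sequences
        tags = read_tag_bed(tmp_path / "nucleosome_tags.bed")
        assert tags.intervals == data.nucleosome_tags.intervals
        snps = read_snp_table(tmp_path / "snps.tsv")
        assert len(snps) == len(data.snps)
        muts = read_site_table(tmp_path / "mutation_sites.tsv")
        assert [s.pos for s in muts] == data.mutation_sites.tolist()
        track = read_methylation_table(tmp_path / "methylation.tsv")
        assert track.sites == data.methylation.sites
        assert (tmp_path / "ground_truth.json").exists()
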