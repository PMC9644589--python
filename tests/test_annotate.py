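import numpy as np
import pytest

from iskit.annotate import (
    annotate_sites,
    chrom_distribution,
    feature_coverage,
    gene_density,
    hotspot_tally,
    presence_matrix,
    tss_profile,
)
from iskit.iscall import IntegrationSite
from iskit.refmodel import AnnotationParams, Genome, build_feature_index
from iskit.simjunction import PRESETS, SimConfig, plant_sites, simulate_reference, simulate_sample


def _site(chrom, pos, strand="+", n_reads=1, n_frags=None, sample="S"):
    return IntegrationSite(sample, chrom, pos, strand, n_reads, n_frags or n_reads, f"{chrom}:{pos}")


def _truth_sites(sim, weight_col=None):
    """Sites straight from the planted truth, read counts from emitted pairs."""
    reads_per_site = sim.fragments.groupby("site_id")["n_copies"].sum()
    return [
        IntegrationSite(
            sim.sample_id, r.chrom, r.pos, r.strand,
            int(reads_per_site.get(r.site_id, 0)), int(r.n_fragments_emitted), r.site_id,
        )
        for r in sim.truth.itertuples(index=False)
    ]


class TestAnnotateSites:
    def test_promoter_upstream_site(self, toy_index):
        (a,) = annotate_sites([_site("chr1", 9001)], toy_index)
        assert (a.feature_class, a.gene_id, a.dist_to_tss) == ("promoter", "G", -1000)

    def test_exon_site(self, toy_index):
        (a,) = annotate_sites([_site("chr1", 11500)], toy_index)
        assert (a.feature_class, a.gene_id) == ("exon", "G")

    def test_unknown_chromosome_errors_with_site_names(self, toy_index):
        with pytest.raises(KeyError, match="chrX"):
            annotate_sites([_site("chrX", 5)], toy_index)

    def test_agrees_with_brute_force_on_simulation(self, small_clean_sim):
        from conftest import brute_force_classify

        sim = small_clean_sim
        sites = _truth_sites(sim)
        annotated = annotate_sites(sites, sim.index)
        for a in annotated:
            expected = brute_force_classify(sim.models, sim.index.params, a.chrom, a.pos)
            assert (a.feature_class, a.gene_id, a.dist_to_tss) == expected


class TestFeatureCoverage:
    def test_all_promoter_reads(self, toy_index):
        ann = annotate_sites([_site("chr1", 9001, n_reads=5), _site("chr1", 8500, n_reads=3)], toy_index)
        cov = feature_coverage(ann, "reads")
        assert cov.percentages["promoter"] == 100.0
        assert sum(v for k, v in cov.percentages.items() if k != "promoter") == 0.0

    def test_percentages_sum_to_100(self, small_clean_sim):
        ann = annotate_sites(_truth_sites(small_clean_sim), small_clean_sim.index)
        for mode in ("reads", "sites"):
            cov = feature_coverage(ann, mode)
            assert sum(cov.percentages.values()) == pytest.approx(100.0, abs=1e-9)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            feature_coverage([])

    def test_reads_and_sites_modes_differ_when_weights_skew(self, toy_index):
        ann = annotate_sites([_site("chr1", 9001, n_reads=99), _site("chr1", 11500, n_reads=1)], toy_index)
        assert feature_coverage(ann, "reads").percentages["promoter"] == 99.0
        assert feature_coverage(ann, "sites").percentages["promoter"] == 50.0

    def test_retro_preset_recovered_within_two_points(self):
        cfg = SimConfig(seed=1, vector_preset="retro", error_rate=0.0, dup_rate=0.0)
        sim = simulate_sample(cfg)
        ann = annotate_sites(_truth_sites(sim), sim.index)
        cov = feature_coverage(ann, "reads")
        for cls, expected in PRESETS["retro"].items():
            assert abs(cov.percentages[cls] - 100 * expected) <= 2.0, cls


class TestChromDistribution:
    def test_single_chromosome(self, toy_index):
        ann = annotate_sites([_site("chr1", 9001)], toy_index)
        assert chrom_distribution(ann) == {"chr1": 100.0}

    def test_uniform_planting_over_equal_chromosomes(self):
        cfg = SimConfig(
            seed=17, n_sites=2000, n_genes=0,
            feature_proportions={"intergenic": 1.0}, vector_preset="custom",
        )
        genome, models = simulate_reference(cfg)
        index = build_feature_index(models, cfg.annotation, chromosomes=genome.lengths)
        truth = plant_sites(cfg, genome, index)
        sites = [_site(r.chrom, r.pos, r.strand) for r in truth.itertuples(index=False)]
        dist = chrom_distribution(annotate_sites(sites, index))
        for chrom in genome.lengths:
            # 4 sigma binomial bound at n=2000, p=1/3
            assert abs(dist[chrom] - 100 / 3) < 400 * np.sqrt((1 / 3) * (2 / 3) / 2000)

    def test_gene_dense_chromosome_over_represented_under_genic_preset(self, small_clean_sim):
        sim = small_clean_sim
        dist = chrom_distribution(annotate_sites(_truth_sites(sim), sim.index))
        densities = gene_density(sim.models, sim.genome)
        densest = max(densities, key=densities.get)
        assert dist[densest] > 100 / len(sim.genome.lengths)


class TestGeneDensity:
    def test_counts_per_megabase(self):
        genome = Genome({"chr1": "A" * 1_000_000, "chr2": "C" * 500_000})
        from iskit.refmodel import GeneModel

        models = [
            GeneModel(f"G{i}", "chr1", "+", (1000 * i + 1, 1000 * i + 500), [(1000 * i + 1, 1000 * i + 500)])
            for i in range(10)
        ]
        dens = gene_density(models, genome)
        assert dens == {"chr1": 10.0, "chr2": 0.0}

    def test_recomputes_from_simulator_placement(self):
        genome, models = simulate_reference(SimConfig(seed=5))
        dens = gene_density(models, genome)
        for chrom in genome.lengths:
            n = sum(m.chrom == chrom for m in models)
            assert dens[chrom] == pytest.approx(n / (genome.lengths[chrom] / 1e6))


class TestTssProfile:
    def test_point_mass_lands_in_single_bin(self, toy_index):
        ann = annotate_sites([_site("chr1", 9001, n_reads=7)], toy_index)  # dist -1000
        prof = tss_profile(ann, toy_index)
        nz = np.flatnonzero(prof.signal)
        assert len(nz) == 1
        assert prof.edges[nz[0]] <= -1000 < prof.edges[nz[0] + 1]
        assert prof.signal.sum() == pytest.approx(1.0)

    def test_no_reads_in_window_flagged_empty(self, toy_index):
        ann = annotate_sites([_site("chr1", 50000)], toy_index)
        prof = tss_profile(ann, toy_index)
        assert prof.empty and prof.signal.sum() == 0

    def test_bin_size_must_divide_window(self, toy_index):
        with pytest.raises(ValueError):
            tss_profile([], toy_index, AnnotationParams(tss_window=3000, tss_bin=70))

    def test_symmetric_planting_gives_symmetric_profile(self, rng):
        genome, models = simulate_reference(SimConfig(seed=23, n_genes=30, chrom_len=200_000))
        index = build_feature_index(models, chromosomes=genome.lengths)
        sites = []
        n = 400
        for _ in range(n):
            m = models[rng.integers(len(models))]
            offset = int(rng.integers(1, 2000)) * (1 if rng.random() < 0.5 else -1)
            pos = m.tss + offset if m.strand == "+" else m.tss - offset
            if 1 <= pos <= genome.lengths[m.chrom]:
                sites.append(_site(m.chrom, pos))
        prof = tss_profile(annotate_sites(sites, index), index, weight_mode="sites")
        half = len(prof.signal) // 2
        up, down = prof.signal[:half].sum(), prof.signal[half:].sum()
        sd = np.sqrt(0.25 / prof.n_in_window)
        assert abs(up - down) < 6 * sd  # 3 sigma on each half


class TestHotspots:
    def _cohort(self, n_samples=5):
        genome, models = simulate_reference(SimConfig(seed=41, n_genes=30, chrom_len=200_000))
        index = build_feature_index(models, chromosomes=genome.lengths)
        per_sample = {}
        for i in range(n_samples):
            cfg = SimConfig(
                seed=400 + i, n_sites=120, vector_preset="retro",
                n_genes=30, chrom_len=200_000,
            )
            truth = plant_sites(cfg, genome, index)
            sites = [
                IntegrationSite(f"S{i}", r.chrom, r.pos, r.strand, 1, 1, r.site_id)
                for r in truth.itertuples(index=False)
            ]
            per_sample[f"S{i}"] = annotate_sites(sites, index)
        return index, per_sample

    def test_matrix_matches_brute_force_interval_counts(self):
        index, per_sample = self._cohort()
        mat = hotspot_tally(per_sample, "promoter")
        for gene in mat.index:
            intervals = index.feature_intervals(gene, "promoter")
            for sid, annotated in per_sample.items():
                brute = sum(
                    a.chrom == index.gene(gene).chrom and any(lo <= a.pos <= hi for lo, hi in intervals)
                    for a in annotated
                )
                assert mat.loc[gene, sid] == brute

    def test_gene_hit_in_all_samples_ranks_first(self, toy_index):
        per_sample = {
            sid: annotate_sites([_site("chr1", 9001, sample=sid)], toy_index) for sid in ("A", "B", "C")
        }
        mat = hotspot_tally(per_sample, "promoter")
        assert list(mat.index)[0] == "G"

    def test_zscore_rows_standardized(self):
        _, per_sample = self._cohort()
        mat = hotspot_tally(per_sample, "promoter", zscore=True)
        raw = hotspot_tally(per_sample, "promoter")
        varying = raw.std(axis=1, ddof=0) > 0
        assert np.allclose(mat.loc[varying].mean(axis=1), 0, atol=1e-12)
        assert np.allclose(mat.loc[varying].std(axis=1, ddof=0), 1, atol=1e-12)
        assert (mat.loc[~varying] == 0).all().all()

    def test_sample_permutation_invariance(self):
        _, per_sample = self._cohort(4)
        mat = hotspot_tally(per_sample, "exon")
        reordered = dict(reversed(list(per_sample.items())))
        mat2 = hotspot_tally(reordered, "exon")
        assert mat.sort_index(axis=1).equals(mat2.sort_index(axis=1).loc[mat.index])

    def test_unknown_region_class_rejected(self):
        with pytest.raises(ValueError):
            hotspot_tally({"S": []}, "intergenic")

    def test_presence_matrix_booleans(self, toy_index):
        per_sample = {
            "A": annotate_sites([_site("chr1", 9001, sample="A")], toy_index),
            "B": annotate_sites([_site("chr1", 50000, sample="B")], toy_index),
        }
        pm = presence_matrix(per_sample)
        assert pm.loc["G", "A"] and not pm.loc["G", "B"]
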