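import json

import numpy as np
import pytest

import hybridtrace as ht
from hybridtrace import simulate as sim
from hybridtrace.errors import ArgumentError


def small_config(**kw):
    defaults = dict(n_chromosomes=2, sites_per_chromosome=400, seed=1)
    defaults.update(kw)
    return ht.SimConfig(**defaults)


class TestConfig:
    def test_inconsistent_fractions_rejected(self):
        with pytest.raises(ArgumentError):
            ht.SimConfig(fixed_diff_fraction=0.8, within_pop_het_fraction=0.4)

    def test_invalid_rates_rejected(self):
        with pytest.raises(ArgumentError):
            ht.SimConfig(map_length=-1)
        with pytest.raises(ArgumentError):
            ht.SimConfig(error_rate=1.0)


class TestParentalPanels:
    def test_all_fixed_diff_all_recovered(self):
        cfg = small_config(fixed_diff_fraction=1.0, within_pop_het_fraction=0.0,
                           sites_per_chromosome=100, error_rate=0.0)
        ds = ht.simulate_dataset(cfg)
        ss = ht.find_discriminatory_sites(ds.matrix, "parentA", "parentB")
        assert len(ss) == 200

    def test_all_within_pop_poly_recovers_none(self):
        cfg = small_config(fixed_diff_fraction=0.0, within_pop_het_fraction=1.0,
                           sites_per_chromosome=100, error_rate=0.0)
        ds = ht.simulate_dataset(cfg)
        ss = ht.find_discriminatory_sites(ds.matrix, "parentA", "parentB")
        assert len(ss) == 0

    def test_panel_polymorphic_sites_segregate_in_panel(self):
        cfg = small_config(fixed_diff_fraction=0.0, within_pop_het_fraction=1.0)
        rng = np.random.default_rng(3)
        panelA, panelB, sites = sim.simulate_parental_panels(cfg, rng)
        for c in range(cfg.n_chromosomes):
            polyA = sites.role[c] == sim.ROLE_POLY_A
            haps = np.stack([ind.haplotypes[c][h] for ind in panelA for h in range(2)])
            assert not np.any(np.all(haps[:, polyA] == haps[:1, polyA], axis=0))

    def test_exact_role_counts(self):
        cfg = small_config(fixed_diff_fraction=0.5, within_pop_het_fraction=0.25)
        rng = np.random.default_rng(0)
        _, _, sites = sim.simulate_parental_panels(cfg, rng)
        for role in sites.role:
            assert int((role == sim.ROLE_FIXED_DIFF).sum()) == 200


class TestMeiosis:
    @pytest.fixture
    def mixed_parent(self):
        cfg = small_config()
        rng = np.random.default_rng(0)
        _, _, sites = sim.simulate_parental_panels(cfg, rng)
        parent = sim.draw_individual(sites, 0, rng)
        parent.haplotypes[0][0][:] = 0
        parent.haplotypes[0][1][:] = 1
        parent.ancestry[0][0][:] = 0
        parent.ancestry[0][1][:] = 1
        return parent

    def test_zero_map_length_returns_one_parental_haplotype(self, mixed_parent):
        rng = np.random.default_rng(1)
        seen = set()
        for _ in range(20):
            alleles, anc = sim.meiosis(mixed_parent, 0, 0.0, rng)
            assert len(set(alleles)) == 1  # no switching
            assert alleles[0] == anc[0]
            seen.add(int(alleles[0]))
        assert seen == {0, 1}  # both haplotypes chosen across draws

    def test_crossover_count_poisson_moment(self, mixed_parent):
        rng = np.random.default_rng(2)
        switches = []
        for _ in range(5000):
            alleles, _ = sim.meiosis(mixed_parent, 0, 2.0, rng)
            switches.append(int(np.count_nonzero(np.diff(alleles) != 0)))
        # observed haplotype switches track the Poisson(2) crossover count
        se = np.std(switches) / np.sqrt(len(switches))
        assert abs(np.mean(switches) - 2.0) < 3 * se + 0.05

    def test_f1_gamete_block_count(self, mixed_parent):
        rng = np.random.default_rng(3)
        blocks = [
            1 + int(np.count_nonzero(np.diff(sim.meiosis(mixed_parent, 0, 1.0, rng)[1]) != 0))
            for _ in range(4000)
        ]
        se = np.std(blocks) / np.sqrt(len(blocks))
        assert abs(np.mean(blocks) - 2.0) < 3 * se + 0.05


class TestMakeHybrid:
    def test_f1_heterozygous_at_every_diagnostic_site(self):
        cfg = small_config(error_rate=0.0)
        ds = ht.simulate_dataset(cfg, pedigree="F1")
        ss = ht.find_discriminatory_sites(ds.matrix, "parentA", "parentB")
        classes, table = ht.classify_focal_genotypes(ss, ds.matrix, "hybrid")
        assert set(classes["class"]) == {"Aa"}
        assert ds.truth["generation"] == 0

    def test_bc1f1_heterozygous_fraction(self):
        # average over replicates; per-genome fractions vary with linkage
        fracs = []
        for seed in range(1, 31):
            cfg = ht.SimConfig(n_chromosomes=4, sites_per_chromosome=500,
                               error_rate=0.0, seed=seed)
            ds = ht.simulate_dataset(cfg, pedigree="BC1F1")
            ss = ht.find_discriminatory_sites(ds.matrix, "parentA", "parentB")
            _, table = ht.classify_focal_genotypes(ss, ds.matrix, "hybrid")
            n = table.counts
            fracs.append(n[1] / sum(n))
        se = np.std(fracs) / np.sqrt(len(fracs))
        assert abs(np.mean(fracs) - 0.5) < 3 * se + 0.01

    def test_maternal_organelle_inheritance(self):
        cfg = small_config()
        ds_b = ht.simulate_dataset(cfg, pedigree="BC1F1", mother_species="B")
        assert ds_b.truth["organelle"] == "B"
        ds_a = ht.simulate_dataset(cfg, pedigree="BC1F1", mother_species="A")
        assert ds_a.truth["organelle"] == "A"

    def test_generation_labels(self):
        assert sim.pedigree_generation("F1") == 0
        assert sim.pedigree_generation("BC1F1") == 1
        assert sim.pedigree_generation("BC5F1") == 5
        assert sim.pedigree_generation(3) == 3
        with pytest.raises(ArgumentError):
            sim.pedigree_generation("F2")


class TestGenotypeError:
    def test_zero_rate_is_identity(self):
        rng = np.random.default_rng(0)
        gt = np.array([[0, 0], [0, 1], [1, 1]] * 10, dtype=np.int16)
        out = sim.apply_genotype_error(gt, 0.0, rng)
        assert np.array_equal(out, gt)

    def test_full_rate_uniform_over_three_classes(self):
        rng = np.random.default_rng(1)
        gt = np.zeros((30_000, 2), dtype=np.int16)
        out = sim.apply_genotype_error(gt, 0.999999, rng)
        labels = out.sum(axis=1)  # 0 -> hom ref, 1 -> het, 2 -> hom alt
        fracs = np.bincount(labels, minlength=3) / len(labels)
        se = np.sqrt((1 / 3) * (2 / 3) / len(labels))
        assert np.all(np.abs(fracs - 1 / 3) < 4 * se)

    def test_uniform_error_aa_fraction_is_one_third_of_rate(self):
        # BC1F1 with eps = 0.06: observed aa fraction ~ 0.02
        cfg = ht.SimConfig(n_chromosomes=5, sites_per_chromosome=3000,
                           error_rate=0.06, seed=9)
        ds = ht.simulate_dataset(cfg, pedigree="BC1F1")
        ss = ht.find_discriminatory_sites(ds.matrix, "parentA", "parentB")
        _, table = ht.classify_focal_genotypes(ss, ds.matrix, "hybrid")
        n = table.counts
        frac_aa = n[2] / sum(n)
        se = np.sqrt(0.02 * 0.98 / sum(n))
        assert abs(frac_aa - 0.02) < 4 * se

    def test_aa_flip_mode_gives_error_rate_exactly(self):
        cfg = ht.SimConfig(n_chromosomes=5, sites_per_chromosome=3000,
                           error_rate=0.05, seed=9)
        ds = ht.simulate_dataset(cfg, pedigree="BC1F1", error_mode="aa_flip")
        ss = ht.find_discriminatory_sites(ds.matrix, "parentA", "parentB")
        _, table = ht.classify_focal_genotypes(ss, ds.matrix, "hybrid")
        n = table.counts
        frac_aa = n[2] / sum(n)
        se = np.sqrt(0.05 * 0.95 / sum(n))
        assert abs(frac_aa - 0.05) < 4 * se


class TestWriteSimulatedVcf:
    def test_round_trip_and_sidecars(self, tmp_path, clean_bc1f1_dataset):
        paths = ht.write_simulated_vcf(clean_bc1f1_dataset, tmp_path)
        back = ht.read_vcf(paths["vcf"], paths["panels"])
        assert np.array_equal(back.gt, clean_bc1f1_dataset.matrix.gt)
        assert len(back.samples) == 3 + 3 + 1
        truth = json.loads(paths["truth"].read_text())
        assert truth["generation"] == 1
        # truth diagnostic list equals finder output on the clean data
        ss = ht.find_discriminatory_sites(back, "parentA", "parentB")
        n_truth = sum(len(v["diagnostic_index"]) for v in truth["chroms"].values())
        assert len(ss) == n_truth

    def test_seed_determinism_byte_identical(self, tmp_path):
        cfg = small_config(seed=17)
        for name in ("x", "y"):
            ds = ht.simulate_dataset(ht.SimConfig(**{**cfg.__dict__}), pedigree="BC1F1")
            ht.write_simulated_vcf(ds, tmp_path, prefix=name)
        assert (tmp_path / "x.vcf").read_bytes() == (tmp_path / "y.vcf").read_bytes()
        assert (tmp_path / "x.truth.json").read_text() == (tmp_path / "y.truth.json").read_text()

    def test_seed_recorded_in_header(self, tmp_path, clean_bc1f1_dataset):
        paths = ht.write_simulated_vcf(clean_bc1f1_dataset, tmp_path)
        header = paths["vcf"].read_text().split("#CHROM")[0]
        assert f"##hybridtrace_sim_seed={clean_bc1f1_dataset.config.seed}" in header
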