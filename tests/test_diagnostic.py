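import numpy as np
import pandas as pd
import pytest

import hybridtrace as ht
from hybridtrace.diagnostic import per_chromosome_summary, tabulate_classes
from hybridtrace.errors import ConfigurationError, DataError
from hybridtrace.variants_io import SamplePanel

from conftest import make_matrix

SAMPLES = ["a1", "a2", "a3", "hy", "b1", "b2", "b3"]
PANELS = {"parentA": ["a1", "a2", "a3"], "parentB": ["b1", "b2", "b3"], "focal": ["hy"]}


def seven_sample_matrix(records):
    return make_matrix(records, SAMPLES, panels=PANELS)


def site(chrom, pos, gA, ghy, gB, ref="C", alts=("T",)):
    """Three panel-A genotypes, the focal genotype, three panel-B genotypes."""
    return (chrom, pos, ref, list(alts), list(gA) + [ghy] + list(gB))


HOM0 = (0, 0)
HOM1 = (1, 1)
HET = (0, 1)


class TestFindDiscriminatorySites:
    def test_fixed_opposite_included_with_alleles(self):
        m = seven_sample_matrix([site("chr1", 10, [HOM0] * 3, HET, [HOM1] * 3)])
        ss = ht.find_discriminatory_sites(m, "parentA", "parentB")
        assert len(ss) == 1
        row = ss.table.iloc[0]
        assert (row["allele_A"], row["allele_a"]) == ("C", "T")

    def test_heterozygous_panel_sample_excluded(self):
        m = seven_sample_matrix([site("chr1", 10, [HOM0, HOM0, HET], HET, [HOM1] * 3)])
        assert len(ht.find_discriminatory_sites(m, "parentA", "parentB")) == 0

    def test_hand_enumerated_six_sites(self):
        records = [
            site("chr1", 10, [HOM0] * 3, HET, [HOM1] * 3),   # fixed opposite
            site("chr1", 20, [HOM1] * 3, HET, [HOM0] * 3),   # fixed opposite (swapped)
            site("chr1", 30, [HOM0] * 3, HOM0, [HOM0] * 3),  # shared fixed
            site("chr1", 40, [HOM0, HET, HOM0], HET, [HOM1] * 3),  # polymorphic in A
            site("chr1", 50, [HOM0] * 3, HET, [HOM1, HOM1, HET]),  # polymorphic in B
            site("chr2", 10, [HOM1] * 3, HET, [HOM0] * 3),   # fixed opposite
        ]
        ss = ht.find_discriminatory_sites(seven_sample_matrix(records), "parentA", "parentB")
        assert len(ss) == 3
        assert list(ss.table["pos"]) == [10, 20, 10]
        assert list(ss.table["chrom"]) == ["chr1", "chr1", "chr2"]

    def test_panels_sharing_sample_rejected(self):
        m = seven_sample_matrix([site("chr1", 10, [HOM0] * 3, HET, [HOM1] * 3)])
        with pytest.raises(ConfigurationError):
            ht.find_discriminatory_sites(
                m, SamplePanel("x", ("a1", "a2")), SamplePanel("y", ("a2", "b1"))
            )

    def test_frequency_threshold_mode(self):
        # 5/6 panel-A chromosomes carry the ref allele: excluded at strict
        # fixation but admitted at min_freq <= 5/6
        m = seven_sample_matrix([site("chr1", 10, [HOM0, HOM0, HET], HET, [HOM1] * 3)])
        assert len(ht.find_discriminatory_sites(m, "parentA", "parentB")) == 0
        assert len(ht.find_discriminatory_sites(m, "parentA", "parentB", min_freq=0.8)) == 1

    def test_symmetry_under_panel_swap(self, bc1f1_dataset):
        m = bc1f1_dataset.matrix
        fwd = ht.find_discriminatory_sites(m, "parentA", "parentB")
        rev = ht.find_discriminatory_sites(m, "parentB", "parentA")
        assert np.array_equal(fwd.site_index, rev.site_index)
        assert list(fwd.table["allele_A"]) == list(rev.table["allele_a"])
        cls_f, tab_f = ht.classify_focal_genotypes(fwd, m, "hybrid")
        cls_r, tab_r = ht.classify_focal_genotypes(rev, m, "hybrid")
        nf, nr = tab_f.counts, tab_r.counts
        assert (nf[0], nf[1], nf[2]) == (nr[2], nr[1], nr[0])
        swap = {"AA": "aa", "aa": "AA", "Aa": "Aa", "other": "other"}
        assert [swap[c] for c in cls_f["class"]] == list(cls_r["class"])

    def test_exact_recovery_on_clean_simulation(self, clean_bc1f1_dataset):
        ds = clean_bc1f1_dataset
        ss = ht.find_discriminatory_sites(ds.matrix, "parentA", "parentB")
        truth_idx = []
        offset = 0
        for name in ds.config.chrom_names:
            truth_idx.extend(i + offset for i in ds.truth["chroms"][name]["diagnostic_index"])
            offset += ds.config.sites_per_chromosome
        assert list(ss.site_index) == truth_idx


class TestClassifyFocalGenotypes:
    def test_heterozygote_is_Aa(self):
        m = seven_sample_matrix([site("chr1", 10, [HOM0] * 3, HET, [HOM1] * 3)])
        ss = ht.find_discriminatory_sites(m, "parentA", "parentB")
        classes, table = ht.classify_focal_genotypes(ss, m, "hy")
        assert list(classes["class"]) == ["Aa"]
        assert table.counts == (0, 1, 0)

    def test_third_allele_goes_to_other_bucket(self):
        # panels fixed on ref/alt1; focal carries alt2
        m = seven_sample_matrix(
            [site("chr1", 10, [HOM0] * 3, (0, 2), [HOM1] * 3, alts=("T", "G"))]
        )
        ss = ht.find_discriminatory_sites(m, "parentA", "parentB")
        classes, table = ht.classify_focal_genotypes(ss, m, "hy")
        assert list(classes["class"]) == ["other"]
        assert table.counts == (0, 0, 0)
        assert int(table.table.loc["All", "N_other"]) == 1

    def test_missing_focal_genotype_raises(self):
        m = seven_sample_matrix([site("chr1", 10, [HOM0] * 3, None, [HOM1] * 3)])
        ss = ht.find_discriminatory_sites(m, "parentA", "parentB")
        with pytest.raises(DataError):
            ht.classify_focal_genotypes(ss, m, "hy")

    def test_classes_match_simulated_truth(self, clean_bc1f1_dataset):
        ds = clean_bc1f1_dataset
        ss = ht.find_discriminatory_sites(ds.matrix, "parentA", "parentB")
        classes, _ = ht.classify_focal_genotypes(ss, ds.matrix, "hybrid")
        truth = [c for name in ds.config.chrom_names
                 for c in ds.truth["chroms"][name]["true_class"]]
        assert list(classes["class"]) == truth

    def test_bc1f1_fractions_near_half(self, clean_bc1f1_dataset):
        ds = clean_bc1f1_dataset
        ss = ht.find_discriminatory_sites(ds.matrix, "parentA", "parentB")
        _, table = ht.classify_focal_genotypes(ss, ds.matrix, "hybrid")
        n_aa, n_het, n_bb = table.counts
        assert n_bb == 0  # impossible without error in a backcross to A
        # realized ancestry is linked, so allow wide (not binomial) slack
        assert 0.15 < n_het / (n_aa + n_het) < 0.85

    def test_all_row_sums_per_scope_rows(self, bc1f1_dataset):
        ds = bc1f1_dataset
        ss = ht.find_discriminatory_sites(ds.matrix, "parentA", "parentB")
        _, table = ht.classify_focal_genotypes(ss, ds.matrix, "hybrid")
        t = table.table
        per_chrom = t.drop(index="All")
        for col in ("N_AA", "N_Aa", "N_aa", "N_other"):
            assert per_chrom[col].sum() == t.loc["All", col]
        fr = t[["frac_AA", "frac_Aa", "frac_aa"]].sum(axis=1)
        assert np.allclose(fr, 1.0, atol=1e-12)

    def test_unanchored_grouping(self):
        classes = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1", "ctg7", "ctg9"],
                "pos": [1, 2, 1, 1],
                "class": ["AA", "Aa", "Aa", "aa"],
            }
        )
        t = tabulate_classes(classes, anchored=["chr1"]).table
        assert set(t.index) == {"chr1", "unanchored", "All"}
        assert t.loc["unanchored", "N_Aa"] == 1
        assert t.loc["All", "N_aa"] == 1


class TestPerChromosomeSummary:
    def test_hand_computed_rates(self):
        classes = pd.DataFrame(
            {
                "chrom": ["chr1"] * 4 + ["chr2"] * 4,
                "pos": [1, 2, 3, 4] * 2,
                "class": ["Aa", "Aa", "AA", "Aa", "Aa", "AA", "AA", "aa"],
            }
        )
        t = per_chromosome_summary(classes).set_index("chrom")
        assert t.loc["chr1", "het_rate"] == 0.75
        assert t.loc["chr2", "het_rate"] == 0.25

    def test_all_homozygous_chromosome_is_zero(self):
        classes = pd.DataFrame({"chrom": ["chr1"] * 3, "pos": [1, 2, 3],
                                "class": ["AA"] * 3})
        assert per_chromosome_summary(classes)["het_rate"].iloc[0] == 0.0

    def test_only_other_sites_is_undefined_not_zero(self):
        classes = pd.DataFrame({"chrom": ["chr1"], "pos": [1], "class": ["other"]})
        assert np.isnan(per_chromosome_summary(classes)["het_rate"].iloc[0])
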