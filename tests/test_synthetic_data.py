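"""The synthetic-cohort generators and their planted-truth contracts."""

import numpy as np
import pandas as pd
import pytest

import hypertad as ht
from hypertad.simulate import _domain_multipliers, expected_contacts


class TestSeedDeterminism:
    def test_hic_byte_identical_under_fixed_seed(self, small_genome, strong_tads):
        m1, _ = ht.simulate_hic(small_genome, strong_tads, depth=10, seed=42)
        m2, _ = ht.simulate_hic(small_genome, strong_tads, depth=10, seed=42)
        for c in m1:
            np.testing.assert_array_equal(m1[c].counts, m2[c].counts)

    def test_expression_identical_under_fixed_seed(self, dosage_genome):
        tads = ht.regular_tads(dosage_genome, domain_size=1_000_000)
        cohort = ht.make_cohort(dosage_genome, 5, 5, seed=1)
        s1 = ht.simulate_expression(dosage_genome, cohort, tads, n_genes=60,
                                    seed=7)
        s2 = ht.simulate_expression(dosage_genome, cohort, tads, n_genes=60,
                                    seed=7)
        pd.testing.assert_frame_equal(s1.rna.values, s2.rna.values)
        pd.testing.assert_frame_equal(s1.protein.values, s2.protein.values)

    def test_cms_and_annotations_identical_under_fixed_seed(self, small_genome,
                                                            strong_tads):
        t1 = ht.simulate_cms(seed=5)
        t2 = ht.simulate_cms(seed=5)
        pd.testing.assert_frame_equal(t1.table, t2.table)
        a1 = ht.simulate_annotations(small_genome, strong_tads, seed=5)
        a2 = ht.simulate_annotations(small_genome, strong_tads, seed=5)
        pd.testing.assert_frame_equal(a1[0].intervals, a2[0].intervals)
        pd.testing.assert_frame_equal(a1[2].table, a2[2].table)


class TestSimulateHic:
    def test_full_strength_hides_nothing_across_boundary(self):
        m = _domain_multipliers(2, np.array([1.0]), enrichment=3.0)
        assert m[0, 1] == pytest.approx(1.0)

    def test_zero_strength_makes_boundary_invisible(self):
        m = _domain_multipliers(2, np.array([0.0]), enrichment=3.0)
        assert m[0, 1] == pytest.approx(3.0)

    def test_minimum_strength_governs_multi_domain_pairs(self):
        m = _domain_multipliers(3, np.array([1.0, 0.5]), enrichment=3.0)
        # crossing both boundaries: s_min = 0.5 -> 1 + 2 * 0.5 = 2
        assert m[0, 2] == pytest.approx(2.0)

    def test_poisson_mean_matches_closed_form(self):
        """Adjacent intra-TAD bins at depth 10, decay 1, enrichment 3 have
        expected count 10 * 2^-1 * 3 = 15; the Monte-Carlo mean over >= 1e4
        realized pixels agrees within 2%."""
        g = ht.GenomeSpec(
            chromosomes=[ht.Chromosome("chr1", 2_500_000, 2)], bin_size=25_000
        )
        tads = ht.TadTruth(domains={"chr1": [(0, 2_500_000)]})
        draws = []
        for seed in range(110):
            mats, _ = ht.simulate_hic(g, tads, depth=10.0, decay_exponent=1.0,
                                      tad_enrichment=3.0, seed=seed)
            draws.append(np.diagonal(mats["chr1"].counts, offset=1))
        draws = np.concatenate(draws)
        assert len(draws) >= 10_000
        assert draws.mean() == pytest.approx(15.0, rel=0.02)

    def test_expected_contacts_symmetric_and_scaled(self, small_genome,
                                                    strong_tads):
        mu = expected_contacts(small_genome, strong_tads, "chr1", depth=10,
                               decay_exponent=1.0, tad_enrichment=3.0)
        np.testing.assert_allclose(mu, mu.T)
        assert mu[0, 0] == pytest.approx(10.0 * 3.0)  # distance 0, intra-TAD

    def test_off_grid_domain_edge_rejected_by_name(self, small_genome):
        tads = ht.TadTruth(
            domains={"chr1": [(0, 1_012_345), (1_012_345, 20_000_000)]}
        )
        with pytest.raises(ValueError, match="1012345"):
            ht.simulate_hic(small_genome, tads, depth=5, seed=0)

    def test_realized_matrices_symmetric_nonnegative(self, balanced_hic):
        for cm in balanced_hic.values():
            np.testing.assert_allclose(cm.counts, cm.counts.T)
            assert (cm.counts >= 0).all()


class TestSimulateExpression:
    def test_trisomy_shift_is_exact_without_noise(self, dosage_genome):
        tads = ht.regular_tads(dosage_genome, domain_size=1_000_000)
        cohort = ht.make_cohort(
            dosage_genome, 4, 4, gain_fractions={"chr1": 1.0}, seed=2
        )
        sim = ht.simulate_expression(
            dosage_genome, cohort, tads, n_genes=60, noise_sd=1e-12, seed=2,
            tad_factor_sd=0.0, batch_sd=0.0,
        )
        heh = cohort.subtypes[cohort.subtypes == "HeH-like"].index
        ctrl = cohort.subtypes[cohort.subtypes == "control"].index
        chr1_genes = sim.genes.loc[sim.genes["chrom"] == "chr1", "gene"]
        shift = (
            sim.rna.values.loc[chr1_genes, heh].mean(axis=1)
            - sim.rna.values.loc[chr1_genes, ctrl].mean(axis=1)
        )
        np.testing.assert_allclose(shift, np.log2(1.5), atol=1e-6)

    def test_zero_attenuation_decouples_protein_from_dosage(self, dosage_genome):
        tads = ht.regular_tads(dosage_genome, domain_size=1_000_000)
        cohort = ht.make_cohort(
            dosage_genome, 20, 20,
            gain_fractions={c: 1.0 for c in dosage_genome.names},
            seed=4, attenuation=0.0,
        )
        sim = ht.simulate_expression(dosage_genome, cohort, tads, n_genes=960,
                                     seed=4)
        d = ht.cohens_d(sim.protein.values, sim.protein.groups)
        per_chrom = ht.chromosome_effect_sizes(d, sim.genes)
        assert per_chrom.abs().mean() < 0.05
        assert (per_chrom.abs() < 0.15).all()

    def test_cohort_chromosome_missing_from_genome_rejected(self, dosage_genome):
        tads = ht.regular_tads(dosage_genome, domain_size=1_000_000)
        cohort = ht.make_cohort(dosage_genome, 3, 3, seed=0)
        cohort.copy_numbers["chr99"] = 2
        with pytest.raises(ValueError, match="chr99"):
            ht.simulate_expression(dosage_genome, cohort, tads, n_genes=60,
                                   seed=0)

    def test_truth_objects_roundtrip_through_writers(self, tmp_path,
                                                     dosage_genome):
        from hypertad import io as hio

        tads = ht.regular_tads(dosage_genome, domain_size=1_000_000)
        cohort = ht.make_cohort(dosage_genome, 4, 4, seed=6)
        sim = ht.simulate_expression(dosage_genome, cohort, tads, n_genes=60,
                                     seed=6)
        hio.write_expression(sim.rna, tmp_path / "rna.tsv")
        back = hio.read_expression(tmp_path / "rna.tsv")
        pd.testing.assert_frame_equal(back.values, sim.rna.values)
        assert list(back.groups) == list(sim.rna.groups)
        hio.write_segments(sim.copy_number, tmp_path / "seg.tsv")
        seg = hio.read_segments(tmp_path / "seg.tsv")
        pd.testing.assert_frame_equal(seg.segments, sim.copy_number.segments)
        hio.write_genes(sim.genes, tmp_path / "genes.tsv")
        pd.testing.assert_frame_equal(hio.read_genes(tmp_path / "genes.tsv"),
                                      sim.genes)


class TestSimulateAnnotations:
    def test_zero_background_gives_full_peak_support(self, small_genome,
                                                     strong_tads):
        ctcf, _r, _a, _b = ht.simulate_annotations(
            small_genome, strong_tads, peak_rate=0.0, seed=1,
            boundary_jitter=5_000,
        )
        from conftest import truth_boundary_set

        bs = truth_boundary_set(small_genome, strong_tads)
        _flags, frac = ht.peak_support(bs, ctcf, window=50_000)
        assert frac == 1.0
        n_boundaries = sum(
            len(strong_tads.boundaries(c)) for c in small_genome.names
        )
        assert len(ctcf.intervals) == n_boundaries

    def test_shared_fraction_zero_empties_consensus(self, small_genome,
                                                    strong_tads):
        _c, _r, ia, ib = ht.simulate_annotations(
            small_genome, strong_tads, seed=2, shared_fraction=0.0
        )
        cons = ht.consensus_interactions(ia, ib, min_pet=10)
        assert len(cons.table) == 0

    def test_shared_fraction_half_gives_half_consensus(self):
        # 100 interactions via 50 domains on two chromosomes
        g = ht.GenomeSpec(
            chromosomes=[ht.Chromosome(f"c{i}", 50_000_000, 2) for i in (1, 2)],
            bin_size=25_000,
        )
        tads = ht.regular_tads(g, domain_size=1_000_000)
        sizes = []
        for seed in range(20):
            _c, _r, ia, ib = ht.simulate_annotations(
                g, tads, seed=seed, shared_fraction=0.5
            )
            cons = ht.consensus_interactions(ia, ib, min_pet=10)
            sizes.append(len(cons.table) / (len(tads.domains["c1"]) * 2))
        assert np.mean(sizes) == pytest.approx(0.5, abs=0.05)


class TestSimulateCms:
    def test_extreme_means_give_exact_scores(self):
        t = ht.simulate_cms(n_per_group=(5, 5), group_means=(1.0, 3.0),
                            metaphases_per_case=10, seed=0, case_sd=0.0)
        res = ht.compare_cms(t)
        means = res["group_means"]
        assert means["HeH"] == 1.0
        assert means["ETV6_RUNX1"] == 3.0

    def test_means_outside_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            ht.simulate_cms(group_means=(0.5, 2.0))

    def test_paper_cohort_power(self):
        """Means 1.8 vs 2.1 with 37 vs 33 cases of 20 metaphases each are
        detected in well over half of replicates at alpha = 0.05."""
        hits = 0
        n_rep = 200
        for seed in range(n_rep):
            t = ht.simulate_cms(seed=seed)
            if ht.compare_cms(t)["pvalue"] < 0.05:
                hits += 1
        assert hits / n_rep > 0.5

    def test_scores_live_on_the_ordinal_scale(self):
        t = ht.simulate_cms(seed=3)
        assert t.table["score"].isin([1, 2, 3]).all()
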