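"""Forward-in-time simulator: inheritance, trait construction, selection."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import predslice as ps
from predslice.errors import DegenerateInputError, InvalidInputError
from predslice.simulator import _genome_layout, _meiosis


class TestFoundersAndGenome:
    def test_founder_frequencies_in_range(self):
        genome = ps.GenomeSpec(n_chromosomes=2, markers_per_chromosome=200,
                               qtn_per_chromosome=10, founder_maf_range=(0.2, 0.5))
        haps, positions, qtn_mask = ps.simulate_founders(genome, 500, seed=3)
        freq = haps.mean(axis=(0, 1))
        maf = np.minimum(freq, 1 - freq)
        # per-locus draws at the configured frequencies; sampling noise at n=500
        assert np.quantile(maf, 0.02) > 0.12
        assert maf.max() <= 0.5

    def test_determinism(self, tiny_config, tiny_population):
        pop1, real1 = tiny_population
        pop2, real2 = ps.run_generations(tiny_config, seed=11)
        pd.testing.assert_frame_equal(pop1.individuals, pop2.individuals)
        np.testing.assert_array_equal(pop1.genotypes.dosages, pop2.genotypes.dosages)
        pd.testing.assert_frame_equal(real1.table, real2.table)

    def test_burn_in_builds_ld(self, tiny_population):
        """After bottleneck random mating, linkage disequilibrium (r^2) between
        adjacent markers exceeds that between distant markers."""
        pop, _ = tiny_population
        ind = pop.individuals
        g0 = ind.index[ind.generation == 0]
        dose = pop.genotypes.dosages[g0.to_numpy()].astype(float)
        # chromosome 1 markers sit in the first block of columns
        block = dose[:, :100]
        keep = block.std(axis=0) > 0
        block = block[:, keep]
        corr = np.corrcoef(block.T) ** 2
        adjacent = np.mean(np.diag(corr, 1))
        distant = np.mean(corr[: corr.shape[0] // 3, -corr.shape[0] // 3:])
        assert adjacent > distant * 2

    def test_genome_layout_sorted_and_disjoint(self):
        genome = ps.GenomeSpec(n_chromosomes=3, markers_per_chromosome=50,
                               qtn_per_chromosome=7)
        positions, qtn_mask = _genome_layout(genome, np.random.default_rng(0))
        assert len(positions) == 3
        for pos in positions:
            assert np.all(np.diff(pos) >= 0)
            assert pos.max() <= genome.chromosome_length_cm / 100.0
        assert qtn_mask.sum() == 21


class TestMeiosis:
    def test_poisson_crossover_rate(self):
        """Expected crossover count per 1-Morgan chromosome is 1; measured via
        the fraction of recombinant gametes from a fully heterozygous parent
        with all-0 / all-1 haplotypes: a gamete is a mosaic iff >= 1 crossover
        falls between the tracked loci, P ~ 1 - exp(-1) for a dense map."""
        n_loci, n_g = 200, 10_000
        pos = [np.linspace(0.0025, 0.9975, n_loci)]
        haps = np.zeros((1, 2, n_loci), np.uint8)
        haps[0, 1] = 1
        rng = np.random.default_rng(8)
        gam = _meiosis(haps, np.zeros(n_g, dtype=int), pos, [1.0], rng)
        switches = np.abs(np.diff(gam.astype(int), axis=1)).sum(axis=1)
        # mean switch count across the tracked interval ~ map length (Haldane)
        assert switches.mean() == pytest.approx(1.0 * (pos[0][-1] - pos[0][0]),
                                                abs=0.05)

    def test_inheritance_no_mutation(self, tiny_population):
        pop, _ = tiny_population
        ind = pop.individuals.set_index("id")
        dose = pd.DataFrame(pop.genotypes.dosages, index=pop.genotypes.individual_ids)
        kids = ind[ind.generation == 2].head(20)
        for kid, row in kids.iterrows():
            lo = np.minimum(np.ceil(dose.loc[row.sire] / 2) > 0,
                            np.ceil(dose.loc[row.dam] / 2) > 0)
            # offspring dosage bounded by what the parents can transmit
            min_d = (dose.loc[row.sire] == 2).astype(int) + (dose.loc[row.dam] == 2).astype(int)
            max_d = (dose.loc[row.sire] > 0).astype(int) + (dose.loc[row.dam] > 0).astype(int)
            d = dose.loc[kid]
            assert (d >= min_d).all() and (d <= max_d).all()


class TestTraits:
    def test_qtn_effects_scaled_to_unit_variance(self, tiny_population):
        pop, real = tiny_population
        assert real.h2(1, 0) == pytest.approx(0.4, abs=1e-9)
        assert real.h2(2, 0) == pytest.approx(0.1, abs=1e-9)

    def test_gamma_effects_leptokurtic(self):
        rng = np.random.default_rng(0)
        eff = ps.sample_qtn_effects(3000, gamma_shape=0.4, rng=rng)
        mags = np.abs(eff[:, 0])
        assert mags.max() / np.median(mags) > 10
        # signs balanced
        assert abs(np.mean(np.sign(eff[:, 0]))) < 0.1

    def test_founder_traits_uncorrelated(self, tiny_population):
        pop, _ = tiny_population
        g0 = pop.individuals[pop.individuals.generation == 0]
        r = np.corrcoef(g0.u1, g0.u2)[0, 1]
        assert abs(r) < 3 / np.sqrt(len(g0)) + 0.05

    def test_composite_reduces_to_scaled_u2_at_beta_zero(self, rng):
        u1 = rng.standard_normal(500)
        u2 = rng.standard_normal(500)
        u3, alpha = ps.composite_trait(u1, u2, beta=0.0, ref_mean_u1=0.0)
        np.testing.assert_allclose(u3, u2 / np.std(u2, ddof=1), atol=1e-12)
        assert np.corrcoef(u1, u3)[0, 1] == pytest.approx(np.corrcoef(u1, u2)[0, 1])

    def test_composite_unit_variance(self, rng):
        for beta in (0.0, 0.1, 0.5):
            u3, _ = ps.composite_trait(rng.standard_normal(300),
                                       rng.standard_normal(300), beta, 0.2)
            assert np.var(u3, ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_composite_symmetric_case_keeps_correlation(self, rng):
        """With centered symmetric u1, corr(u1, u1^2) ~ 0, so any beta leaves
        corr(u1, u3) near corr(u1, u2)."""
        n = 100_000
        u1 = rng.standard_normal(n)
        u2 = rng.standard_normal(n)
        u3, _ = ps.composite_trait(u1, u2, beta=0.4, ref_mean_u1=0.0)
        assert np.corrcoef(u1, u3)[0, 1] == \
            pytest.approx(np.corrcoef(u1, u2)[0, 1], abs=0.02)

    def test_composite_degenerate(self):
        with pytest.raises(DegenerateInputError):
            ps.composite_trait(np.ones(5), np.ones(5), 0.0, 1.0)

    def test_phenotype_residual_variances(self, tiny_population, tiny_config):
        pop, _ = tiny_population
        sve = tiny_config.traits.residual_variances
        for j, grp in pop.individuals.groupby("generation"):
            for t, v in zip((1, 2, 3), sve):
                resid = grp[f"y{t}"] - grp[f"u{t}"]
                se = v * np.sqrt(2 / (len(grp) - 1)) * 3
                assert resid.var(ddof=1) == pytest.approx(v, abs=se)


class TestSelection:
    def test_top_gebv_parents_selected(self, rng):
        cand = pd.DataFrame({"sex": ["M"] * 10 + ["F"] * 20},
                            index=[f"i{k}" for k in range(30)])
        gebv = pd.Series(rng.standard_normal(30), index=cand.index)
        genome = ps.GenomeSpec(n_chromosomes=1, markers_per_chromosome=20,
                               qtn_per_chromosome=2)
        haps, positions, _ = ps.simulate_founders(genome, 30, seed=0)
        scheme = ps.SelectionScheme(n_sires=3, n_dams=10, offspring_per_generation=20)
        off, off_haps = ps.select_and_mate(cand, haps, gebv, scheme, positions,
                                           [1.0], rng, id_prefix="T")
        males = gebv.loc[cand.index[cand.sex == "M"]]
        top_sires = set(males.nlargest(3).index)
        assert set(off["sire"]) <= top_sires
        top_dams = set(gebv.loc[cand.index[cand.sex == "F"]].nlargest(10).index)
        assert set(off["dam"]) == top_dams
        assert off_haps.shape == (20, 2, haps.shape[2])

    def test_not_enough_candidates(self, rng):
        cand = pd.DataFrame({"sex": ["M", "F"]}, index=["a", "b"])
        scheme = ps.SelectionScheme(n_sires=2, n_dams=1, offspring_per_generation=4)
        with pytest.raises(InvalidInputError):
            ps.select_and_mate(cand, np.zeros((2, 2, 4), np.uint8),
                               pd.Series([1.0, 2.0], index=["a", "b"]),
                               scheme, [np.linspace(0, 1, 4)], [1.0], rng)

    def test_selection_raises_mean_and_erodes_h2(self, tiny_population):
        pop, real = tiny_population
        t = real.table.sort_values("generation")
        means = t["mean_u1"].to_numpy()
        assert np.all(np.diff(means) > 0)
        assert t["h2_1"].iloc[-1] < t["h2_1"].iloc[0] + 0.02

    def test_no_selection_control_flat(self, noselect_population):
        """Random parents: realized h2 of the production trait stays at 0.40
        and the mean breeding value shows no systematic trend."""
        _, real = noselect_population
        t = real.table.sort_values("generation")
        assert np.allclose(t["h2_1"], 0.4, atol=0.05)
        assert abs(t["mean_u1"].iloc[-1]) < 0.5

    def test_effective_population_size(self):
        assert ps.effective_population_size(13, 10_000) == pytest.approx(51.9, abs=0.05)
        assert ps.effective_population_size(13, 500) == pytest.approx(50.7, abs=0.05)


class TestRealizedParameters:
    def test_zero_variance_h2(self):
        df = pd.DataFrame({
            "id": ["a", "b", "c"], "generation": 0, "sex": "M",
            "sire": "", "dam": "",
            "u1": [1.0, 1.0, 1.0], "u2": [0.0, 1.0, 2.0], "u3": [0.0, 1.0, 0.5],
            "y1": [1.0, 2.0, 3.0], "y2": [0.0, 1.0, 2.0], "y3": [0.0, 1.0, 0.5]})
        pop = ps.SimPopulation(individuals=df, genotypes=None)
        real = ps.realized_parameters(pop, (1.5, 9.0, 9.0))
        assert real.h2(1, 0) == 0.0

    def test_single_individual_rejected(self):
        df = pd.DataFrame({"id": ["a"], "generation": 0, "sex": "M",
                           "sire": "", "dam": "",
                           "u1": [1.0], "u2": [1.0], "u3": [1.0],
                           "y1": [1.0], "y2": [1.0], "y3": [1.0]})
        pop = ps.SimPopulation(individuals=df, genotypes=None)
        with pytest.raises(DegenerateInputError):
            ps.realized_parameters(pop, (1.5, 9.0, 9.0))

    def test_mean_decline(self):
        tbl = pd.DataFrame({"generation": [0, 1, 2],
                            "corr_u1_u3": [0.0, -0.12, -0.19]})
        real = ps.RealizedParameters(table=tbl)
        assert real.mean_decline_corr_u1_u3() == pytest.approx(-0.095)
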