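"""Heterozygosities, HW exact test, LD permutation, null-allele EM,
rarefaction, private alleles, and the assembled population summary."""

import math

import numpy as np
import pytest
from scipy.stats import kstest

from dmpkit.diversity import (
    expected_heterozygosity_unbiased,
    fisher_combine,
    genotypic_ld_test,
    hw_exact_test,
    null_allele_em,
    observed_heterozygosity,
    population_summary,
    private_allele_counts,
    rarefied_allelic_richness,
)
from dmpkit.popdata import (
    AlleleFrequencyTable,
    GenotypeDataset,
    Individual,
    Locus,
    PopulationSample,
    read_genepop,
    write_genepop,
)
from dmpkit.slcsd import build_scenario, sample_trap_survey, simulate_population


class TestHeterozygosity:
    def test_observed_counts_diploids_only(self, make_diploid_pop):
        pop = make_diploid_pop([{"L": (1, 2)}, {"L": (1, 1)}, {"L": (2, 3)}, {"L": (3, 3)}])
        pop.individuals.append(
            Individual(id="h", sex="male", declared_ploidy="haploid", genotypes={"L": (1,)})
        )
        assert observed_heterozygosity(pop, "L") == 0.5

    def test_observed_extremes_and_untyped(self, make_diploid_pop):
        assert observed_heterozygosity(make_diploid_pop([{"L": (1, 1)}] * 3), "L") == 0.0
        assert observed_heterozygosity(make_diploid_pop([{"L": (1, 2)}] * 3), "L") == 1.0
        assert math.isnan(observed_heterozygosity(make_diploid_pop([{}]), "L"))

    def test_expected_unbiased_hand_value(self):
        tab = AlleleFrequencyTable("L", {1: 3, 2: 1}, 4)
        assert expected_heterozygosity_unbiased(tab) == pytest.approx(0.5)

    def test_expected_monomorphic_and_small_n(self):
        assert expected_heterozygosity_unbiased(AlleleFrequencyTable("L", {1: 5}, 5)) == 0.0
        with pytest.raises(ValueError):
            expected_heterozygosity_unbiased(AlleleFrequencyTable("L", {1: 1}, 1))

    def test_expected_reaches_gene_diversity_at_large_n(self):
        n = 10**6
        tab = AlleleFrequencyTable("L", {1: n // 2, 2: n // 2}, n)
        assert expected_heterozygosity_unbiased(tab) == pytest.approx(0.5, abs=1e-5)


class TestHardyWeinberg:
    def test_two_heterozygotes_full_enumeration(self, make_diploid_pop):
        # tables given counts 2A/2a: {2 hets} prob 2/3, {AA,aa} prob 1/3 -> p = 1
        pop = make_diploid_pop([{"L": (1, 2)}, {"L": (1, 2)}])
        assert hw_exact_test(pop, "L") == pytest.approx(1.0)

    def test_monomorphic_is_one(self, make_diploid_pop):
        assert hw_exact_test(make_diploid_pop([{"L": (1, 1)}] * 5), "L") == 1.0

    def test_enumeration_matches_independent_levene_formula(self, make_diploid_pop):
        # biallelic oracle: het-count distribution under Levene, computed directly
        n, nA, h = 30, 18, 10
        nAA, nBB = (nA - h) // 2, (2 * n - nA - h) // 2
        genos = [{"L": (1, 1)}] * nAA + [{"L": (1, 2)}] * h + [{"L": (2, 2)}] * nBB
        pop = make_diploid_pop(genos)

        nB = 2 * n - nA
        hs = list(range(nA % 2, min(nA, nB) + 1, 2))
        logs = []
        for hh in hs:
            aa, bb = (nA - hh) // 2, (nB - hh) // 2
            logs.append(
                math.lgamma(n + 1) - math.lgamma(aa + 1) - math.lgamma(hh + 1)
                - math.lgamma(bb + 1) + hh * math.log(2)
                + math.lgamma(nA + 1) + math.lgamma(nB + 1) - math.lgamma(2 * n + 1)
            )
        probs = np.exp(logs)
        probs /= probs.sum()
        oracle = probs[probs <= probs[hs.index(h)] + 1e-12].sum()
        assert hw_exact_test(pop, "L") == pytest.approx(float(oracle), rel=1e-9)

    def test_monte_carlo_agrees_with_enumeration(self, make_diploid_pop):
        genos = [(1, 1), (1, 2), (2, 3), (1, 3), (2, 2), (1, 2), (3, 3), (1, 1), (2, 3), (1, 2)]
        pop = make_diploid_pop([{"L": g} for g in genos])
        p_enum = hw_exact_test(pop, "L")
        n_mc = 20_000
        p_mc = hw_exact_test(pop, "L", enum_cap=1, n_mc=n_mc, seed=3)
        assert abs(p_mc - p_enum) <= 3 * np.sqrt(p_enum * (1 - p_enum) / n_mc)

    def test_null_uniformity_multiallelic(self, make_diploid_pop, rng):
        ps = []
        for rep in range(100):
            k = 6
            draws = rng.choice(np.arange(1, k + 1), size=(100, 2))
            pop = make_diploid_pop([{"L": tuple(sorted(d))} for d in draws])
            ps.append(hw_exact_test(pop, "L", seed=rep, n_mc=1500, enum_cap=1))
        assert kstest(ps, "uniform").pvalue > 0.01


class TestLinkageDisequilibrium:
    def test_monomorphic_locus_is_one(self, make_diploid_pop):
        pop = make_diploid_pop([{"A": (1, 2), "B": (3, 3)}] * 10)
        assert genotypic_ld_test(pop, "A", "B", n_perm=100, seed=0) == 1.0

    def test_perfect_coupling_detected(self, make_diploid_pop):
        genos = [{"A": (1, 1), "B": (1, 1)} if i % 2 else {"A": (1, 2), "B": (1, 2)} for i in range(20)]
        pop = make_diploid_pop(genos)
        assert genotypic_ld_test(pop, "A", "B", n_perm=2000, seed=1) <= 0.01

    def test_independent_loci_null_behaviour(self, make_diploid_pop, rng):
        ps = []
        for rep in range(60):
            genos = [
                {"A": tuple(sorted(rng.choice([1, 2], 2))), "B": tuple(sorted(rng.choice([1, 2], 2)))}
                for _ in range(40)
            ]
            ps.append(genotypic_ld_test(make_diploid_pop(genos), "A", "B", n_perm=400, seed=rep))
        ps = np.asarray(ps)
        assert 0.35 < ps.mean() < 0.65
        assert (ps <= 0.05).mean() <= 0.15


class TestFisherCombine:
    @pytest.mark.parametrize(
        "ps, chi2, df",
        [
            ([1.0, 1.0], 0.0, 4),
            ([0.05, 0.05], -4 * math.log(0.05), 4),
            ([0.5], -2 * math.log(0.5), 2),
        ],
    )
    def test_values(self, ps, chi2, df):
        c, d, _ = fisher_combine(ps)
        assert c == pytest.approx(chi2)
        assert d == df

    def test_zero_pvalue_rejected(self):
        with pytest.raises(ValueError):
            fisher_combine([0.0, 0.5])


def _null_model_pop(r, n, rng, pvis=(0.375, 0.375, 0.25)):
    """Diploids drawn from HW with a null allele at frequency r."""
    freqs = np.append(np.asarray(pvis) * (1 - r), r)
    inds = []
    for i in range(n):
        a, b = rng.choice(4, size=2, p=freqs)
        geno = {"L2": (1, 2)}  # second locus marks blanks as genotyped diploids
        vis = [x for x in (a, b) if x != 3]
        if len(vis) == 2:
            geno["L1"] = (vis[0] + 1, vis[1] + 1)
        elif len(vis) == 1:
            geno["L1"] = (vis[0] + 1, vis[0] + 1)
        inds.append(Individual(id=f"i{i}", sex="female", declared_ploidy="diploid", genotypes=geno))
    return PopulationSample(name="p", habitat="mainland", individuals=inds)


class TestNullAlleleEM:
    def test_exact_hw_no_blanks_gives_zero(self, make_diploid_pop):
        genos = [{"L": (1, 1)}] * 25 + [{"L": (1, 2)}] * 50 + [{"L": (2, 2)}] * 25
        r, p = null_allele_em(make_diploid_pop(genos), "L")
        assert r < 1e-6
        assert p[1] == pytest.approx(0.5, abs=1e-6)

    def test_parameter_recovery(self, rng):
        ests = np.array(
            [null_allele_em(_null_model_pop(0.2, 500, rng), "L1")[0] for _ in range(40)]
        )
        assert np.abs(ests - 0.2).max() < 0.05
        assert abs(ests.mean() - 0.2) < 0.02

    def test_zero_truth_estimates_near_zero(self, rng):
        ests = np.array(
            [null_allele_em(_null_model_pop(0.0, 500, rng), "L1")[0] for _ in range(30)]
        )
        assert (ests < 0.03).mean() >= 0.95

    def test_matches_grid_search_likelihood_oracle(self, make_diploid_pop):
        # biallelic + null: maximize the multinomial likelihood on a grid
        n_aa, n_ab, n_bb, n_blank = 30, 40, 20, 5
        genos = (
            [{"L": (1, 1), "M": (1, 2)}] * n_aa
            + [{"L": (1, 2), "M": (1, 2)}] * n_ab
            + [{"L": (2, 2), "M": (1, 2)}] * n_bb
            + [{"M": (1, 2)}] * n_blank
        )
        r_em, _ = null_allele_em(make_diploid_pop(genos), "L")

        pa = np.linspace(0.01, 0.98, 400)[:, None]
        r = np.linspace(0.0, 0.4, 401)[None, :]
        pb = 1 - pa - r
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = (
                n_aa * np.log(pa**2 + 2 * pa * r)
                + n_ab * np.log(2 * pa * pb)
                + n_bb * np.log(pb**2 + 2 * pb * r)
                + (n_blank * np.log(r**2) if n_blank else 0.0)
            )
        ll[pb <= 0] = -np.inf
        r_grid = r.ravel()[np.unravel_index(np.nanargmax(ll), ll.shape)[1]]
        assert r_em == pytest.approx(r_grid, abs=1e-3)


class TestRarefaction:
    def test_hand_example(self):
        tabs = {"p": AlleleFrequencyTable("L", {1: 3, 2: 1}, 4)}
        assert rarefied_allelic_richness(tabs, g=2)["p"] == pytest.approx(1.5)

    def test_g_equal_n_is_observed_count(self):
        tabs = {"p": AlleleFrequencyTable("L", {1: 5, 2: 3, 3: 2}, 10)}
        assert rarefied_allelic_richness(tabs, g=10)["p"] == pytest.approx(3.0)

    def test_monomorphic_is_one_and_monotone_in_g(self):
        tabs = {"p": AlleleFrequencyTable("L", {1: 8}, 8)}
        assert rarefied_allelic_richness(tabs, g=3)["p"] == pytest.approx(1.0)
        tabs = {"p": AlleleFrequencyTable("L", {1: 6, 2: 3, 3: 1}, 10)}
        vals = [rarefied_allelic_richness(tabs, g=g)["p"] for g in range(1, 11)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_default_g_is_min_and_oversize_g_rejected(self):
        tabs = {
            "a": AlleleFrequencyTable("L", {1: 3, 2: 3}, 6),
            "b": AlleleFrequencyTable("L", {1: 2, 2: 2}, 4),
        }
        r = rarefied_allelic_richness(tabs)  # g = 4
        assert r["b"] == pytest.approx(2.0)
        with pytest.raises(ValueError, match="exceeds"):
            rarefied_allelic_richness(tabs, g=5)


class TestPrivateAlleles:
    def _dataset(self, pops):
        return GenotypeDataset(
            loci=[Locus("L")],
            populations=[
                PopulationSample(
                    name=name,
                    habitat="mainland",
                    individuals=[
                        Individual(
                            id=f"{name}{i}", sex="male", declared_ploidy="haploid",
                            genotypes={"L": (a,)},
                        )
                        for i, a in enumerate(alleles)
                    ],
                )
                for name, alleles in pops.items()
            ],
        )

    def test_enumeration_example(self):
        ds = self._dataset({"P1": [1, 2], "P2": [2, 3], "P3": [2]})
        assert private_allele_counts(ds) == {"P1": 1, "P2": 1, "P3": 0}

    def test_identical_populations_have_none(self):
        ds = self._dataset({"P1": [1, 2], "P2": [1, 2]})
        assert private_allele_counts(ds) == {"P1": 0, "P2": 0}

    def test_total_bounded_by_distinct_alleles(self):
        ds = self._dataset({"P1": [1, 2, 5], "P2": [2, 3], "P3": [2, 4]})
        assert sum(private_allele_counts(ds).values()) <= 5

    def test_single_population_warns(self):
        ds = self._dataset({"P1": [1, 2]})
        with pytest.warns(UserWarning, match="private"):
            private_allele_counts(ds)


@pytest.fixture(scope="module")
def sim_dataset():
    pops = []
    loci = None
    for i, preset in enumerate(["mainland", "captive_small"]):
        sim = simulate_population(build_scenario(preset, seed=42 + i))
        ds = sample_trap_survey(
            sim, n_males=40, n_females=0, seed=99 + i,
            population_name=f"pop{i}", habitat="mainland" if i == 0 else "captive",
        )
        loci = ds.loci
        pops.append(ds.populations[0])
    return GenotypeDataset(loci=loci, populations=pops)


class TestPopulationSummary:
    def test_richness_column_is_composition_of_rarefaction(self, sim_dataset):
        s = population_summary(sim_dataset, mode="males_merged_pairs", n_mc=200, enum_cap=500)
        for _, row in s.per_population.iterrows():
            sel = s.per_locus[s.per_locus["population"] == row["population"]]
            assert row["overall_richness"] == pytest.approx(
                np.nanmean(sel["richness"].to_numpy(dtype=float))
            )

    def test_summary_invariant_to_genepop_roundtrip(self, sim_dataset, tmp_path):
        path = tmp_path / "d.gen"
        write_genepop(sim_dataset, path)
        back = read_genepop(path, path.with_suffix(path.suffix + ".sidecar.tsv"))
        a = population_summary(sim_dataset, mode="males_merged_pairs", n_mc=200, enum_cap=500)
        b = population_summary(back, mode="males_merged_pairs", n_mc=200, enum_cap=500)
        import pandas.testing as pdt

        pdt.assert_frame_equal(a.per_locus, b.per_locus)

    def test_hw_equilibrium_dataset_not_rejected_after_fdr(self, rng):
        # one population drawn exactly from HW at 4 loci
        inds = []
        for i in range(100):
            geno = {
                f"L{l}": tuple(sorted(rng.choice(np.arange(1, 5), size=2)))
                for l in range(4)
            }
            inds.append(Individual(id=f"i{i}", sex="female", declared_ploidy="diploid", genotypes=geno))
        ds = GenotypeDataset(
            loci=[Locus(f"L{l}") for l in range(4)],
            populations=[PopulationSample(name="p", habitat="mainland", individuals=inds)],
        )
        s = population_summary(ds, mode="females_diploid", n_mc=2000, enum_cap=1000)
        assert (s.per_locus["hw_p_fdr"].dropna() < 0.05).sum() == 0
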