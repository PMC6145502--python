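"""Coalescent engine calibration, nulls, allele ages and msprime cross-check."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from balscan.coalescent_sim import (
    conditional_allele_age,
    null_tajima_distribution,
    simulate_sample,
)
from balscan.demography import DemographyConfig, PopulationConfig, gravel_2011


def sfs_counts(panel):
    n = panel.n_haplotypes
    counts = panel.matrix.sum(axis=0)
    hist = np.zeros(n - 1, dtype=int)
    for c in counts:
        if 0 < c < n:
            hist[c - 1] += 1
    return hist


class TestSimulateSample:
    def test_pairwise_tmrca_matches_2n(self, single_pop_dem, rng):
        dem = single_pop_dem(n=1000)
        tm = np.array(
            [simulate_sample(dem, {"P": 2}, 100, seed=rng).tmrca for _ in range(2000)]
        )
        se = tm.std(ddof=1) / math.sqrt(tm.size)
        assert abs(tm.mean() - 2000) <= 3 * se

    def test_watterson_and_pi_closed_forms(self, single_pop_dem, rng):
        dem = single_pop_dem(n=1000, mu=1e-6)
        n, L, reps = 50, 10_000, 600
        theta = 4 * 1000 * 1e-6 * L
        S, pi = [], []
        from balscan.panel import GenomicWindow
        from balscan.sfs_scan import tajimas_d_components

        for _ in range(reps):
            samp = simulate_sample(dem, {"P": n}, L, seed=rng)
            st = tajimas_d_components(samp.panel, GenomicWindow("sim", 0, L))
            S.append(st.S)
            pi.append(st.pi)
        S, pi = np.array(S), np.array(pi)
        a1 = sum(1 / i for i in range(1, n))
        for value, expected in ((S, theta * a1), (pi, theta)):
            se = value.std(ddof=1) / math.sqrt(reps)
            assert abs(value.mean() - expected) <= 3 * se

    def test_isolated_populations_error(self):
        dem = DemographyConfig(
            populations=[PopulationConfig("A", 100), PopulationConfig("B", 100)],
        )
        with pytest.raises(ValueError, match="root"):
            simulate_sample(dem, {"A": 2, "B": 2}, 100, seed=0)

    def test_fixed_seed_reproduces_panel(self, single_pop_dem):
        dem = single_pop_dem(n=500, mu=1e-6, r=1e-7)
        a = simulate_sample(dem, {"P": 10}, 5_000, seed=42)
        b = simulate_sample(dem, {"P": 10}, 5_000, seed=42)
        assert a.panel == b.panel
        assert a.tmrca == b.tmrca
        assert np.array_equal(a.mutation_ages, b.mutation_ages)

    def test_tmrca_bounds_mutation_ages(self, single_pop_dem):
        dem = single_pop_dem(n=500, mu=2e-6)
        samp = simulate_sample(dem, {"P": 20}, 5_000, seed=7)
        assert samp.mutation_ages.size > 0
        assert samp.tmrca >= samp.mutation_ages.max()

    def test_matches_msprime_single_population(self, rng):
        """Cross-check against an independent coalescent implementation.

        Replicates are the independent units (site counts within one
        replicate share a genealogy and are overdispersed), so the
        comparison is a two-sample KS on per-replicate S and pi, plus the
        mean SFS shape.
        """
        import msprime

        dem = DemographyConfig(
            populations=[PopulationConfig("P", 800)], mutation_rate=2e-6
        )
        n, L, reps = 10, 5_000, 500
        ours_S, ours_pi = [], []
        sfs = np.zeros(n - 1)
        for _ in range(reps):
            panel = simulate_sample(dem, {"P": n}, L, seed=rng).panel
            counts = panel.matrix.sum(axis=0)
            ours_S.append(panel.n_sites)
            ours_pi.append(float(np.sum(counts * (n - counts))) / (n * (n - 1) / 2))
            sfs += sfs_counts(panel)
        theirs_S, theirs_pi = [], []
        msp_sfs = np.zeros(n - 1)
        mut_seed = np.random.default_rng(77)
        for ts in msprime.sim_ancestry(
            samples=n // 2, population_size=800, sequence_length=L,
            num_replicates=reps, random_seed=99,
        ):
            mts = msprime.sim_mutations(
                ts, rate=2e-6, random_seed=int(mut_seed.integers(1, 2**31)),
                model=msprime.BinaryMutationModel(),
            )
            afs = mts.allele_frequency_spectrum(span_normalise=False, polarised=True)
            msp_sfs += afs[1:n]
            theirs_S.append(afs[1:n].sum())
            theirs_pi.append(float(mts.diversity(span_normalise=False)))
        for a, b in ((ours_S, theirs_S), (ours_pi, theirs_pi)):
            assert sps.ks_2samp(a, b).pvalue > 0.01
        # mean SFS shape ~ theta/i (loose 10% relative band on large classes)
        expected = sfs.sum() * (1 / np.arange(1, n)) / np.sum(1 / np.arange(1, n))
        np.testing.assert_allclose(sfs[:3], expected[:3], rtol=0.1)

    def test_matches_msprime_ooa_demography(self, rng):
        """Joint-demography cross-check on per-population S and pi."""
        import msprime

        g = gravel_2011()
        reps, L = 200, 5_000
        pops = {"AFR": 8, "EUR": 8, "ASN": 8}
        ours = {p: {"S": [], "pi": []} for p in pops}
        for _ in range(reps):
            panel = simulate_sample(g, pops, L, seed=rng, recombination_rate=0).panel
            for p in pops:
                rows = panel.rows_for(p)
                counts = panel.matrix[rows].sum(axis=0)
                n = rows.size
                seg = (counts > 0) & (counts < n)
                ours[p]["S"].append(int(seg.sum()))
                ours[p]["pi"].append(
                    float(np.sum(counts[seg] * (n - counts[seg]))) / (n * (n - 1) / 2)
                )
        dem = msprime.Demography()
        dem.add_population(name="AFR", initial_size=14474)
        dem.add_population(name="EUR", initial_size=34039, growth_rate=0.0038)
        dem.add_population(name="ASN", initial_size=45852, growth_rate=0.0048)
        dem.set_symmetric_migration_rate(["AFR", "EUR"], 2.5e-5)
        dem.set_symmetric_migration_rate(["AFR", "ASN"], 0.78e-5)
        dem.set_symmetric_migration_rate(["EUR", "ASN"], 3.11e-5)
        # legacy-style mass migrations keep every deme active, matching our
        # engine's relabelling semantics exactly
        dem.add_mass_migration(time=920, source="ASN", dest="EUR", proportion=1.0)
        dem.add_population_parameters_change(
            time=920, population="EUR", initial_size=1861, growth_rate=0
        )
        dem.add_migration_rate_change(time=920, rate=0)
        dem.add_symmetric_migration_rate_change(
            time=920, populations=["AFR", "EUR"], rate=15e-5
        )
        dem.add_mass_migration(time=2040, source="EUR", dest="AFR", proportion=1.0)
        dem.add_migration_rate_change(time=2040, rate=0)
        dem.add_population_parameters_change(
            time=5920, population="AFR", initial_size=7310
        )
        dem.sort_events()
        theirs = {p: {"S": [], "pi": []} for p in pops}
        mut_seed = np.random.default_rng(78)
        for ts in msprime.sim_ancestry(
            samples={p: n // 2 for p, n in pops.items()}, demography=dem,
            sequence_length=L, num_replicates=reps, random_seed=1234,
        ):
            mts = msprime.sim_mutations(
                ts, rate=g.mutation_rate,
                random_seed=int(mut_seed.integers(1, 2**31)),
                model=msprime.BinaryMutationModel(),
            )
            for k, p in enumerate(pops):
                samples = mts.samples(population=k)
                afs = mts.allele_frequency_spectrum(
                    sample_sets=[samples], span_normalise=False, polarised=True
                )
                theirs[p]["S"].append(afs[1:len(samples)].sum())
                theirs[p]["pi"].append(
                    float(mts.diversity(sample_sets=samples, span_normalise=False))
                )
        for p in pops:
            for stat in ("S", "pi"):
                pval = sps.ks_2samp(ours[p][stat], theirs[p][stat]).pvalue
                assert pval > 0.01, f"{stat} mismatch in {p} (KS p={pval:.4f})"


class TestNullTajimaDistribution:
    def test_constant_size_null_is_centred_on_zero(self, single_pop_dem, rng):
        # recombining windows (rho ~ 16), the regime the scan's windows
        # live in; without recombination D's single-tree null mean is
        # visibly negative (its classic finite-sample bias)
        dem = single_pop_dem(n=800, mu=1.5e-6, r=5e-7)
        null = null_tajima_distribution(
            dem, {"P": 40}, window=10_000, n_reps=500, seed=5
        )
        vals = null.values["P"]
        se = vals.std(ddof=1) / math.sqrt(vals.size)
        assert abs(vals.mean()) <= 3 * se
        assert null.thresholds["P"] >= np.median(vals)

    def test_determinism_and_min_reps(self, single_pop_dem):
        dem = single_pop_dem(n=500, mu=1e-6)
        a = null_tajima_distribution(dem, {"P": 10}, 5_000, n_reps=100, seed=3)
        b = null_tajima_distribution(dem, {"P": 10}, 5_000, n_reps=100, seed=3)
        assert np.array_equal(a.values["P"], b.values["P"])
        with pytest.raises(ValueError):
            null_tajima_distribution(dem, {"P": 10}, 5_000, n_reps=50, seed=3)


class TestConditionalAlleleAge:
    def test_common_alleles_are_older_than_rare_ones(self, single_pop_dem):
        dem = single_pop_dem(n=400)
        young = conditional_allele_age(
            dem, {"P": 12}, {"P": 1}, n_accepted=150, seed=1
        )
        old = conditional_allele_age(
            dem, {"P": 12}, {"P": 11}, n_accepted=150, seed=1
        )
        assert old.age_mean > young.age_mean

    def test_matches_frequency_conditioned_closed_form(self, single_pop_dem):
        dem = single_pop_dem(n=1000)
        n, i = 50, 15
        est = conditional_allele_age(
            dem, {"P": n}, {"P": i}, n_accepted=250, seed=5
        )
        x = i / n
        expected = -4 * 1000 * x / (1 - x) * math.log(x)
        assert abs(est.age_mean - expected) <= 3 * est.age_se
        assert est.tmrca_mean > est.age_mean

    def test_years_conversion_uses_generation_time(self, single_pop_dem):
        dem = single_pop_dem(n=300)
        est = conditional_allele_age(dem, {"P": 10}, {"P": 3}, n_accepted=50, seed=2)
        assert est.age_years == pytest.approx(est.age_mean * dem.generation_time)

    def test_fixed_seed_reproduces_estimate(self, single_pop_dem):
        dem = single_pop_dem(n=300)
        a = conditional_allele_age(dem, {"P": 10}, {"P": 3}, n_accepted=50, seed=9)
        b = conditional_allele_age(dem, {"P": 10}, {"P": 3}, n_accepted=50, seed=9)
        assert a.age_mean == b.age_mean and a.tmrca_mean == b.tmrca_mean

    def test_invalid_counts_error(self, single_pop_dem):
        dem = single_pop_dem(n=300)
        with pytest.raises(ValueError):
            conditional_allele_age(dem, {"P": 10}, {"P": 0}, n_accepted=10, seed=0)
        with pytest.raises(ValueError):
            conditional_allele_age(dem, {"P": 10}, {"P": 10}, n_accepted=10, seed=0)
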