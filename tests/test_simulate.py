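"""Generator-level checks: allele frequencies, pedigree structure,
dispersal kernels, Mendelian genotypes and the fecal-sampling layer."""

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from snpdispersal.markers import HET, MISSING
from snpdispersal.simulate import (
    SimulationConfig,
    assign_home_ranges,
    default_panel,
    observe_genotypes,
    simulate_allele_frequencies,
    simulate_dataset,
    simulate_fecal_samples,
    simulate_pedigree_population,
    simulate_true_genotypes,
)


class TestAlleleFrequencies:
    def test_mean_maf_matches_panel_design(self):
        maf = simulate_allele_frequencies(87, 0.37, seed=1)
        assert np.all((maf > 0) & (maf <= 0.5))
        assert 0.35 <= maf.mean() <= 0.39

    def test_single_locus_bounds_at_maximal_maf(self):
        maf = simulate_allele_frequencies(1, 0.5, seed=0)
        assert maf.shape == (1,) and 0 < maf[0] <= 0.5

    def test_seeded_determinism(self):
        a = simulate_allele_frequencies(50, 0.3, seed=9)
        b = simulate_allele_frequencies(50, 0.3, seed=9)
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize("bad", [0.0, 0.6, -0.1])
    def test_invalid_maf_mean_rejected(self, bad):
        with pytest.raises(ValueError):
            simulate_allele_frequencies(10, bad, seed=0)


class TestPedigree:
    def test_no_offspring_when_mean_zero(self):
        cfg = SimulationConfig(n_founders_f=5, n_founders_m=5,
                               mean_offspring_per_mother=0.0, seed=0)
        truth = simulate_pedigree_population(cfg)
        assert truth.individuals["mother_id"].isna().all()

    def test_parentage_graph_is_acyclic(self):
        cfg = SimulationConfig(n_founders_f=10, n_founders_m=10, seed=3)
        truth = simulate_pedigree_population(cfg)
        g = nx.DiGraph()
        for _, r in truth.individuals.iterrows():
            for p in (r["mother_id"], r["father_id"]):
                if p is not None:
                    g.add_edge(p, r["id"])
        assert nx.is_directed_acyclic_graph(g)
        sex = dict(zip(truth.individuals["id"], truth.individuals["sex"]))
        for _, r in truth.individuals.iterrows():
            if r["mother_id"] is not None:
                assert sex[r["mother_id"]] == "F"
                assert sex[r["father_id"]] == "M"

    def test_offspring_count_within_poisson_interval(self):
        # 100 mothers x Poisson(2): total offspring ~ Poisson(200)
        cfg = SimulationConfig(n_founders_f=100, n_founders_m=100,
                               n_generations=2, mean_offspring_per_mother=2.0,
                               seed=11)
        truth = simulate_pedigree_population(cfg)
        n_off = int(truth.individuals["mother_id"].notna().sum())
        lo, hi = stats.poisson.ppf([0.005, 0.995], 200)
        assert lo <= n_off <= hi

    def test_too_few_generations_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_generations=1)


class TestHomeRanges:
    def test_zero_kernel_collapses_offspring_onto_mother(self):
        cfg = SimulationConfig(n_founders_f=6, n_founders_m=6,
                               disp_mean_f_km=0.0, disp_mean_m_km=0.0,
                               cub_litter_prob=0.0, seed=5)
        truth = assign_home_ranges(simulate_pedigree_population(cfg), cfg)
        df = truth.individuals.set_index("id")
        for _, r in df[df["mother_id"].notna()].iterrows():
            m = df.loc[r["mother_id"]]
            assert r["x_km"] == m["x_km"] and r["y_km"] == m["y_km"]

    def test_male_kernel_mean_recovered(self):
        from snpdispersal.simulate import _displacements
        rng = np.random.default_rng(2)
        d = _displacements(10_000, 33.8, "exponential", rng)
        mags = np.hypot(d[:, 0], d[:, 1])
        se = mags.std(ddof=1) / 100
        assert abs(mags.mean() - 33.8) < 3 * se

    def test_directions_are_isotropic(self):
        from snpdispersal.simulate import _displacements
        rng = np.random.default_rng(3)
        d = _displacements(20_000, 10.0, "halfnormal", rng)
        # mean displacement vector should vanish by symmetry
        assert np.all(np.abs(d.mean(axis=0)) < 0.3)


class TestGenotypes:
    def test_mendelian_sharing_with_both_parents(self, ideal_dataset):
        ds = ideal_dataset
        G = ds.truth.true_genotypes[:, ds.panel.autosomal_idx]
        idx = ds.truth.index_of()
        for _, r in ds.truth.individuals.iterrows():
            if r["mother_id"] is None:
                continue
            o = G[idx[r["id"]]]
            for p in (r["mother_id"], r["father_id"]):
                gp = G[idx[p]]
                # opposite homozygotes would violate Mendelian descent
                assert not np.any(((o == 0) & (gp == 2)) | ((o == 2) & (gp == 0)))

    def test_replicates_identical_without_error(self, ideal_dataset):
        gt = ideal_dataset.genotypes
        for _, ix in gt.groups().items():
            if len(ix) > 1:
                assert np.all(gt.calls[ix] == gt.calls[ix[0]])

    def test_miscall_rate_matches_binomial_oracle(self, small_panel, rng):
        # replicate a heterozygote 1e5 times at epsilon=0.01: each of the
        # two alleles flips independently, so P(call changes) = 2e(1-e)
        n = 100_000
        true = np.full((n, small_panel.n_loci), MISSING, dtype=np.int8)
        true[:, small_panel.autosomal_idx[0]] = HET
        obs = observe_genotypes(true, small_panel, epsilon=0.01,
                                dropout_rate=0.0, rng=rng)
        changed = (obs[:, small_panel.autosomal_idx[0]] != HET).mean()
        p = 2 * 0.01 * 0.99
        se = np.sqrt(p * (1 - p) / n)
        assert abs(changed - p) < 3 * se

    def test_dropout_fraction_converges(self, small_panel, rng):
        n = 50_000
        l0 = small_panel.autosomal_idx[0]
        true = np.full((n, small_panel.n_loci), MISSING, dtype=np.int8)
        true[:, l0] = HET
        obs = observe_genotypes(true, small_panel, epsilon=0.0,
                                dropout_rate=0.05, rng=rng)
        hom = np.isin(obs[:, l0], [0, 2]).mean()
        se = np.sqrt(0.05 * 0.95 / n)
        assert abs(hom - 0.05) < 3 * se

    def test_sex_linked_and_mt_structure(self, ideal_dataset):
        ds = ideal_dataset
        G = ds.truth.true_genotypes
        idx = ds.truth.index_of()
        hap = dict(zip(ds.truth.individuals["id"],
                       ds.truth.individuals["mt_haplotype"]))
        for _, r in ds.truth.individuals.iterrows():
            row = G[idx[r["id"]]]
            if r["sex"] == "M":
                assert np.all(row[ds.panel.y_idx] >= 0)
                assert not np.any(row[ds.panel.x_idx] == HET)
            else:
                assert np.all(row[ds.panel.y_idx] == MISSING)
            if r["mother_id"] is not None:
                assert hap[r["id"]] == hap[r["mother_id"]]


class TestFecalSamples:
    def test_zero_scatter_puts_samples_at_center(self):
        cfg = SimulationConfig(n_founders_f=5, n_founders_m=5,
                               sample_scatter_km=0.0, seed=8)
        truth = assign_home_ranges(simulate_pedigree_population(cfg), cfg)
        samples = simulate_fecal_samples(truth, cfg)
        centers = truth.individuals.set_index("id")[["x_km", "y_km"]]
        for _, s in samples.iterrows():
            c = centers.loc[s["individual_id"]]
            assert s["x_km"] == c["x_km"] and s["y_km"] == c["y_km"]

    def test_sample_counts_bounded_by_19(self):
        cfg = SimulationConfig(n_founders_f=60, n_founders_m=60, seed=4)
        truth = assign_home_ranges(simulate_pedigree_population(cfg), cfg)
        samples = simulate_fecal_samples(truth, cfg)
        counts = samples.groupby("individual_id").size()
        assert counts.max() <= 19 and counts.min() >= 1

    def test_full_dataset_is_seed_deterministic(self):
        cfg = SimulationConfig(n_founders_f=5, n_founders_m=5, seed=13)
        d1, d2 = simulate_dataset(cfg), simulate_dataset(cfg)
        np.testing.assert_array_equal(d1.genotypes.calls, d2.genotypes.calls)
        assert d1.samples.equals(d2.samples)
        assert d1.truth.individuals.equals(d2.truth.individuals)
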