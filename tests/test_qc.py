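"""Consolidation, error-rate, sex-calling, haplotype and panel-summary
checks, with brute-force oracles for the probability of identity."""

import itertools

import numpy as np
import pytest

from snpdispersal.markers import HET, HOM_A, HOM_B, INVALID, MISSING, build_panel
from snpdispersal.qc import (
    GenotypeTable,
    assign_mt_haplotype,
    build_individuals,
    call_sexes,
    consolidate_replicates,
    determine_sex,
    estimate_error_rates,
    panel_summaries,
    probability_of_identity,
)
from snpdispersal.simulate import SimulationConfig, simulate_dataset


def _table(panel, rows, groups=None):
    rows = np.asarray(rows, dtype=np.int8)
    n = rows.shape[0]
    groups = groups if groups is not None else [f"g{i}" for i in range(n)]
    return GenotypeTable(
        sample_ids=[f"s{i}" for i in range(n)], group_ids=list(groups),
        calls=rows, locus_ids=list(panel.locus_ids),
    )


class TestConsolidation:
    def test_identical_replicates_reproduce_themselves(self, small_panel):
        row = np.full(small_panel.n_loci, HET, dtype=np.int8)
        t = _table(small_panel, [row, row, row], groups=["a"] * 3)
        res = consolidate_replicates(t, small_panel)
        np.testing.assert_array_equal(res.individuals.calls[0], row)

    def test_majority_vote_and_tie(self, small_panel):
        l0 = small_panel.autosomal_idx[0]
        base = np.full(small_panel.n_loci, HOM_A, dtype=np.int8)
        r1, r2, r3 = base.copy(), base.copy(), base.copy()
        r3[l0] = HET  # {AA, AA, AB} -> AA
        res = consolidate_replicates(_table(small_panel, [r1, r2, r3], ["a"] * 3),
                                     small_panel)
        assert res.individuals.calls[0, l0] == HOM_A
        r2[l0] = HET  # {AA, AB} tie -> missing
        res = consolidate_replicates(_table(small_panel, [r1, r2], ["a"] * 2),
                                     small_panel)
        assert res.individuals.calls[0, l0] == MISSING

    def test_mixture_group_flagged_as_contamination(self, small_panel, rng):
        a_idx = small_panel.autosomal_idx
        r1 = np.full(small_panel.n_loci, HOM_A, dtype=np.int8)
        r2 = r1.copy()
        r2[a_idx] = HOM_B  # two different "individuals" in one group
        res = consolidate_replicates(_table(small_panel, [r1, r2], ["a"] * 2),
                                     small_panel)
        assert res.contaminated == ["a"]
        assert res.individuals.n_samples == 0

    def test_empty_table_rejected(self, small_panel):
        with pytest.raises(ValueError):
            consolidate_replicates(
                _table(small_panel, np.empty((0, small_panel.n_loci))),
                small_panel)


class TestErrorRates:
    def test_worked_example_arithmetic(self, small_panel):
        # 10 duplicate pairs at one het locus, one discordant
        l0 = small_panel.autosomal_idx[0]
        rows, groups = [], []
        for g in range(10):
            r = np.full(small_panel.n_loci, MISSING, dtype=np.int8)
            r[l0] = HET
            r2 = r.copy()
            if g == 0:
                r2[l0] = HOM_A
            rows += [r, r2]
            groups += [f"g{g}"] * 2
        est = estimate_error_rates(_table(small_panel, rows, groups), small_panel)
        assert est.n_het_comparisons == 10
        assert est.mismatch_error_rate == pytest.approx(1 / 10)
        assert est.allelic_dropout_rate == pytest.approx(1 / 20)

    def test_concordant_replicates_give_zero(self, small_panel):
        r = np.full(small_panel.n_loci, HET, dtype=np.int8)
        est = estimate_error_rates(_table(small_panel, [r, r], ["a"] * 2),
                                   small_panel)
        assert est.mismatch_error_rate == 0.0
        assert est.allelic_dropout_rate == 0.0

    def test_no_replicates_is_an_error(self, small_panel):
        r = np.full(small_panel.n_loci, HET, dtype=np.int8)
        with pytest.raises(ValueError):
            estimate_error_rates(_table(small_panel, [r, r], ["a", "b"]),
                                 small_panel)

    def test_dropout_estimator_recovers_simulated_rate(self):
        # ~1e4 replicated het comparisons with dropout 0.05
        cfg = SimulationConfig(n_founders_f=60, n_founders_m=60,
                               n_generations=2, mean_offspring_per_mother=0.0,
                               epsilon=0.0, dropout_rate=0.05,
                               missing_rate=0.0, invalid_rate=0.0,
                               prop_sampled=1.0, seed=21)
        ds = simulate_dataset(cfg)
        est = estimate_error_rates(ds.genotypes, ds.panel)
        d, n = 0.05, est.n_het_comparisons
        assert n > 2000
        # a comparison is counted when >=1 call is still het, so pairs
        # where both replicates dropped fall out of the denominator:
        # E[rate] = 2d(1-d) / (1-d^2) = 2d/(1+d)
        expected = 2 * d / (1 + d)
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(est.mismatch_error_rate - expected) < 3 * se


class TestSexCalling:
    def test_rule_table(self):
        y2 = np.array([HOM_A, HOM_A])
        assert determine_sex(y2, np.array([HOM_A, HOM_B, HOM_A])) == "M"
        assert determine_sex(np.array([MISSING, MISSING]),
                             np.array([HET, HOM_A, HOM_A])) == "F"
        assert determine_sex(y2, np.array([HET, HOM_A, HOM_A])) == "U"
        assert determine_sex(np.array([HOM_A, MISSING]),
                             np.array([HOM_A] * 3)) == "U"

    def test_error_free_simulation_fully_recovered(self, ideal_dataset):
        ds = ideal_dataset
        cons = consolidate_replicates(ds.genotypes, ds.panel)
        sexes = call_sexes(cons.individuals, ds.panel)
        truth = ds.truth.individuals.set_index("id")["sex"]
        for gid, s in zip(cons.individuals.group_ids, sexes):
            assert s == truth[gid]


class TestMtHaplotype:
    def test_exact_match_and_missing(self, small_panel):
        key = small_panel.haplotype_key
        assert assign_mt_haplotype(np.array(key["south"]), key) == "south"
        pat = np.array(key["south"])
        pat[0] = MISSING
        assert assign_mt_haplotype(pat, key) == "unassigned"

    def test_matriline_constant_in_simulation(self, ideal_dataset):
        ds = ideal_dataset
        cons = consolidate_replicates(ds.genotypes, ds.panel)
        ind = build_individuals(cons, ds.panel)
        truth = ds.truth.individuals.set_index("id")["mt_haplotype"]
        for _, r in ind.iterrows():
            assert r["mt_haplotype"] == truth[r["id"]]


class TestPanelSummaries:
    def test_pid_single_locus_enumeration(self):
        # p = q = 0.5: enumerate genotype pairs under HWE
        probs = {HOM_A: 0.25, HET: 0.5, HOM_B: 0.25}
        brute = sum(p * p for p in probs.values())
        assert probability_of_identity(np.array([0.5])) == pytest.approx(brute)
        assert brute == pytest.approx(0.375)

    def test_pid_multilocus_matches_pair_enumeration(self):
        maf = np.array([0.1, 0.37, 0.5])
        def hwe(q):
            return np.array([(1 - q) ** 2, 2 * q * (1 - q), q ** 2])
        brute = 1.0
        for q in maf:
            brute *= sum(p * p for p in hwe(q))
        assert probability_of_identity(maf) == pytest.approx(brute)

    def test_pid_monomorphic_factor_is_one(self):
        assert probability_of_identity(np.array([0.0])) == 1.0

    def test_pid_decreases_as_loci_added(self, rng):
        maf = rng.uniform(0.05, 0.5, size=20)
        pids = [probability_of_identity(maf[: k + 1]) for k in range(20)]
        assert np.all(np.diff(pids) < 0)

    def test_call_rate_counts_invalid_and_missing(self, small_panel):
        n_loci = small_panel.n_loci
        r = np.full(n_loci, HOM_A, dtype=np.int8)
        r[small_panel.autosomal_idx[0]] = MISSING
        r[small_panel.autosomal_idx[1]] = INVALID
        r[small_panel.y_idx] = MISSING  # female: excluded (Y loci)
        t = _table(small_panel, [r])
        s = panel_summaries(t, small_panel)
        non_y = n_loci - len(small_panel.y_idx)
        assert s.call_rate == pytest.approx((non_y - 2) / non_y)
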