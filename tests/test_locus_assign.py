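"""Decomposition enumeration, EM, configuration scoring and annealed search."""

import itertools
import math

import numpy as np
import pytest

from mhcpopgen.io_model import ObservedAlleleSet
from mhcpopgen.locus_assign import (
    NULL_ALLELE,
    SAOptions,
    call_genotypes,
    em_allele_frequencies,
    enumerate_decompositions,
    exhaustive_search,
    sa_search,
    score_configuration,
    select_locus_number,
    _set_partitions,
)
from mhcpopgen.synthetic import SimConfig, simulate_multilocus_dataset


def obs(*sets):
    return [
        ObservedAlleleSet(f"i{k}", "p", frozenset(s)) for k, s in enumerate(sets)
    ]


class TestEnumerateDecompositions:
    def test_forced_two_two_split(self):
        d = enumerate_decompositions(
            frozenset("abcd"), {"a": 1, "b": 1, "c": 2, "d": 2}, 2
        )
        assert d == [(("a", "b"), ("c", "d"))]

    def test_homozygote_vs_null_heterozygote(self):
        part = {"a": 1, "b": 1, "c": 2}
        no_null = enumerate_decompositions(frozenset("abc"), part, 2, allow_null=False)
        with_null = enumerate_decompositions(frozenset("abc"), part, 2, allow_null=True)
        assert no_null == [(("a", "b"), ("c", "c"))]
        assert len(with_null) == 2
        assert (("a", "b"), ("c", NULL_ALLELE)) in with_null

    def test_three_alleles_on_one_locus_incompatible(self):
        d = enumerate_decompositions(
            frozenset("abcd"), {"a": 1, "b": 1, "c": 1, "d": 2}, 2
        )
        assert d == []

    def test_uncovered_locus_needs_null(self):
        part = {"a": 1, "b": 1}
        assert enumerate_decompositions(frozenset("ab"), {**part, "c": 2}, 2) == []
        d = enumerate_decompositions(frozenset("ab"), {**part, "c": 2}, 2, allow_null=True)
        assert d == [(("a", "b"), (NULL_ALLELE, NULL_ALLELE))]


class TestEM:
    def test_degenerate_single_individual_single_allele(self):
        r = em_allele_frequencies(obs({"a"}), {"a": 1}, 1)
        assert r.freqs == [{"a": 1.0}]
        assert r.loglik == pytest.approx(0.0)

    def test_unique_decompositions_equal_counting(self):
        # every individual has a forced decomposition: EM == direct counting
        observations = obs({"a", "b", "c", "d"}, {"a", "b", "c", "d"}, {"a", "b", "c", "d"})
        part = {"a": 1, "b": 1, "c": 2, "d": 2}
        r = em_allele_frequencies(observations, part, 2)
        assert r.freqs[0] == pytest.approx({"a": 0.5, "b": 0.5})
        # lnL equals the plain HWE multinomial log-likelihood
        expect = 3 * (math.log(2 * 0.5 * 0.5) * 2)
        assert r.loglik == pytest.approx(expect)

    def test_monotone_loglik(self):
        cfg = SimConfig(m=2, alleles_per_locus=[3, 3], n_individuals=40, seed=9)
        _, truth = simulate_multilocus_dataset(cfg)
        r = em_allele_frequencies(truth.observed_sets, truth.partition, 2)
        hist = np.array(r.loglik_history)
        assert np.all(np.diff(hist) >= -1e-9)

    def test_em_attains_grid_maximum(self):
        # two loci with two alleles each: the likelihood has two free
        # frequencies; compare EM against a coarse grid of the marginal
        # likelihood computed by explicit decomposition enumeration
        cfg = SimConfig(m=2, alleles_per_locus=[2, 2], n_individuals=20, seed=3)
        _, truth = simulate_multilocus_dataset(cfg)
        observations = truth.observed_sets
        part = truth.partition
        em = em_allele_frequencies(observations, part, 2)

        names = sorted(part)
        l1 = [a for a in names if part[a] == 1]
        l2 = [a for a in names if part[a] == 2]

        def loglik(p1, p2):
            f = {l1[0]: p1, l1[1]: 1 - p1, l2[0]: p2, l2[1]: 1 - p2}
            total = 0.0
            for o in observations:
                s = 0.0
                for d in enumerate_decompositions(o.alleles, part, 2):
                    t = 1.0
                    for g in d:
                        t *= f[g[0]] ** 2 if g[0] == g[1] else 2 * f[g[0]] * f[g[1]]
                    s += t
                total += math.log(s) if s > 0 else -math.inf
            return total

        grid = np.linspace(0.01, 0.99, 99)
        best = max(loglik(p1, p2) for p1 in grid for p2 in grid)
        assert em.loglik >= best - 1e-3

    def test_infeasible_individual_gives_minus_inf(self):
        r = em_allele_frequencies(obs({"a", "b", "c"}), {"a": 1, "b": 1, "c": 1}, 1)
        assert not r.feasible and r.loglik == -math.inf


class TestScoreConfiguration:
    def test_hand_computed_hwe_multinomial(self, tiny_observations):
        cfg = score_configuration(tiny_observations, {"a": 1, "b": 1}, 1)
        assert cfg.loglik == pytest.approx(math.log(0.5625) + math.log(0.375))
        assert cfg.n_params == 1
        assert cfg.aic == pytest.approx(2 - 2 * cfg.loglik)

    def test_infeasible_scores_infinite(self):
        cfg = score_configuration(
            obs({"a", "b", "c"}), {"a": 1, "b": 1, "c": 1}, 1
        )
        assert cfg.aic == math.inf and cfg.bic == math.inf

    def test_bic_offset_closed_form(self):
        observations = obs(*[{"a", "b"}] * 100)
        a = score_configuration(observations, {"a": 1, "b": 1}, 1, criterion="AIC")
        b = score_configuration(observations, {"a": 1, "b": 1}, 1, criterion="BIC")
        assert b.bic - a.aic == pytest.approx(a.n_params * (math.log(100) - 2))

    def test_empty_locus_rejected(self):
        with pytest.raises(ValueError, match="at least one allele"):
            score_configuration(obs({"a"}), {"a": 1}, 2)


class TestSearch:
    def test_stirling_partition_counts(self):
        assert len(list(_set_partitions(list("abc"), 2))) == 3
        assert len(list(_set_partitions(list("abcde"), 2))) == 15
        assert len(list(_set_partitions(list("abcdef"), 2))) == 31

    def test_exhaustive_minimum_bounds_every_partition(self):
        cfg = SimConfig(m=2, alleles_per_locus=[3, 2], n_individuals=30, seed=5)
        _, truth = simulate_multilocus_dataset(cfg)
        observations = truth.observed_sets
        best = exhaustive_search(observations, 2)
        names = sorted({a for o in observations for a in o.alleles})
        for blocks in _set_partitions(names, 2):
            part = {a: i + 1 for i, b in enumerate(blocks) for a in b}
            cfg_ = score_configuration(observations, part, 2)
            assert best.score <= cfg_.score + 1e-9

    def test_exhaustive_guard(self):
        observations = obs({f"a{i}" for i in range(13)})
        with pytest.raises(ValueError, match="guard"):
            exhaustive_search(observations, 2)

    def test_cooccurrence_split_recovered_and_matches_oracle(self):
        # a,b never co-occur with pairing constraints that force a 2-2 split
        observations = obs(
            *[{"a", "b", "c", "d"}] * 10, *[{"a", "c"}] * 5, *[{"b", "d"}] * 5
        )
        sa = sa_search(observations, 2, SAOptions(seed=1))
        ex = exhaustive_search(observations, 2)
        assert sa.score == pytest.approx(ex.score)
        blocks = sa.canonical_partition()
        assert ({"a", "b"} in [set(b) for b in blocks]) or (
            {"a", "c"} in [set(b) for b in blocks]
        )

    def test_m_equals_one_returns_single_partition(self):
        observations = obs({"a", "b"}, {"a"})
        cfg = sa_search(observations, 1, SAOptions(seed=0))
        assert set(cfg.partition.values()) == {1}

    def test_reproducible_given_seed(self):
        cfg = SimConfig(m=2, alleles_per_locus=[3, 3], n_individuals=40, seed=21)
        _, truth = simulate_multilocus_dataset(cfg)
        o = truth.observed_sets
        a = sa_search(o, 2, SAOptions(seed=11, cycles=2))
        b = sa_search(o, 2, SAOptions(seed=11, cycles=2))
        assert a.partition == b.partition and a.score == b.score

    def test_score_invariant_to_relabeling(self):
        cfg = SimConfig(m=2, alleles_per_locus=[3, 2], n_individuals=25, seed=8)
        _, truth = simulate_multilocus_dataset(cfg)
        observations = truth.observed_sets
        part = truth.partition
        base = score_configuration(observations, part, 2)
        flipped = {a: 3 - l for a, l in part.items()}
        swap = score_configuration(observations, flipped, 2)
        assert base.score == pytest.approx(swap.score)
        assert base.canonical_partition() == swap.canonical_partition()

    def test_select_locus_number_feasibility_bound(self):
        observations = obs({"a", "b", "c"}, {"a", "b"})
        m_best, table = select_locus_number(observations, [1, 2], options=SAOptions(seed=0, cycles=1))
        row_m1 = table[table["m"] == 1].iloc[0]
        assert row_m1["score"] == math.inf  # 3 alleles cannot fit one locus
        assert m_best == 2


class TestCallGenotypes:
    def test_forced_decomposition_posterior_one(self):
        observations = obs({"a", "b", "c", "d"})
        cfg = score_configuration(
            observations, {"a": 1, "b": 1, "c": 2, "d": 2}, 2
        )
        ds, summary = call_genotypes(observations, cfg)
        assert summary["posterior"].iloc[0] == pytest.approx(1.0)
        called = ds.df
        g1 = called[called["locus"] == "locus1"].iloc[0]
        assert {g1["allele_a"], g1["allele_b"]} == {"a", "b"}

    def test_null_vs_homozygote_posterior(self):
        # single observed allele at one locus with allow_null: homozygote
        # wins iff p_a >= p_null (two-term posterior compared by hand)
        observations = obs(*[{"a"}] * 30, *[{"a", "b"}] * 4)
        cfg = score_configuration(
            observations, {"a": 1, "b": 1}, 1, allow_null=True
        )
        p = cfg.freqs[0]
        ds, _ = call_genotypes(observations, cfg, allow_null=True)
        first = ds.df.iloc[0]
        if p["a"] * p["a"] >= 2 * p["a"] * p.get(NULL_ALLELE, 0.0):
            assert (first["allele_a"], first["allele_b"]) == ("a", "a")
        else:
            assert (first["allele_a"], first["allele_b"]) == ("a", ".")

    def test_simulation_recovery_accuracy(self):
        cfg = SimConfig(m=2, alleles_per_locus=[4, 3], n_individuals=100, seed=17)
        _, truth = simulate_multilocus_dataset(cfg)
        best = exhaustive_search(truth.observed_sets, 2)
        ds, _ = call_genotypes(truth.observed_sets, best)
        # align locus labels to truth by allele overlap
        blocks = best.canonical_partition()
        truth_blocks = {}
        for a, l in truth.partition.items():
            truth_blocks.setdefault(l, set()).add(a)
        correct = total = 0
        merged = ds.df.merge(
            truth.genotypes.df,
            on=["individual_id"],
            suffixes=("_called", "_true"),
        )
        # compare genotype multisets per individual ignoring locus labels
        for ind, grp in ds.df.groupby("individual_id"):
            called = {
                frozenset((r.allele_a, r.allele_b)) for r in grp.itertuples()
            }
            tgrp = truth.genotypes.df[truth.genotypes.df["individual_id"] == ind]
            true = {
                frozenset((r.allele_a, r.allele_b)) for r in tgrp.itertuples()
            }
            total += 1
            correct += called == true
        assert correct / total >= 0.95
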