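"""Boltzmann partition functions, exact supports and the history sampler."""

import math

import numpy as np
import pytest

import adjscaff as A
from adjscaff.boltzmann import BoltzmannDP, empirical_supports
from helpers import enum_class_histories, random_small_classes, \
    two_species_world


def boltzmann_for(dataset, params):
    classes = A.partition(dataset.observed_adjacencies(), dataset.forest)
    assert len(classes) == 1
    return BoltzmannDP(classes[0], dataset.assemblies,
                       dataset.profiles(params), params)


class TestPartitionFunction:
    def test_unique_solution_class(self):
        # two sister species, both adjacencies observed, fully assembled:
        # essentially a single optimal history of score Gain dominates
        params = A.CostParameters()
        ds, _ = two_species_world(observed_y=True)
        b = boltzmann_for(ds, params)
        histories = enum_class_histories(b.dp)
        z_enum = sum(math.exp(-s / params.kT) for s, _ in histories)
        assert b.log_partition() == pytest.approx(math.log(z_enum))
        best = min(s for s, _ in histories)
        assert best == pytest.approx(params.gain)
        # every support of the optimal solution's adjacencies is ~1
        for support in b.all_supports().values():
            assert support == pytest.approx(1.0, abs=1e-3) or support < 0.05

    def test_partition_matches_enumeration_on_random_classes(self):
        params = A.CostParameters()
        for acls, ds, profiles in random_small_classes(50):
            b = BoltzmannDP(acls, ds.assemblies, profiles, params)
            z_enum = sum(math.exp(-s / params.kT)
                         for s, _ in enum_class_histories(b.dp))
            assert b.log_partition() == pytest.approx(math.log(z_enum),
                                                      abs=1e-6)

    def test_supports_match_enumeration(self):
        params = A.CostParameters()
        for acls, ds, profiles in random_small_classes(50):
            b = BoltzmannDP(acls, ds.assemblies, profiles, params)
            histories = enum_class_histories(b.dp)
            z = sum(math.exp(-s / params.kT) for s, _ in histories)
            for pair, support in b.all_supports().items():
                expect = sum(math.exp(-s / params.kT)
                             for s, ps in histories if pair in ps) / z
                assert support == pytest.approx(expect, abs=1e-6)

    def test_supports_are_probabilities(self):
        params = A.CostParameters()
        for acls, ds, profiles in random_small_classes(50):
            b = BoltzmannDP(acls, ds.assemblies, profiles, params)
            for support in b.all_supports().values():
                assert 0.0 <= support <= 1.0


class TestTemperatureLimits:
    def test_low_kt_tends_to_optimal_fraction(self):
        params_cold = A.CostParameters(kT=0.01)
        for acls, ds, profiles in random_small_classes(20):
            b = BoltzmannDP(acls, ds.assemblies, profiles, params_cold)
            histories = enum_class_histories(b.dp)
            best = min(s for s, _ in histories)
            optima = [ps for s, ps in histories if s <= best + 1e-9]
            for pair, support in b.all_supports().items():
                frac = sum(1 for ps in optima if pair in ps) / len(optima)
                assert support == pytest.approx(frac, abs=0.02)

    def test_high_kt_tends_to_counting_fraction(self):
        params_hot = A.CostParameters(kT=1e4)
        for acls, ds, profiles in random_small_classes(10):
            b = BoltzmannDP(acls, ds.assemblies, profiles, params_hot)
            histories = [ps for s, ps in enum_class_histories(b.dp)
                         if s < math.inf]
            for pair, support in b.all_supports().items():
                frac = sum(1 for ps in histories if pair in ps) \
                    / len(histories)
                assert support == pytest.approx(frac, abs=0.02)


class TestSampler:
    def test_unique_solution_sampled_identically(self):
        params = A.CostParameters(kT=0.01)
        ds, _ = two_species_world(observed_y=True)
        b = boltzmann_for(ds, params)
        histories = b.sample_histories(50, seed=0)
        keys = {tuple((e.v1.name, e.v2.name, e.state) for e in h.entries)
                for h in histories}
        assert len(keys) == 1

    def test_reproducible_under_seed(self):
        params = A.CostParameters()
        acls, ds, profiles = random_small_classes(10)[3]
        b = BoltzmannDP(acls, ds.assemblies, profiles, params)
        h1 = b.sample_histories(100, seed=7)
        h2 = b.sample_histories(100, seed=7)
        assert [h.score for h in h1] == [h.score for h in h2]

    def test_empirical_matches_exact_supports(self):
        # 3-sigma binomial agreement at N=2000 on a handful of classes
        params = A.CostParameters()
        n = 2000
        for acls, ds, profiles in random_small_classes(8):
            b = BoltzmannDP(acls, ds.assemblies, profiles, params)
            emp = empirical_supports(b.sample_histories(n, seed=11))
            for pair, exact in b.all_supports().items():
                got = emp.get(pair, 0.0)
                se = math.sqrt(max(exact * (1 - exact), 0.0) / n)
                assert abs(got - exact) <= 3 * se + 5e-3

    def test_cold_sampler_hits_optima(self):
        # at kT = 0.1 the ensemble is dominated by optimal histories
        params = A.CostParameters()
        hits = total = 0
        for acls, ds, profiles in random_small_classes(10):
            from adjscaff.dp import AdjacencyDP
            best = AdjacencyDP(acls, ds.assemblies, profiles,
                               params).total_cost()
            b = BoltzmannDP(acls, ds.assemblies, profiles, params)
            for h in b.sample_histories(200, seed=3):
                total += 1
                hits += h.score <= best + 1e-6
        assert hits / total >= 0.95

    def test_sampled_scores_match_enumerated_support(self):
        params = A.CostParameters()
        acls, ds, profiles = random_small_classes(10)[5]
        b = BoltzmannDP(acls, ds.assemblies, profiles, params)
        freqs = {}
        n = 4000
        for h in b.sample_histories(n, seed=5):
            key = round(h.score, 6)
            freqs[key] = freqs.get(key, 0) + 1
        z = math.exp(b.log_partition())
        for s, _ in enum_class_histories(b.dp):
            freqs.setdefault(round(s, 6), 0)
        # aggregate enumeration by score
        by_score = {}
        for s, _ in enum_class_histories(b.dp):
            key = round(s, 6)
            by_score[key] = by_score.get(key, 0.0) + math.exp(-s / params.kT)
        for key, mass in by_score.items():
            expect = mass / z
            got = freqs.get(key, 0) / n
            se = math.sqrt(max(expect * (1 - expect), 0.0) / n)
            assert abs(got - expect) <= 3 * se + 5e-3
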