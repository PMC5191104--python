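"""Genetic-programming engine: protected semantics, evolution, relevance."""

import math

import numpy as np
import pytest

from jellyrec import gp
from jellyrec.dataset import CVPlan, Dataset
from jellyrec.synthetic import separable_table

# Independent oracles for the three published ensemble members, written
# directly from their printed expressions with the same protected
# conventions (natural log of |v| with log 0 = 0, a/b = 1 for b ~ 0).


def _plog(v):
    return 0.0 if abs(v) == 0 else math.log(abs(v))


def _pdiv(a, b):
    return 1.0 if abs(b) < 1e-12 else a / b


C1_TEXT = "log(sAxm) + atan(ecc) - 0.3/(1 + ecc)"
C2_TEXT = "log(atan(ecc)) + cos(ecc - sAxm) + sAxm/4 + log(atan(sAxm))"
C3_TEXT = "2*sAxm + tan(log(ecc)) + log(sAxm) + cos(log(sAxm))"


def c1_oracle(s, e):
    return _plog(s) + math.atan(e) - _pdiv(0.3, 1 + e)


def c2_oracle(s, e):
    return (_plog(math.atan(e)) + math.cos(e - s) + _pdiv(s, 4)
            + _plog(math.atan(s)))


def c3_oracle(s, e):
    return 2 * s + math.tan(_plog(e)) + _plog(s) + math.cos(_plog(s))


def vec(semiAxm=1.0, ecc=0.5, axm=1.0):
    x = dict.fromkeys(gp.FEATURE_NAMES, 1.0)
    x.update(semiAxm=semiAxm, ecc=ecc, axm=axm)
    return x


class TestProtectedEval:
    def test_division_by_zero_is_one(self):
        tree = gp.parse_expression("semiAxm / 0")
        assert gp.protected_eval(tree, vec(semiAxm=42.0)) == 1.0

    def test_log_of_zero_is_zero(self):
        tree = gp.parse_expression("log(ecc)")
        assert gp.protected_eval(tree, vec(ecc=0.0)) == 0.0

    def test_sqrt_of_negative_uses_absolute_value(self):
        tree = gp.parse_expression("sqrt(0 - semiAxm)")
        assert gp.protected_eval(tree, vec(semiAxm=9.0)) == pytest.approx(3.0)

    def test_c1_printed_values(self):
        tree = gp.parse_expression(C1_TEXT)
        assert gp.variables_used(tree) == {"semiAxm", "ecc"}
        assert gp.protected_eval(tree, vec(semiAxm=1, ecc=0)) == pytest.approx(-0.3)
        v = gp.protected_eval(tree, vec(semiAxm=10, ecc=0.9))
        assert v == pytest.approx(2.878, abs=5e-3)

    def test_always_finite_on_extreme_inputs(self):
        tree = gp.parse_expression("tan(semiAxm) * tan(ecc) / (ecc - ecc)")
        out = gp.protected_eval(tree, vec(semiAxm=1.5707963, ecc=1e300))
        assert np.isfinite(out)

    def test_unbound_variable_errors(self):
        tree = gp.Node("var", value="nosuch")
        with pytest.raises(gp.GPError):
            gp.protected_eval(tree, vec())


class TestClassify:
    @pytest.mark.parametrize("value,label", [(-0.3, 0), (0.0, 0), (2.88, 1)])
    def test_strict_positive_threshold(self, value, label):
        tree = gp.constant(value)
        assert gp.classify(tree, vec()) == label


class TestRawFitness:
    def table(self):
        X = np.zeros((4, len(gp.FEATURE_NAMES)))
        X[:, 0] = [10, 12, -5, -7]  # semiAxm
        return Dataset(X, [1, 1, 0, 0])

    def test_perfect_classifier_zero(self):
        assert gp.raw_fitness(gp.parse_expression("semiAxm"), self.table()) == 0.0

    def test_inverted_classifier_one(self):
        assert gp.raw_fitness(gp.parse_expression("0 - semiAxm"),
                              self.table()) == 1.0

    def test_three_of_four_correct(self):
        # threshold at 11 mislabels one positive
        tree = gp.parse_expression("semiAxm - 11")
        assert gp.raw_fitness(tree, self.table()) == 0.25

    def test_empty_dataset_errors(self):
        with pytest.raises(Exception):
            gp.raw_fitness(gp.constant(1.0),
                           Dataset(np.zeros((0, 11)), np.zeros(0, int)))


class TestInitialization:
    def test_population_size_and_depth(self):
        params = gp.GPParams(population_size=200, seed=0)
        rng = np.random.default_rng(0)
        pset = gp.PrimitiveSet.create(rng)
        pop = gp.ramped_half_and_half(params, pset, rng)
        assert len(pop) == 200
        assert all(gp.depth(t) <= 4 for t in pop)

    def test_same_seed_identical_population(self):
        params = gp.GPParams(population_size=50, seed=5)
        pops = []
        for _ in range(2):
            rng = np.random.default_rng(5)
            pset = gp.PrimitiveSet.create(rng)
            pops.append([gp.serialize_expression(t)
                         for t in gp.ramped_half_and_half(params, pset, rng)])
        assert pops[0] == pops[1]

    def test_constants_within_stated_ranges(self):
        for s in range(20):
            pset = gp.PrimitiveSet.create(np.random.default_rng(s))
            assert 0 <= len(pset.constants) <= 10
            assert all(-10 <= c <= 10 for c in pset.constants)


class TestSelectionAndReproduction:
    def test_roulette_proportions(self):
        # scaled fitnesses {3, 1}: first individual picked 75% of the time
        rng = np.random.default_rng(0)
        cum = np.cumsum([3.0, 1.0])
        picks = sum(gp._roulette_pick(cum, rng) == 0 for _ in range(10_000))
        assert abs(picks / 10_000 - 0.75) < 0.02

    def test_offspring_never_exceed_depth_limit(self):
        rng = np.random.default_rng(1)
        pset = gp.PrimitiveSet.create(rng)
        params = gp.GPParams(population_size=30, seed=1)
        pop = gp.ramped_half_and_half(params, pset, rng)
        cum = np.cumsum(np.ones(len(pop)))
        for _ in range(2000):
            child, _, _, _ = gp.reproduce(pop, cum, params, pset, rng)
            assert gp.depth(child) <= params.max_depth


class TestEvolve:
    def test_separable_fixture_reaches_zero_fitness(self):
        # positives semiAxm ~ N(15,1), negatives ~ N(3,1)
        wins = 0
        for s in range(20):
            ds = separable_table(seed=s, n_per_class=30)
            rng = np.random.default_rng((s, 99))
            pset = gp.PrimitiveSet.create(rng, ds.feature_names)
            params = gp.GPParams(seed=s)  # operating scale: pop 1000, 500 gens
            ind = gp.evolve(ds, params, pset, rng)
            wins += ind.raw_fitness == 0.0
        assert wins >= 19  # >= 95% of 20 seeded runs

    def test_population_size_constant_and_elitism_monotone(self):
        ds = separable_table(seed=0, n_per_class=10)
        # near-random data so evolution runs a few generations
        rng_lab = np.random.default_rng(0)
        ds = Dataset(ds.X, rng_lab.integers(0, 2, ds.n))
        params = gp.GPParams(population_size=80, max_generations=8, seed=0)
        log = gp.EvolutionLog()
        rng = np.random.default_rng(0)
        pset = gp.PrimitiveSet.create(rng)
        gp.evolve(ds, params, pset, rng, log)
        assert all(sz == 80 for sz in log.pop_sizes)
        assert all(a >= b for a, b in zip(log.best_raw, log.best_raw[1:]))


class TestPoolAndRelevance:
    def _pool_from_sets(self, var_sets):
        inds = []
        for vs in var_sets:
            tree = gp.variable(vs[0]) if len(vs) == 1 else None
            if tree is None:
                tree = gp.variable(vs[0])
                for v in vs[1:]:
                    tree = gp.Node("add", (tree, gp.variable(v)))
            inds.append(gp.Individual(tree, 0.1))
        return gp.PopulationPool(inds)

    def test_build_pool_one_individual_per_run(self):
        ds = separable_table(seed=1, n_per_class=20)
        plan = CVPlan(k_folds=2, subsamples_per_fold=3, seed=1)
        params = gp.GPParams(population_size=60, max_generations=10, seed=1)
        pool = gp.build_population_pool(ds, plan, params)
        assert len(pool.individuals) == 6
        assert all(c <= 6 for c in pool.occurrence_counts.values())

    def test_ubiquitous_feature_is_relevant(self):
        sets = [("semiAxm", "ecc", "stdg")] * 50 + [("semiAxm", "ent")] * 50
        rel = gp.relevance_test(self._pool_from_sets(sets), 0.001)
        assert "semiAxm" in rel.relevant_features
        assert 0 < rel.p0 < 1

    def test_absent_feature_never_relevant(self):
        sets = [("semiAxm",)] * 100
        rel = gp.relevance_test(self._pool_from_sets(sets), 0.001)
        assert "contrast" not in rel.relevant_features

    def test_type_one_error_rate_bounded(self):
        # uniform random variable usage: flags should be rare
        rng = np.random.default_rng(42)
        p_value = 0.02  # larger alpha keeps the Monte-Carlo check cheap
        flagged = total = 0
        for _ in range(200):
            sets = []
            for _ in range(60):
                mask = rng.random(11) < 0.25
                if not mask.any():
                    mask[rng.integers(0, 11)] = True
                sets.append(tuple(np.array(gp.FEATURE_NAMES)[mask]))
            rel = gp.relevance_test(self._pool_from_sets(sets), p_value)
            flagged += len(rel.relevant_features)
            total += 11
        assert flagged / total <= 2 * p_value + 0.02


class TestEnsemble:
    def members(self):
        return [gp.Individual(gp.parse_expression(t), 0.1)
                for t in (C1_TEXT, C2_TEXT, C3_TEXT)]

    def test_minimal_variable_members_selected(self):
        extra = [gp.Individual(gp.parse_expression("stdg + ent + semiAxm"), 0.1),
                 gp.Individual(gp.parse_expression("areap"), 0.1)]
        pool = gp.PopulationPool(self.members() + extra)
        rel = gp.RelevanceResult(0.001, 0.3, 5,
                                 frozenset({"semiAxm", "axm", "ecc"}))
        ens = gp.build_ensemble(pool, rel)
        texts = {gp.serialize_expression(m.tree) for m in ens.members}
        expect = {gp.serialize_expression(m.tree) for m in self.members()}
        assert texts == expect

    def test_single_qualifying_member(self):
        pool = gp.PopulationPool(
            [gp.Individual(gp.parse_expression("semiAxm - 3"), 0.0),
             gp.Individual(gp.parse_expression("stdg"), 0.2)])
        rel = gp.RelevanceResult(0.001, 0.2, 5, frozenset({"semiAxm"}))
        assert len(gp.build_ensemble(pool, rel).members) == 1

    def test_no_qualifying_member_errors(self):
        pool = gp.PopulationPool([gp.Individual(gp.parse_expression("stdg"), 0.2)])
        rel = gp.RelevanceResult(0.001, 0.2, 5, frozenset({"semiAxm"}))
        with pytest.raises(gp.GPError):
            gp.build_ensemble(pool, rel)

    def test_vote_semantics(self):
        ens = gp.Ensemble([gp.Individual(gp.constant(1.0)),
                           gp.Individual(gp.constant(-1.0))], frozenset())
        assert gp.ensemble_classify(ens, vec()) == 0  # tie -> 0
        ens2 = gp.Ensemble([gp.Individual(gp.constant(1.0))] * 3, frozenset())
        assert gp.ensemble_classify(ens2, vec()) == 1

    def test_published_members_match_hand_vote(self):
        ens = gp.Ensemble(self.members(), frozenset({"semiAxm", "axm", "ecc"}))
        s, e = 10.0, 0.9
        votes = [1 if f(s, e) > 0 else -1
                 for f in (c1_oracle, c2_oracle, c3_oracle)]
        expected = int(sum(votes) > 0)
        assert gp.ensemble_classify(ens, vec(semiAxm=s, ecc=e, axm=20.0)) == expected


class TestExpressionRoundTrip:
    @pytest.mark.parametrize("text,oracle", [
        (C1_TEXT, c1_oracle), (C2_TEXT, c2_oracle), (C3_TEXT, c3_oracle),
    ])
    def test_matches_independent_oracle_on_random_inputs(self, text, oracle):
        tree = gp.parse_expression(text)
        rng = np.random.default_rng(0)
        for _ in range(100):
            s = rng.uniform(0.1, 30.0)
            e = rng.uniform(0.0, 1.0)
            got = gp.protected_eval(tree, vec(semiAxm=s, ecc=e))
            assert got == pytest.approx(oracle(s, e), rel=1e-9, abs=1e-9)

    @pytest.mark.parametrize("text", [C1_TEXT, C2_TEXT, C3_TEXT])
    def test_serialize_parse_round_trip(self, text):
        tree = gp.parse_expression(text)
        back = gp.parse_expression(gp.serialize_expression(tree))
        rng = np.random.default_rng(1)
        for _ in range(100):
            x = vec(semiAxm=rng.uniform(-20, 20), ecc=rng.uniform(-2, 2))
            assert gp.protected_eval(tree, x) == gp.protected_eval(back, x)

    def test_unknown_function_errors(self):
        with pytest.raises(gp.ParseError):
            gp.parse_expression("foo(semiAxm)")

    def test_unknown_symbol_errors_with_position(self):
        with pytest.raises(gp.ParseError, match="col"):
            gp.parse_expression("semiAxm + wibble")

    def test_arity_mismatch_errors(self):
        with pytest.raises(gp.ParseError):
            gp.parse_expression("log(semiAxm, ecc)")
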