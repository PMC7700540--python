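import numpy as np
import pytest

from harkit.ga import (
    Chromosome,
    GAFeatureSelector,
    crossover,
    evolve,
    fitness,
    init_population,
    mutate,
    reweight,
    select_features,
)
from harkit.types import GAConfig

FAST_GA = GAConfig(population_size=8, max_generations=5, patience=3, rf_estimators=20)


class TestInitPopulation:
    def test_deterministic(self):
        a = init_population(10, 7, seed=5)
        b = init_population(10, 7, seed=5)
        for ca, cb in zip(a.members, b.members):
            np.testing.assert_array_equal(ca.weights, cb.weights)

    def test_genes_in_unit_interval(self):
        pop = init_population(30, 71, seed=1)
        for ch in pop.members:
            assert np.all((ch.weights >= 0) & (ch.weights <= 1))

    def test_bad_sizes_raise(self):
        with pytest.raises(ValueError):
            init_population(1, 5, seed=0)
        with pytest.raises(ValueError):
            init_population(5, 0, seed=0)


class TestCrossover:
    def test_identical_parents_unchanged(self):
        p = Chromosome(np.full(6, 0.4))
        o1, o2 = crossover(p, p, seed=3)
        np.testing.assert_array_equal(o1.weights, p.weights)
        np.testing.assert_array_equal(o2.weights, p.weights)

    def test_block_structure_from_extreme_parents(self):
        p0, p1 = Chromosome(np.zeros(10)), Chromosome(np.ones(10))
        o1, o2 = crossover(p0, p1, seed=1)
        d1 = np.diff(o1.weights)
        assert np.sum(d1 != 0) == 1  # one 0-block then one 1-block
        np.testing.assert_array_equal(o1.weights + o2.weights, np.ones(10))

    def test_positionwise_multiset_conserved(self, rng):
        p1 = Chromosome(rng.uniform(size=12))
        p2 = Chromosome(rng.uniform(size=12))
        o1, o2 = crossover(p1, p2, seed=7)
        for j in range(12):
            assert {o1.weights[j], o2.weights[j]} == {p1.weights[j], p2.weights[j]}

    def test_mismatched_lengths_raise(self):
        with pytest.raises(ValueError):
            crossover(Chromosome(np.zeros(3)), Chromosome(np.zeros(4)))


class TestMutate:
    def test_rate_zero_identity(self, rng):
        ch = Chromosome(rng.uniform(size=20))
        out = mutate(ch, rate=0.0, seed=1)
        np.testing.assert_array_equal(out.weights, ch.weights)

    def test_rate_one_replays_seeded_stream(self):
        ch = Chromosome(np.full(10, 0.5))
        out = mutate(ch, rate=1.0, seed=11)
        # oracle: replay the same seeded uniform stream
        r = np.random.default_rng(11)
        mask = r.uniform(size=10) < 1.0
        expected = r.uniform(0.0, 1.0, size=10)
        assert mask.all()
        np.testing.assert_array_equal(out.weights, expected)

    def test_mutated_count_within_binomial_bound(self):
        n, rate = 10_000, 0.05
        ch = Chromosome(np.full(n, 0.5))
        out = mutate(ch, rate=rate, seed=2)
        changed = int(np.sum(out.weights != ch.weights))
        sd = np.sqrt(n * rate * (1 - rate))
        assert abs(changed - n * rate) <= 3 * sd

    def test_bad_rate_raises(self):
        with pytest.raises(ValueError):
            mutate(Chromosome(np.zeros(3)), rate=1.5)


class TestReweight:
    def test_all_ones_identity(self, rng):
        X = rng.normal(size=(5, 4))
        np.testing.assert_array_equal(reweight(X, Chromosome(np.ones(4))), X)

    def test_basis_vector_keeps_one_column(self, rng):
        X = rng.normal(size=(5, 4))
        w = np.zeros(4)
        w[0] = 1.0
        out = reweight(X, Chromosome(w))
        np.testing.assert_array_equal(out[:, 0], X[:, 0])
        np.testing.assert_array_equal(out[:, 1:], np.zeros((5, 3)))

    def test_matches_elementwise_product(self, rng):
        X = rng.normal(size=(6, 5))
        w = rng.uniform(size=5)
        out = reweight(X, Chromosome(w))
        for i in range(6):
            for j in range(5):
                assert out[i, j] == X[i, j] * w[j]

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            reweight(rng.normal(size=(5, 4)), Chromosome(np.ones(3)))


class TestFitness:
    def test_separable_classes_score_high(self, rng):
        X = np.vstack([rng.normal(0, 1, (50, 4)), rng.normal(6, 1, (50, 4))])
        y = np.array(["a"] * 50 + ["b"] * 50)
        rec = fitness(Chromosome(np.ones(4)), X, y, seed=0, config=FAST_GA)
        assert rec.combined > 0.95

    def test_permuted_labels_score_at_chance(self, rng):
        X = rng.normal(size=(200, 6))
        y = np.array(["a", "b"] * 100)
        rec = fitness(Chromosome(np.ones(6)), X, y, seed=1, config=FAST_GA)
        assert 0.35 <= rec.combined <= 0.65

    def test_combined_is_mean_of_accuracies(self):
        from harkit.ga import FitnessRecord

        assert FitnessRecord(acc_lsvm=0.8, acc_rf=0.6).combined == pytest.approx(0.7)

    def test_single_class_raises(self, rng):
        X = rng.normal(size=(20, 3))
        y = np.array(["a"] * 20)
        with pytest.raises(ValueError):
            fitness(Chromosome(np.ones(3)), X, y)


class TestEvolve:
    @pytest.fixture()
    def table(self, rng):
        X = np.vstack([rng.normal(0, 1, (40, 6)), rng.normal(1.5, 1, (40, 6))])
        y = np.array(["a"] * 40 + ["b"] * 40)
        return X, y

    def test_history_non_decreasing(self, table):
        X, y = table
        for seed in (0, 1, 2):
            _, hist = evolve(X, y, FAST_GA, seed=seed)
            assert all(b >= a for a, b in zip(hist, hist[1:]))

    def test_single_generation_config(self, table):
        X, y = table
        cfg = GAConfig(population_size=6, max_generations=1, rf_estimators=10)
        _, hist = evolve(X, y, cfg, seed=0)
        assert len(hist) == 1

    def test_bit_identical_determinism(self, table):
        X, y = table
        b1, h1 = evolve(X, y, FAST_GA, seed=4)
        b2, h2 = evolve(X, y, FAST_GA, seed=4)
        np.testing.assert_array_equal(b1.weights, b2.weights)
        assert h1 == h2


class TestSelectFeatures:
    def _fit(self, w):
        from harkit.ga import FitnessRecord

        return Chromosome(np.array(w), FitnessRecord(0.9, 0.9))

    def test_threshold_rule(self):
        names = ["a", "b", "c", "d"]
        assert select_features(self._fit([0.8, 0.2, 0.6, 0.4]), names) == ["a", "c"]

    def test_uniform_weights_keep_all(self):
        names = ["a", "b", "c"]
        assert select_features(self._fit([0.5, 0.5, 0.5]), names) == names

    def test_single_dominant_weight(self):
        names = ["a", "b", "c"]
        assert select_features(self._fit([0.0, 0.9, 0.0]), names) == ["b"]

    def test_unscored_chromosome_raises(self):
        with pytest.raises(ValueError):
            select_features(Chromosome(np.ones(2)), ["a", "b"])


class TestGAFeatureSelectorEstimator:
    def test_sklearn_contract(self, rng):
        from sklearn.pipeline import Pipeline

        X = np.vstack([rng.normal(0, 1, (30, 5)), rng.normal(2, 1, (30, 5))])
        y = np.array(["a"] * 30 + ["b"] * 30)
        sel = GAFeatureSelector(
            population_size=6, max_generations=3, patience=2,
            rf_estimators=10, random_state=0,
        )
        params = sel.get_params()
        assert params["mutation_rate"] == 0.05
        pipe = Pipeline([("sel", sel)])
        Xt = pipe.fit_transform(X, y)
        assert Xt.shape[0] == 60
        assert Xt.shape[1] == int(sel.support_.sum())
        assert len(sel.weights_) == 5
        # transform reweights then restricts to retained columns
        manual = (X * sel.weights_)[:, sel.support_]
        np.testing.assert_array_equal(Xt, manual)

    def test_transform_shape_mismatch_raises(self, rng):
        X = np.vstack([rng.normal(0, 1, (30, 5)), rng.normal(2, 1, (30, 5))])
        y = np.array(["a"] * 30 + ["b"] * 30)
        sel = GAFeatureSelector(population_size=4, max_generations=2,
                                rf_estimators=10, random_state=0).fit(X, y)
        with pytest.raises(ValueError):
            sel.transform(X[:, :3])
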