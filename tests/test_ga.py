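"""GA mechanics: noise subsets, rank AUC, the fitness criterion, mutation,
crossover and the evolution loop."""

import numpy as np
import pytest

from cadnet.ga import (
    GAConfig,
    GeneRanges,
    Genome,
    SplitData,
    build_noise_subsets,
    crossover,
    evaluate_genome,
    evolve,
    fitness,
    mutate,
    rank_auc,
)


def _genome(**kw):
    base = dict(alpha=0.5, log_lambda=0.0, upweight_factor=2.0,
                gensini_weight_threshold=1.0, corr_threshold=0.9)
    base.update(kw)
    return Genome(**base)


class TestNoiseSubsets:
    def test_nesting_rule(self):
        part = build_noise_subsets(
            np.array([1.0, 2.0, 3.0, 4.0, 5.0]),
            np.array([1.0, 2.0, 3.0, 4.0, 5.0]),
            np.array([1.5, 2.5, 3.5, 4.5]),
        )
        assert [len(s) for s in part.train_subsets] == [5, 4, 3, 2, 1]
        # each subset nests inside its predecessor
        for a, b in zip(part.train_subsets, part.train_subsets[1:]):
            assert set(b) <= set(a)

    def test_all_thresholds_above_max_gives_identical_subsets(self):
        part = build_noise_subsets(
            np.array([1.0, 2.0]), np.array([1.0]), np.array([10.0, 11.0, 12.0, 13.0])
        )
        assert all(len(s) == 2 for s in part.train_subsets)

    def test_empty_subset_is_an_error(self):
        with pytest.raises(ValueError, match="subset 2 is empty"):
            build_noise_subsets(
                np.array([5.0, 5.0]), np.array([5.0]), np.array([1.0, 2.0, 3.0, 4.0])
            )

    def test_thresholds_must_ascend(self):
        with pytest.raises(ValueError):
            build_noise_subsets(
                np.array([1.0]), np.array([1.0]), np.array([4.0, 3.0, 2.0, 1.0])
            )


class TestRankAuc:
    def test_enumerated_example(self):
        # pairs: (0.35 vs 0.1, 0.4), (0.8 vs 0.1, 0.4): 3 of 4 concordant
        auc = rank_auc(np.array([0.1, 0.4, 0.35, 0.8]), np.array([0, 0, 1, 1], bool))
        assert auc == pytest.approx(0.75)

    def test_perfect_separation(self):
        assert rank_auc(np.array([1, 2, 10, 11.0]), np.array([0, 0, 1, 1], bool)) == 1.0

    def test_all_ties_give_half(self):
        assert rank_auc(np.ones(6), np.array([0, 1, 0, 1, 0, 1], bool)) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            rank_auc(np.array([1.0, 2.0]), np.array([1, 1], bool))

    def test_matches_sklearn(self, rng):
        sk = pytest.importorskip("sklearn.metrics")
        for _ in range(20):
            scores = rng.integers(0, 8, size=60).astype(float)  # forces ties
            labels = rng.random(60) < 0.4
            if labels.all() or not labels.any():
                continue
            assert rank_auc(scores, labels) == pytest.approx(
                sk.roc_auc_score(labels, scores)
            )

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.standard_normal(80)
        labels = rng.random(80) < 0.35
        a = rank_auc(scores, labels)
        assert rank_auc(np.exp(3.0 * scores) + 5.0, labels) == pytest.approx(a)


class TestFitness:
    def _partition(self, n_t=20, n_v=20):
        vols = np.linspace(0, 1, n_t)
        return build_noise_subsets(vols, np.linspace(0, 1, n_v),
                                   np.array([0.6, 0.7, 0.8, 0.9]))

    def test_perfect_ranking_scores_zero(self):
        labels = np.tile([False, True], 10)
        scores = labels.astype(float)
        part = self._partition()
        fv = fitness(scores, labels, scores, labels, part)
        assert fv.fitness == 0.0
        assert np.all(fv.auc_train == 1.0)

    def test_coin_flip_scores_minus_3_125(self):
        # all AUCs 0.5: fitness = -5 * (0.25 + 1.5 * 0.25)
        labels = np.tile([False, True], 10)
        scores = np.zeros(20)  # all ties -> AUC 0.5 in every subset
        fv = fitness(scores, labels, scores, labels, self._partition())
        assert fv.fitness == pytest.approx(-3.125)

    def test_train_perfect_val_080_scores_minus_030(self):
        # AUC(T_i) = 1, AUC(V_i) = 0.8 for all i: fitness = -5 * 1.5 * 0.04
        # thresholds sit above every noise volume, so all 5 subsets coincide
        labels_t = np.tile([False, True], 5)
        scores_t = labels_t.astype(float)
        labels_v = np.tile([False, True], 5)
        scores_v = labels_v.astype(float)
        scores_v[1] = -1.0  # one of 5 positives below all negatives: AUC 4/5
        part = build_noise_subsets(
            np.zeros(10), np.zeros(10), np.array([0.6, 0.7, 0.8, 0.9])
        )
        fv = fitness(scores_t, labels_t, scores_v, labels_v, part)
        assert np.all(fv.auc_train == 1.0)
        assert np.all(fv.auc_val == pytest.approx(0.8))
        assert fv.fitness == pytest.approx(-0.3)

    def test_fitness_nonpositive_and_names_bad_subset(self, rng):
        labels = rng.random(20) < 0.5
        labels[:2] = [True, False]
        scores = rng.standard_normal(20)
        part = self._partition()
        assert fitness(scores, labels, scores, labels, part).fitness <= 0.0
        one_class = np.zeros(20, bool)
        one_class[19] = True  # positives only in the noisiest stratum
        with pytest.raises(ValueError, match="subset"):
            fitness(scores, one_class, scores, labels, part)


class TestMutation:
    def test_probability_zero_is_identity(self, rng):
        g = _genome()
        cfg = GAConfig(mutation_prob=0.0)
        assert mutate(g, cfg, rng) == g

    def test_per_gene_frequency_is_one_third(self):
        rng = np.random.default_rng(0)
        cfg = GAConfig(mutation_prob=0.33)
        g = _genome()
        n_trials = 100_000
        changed = np.zeros(5)
        for _ in range(n_trials):
            m = mutate(g, cfg, rng)
            changed += g.as_array() != m.as_array()
        freq = changed / n_trials
        # perturbations can land exactly on the old value only with
        # probability 0, so observed change frequency estimates 0.33
        assert np.all(np.abs(freq - 0.33) < 0.005)

    def test_mutants_stay_in_range(self, rng):
        cfg = GAConfig(mutation_prob=1.0)
        ranges = GeneRanges()
        b = ranges.bounds()
        for _ in range(500):
            m = mutate(_genome(), cfg, rng, ranges).as_array()
            assert np.all(m >= b[:, 0]) and np.all(m <= b[:, 1])


class TestCrossover:
    def test_identical_parents_reproduce_themselves(self, rng):
        g = _genome()
        assert crossover(g, g, rng) == g

    def test_genes_traceable_to_one_parent(self, rng):
        a = _genome(alpha=0.1, log_lambda=-3.0, upweight_factor=1.5,
                    gensini_weight_threshold=0.5, corr_threshold=0.85)
        b = _genome(alpha=0.9, log_lambda=1.0, upweight_factor=9.0,
                    gensini_weight_threshold=4.0, corr_threshold=0.99)
        for _ in range(50):
            child = crossover(a, b, rng).as_array()
            av, bv = a.as_array(), b.as_array()
            from_a = child == av
            from_b = child == bv
            assert np.all(from_a | from_b)
            # single point: a-genes form a prefix, b-genes a suffix
            cut = int(np.sum(from_a))
            assert 1 <= cut <= 4
            assert np.all(from_a[:cut]) and np.all(from_b[cut:])


class TestEvolve:
    def test_forced_stagnation_stops_after_exactly_10_generations(self):
        calls = []

        def flat_fitness(genome):
            calls.append(genome)
            return -1.0

        cfg = GAConfig(population_size=6, mutation_prob=0.0, stagnation_limit=10,
                       max_generations=500, seed=3)
        result = evolve(None, None, None, cfg, evaluator=flat_fitness)
        # generation 1 establishes the best; 10 further stagnant generations
        assert result.n_generations == 11
        assert not result.truncated

    def test_best_fitness_monotone_nondecreasing(self):
        def sphere(genome):
            x = genome.as_array()
            target = np.array([0.5, -1.0, 4.0, 2.0, 0.9])
            return -float(np.sum((x - target) ** 2))

        cfg = GAConfig(population_size=12, max_generations=40, seed=5)
        result = evolve(None, None, None, cfg, evaluator=sphere)
        best = result.history["best_fitness"].to_numpy()
        assert np.all(np.diff(best) >= 0)

    def test_beats_random_search_at_equal_budget(self):
        """On a smooth unimodal 5-gene objective the GA should outperform a
        pure random search with the same number of evaluations in >= 8/10
        seeds."""
        target = np.array([0.31, -0.7, 6.2, 2.2, 0.93])

        def objective_fn(x):
            return -float(np.sum(((x - target) / np.array([1, 6, 9, 5.1, 0.2])) ** 2))

        wins = 0
        ranges = GeneRanges()
        for seed in range(10):
            cfg = GAConfig(population_size=10, max_generations=10,
                           stagnation_limit=10, seed=seed)
            n_evals = [0]

            def ga_eval(genome):
                n_evals[0] += 1
                return objective_fn(genome.as_array())

            result = evolve(None, None, None, cfg, evaluator=ga_eval, ranges=ranges)
            rng = np.random.default_rng(1000 + seed)
            b = ranges.bounds()
            random_best = max(
                objective_fn(rng.uniform(b[:, 0], b[:, 1])) for _ in range(max(n_evals[0], 100))
            )
            wins += result.best_fitness >= random_best
        assert wins >= 8

    def test_truncation_flag_at_budget_cap(self):
        rng_state = np.random.default_rng(0)

        def noisy(genome):
            return float(rng_state.random())  # always improving somewhere

        cfg = GAConfig(population_size=6, max_generations=5, seed=1)
        result = evolve(None, None, None, cfg, evaluator=noisy)
        assert result.truncated
        assert result.n_generations == 5

    def test_reproducible_per_seed(self, small_cohort, small_config):
        from cadnet.cohort import features_matrix

        train = [s for s in small_cohort if s.split == "train"]
        val = [s for s in small_cohort if s.split == "validation"]

        def split_data(rows):
            return SplitData(
                X=features_matrix(rows),
                y_gensini=np.array([s.gensini_modified for s in rows]),
                labels=np.array([s.cad for s in rows]),
                noise_volume=np.array([s.noise_volume for s in rows]),
            )

        tr, va = split_data(train), split_data(val)
        part = build_noise_subsets(
            tr.noise_volume, va.noise_volume,
            np.percentile(tr.noise_volume, [60, 70, 80, 90]),
        )
        cfg = GAConfig(population_size=6, max_generations=4, seed=11)
        kw = dict(n_reducible=small_config.n_features)
        r1 = evolve(tr, va, part, cfg, **kw)
        r2 = evolve(tr, va, part, cfg, **kw)
        assert r1.best_genome == r2.best_genome
        assert r1.best_fitness == r2.best_fitness


class TestEvaluateGenome:
    def _data(self, small_cohort, small_config):
        from cadnet.cohort import features_matrix

        def split_data(rows):
            return SplitData(
                X=features_matrix(rows),
                y_gensini=np.array([s.gensini_modified for s in rows]),
                labels=np.array([s.cad for s in rows]),
                noise_volume=np.array([s.noise_volume for s in rows]),
            )

        tr = split_data([s for s in small_cohort if s.split == "train"])
        va = split_data([s for s in small_cohort if s.split == "validation"])
        part = build_noise_subsets(
            tr.noise_volume, va.noise_volume,
            np.percentile(tr.noise_volume, [60, 70, 80, 90]),
        )
        return tr, va, part, small_config.n_features

    def test_huge_lambda_gives_constant_predictor_fitness(self, small_cohort, small_config):
        tr, va, part, nf = self._data(small_cohort, small_config)
        fv = evaluate_genome(_genome(log_lambda=4.0, alpha=1.0), tr, va, part,
                             n_reducible=nf)
        # all-zero weights -> constant output -> tie-only AUC = 0.5 everywhere
        assert np.all(fv.auc_train == 0.5)
        assert fv.fitness == pytest.approx(-3.125)

    def test_deterministic(self, small_cohort, small_config):
        tr, va, part, nf = self._data(small_cohort, small_config)
        g = _genome()
        a = evaluate_genome(g, tr, va, part, n_reducible=nf)
        b = evaluate_genome(g, tr, va, part, n_reducible=nf)
        assert a.fitness == b.fitness
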