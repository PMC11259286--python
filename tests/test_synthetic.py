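import numpy as np
import pytest

import conceptmap as cm
from conceptmap.synthetic import label_recovery_rate, planted_partition
from oracles import adjusted_rand


class TestGenerateSorts:
    def test_noiseless_sorts_equal_planted_partition(self, small_synthetic):
        config, dataset, truth = small_synthetic
        for sort in dataset.sorts:
            piles = {frozenset(m) for _, m in sort.piles}
            planted = {
                frozenset(s for s, c in truth.planted_partition.items() if c == k)
                for k in range(1, config.K + 1)
            }
            assert piles == planted

    def test_every_sort_is_a_valid_partition(self):
        config = cm.SyntheticConfig(S=30, K=5, N_sorters=10, epsilon=0.4,
                                    merge_prob=0.8, split_prob=0.8, seed=3)
        sorts, _ = cm.generate_sorts(config)
        statements = cm.generate_statements(config)
        for sort in sorts:
            sort.validate(statements)  # raises on any violation

    def test_full_jitter_destroys_cluster_signal(self):
        # epsilon = 1: every card moves to a uniform different pile, so the
        # within-cluster co-occurrence rate approaches the between rate.
        # Analytically, within = 1/(K-1) and between = (K-2)/(K-1)^2.
        k = 10
        config = cm.SyntheticConfig(S=30, K=k, N_sorters=150, epsilon=1.0,
                                    merge_prob=0.0, split_prob=0.0, seed=7)
        sorts, truth = cm.generate_sorts(config)
        statements = cm.generate_statements(config)
        sim = cm.similarity_from_sorts(sorts, statements)
        part = truth.planted_partition
        within, between = [], []
        for i, a in enumerate(statements.ids):
            for b in statements.ids[i + 1:]:
                rate = sim.values[i, statements.index_of(b)] / sim.n_sorters
                (within if part[a] == part[b] else between).append(rate)
        assert np.mean(within) == pytest.approx(1 / (k - 1), abs=0.03)
        assert np.mean(between) == pytest.approx((k - 2) / (k - 1) ** 2, abs=0.03)
        assert abs(np.mean(within) - np.mean(between)) < 0.05

    def test_byte_identical_datasets_for_fixed_seed(self, tmp_path):
        config = cm.SyntheticConfig(S=20, K=4, N_sorters=6, seed=13,
                                    group_sizes={"consumer": 3, "provider": 4})
        for name in ("a", "b"):
            dataset, _ = cm.generate_dataset(config)
            cm.write_dataset(dataset, tmp_path / name)
        for fname in ("statements.csv", "sorts.csv", "ratings.csv"):
            assert (tmp_path / "a" / fname).read_bytes() == \
                (tmp_path / "b" / fname).read_bytes()

    def test_rater_count_does_not_perturb_sorts(self):
        base = cm.SyntheticConfig(S=20, K=4, N_sorters=6, seed=13)
        more_raters = cm.SyntheticConfig(
            S=20, K=4, N_sorters=6, seed=13,
            group_sizes={"consumer": 50, "provider": 50},
        )
        sorts_a, _ = cm.generate_sorts(base)
        sorts_b, _ = cm.generate_sorts(more_raters)
        assert sorts_a == sorts_b

    def test_noiseless_aggregate_is_block_structured(self, small_synthetic):
        config, dataset, truth = small_synthetic
        sim = cm.similarity_from_sorts(dataset.sorts, dataset.statements)
        part = truth.planted_partition
        for i, a in enumerate(dataset.statements.ids):
            for j, b in enumerate(dataset.statements.ids):
                expected = config.N_sorters if part[a] == part[b] else 0
                assert sim.values[i, j] == expected


class TestGenerateRatings:
    def test_noiseless_integer_latents_reproduced_exactly(self):
        config = cm.SyntheticConfig(
            S=6, K=2, N_sorters=2, statement_effect_sd=0.0, rating_noise_sd=0.0,
            group_baselines={"consumer": 4.0, "provider": 2.0},
            group_cluster_effects={("consumer", 1): 0.0, ("consumer", 2): -1.0,
                                   ("provider", 1): 0.0, ("provider", 2): 1.0},
            group_sizes={"consumer": 3, "provider": 3}, seed=0,
        )
        _, truth = cm.generate_sorts(config)
        for record in cm.generate_ratings(config, truth):
            for sid, value in record.ratings.items():
                assert value == truth.planted_statement_means[(record.group, sid)]

    def test_extreme_latent_means_clip_to_scale(self):
        config = cm.SyntheticConfig(
            S=4, K=1, N_sorters=2, statement_effect_sd=0.0, rating_noise_sd=0.0,
            group_baselines={"consumer": 9.0, "provider": -3.0},
            group_cluster_effects={},
            group_sizes={"consumer": 2, "provider": 2}, seed=0,
        )
        _, truth = cm.generate_sorts(config)
        for record in cm.generate_ratings(config, truth):
            expected = 5 if record.group == "consumer" else 1
            assert set(record.ratings.values()) == {expected}

    def test_planted_cluster_ordering_recovered_in_most_replicates(self):
        # ordered cluster effects with mild noise: the sample cluster-mean
        # ordering should match the planted one in >= 95% of replicates
        hits = 0
        n_rep = 200
        for seed in range(n_rep):
            config = cm.SyntheticConfig(
                S=12, K=3, N_sorters=2, seed=seed,
                statement_effect_sd=0.05, rating_noise_sd=0.5,
                group_baselines={"consumer": 3.5},
                group_cluster_effects={("consumer", 1): 0.6, ("consumer", 2): 0.0,
                                       ("consumer", 3): -0.6},
                group_sizes={"consumer": 23},
            )
            dataset, truth = cm.generate_dataset(config)
            means = cm.statement_means(dataset.ratings)
            solution = cm.ClusterSolution(k=3, assignment=truth.planted_partition)
            summaries = cm.cluster_summary(solution, means)
            ordering = [s.cluster for s in
                        sorted(summaries, key=lambda s: -s.cluster_mean)]
            hits += ordering == [1, 2, 3]
        assert hits / n_rep >= 0.95

    def test_rating_means_converge_to_latent_means(self):
        # error in the statement mean shrinks at the sd/sqrt(n) scale
        errors = {}
        for n_raters in (10, 160):
            config = cm.SyntheticConfig(
                S=8, K=2, N_sorters=2, seed=21, rating_noise_sd=1.0,
                statement_effect_sd=0.0,
                group_baselines={"consumer": 3.0},
                group_cluster_effects={("consumer", 1): 0.4, ("consumer", 2): -0.4},
                group_sizes={"consumer": n_raters},
            )
            dataset, truth = cm.generate_dataset(config)
            means = cm.statement_means(dataset.ratings)
            errs = [
                abs(means[sid] - truth.planted_statement_means[("consumer", sid)])
                for sid in dataset.statements.ids
            ]
            errors[n_raters] = np.mean(errs)
        assert errors[160] < errors[10]
        assert errors[160] < 2 * 1.0 / np.sqrt(160) + 0.1  # discretization slack


class TestRecovery:
    def test_noiseless_recovery_is_perfect(self, small_synthetic):
        config, dataset, truth = small_synthetic
        report = cm.recovery_report(dataset, truth, seed=1)
        assert report.ari == 1.0
        assert report.label_recovery_rate == 1.0

    def test_ari_oracle_agreement(self, rng):
        from sklearn.metrics import adjusted_rand_score

        for _ in range(100):
            n = int(rng.integers(6, 30))
            a = rng.integers(0, 4, size=n)
            b = rng.integers(0, 4, size=n)
            assert adjusted_rand_score(a, b) == pytest.approx(
                adjusted_rand(a, b), abs=1e-12
            )

    def test_identical_partitions_score_one_random_score_zero(self, rng):
        labels = rng.integers(0, 5, size=40)
        assert adjusted_rand(labels, labels) == pytest.approx(1.0)
        scores = []
        for _ in range(100):
            scores.append(adjusted_rand(rng.integers(0, 5, size=40),
                                        rng.integers(0, 5, size=40)))
        assert abs(np.mean(scores)) < 0.1

    def test_pipeline_failure_carries_stage_name(self, small_synthetic):
        config, dataset, truth = small_synthetic
        broken = cm.StudyDataset(dataset.statements, (), dataset.ratings)
        with pytest.raises(cm.ComputationError, match="similarity"):
            cm.recovery_report(broken, truth)

    def test_label_recovery_reads_planted_tags(self):
        partition = {1: 1, 2: 1, 3: 2, 4: 2}
        truth = cm.GroundTruth(partition, {})
        solution = cm.ClusterSolution(k=2, assignment=partition)
        from conceptmap.interpretation import LabelCandidate

        good = {1: [LabelCandidate("c1 theme", 1.0, "A")],
                2: [LabelCandidate("c2 theme+c9 theme", 0.8, "A")]}
        half = {1: [LabelCandidate("c1 theme", 1.0, "A")],
                2: [LabelCandidate("c7 theme", 0.8, "A")]}
        assert label_recovery_rate(solution, good, truth) == 1.0
        assert label_recovery_rate(solution, half, truth) == 0.5


def test_invalid_configs_rejected():
    with pytest.raises(cm.ValidationError):
        cm.SyntheticConfig(S=5, K=9)
    with pytest.raises(cm.ValidationError):
        cm.SyntheticConfig(epsilon=1.5)
    with pytest.raises(cm.ValidationError):
        cm.SyntheticConfig(S=10, K=2, cluster_sizes=(4, 4))


def test_planted_partition_covers_all_statements():
    config = cm.SyntheticConfig(S=17, K=4)
    part = planted_partition(config)
    assert sorted(part) == list(range(1, 18))
    sizes = sorted(
        (sum(1 for c in part.values() if c == k) for k in range(1, 5)),
        reverse=True,
    )
    assert sizes == [5, 4, 4, 4]
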