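import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist, squareform

import conceptmap as cm
from oracles import kruskal_stress_reference, pava

TOY_D = np.array([[0, 1, 3], [1, 0, 2], [3, 2, 0]], dtype=float)
TOY_X = np.array([[0, 0], [2, 0], [3, 0]], dtype=float)


class TestMonotoneRegression:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ([1, 2, 3], [1, 2, 3]),
            ([2, 1, 3], [1.5, 1.5, 3]),
            ([3, 2, 1], [2, 2, 2]),
        ],
    )
    def test_hand_computed_pava(self, values, expected):
        assert cm.monotone_regression(values) == pytest.approx(expected)

    def test_empty_sequence_rejected(self):
        with pytest.raises(cm.DegenerateInputError):
            cm.monotone_regression([])

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.lists(st.floats(min_value=-50, max_value=50), min_size=1, max_size=30))
    def test_matches_block_pooling_oracle_and_conserves_sum(self, values):
        fit = cm.monotone_regression(values)
        assert np.all(np.diff(fit) >= -1e-9)
        assert fit.sum() == pytest.approx(sum(values), abs=1e-6)
        assert fit == pytest.approx(pava(values), abs=1e-9)

    def test_tie_groups_allow_unequal_fits_within_a_tie(self):
        # primary tie treatment: no constraint inside the tied block, so the
        # tied 3.0 pools with the later 2.0 while the tied 1.0 stays put
        fit = cm.monotone_regression([3.0, 1.0, 2.0], tie_groups=[0, 0, 1])
        assert fit == pytest.approx([2.5, 1.0, 2.5])


class TestKruskalStress:
    def test_hand_computed_toy(self):
        assert cm.kruskal_stress(TOY_D, TOY_X) == pytest.approx(
            np.sqrt(0.5 / 14), abs=1e-12
        )

    def test_monotone_distances_give_zero(self):
        x = np.array([[0, 0], [1, 0], [3, 0]], dtype=float)
        assert cm.kruskal_stress(TOY_D / 3.0, x) == pytest.approx(0.0, abs=1e-12)

    def test_own_distance_matrix_gives_zero(self, rng):
        x = rng.normal(size=(8, 2))
        d = squareform(pdist(x))
        assert cm.kruskal_stress(d, x) == pytest.approx(0.0, abs=1e-12)

    def test_coincident_configuration_rejected(self):
        with pytest.raises(cm.DegenerateInputError):
            cm.kruskal_stress(TOY_D, np.zeros((3, 2)))

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(seed=st.integers(min_value=0, max_value=10_000))
    def test_matches_independent_reference(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        x = rng.normal(size=(n, 2))
        d = squareform(pdist(rng.normal(size=(n, 2))))
        assert cm.kruskal_stress(d, x) == pytest.approx(
            kruskal_stress_reference(d, x), abs=1e-10
        )

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(seed=st.integers(min_value=0, max_value=10_000))
    def test_invariant_under_rigid_transforms_and_scaling(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(7, 2))
        d = squareform(pdist(rng.normal(size=(7, 2))))
        base = cm.kruskal_stress(d, x)
        theta = rng.uniform(0, 2 * np.pi)
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        mirror = np.array([[1, 0], [0, -1]])
        scale = rng.uniform(0.1, 10)
        moved = scale * (x @ rot @ mirror) + rng.normal(size=2)
        assert cm.kruskal_stress(d, moved) == pytest.approx(base, abs=1e-9)


class TestCanonicalize:
    def test_idempotent(self, rng):
        x = cm.canonicalize(rng.normal(size=(9, 2)))
        assert cm.canonicalize(x) == pytest.approx(x, abs=1e-9)

    def test_rotation_and_mirror_collapse_to_same_form(self, rng):
        x = rng.normal(size=(9, 2))
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        assert cm.canonicalize(x @ rot) == pytest.approx(cm.canonicalize(x), abs=1e-8)
        mirrored = x @ np.array([[-1, 0], [0, 1]])
        assert cm.canonicalize(mirrored) == pytest.approx(
            cm.canonicalize(x), abs=1e-8
        )

    def test_distances_preserved_and_centered(self, rng):
        x = rng.normal(size=(9, 2))
        canon = cm.canonicalize(x)
        assert pdist(canon) == pytest.approx(pdist(x), abs=1e-9)
        assert canon.mean(axis=0) == pytest.approx([0, 0], abs=1e-12)
        assert canon[0, 0] >= -1e-9  # first statement's x sign convention


class TestNonmetricMDS:
    def test_equal_dissimilarities_fit_perfectly(self):
        d = np.ones((3, 3)) - np.eye(3)
        pm = cm.nonmetric_mds(d, seed=0, n_starts=3)
        assert pm.stress < 1e-6

    def test_recovers_planted_plane_configuration(self, rng):
        planted = rng.normal(size=(6, 2))
        d = squareform(pdist(planted))
        pm = cm.nonmetric_mds(d, seed=0, n_starts=4)
        assert pm.stress < 1e-4
        # rank order of recovered distances matches the planted ranks
        got = np.argsort(pdist(pm.coordinates))
        assert np.array_equal(got, np.argsort(pdist(planted)))

    def test_stress_trace_descends_within_a_run(self, rng):
        x = rng.normal(size=(12, 2))
        d = squareform(pdist(x)) + rng.uniform(0, 0.5, size=(12, 12))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        pm = cm.nonmetric_mds(d, seed=3, n_starts=2)
        trace = np.array(pm.stress_trace)
        assert np.all(np.diff(trace) <= 1e-12)

    def test_reported_stress_matches_recomputation(self, toy_sorts, four_statements):
        sim = cm.similarity_from_sorts(toy_sorts, four_statements)
        d = cm.to_dissimilarity(sim)
        pm = cm.nonmetric_mds(d, seed=0, n_starts=3)
        assert pm.stress == pytest.approx(
            cm.kruskal_stress(d.values, pm.coordinates), abs=1e-10
        )

    def test_count_and_proportion_transforms_agree(self, rng):
        # nonmetric MDS sees only dissimilarity ranks, so both complements
        # of the same similarity matrix give the same stress
        config = cm.SyntheticConfig(S=20, K=4, N_sorters=6, seed=2)
        sorts, _ = cm.generate_sorts(config)
        statements = cm.generate_statements(config)
        sim = cm.similarity_from_sorts(sorts, statements)
        pm_count = cm.nonmetric_mds(cm.to_dissimilarity(sim, "count_complement"),
                                    seed=4, n_starts=3)
        pm_prop = cm.nonmetric_mds(
            cm.to_dissimilarity(sim, "proportion_complement"), seed=4, n_starts=3
        )
        assert pm_count.stress == pytest.approx(pm_prop.stress, abs=1e-9)
        # same configuration up to the overall dissimilarity scale N
        assert pm_count.coordinates == pytest.approx(
            pm_prop.coordinates * sim.n_sorters, abs=1e-6
        )

    def test_bit_identical_for_fixed_seed(self):
        config = cm.SyntheticConfig(S=15, K=3, N_sorters=5, seed=9)
        sorts, _ = cm.generate_sorts(config)
        statements = cm.generate_statements(config)
        d = cm.to_dissimilarity(cm.similarity_from_sorts(sorts, statements))
        a = cm.nonmetric_mds(d, seed=42, n_starts=4)
        b = cm.nonmetric_mds(d, seed=42, n_starts=4)
        assert np.array_equal(a.coordinates, b.coordinates)
        assert a.stress == b.stress

    def test_too_few_statements_rejected(self):
        with pytest.raises(cm.ValidationError):
            cm.nonmetric_mds(np.array([[0.0, 1.0], [1.0, 0.0]]))

    def test_non_convergence_warns_not_fails(self, rng):
        d = squareform(pdist(rng.normal(size=(15, 2)))) + rng.uniform(
            0, 1, size=(15, 15)
        )
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        with pytest.warns(UserWarning, match="did not reach"):
            pm = cm.nonmetric_mds(d, seed=0, n_starts=1, max_iter=3)
        assert pm.converged is False
        assert 0 <= pm.stress <= 1

    def test_not_worse_than_sklearn_reference(self):
        # independent optimizer cross-check on one mid-size instance
        from sklearn.manifold import MDS

        config = cm.SyntheticConfig(S=25, K=5, N_sorters=8, seed=6)
        sorts, _ = cm.generate_sorts(config)
        statements = cm.generate_statements(config)
        d = cm.to_dissimilarity(cm.similarity_from_sorts(sorts, statements))
        ours = cm.nonmetric_mds(d, seed=1)
        ref = MDS(n_components=2, metric=False, dissimilarity="precomputed",
                  n_init=10, random_state=1, normalized_stress=False)
        coords = ref.fit_transform(d.values)
        ref_stress = cm.kruskal_stress(d.values, coords)
        assert ours.stress <= ref_stress + 0.02
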