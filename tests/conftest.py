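import numpy as np
import pytest

import conceptmap as cm
from conceptmap import datasets


@pytest.fixture(scope="session")
def four_statements() -> cm.StatementSet:
    return cm.StatementSet(cm.Statement(i, f"statement {i}") for i in range(1, 5))


@pytest.fixture(scope="session")
def toy_sorts(four_statements):
    """Three sorters over four statements (hand-enumerated counts)."""
    return (
        cm.SortRecord("A", (("x", frozenset({1, 2})), ("y", frozenset({3, 4})))),
        cm.SortRecord("B", (("x", frozenset({1, 2, 3})), ("y", frozenset({4})))),
        cm.SortRecord(
            "C",
            (("x", frozenset({1})), ("y", frozenset({2, 3})), ("z", frozenset({4}))),
        ),
    )


@pytest.fixture(scope="session")
def moud_statements():
    return datasets.load_moud_statements()


@pytest.fixture(scope="session")
def moud_solution():
    assignment = datasets.load_moud_cluster_assignment()
    return cm.ClusterSolution(k=7, assignment=assignment)


@pytest.fixture(scope="session")
def moud_means():
    return datasets.load_moud_statement_means()


@pytest.fixture(scope="session")
def small_synthetic():
    """A quick noiseless synthetic dataset with planted 3-cluster truth."""
    config = cm.SyntheticConfig(
        S=15, K=3, N_sorters=4, epsilon=0.0, merge_prob=0.0, split_prob=0.0,
        group_sizes={"consumer": 4, "provider": 5}, seed=11,
    )
    dataset, truth = cm.generate_dataset(config)
    return config, dataset, truth


@pytest.fixture(scope="session")
def study_scale_replicates():
    """25 seeded study-scale replicates at default noise, run once.

    Shared by the stress-range and partition-recovery acceptance checks.
    """
    reports = []
    for seed in range(25):
        config = cm.SyntheticConfig(seed=seed)
        dataset, truth = cm.generate_dataset(config)
        reports.append(cm.recovery_report(dataset, truth, seed=seed))
    return reports


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
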