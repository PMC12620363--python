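import numpy as np
import pytest

from ordmine import (
    BranchingSpec,
    LabeledDataset,
    fit_projection,
    make_branching,
    make_ten_class_fixture,
)


@pytest.fixture(scope="session")
def ten_class():
    """The ten-class branching benchmark (100 samples/class)."""
    return make_ten_class_fixture(n_per_class=100, seed=1)


@pytest.fixture(scope="session")
def ten_class_dataset(ten_class):
    return ten_class[0]


@pytest.fixture(scope="session")
def ten_class_truth(ten_class):
    return ten_class[1]


@pytest.fixture(scope="session")
def projected_05(ten_class_dataset):
    """Projection of the benchmark on its two most distant classes."""
    return fit_projection(ten_class_dataset, ("l0", "l5"))


@pytest.fixture(scope="session")
def small_fixture():
    """Fast 20-samples/class copy of the benchmark for heavier loops."""
    return make_ten_class_fixture(n_per_class=20, seed=3)


def make_interval_dataset(intervals, n_per_class=10, seed=0, noise_dims=1):
    spec = BranchingSpec(class_intervals=dict(intervals),
                         n_per_class=n_per_class, noise_dims=noise_dims,
                         seed=seed)
    return make_branching(spec)


def random_layout(rng, n_classes):
    """A random 1-D interval layout with a mix of gaps and overlaps."""
    intervals = {}
    for i in range(n_classes):
        lo = rng.uniform(0.0, 10.0)
        intervals[f"c{i}"] = (lo, lo + rng.uniform(0.3, 3.0))
    return intervals


def tiny_dataset(values_by_label, noise=None):
    """1-feature (optionally 2-feature) dataset from explicit class values."""
    ids, rows, y = [], [], []
    for label, vals in values_by_label.items():
        for i, v in enumerate(vals):
            ids.append(f"{label}_{i}")
            if noise is None:
                rows.append([float(v)])
            else:
                rows.append([float(v), float(noise[label][i])])
            y.append(label)
    return LabeledDataset(tuple(ids), np.asarray(rows), np.asarray(y, dtype=object),
                          tuple(values_by_label))
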