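"""Shared fixtures: small synthetic event tables and one heavy pipeline run."""

import numpy as np
import pytest

import swarmgate as sg


@pytest.fixture
def two_point_table():
    """1-D two-class toy: x = -1 (class 0) and x = +1 (class 1)."""
    return sg.EventTable([[-1.0], [1.0]], ["x"], [0, 1])


@pytest.fixture
def xor_table():
    """XOR layout: not linearly separable, separable under polynomial d=2."""
    return sg.EventTable(
        [[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]], ["a", "b"], [0, 0, 1, 1]
    )


def make_blobs(n_per_class, centers, sd=0.3, seed=0):
    """Well-separated Gaussian blobs as a labeled EventTable."""
    rng = np.random.default_rng(seed)
    centers = np.asarray(centers, dtype=float)
    rows, labels = [], []
    for k, ctr in enumerate(centers):
        rows.append(rng.normal(ctr, sd, size=(n_per_class, centers.shape[1])))
        labels.append(np.full(n_per_class, k))
    return sg.EventTable(
        np.vstack(rows),
        [f"ch{i}" for i in range(centers.shape[1])],
        np.concatenate(labels),
    )


@pytest.fixture
def blobs2():
    return make_blobs(30, [[0.0, 0.0], [3.0, 3.0]], seed=1)


@pytest.fixture
def blobs3():
    return make_blobs(25, [[0.0, 0.0], [4.0, 0.0], [2.0, 4.0]], seed=2)


@pytest.fixture(scope="session")
def pbmc_comparison():
    """Full tuner-comparison pipeline on a 2600-event synthetic PBMC table.

    Computed once per session (it is the expensive end-to-end run) and
    shared by the pipeline-level tests.
    """
    table = sg.generate(sg.default_pbmc_mixture(), 2600, seed=7)
    report = sg.tuner_comparison(table, seed=7)
    return report
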