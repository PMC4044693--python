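import numpy as np
import pytest

from cytofingerprint import CommunitySpec, Component, EventTable, GrayImage


def iso_cov(s):
    return ((s * s, 0.0), (0.0, s * s))


@pytest.fixture
def two_component_spec():
    """Two well-separated clusters, no proliferation (exact fraction oracles)."""
    return CommunitySpec([
        Component((0.3, 0.3), iso_cov(0.02), 0.7, 0.0),
        Component((0.7, 0.7), iso_cov(0.02), 0.3, 0.0),
    ])


@pytest.fixture
def six_cluster_spec():
    means = [(0.2, 0.2), (0.2, 0.7), (0.5, 0.45), (0.8, 0.2), (0.8, 0.75),
             (0.5, 0.8)]
    fracs = [0.30, 0.25, 0.18, 0.12, 0.09, 0.06]
    return CommunitySpec([
        Component(m, iso_cov(0.02), f, 0.0) for m, f in zip(means, fracs)
    ])


def gray(pixels, sample_id="img", n_events=0):
    """Build a GrayImage from a nested list, padding nothing."""
    arr = np.asarray(pixels, dtype=np.int64)
    return GrayImage(arr.shape[0], arr, sample_id=sample_id, n_events=n_events)


def table(values, sample_id="s", channels=("FSC", "DNA")):
    return EventTable(sample_id, list(channels), np.asarray(values, float))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
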