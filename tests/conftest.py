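import pytest

from mabseq.consensus import cluster_reads
from mabseq.fixtures import FixtureConfig, build_world, make_clone_reads


@pytest.fixture(scope="session")
def world():
    """One fixture world shared by the whole suite (seed 1)."""
    return build_world(FixtureConfig(seed=1))


@pytest.fixture(scope="session")
def kappa_reads(world):
    return make_clone_reads(world, "kappa")


@pytest.fixture(scope="session")
def kappa_clusters(kappa_reads):
    reads, _labels = kappa_reads
    return cluster_reads(reads)


@pytest.fixture(scope="session")
def heavy_consensus(world):
    reads, _ = make_clone_reads(world, "heavy")
    clusters = cluster_reads(reads)
    assert len(clusters) == 1
    return clusters[0].consensus


@pytest.fixture(scope="session")
def kappa_consensus(kappa_reads, kappa_clusters):
    _, labels = kappa_reads
    return next(c.consensus for c in kappa_clusters
                if labels[c.member_ids[0]] == "productive")


@pytest.fixture(scope="session")
def aberrant_consensus(kappa_reads, kappa_clusters):
    _, labels = kappa_reads
    return next(c.consensus for c in kappa_clusters
                if labels[c.member_ids[0]] == "aberrant")
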