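import numpy as np
import pytest

from chromotrace import density, synth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_chain():
    """A 50-bead self-avoiding chain reused across fitting tests."""
    return synth.make_chain(50, bond_length=40.0, confinement_radius=350.0, seed=3)


@pytest.fixture(scope="session")
def chain_map(small_chain):
    """Density map rendered from the chain at its own pose."""
    return density.build_map(small_chain.coords, sigma=40.0, voxel_size=25.0)


def brute_force_dbscan(points: np.ndarray, eps: float, min_pts: int):
    """O(n^2) density-reachability oracle.

    Returns (labels, core_mask): core points get the label of their
    eps-connected core component; border (non-core) points get the label
    of an arbitrary core neighbour; everything else is noise (-1).
    """
    n = len(points)
    d = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=2)
    neigh = d <= eps
    core = neigh.sum(axis=1) >= min_pts  # includes self, as DBSCAN counts it
    labels = np.full(n, -1)
    cluster = 0
    for i in range(n):
        if not core[i] or labels[i] != -1:
            continue
        stack = [i]
        labels[i] = cluster
        while stack:
            p = stack.pop()
            for q in np.flatnonzero(neigh[p]):
                if labels[q] == -1:
                    labels[q] = cluster
                    if core[q]:
                        stack.append(q)
        cluster += 1
    return labels, core
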