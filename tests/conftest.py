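import numpy as np
import pytest

from dendromito.skeleton import ArborSkeleton


@pytest.fixture
def straight_path() -> ArborSkeleton:
    """A single unbranched 10 µm path of 1 µm links along x."""
    n = 11
    pos = np.zeros((n, 3))
    pos[:, 0] = np.arange(n, dtype=float)
    parent = np.arange(-1, n - 1)
    return ArborSkeleton(positions=pos, parent=parent)


@pytest.fixture
def y_tree() -> ArborSkeleton:
    """Y-shaped tree: 5 µm trunk along x, two 5 µm arms, 1 µm links."""
    pos = [np.array([float(i), 0.0, 0.0]) for i in range(6)]       # 0..5 trunk
    parent = list(range(-1, 5))
    for k in range(1, 6):                                          # arm +y
        pos.append(np.array([5.0, float(k), 0.0]))
        parent.append(5 if k == 1 else len(pos) - 2)
    for k in range(1, 6):                                          # arm -y
        pos.append(np.array([5.0, -float(k), 0.0]))
        parent.append(5 if k == 1 else len(pos) - 2)
    return ArborSkeleton(positions=np.array(pos), parent=np.array(parent))


def random_tree(rng: np.random.Generator, n_nodes: int = 15) -> ArborSkeleton:
    """Random geometric tree for oracle comparisons (small, arbitrary shape)."""
    pos = rng.uniform(0, 20, size=(n_nodes, 3))
    parent = np.full(n_nodes, -1)
    for i in range(1, n_nodes):
        parent[i] = rng.integers(0, i)
    return ArborSkeleton(positions=pos, parent=parent)
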