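import numpy as np
import pytest

import mtphylo as m


@pytest.fixture(scope="session")
def a2_tree():
    return m.HaplogroupTree.bundled("a2")


@pytest.fixture(scope="session")
def default_tree():
    return m.HaplogroupTree.bundled("default")


@pytest.fixture(scope="session")
def ref():
    return m.synthetic_reference()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)


def random_binary_matrix(rng, n_max=8, c_max=10):
    """Random reduced binary character matrix for network tests."""
    from mtphylo.network import CharacterMatrix

    while True:
        n = int(rng.integers(3, n_max + 1))
        c = int(rng.integers(3, c_max + 1))
        X = np.unique(rng.integers(0, 2, size=(n, c)).astype(np.int8), axis=0)
        n = X.shape[0]
        keep = [j for j in range(X.shape[1]) if 0 < X[:, j].sum() < n]
        X = X[:, keep]
        if n >= 2 and X.shape[1] >= 1:
            return CharacterMatrix(
                taxa=[f"t{i}" for i in range(n)],
                matrix=X,
                characters=[f"c{j}" for j in range(X.shape[1])],
                weights=np.ones(X.shape[1], dtype=int),
                multiplicity=np.ones(n, dtype=int),
                members=[[f"t{i}"] for i in range(n)],
                regions=[{} for _ in range(n)],
            )


def enumerate_rooted_binary_topologies(labels):
    """All rooted binary leaf-labelled tree shapes over the given labels,
    as nested tuples; used by the rho/sigma exhaustive oracle tests."""
    if len(labels) == 1:
        yield labels[0]
        return
    first, rest = labels[0], labels[1:]
    # split rest into the side containing `first` vs the other side
    n = len(rest)
    for mask in range(1, 2 ** n):
        right = [rest[i] for i in range(n) if mask & (1 << i)]
        left = [first] + [rest[i] for i in range(n) if not mask & (1 << i)]
        if not right:
            continue
        # avoid double counting: force labels[0] to the left block
        for lt in enumerate_rooted_binary_topologies(left):
            for rt in enumerate_rooted_binary_topologies(right):
                yield (lt, rt)
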