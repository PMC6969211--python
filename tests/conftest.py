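"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from agcphos.phylo import PhyloTree, TreeNode
from agcphos.synthetic import gen_kinase_family, gen_phospho_site_structure


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def random_binary_tree(
    rng: np.random.Generator,
    n_taxa: int,
    leaf_len=(0.5, 2.0),
    internal_len=(0.3, 1.0),
) -> PhyloTree:
    """A random unrooted binary tree with positive branch lengths.

    Built by random agglomeration; every internal edge length is at least
    ``internal_len[0]``, so the tree's distance matrix is strictly additive
    with a known smallest internal edge.
    """
    nodes = [TreeNode(name=f"T{i}") for i in range(n_taxa)]
    for node in nodes:
        node.length = float(rng.uniform(*leaf_len))
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        new = TreeNode(children=[nodes[i], nodes[j]])
        new.length = float(rng.uniform(*internal_len))
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)] + [new]
    return PhyloTree(root=TreeNode(children=nodes))


def brute_force_min_rmsd(X: np.ndarray, Y: np.ndarray) -> float:
    """Numerically minimise RMSD over rotations+translations, independent of
    the SVD route: multi-start Nelder-Mead over rotation vectors."""
    from scipy.optimize import minimize
    from scipy.spatial.transform import Rotation

    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)

    def cost(rv):
        R = Rotation.from_rotvec(rv).as_matrix()
        return np.sqrt(((Xc @ R.T - Yc) ** 2).sum() / len(X))

    best = np.inf
    starts = [np.zeros(3)] + [
        np.random.default_rng(k).uniform(-np.pi, np.pi, 3) for k in range(6)
    ]
    for x0 in starts:
        res = minimize(cost, x0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
        best = min(best, res.fun)
    return float(best)


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def clean_kinome():
    """Noise-free 61-kinase family: classification must be perfect."""
    return gen_kinase_family(n=61, mutation_rate=0.0, seed=11)


@pytest.fixture(scope="session")
def noisy_kinome():
    """Same family with substitution noise away from motif columns."""
    return gen_kinase_family(n=61, mutation_rate=0.05, seed=11)


@pytest.fixture(scope="session")
def planted_site():
    """Phospho-site neighbourhood with planted 2.2/3.0/5.2 Å contacts."""
    spec = [("ARG", 2.2), ("ARG", 3.0), ("LYS", 5.2)]
    model, truth = gen_phospho_site_structure(spec, seed=5)
    return model, truth, spec
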