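"""Graph coarsening for fixed-size pooling on graphs.

Builds a hierarchy of coarser graphs by greedy heavy-edge matching (pairs
are merged preferring large normalized edge weight), then computes a vertex
permutation with padding ("fake") vertices so that every level has exactly
twice as many vertices as the next: size-2 max pooling then reduces each
level to the next. Fake vertices are isolated and carry zero features.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp


def heavy_edge_matching(A: sp.spmatrix) -> np.ndarray:
    """One level of greedy matching; returns the parent cluster per vertex.

    Vertices are visited in ascending-degree order (stable), and each
    unmatched vertex pairs with the unmatched neighbor maximizing
    w(u, v) * (1/d(u) + 1/d(v)); leftovers become singletons.
    """
    A = sp.csr_matrix(A)
    n = A.shape[0]
    degrees = np.asarray(A.sum(axis=1)).ravel()
    inv_deg = np.divide(1.0, degrees, out=np.zeros(n), where=degrees > 0)
    order = np.argsort(degrees, kind="stable")
    parent = np.full(n, -1, dtype=np.int64)
    cluster = 0
    indptr, indices, data = A.indptr, A.indices, A.data
    for v in order:
        if parent[v] >= 0:
            continue
        best_u, best_w = -1, -np.inf
        for p in range(indptr[v], indptr[v + 1]):
            u = indices[p]
            if u == v or parent[u] >= 0:
                continue
            w = data[p] * (inv_deg[v] + inv_deg[u])
            if w > best_w or (w == best_w and u < best_u):
                best_u, best_w = u, w
        parent[v] = cluster
        if best_u >= 0:
            parent[best_u] = cluster
        cluster += 1
    return parent


def coarsen_graph(A: sp.spmatrix, parent: np.ndarray) -> sp.csr_matrix:
    """Aggregate an adjacency matrix over a cluster assignment."""
    n = A.shape[0]
    m = int(parent.max()) + 1
    S = sp.csr_matrix((np.ones(n), (parent, np.arange(n))), shape=(m, n))
    Ac = S @ A @ S.T
    Ac = sp.csr_matrix(Ac)
    Ac.setdiag(0)
    Ac.eliminate_zeros()
    return Ac


def compute_perm(parents: list[np.ndarray]) -> list[list[int]]:
    """Per-level vertex orderings with fake indices enabling exact halving.

    Returns one index list per level, finest first. Entries >= the level's
    real vertex count denote fake vertices. len(level l) == 2 * len(level
    l+1) for every consecutive pair.
    """
    if not parents:
        return []
    indices = [list(range(int(parents[-1].max()) + 1))]
    for parent in parents[::-1]:
        next_fake = len(parent)
        layer: list[int] = []
        for i in indices[-1]:
            children = list(np.flatnonzero(parent == i))
            if len(children) == 1:
                children.append(next_fake)
                next_fake += 1
            elif len(children) == 0:  # child of a fake: two fakes
                children.extend([next_fake, next_fake + 1])
                next_fake += 2
            layer.extend(children)
        indices.append(layer)
    indices.reverse()
    for finer, coarser in zip(indices[:-1], indices[1:]):
        assert len(finer) == 2 * len(coarser)
    return indices


def perm_adjacency(A: sp.spmatrix, perm: list[int]) -> sp.csr_matrix:
    """Reorder an adjacency matrix by `perm`, padding fakes as isolated."""
    n = A.shape[0]
    n_new = len(perm)
    A = sp.coo_matrix(A)
    new_pos = np.full(n_new, -1, dtype=np.int64)
    for new_idx, old_idx in enumerate(perm):
        if old_idx < n:
            new_pos[old_idx] = new_idx
    rows = new_pos[A.row]
    cols = new_pos[A.col]
    return sp.csr_matrix((A.data, (rows, cols)), shape=(n_new, n_new))


def perm_features(X: np.ndarray, perm: list[int]) -> np.ndarray:
    """Reorder feature columns by `perm`; fake columns are zero."""
    n = X.shape[1]
    out = np.zeros((X.shape[0], len(perm)), dtype=X.dtype)
    for new_idx, old_idx in enumerate(perm):
        if old_idx < n:
            out[:, new_idx] = X[:, old_idx]
    return out


def rescaled_laplacian(A: sp.spmatrix) -> sp.csr_matrix:
    """Symmetric normalized Laplacian rescaled to 2L/lambda_max - I.

    Isolated vertices get L_ii = 1 (their eigenvalue sits inside [0, 2]).
    """
    A = sp.csr_matrix(A, dtype=np.float64)
    n = A.shape[0]
    d = np.asarray(A.sum(axis=1)).ravel()
    d_inv_sqrt = np.divide(1.0, np.sqrt(d), out=np.zeros(n), where=d > 0)
    D = sp.diags(d_inv_sqrt)
    L = sp.identity(n, format="csr") - D @ A @ D
    if n > 2 and L.nnz > 0:
        try:
            lmax = float(sp.linalg.eigsh(
                L, k=1, which="LA", return_eigenvectors=False,
                maxiter=2000, tol=1e-6)[0])
        except sp.linalg.ArpackNoConvergence:
            lmax = 2.0
        lmax = min(max(lmax, 1e-6), 2.0)
    else:
        lmax = 2.0
    return sp.csr_matrix(2.0 / lmax * L - sp.identity(n, format="csr"))
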