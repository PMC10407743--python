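"""node2vec-style network embeddings.

Each node of a graph is sampled by a fixed number of random walks; walk
windows feed a skip-gram model with negative sampling whose input vectors
become the node embedding. With the return and in-out parameters both at 1
the biased second-order walk reduces to a uniform first-order walk, which is
what we sample. The skip-gram SGD runs serially (numba-compiled) so a fixed
seed gives bit-identical embeddings.
"""

from __future__ import annotations

import numpy as np
from numba import njit

DEFAULT_DIMS = 64
DEFAULT_WALKS = 20
DEFAULT_WALK_LENGTH = 10
DEFAULT_WINDOW = 5
DEFAULT_NEGATIVES = 5


def _csr_adjacency(n_nodes: int, edges: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Undirected adjacency in CSR form (indptr, neighbors)."""
    deg = np.zeros(n_nodes, dtype=np.int64)
    np.add.at(deg, edges[:, 0], 1)
    np.add.at(deg, edges[:, 1], 1)
    indptr = np.zeros(n_nodes + 1, dtype=np.int64)
    np.cumsum(deg, out=indptr[1:])
    neigh = np.empty(indptr[-1], dtype=np.int64)
    fill = indptr[:-1].copy()
    for a, b in edges:
        neigh[fill[a]] = b
        fill[a] += 1
        neigh[fill[b]] = a
        fill[b] += 1
    return indptr, neigh


def simulate_walks(
    n_nodes: int,
    edges: np.ndarray,
    n_walks: int = DEFAULT_WALKS,
    walk_length: int = DEFAULT_WALK_LENGTH,
    seed: int = 0,
) -> np.ndarray:
    """Uniform random walks, ``n_walks`` per node, each of ``walk_length`` nodes.

    Walks from isolated nodes stay in place (their windows contribute no
    cross-node pairs). Returns an array (n_nodes * n_walks, walk_length).
    """
    indptr, neigh = _csr_adjacency(n_nodes, edges)
    deg = np.diff(indptr)
    rng = np.random.default_rng(seed)
    starts = np.repeat(np.arange(n_nodes), n_walks)
    walks = np.empty((starts.size, walk_length), dtype=np.int64)
    walks[:, 0] = starts
    cur = starts.copy()
    for step in range(1, walk_length):
        u = rng.random(cur.size)
        d = deg[cur]
        movable = d > 0
        offset = np.zeros(cur.size, dtype=np.int64)
        offset[movable] = (u[movable] * d[movable]).astype(np.int64)
        nxt = cur.copy()
        nxt[movable] = neigh[indptr[cur[movable]] + offset[movable]]
        walks[:, step] = nxt
        cur = nxt
    return walks


def _training_pairs(
    walks: np.ndarray, window: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """(center, context) pairs with the word2vec random-reduced window."""
    n_walks, length = walks.shape
    centers = []
    contexts = []
    # reduced window size per center position, as in word2vec
    red = rng.integers(1, window + 1, size=walks.size).reshape(walks.shape)
    for pos in range(length):
        for off in range(1, window + 1):
            j = pos + off
            if j >= length:
                break
            use = red[:, pos] >= off
            c = walks[use, pos]
            o = walks[use, j]
            keep = c != o
            centers.append(c[keep])
            contexts.append(o[keep])
            centers.append(o[keep])
            contexts.append(c[keep])
    return np.concatenate(centers), np.concatenate(contexts)


@njit(cache=True)
def _sgd_skipgram(
    syn0: np.ndarray,
    syn1: np.ndarray,
    centers: np.ndarray,
    contexts: np.ndarray,
    neg_table: np.ndarray,
    neg_draws: np.ndarray,
    n_negative: int,
    alpha0: float,
    alpha_min: float,
) -> None:
    dims = syn0.shape[1]
    n_pairs = centers.shape[0]
    for i in range(n_pairs):
        alpha = alpha0 * (1.0 - i / (n_pairs + 1))
        if alpha < alpha_min:
            alpha = alpha_min
        c = centers[i]
        grad = np.zeros(dims)
        for k in range(n_negative + 1):
            if k == 0:
                target = contexts[i]
                label = 1.0
            else:
                target = neg_table[neg_draws[i * n_negative + k - 1]]
                if target == contexts[i]:
                    continue
                label = 0.0
            dot = 0.0
            for d in range(dims):
                dot += syn0[c, d] * syn1[target, d]
            if dot > 6.0:
                pred = 1.0
            elif dot < -6.0:
                pred = 0.0
            else:
                pred = 1.0 / (1.0 + np.exp(-dot))
            g = (label - pred) * alpha
            for d in range(dims):
                grad[d] += g * syn1[target, d]
                syn1[target, d] += g * syn0[c, d]
        for d in range(dims):
            syn0[c, d] += grad[d]


def embed_graph(
    n_nodes: int,
    edges: np.ndarray,
    dims: int = DEFAULT_DIMS,
    n_walks: int = DEFAULT_WALKS,
    walk_length: int = DEFAULT_WALK_LENGTH,
    window: int = DEFAULT_WINDOW,
    n_negative: int = DEFAULT_NEGATIVES,
    alpha: float = 0.025,
    seed: int = 0,
) -> np.ndarray:
    """Embed a graph; rows of the result are node vectors.

    One skip-gram training epoch over the sampled walks; negative samples come
    from the unigram^(3/4) distribution over walk tokens.
    """
    if edges.shape[0] == 0:
        raise ValueError("cannot embed a graph with no edges")
    walks = simulate_walks(n_nodes, edges, n_walks, walk_length, seed=seed)
    rng = np.random.default_rng(seed + 1)
    centers, contexts = _training_pairs(walks, window, rng)
    order = rng.permutation(centers.size)
    centers, contexts = centers[order], contexts[order]

    counts = np.bincount(walks.ravel(), minlength=n_nodes).astype(np.float64)
    weights = counts**0.75
    probs = weights / weights.sum()
    neg_table = rng.choice(n_nodes, size=1_000_003, p=probs).astype(np.int64)
    neg_draws = rng.integers(0, neg_table.size, size=centers.size * n_negative)

    syn0 = (rng.random((n_nodes, dims)) - 0.5) / dims
    syn1 = np.zeros((n_nodes, dims))
    _sgd_skipgram(
        syn0,
        syn1,
        centers.astype(np.int64),
        contexts.astype(np.int64),
        neg_table,
        neg_draws.astype(np.int64),
        n_negative,
        alpha,
        alpha * 1e-3,
    )
    return syn0
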