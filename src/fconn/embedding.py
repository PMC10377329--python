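"""Brain graphs and node2vec-style node embeddings.

Each subject's FC matrix becomes a weighted undirected graph over the ROIs.
Node representations are learned with the node2vec procedure: second-order
biased random walks (return parameter ``p``, in-out parameter ``q``)
generate node sequences, and a skip-gram model with negative sampling is
trained on them.  The trainer is a deterministic, single-threaded batched
SGD implementation in numpy: given the same seed it produces bit-identical
embeddings, which is what makes node vectors comparable across subjects
(all subjects share the ROI atlas, the walk schedule and the initial
weights, so systematic differences between their graphs — not run-to-run
noise — drive differences between their feature vectors).

The subject-level feature vector is the row-major concatenation of the R
node vectors in fixed ROI order.  An alternative feature mode that flattens
the FC matrix's upper triangle is provided for ablation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ValidationError
from .fc import FCMatrix


@dataclass
class Node2VecConfig:
    dimensions: int = 16
    walk_length: int = 40
    walks_per_node: int = 10
    window: int = 5
    p: float = 1.0
    q: float = 1.0
    epochs: int = 5
    negative_samples: int = 5
    learning_rate: float = 0.1  # tuned for mean-gradient batched SGD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dimensions < 2:
            raise ValidationError("dimensions must be >= 2")
        for name in ("walk_length", "walks_per_node", "window", "epochs",
                     "negative_samples"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if self.p <= 0 or self.q <= 0:
            raise ValidationError("p and q must be > 0")
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be > 0")


@dataclass
class BrainGraph:
    """Weighted undirected graph over ROIs; each pair stored once (i < j)."""

    n_nodes: int
    edges: list[tuple[int, int, float]]
    node_order: list[str]

    def __post_init__(self) -> None:
        if len(self.node_order) != self.n_nodes:
            raise ValidationError("node_order length must equal n_nodes")
        seen = set()
        for i, j, w in self.edges:
            if i == j:
                raise ValidationError(f"self-loop at node {i}")
            if not (0 <= i < self.n_nodes and 0 <= j < self.n_nodes):
                raise ValidationError(f"edge ({i},{j}) out of range")
            if not np.isfinite(w) or w < 0:
                raise ValidationError(f"edge ({i},{j}) has invalid weight {w}")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValidationError(f"duplicate edge {key}")
            seen.add(key)

    def adjacency(self):
        """neighbors[v], weights[v], neighbor_sets[v] for fast walk steps."""
        nbrs: list[list[int]] = [[] for _ in range(self.n_nodes)]
        wts: list[list[float]] = [[] for _ in range(self.n_nodes)]
        for i, j, w in self.edges:
            nbrs[i].append(j)
            wts[i].append(w)
            nbrs[j].append(i)
            wts[j].append(w)
        neighbor_arr = [np.asarray(v, dtype=np.int64) for v in nbrs]
        weight_arr = [np.asarray(v, dtype=float) for v in wts]
        neighbor_set = [set(v) for v in nbrs]
        return neighbor_arr, weight_arr, neighbor_set

    def is_connected(self) -> bool:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from((i, j) for i, j, _ in self.edges)
        return self.n_nodes > 0 and nx.is_connected(g)


def _edge_weights_for_measure(fc: FCMatrix) -> np.ndarray:
    """Measure-aware non-negative edge weights.

    PCC edges enter by absolute value (a strong anticorrelation is a strong
    connection for the walk); MIC is already in [0, 1]; eMIC's occasional
    small negative values are clamped to 0 here only — the estimator output
    itself is never altered.
    """
    if fc.measure == "PCC":
        return np.abs(fc.values)
    if fc.measure == "eMIC":
        return np.maximum(fc.values, 0.0)
    return fc.values.copy()


def fc_to_graph(fc: FCMatrix, sparsify_top_fraction: float = 1.0) -> BrainGraph:
    """Build the ROI graph, keeping the top fraction of edges by weight.

    Ties are broken by (i, j) lexicographic order.  Any node isolated by the
    thresholding is reattached through its single strongest edge so that
    random walks remain well defined.
    """
    if not (0 < sparsify_top_fraction <= 1):
        raise ValidationError("sparsify_top_fraction must be in (0, 1]")
    w = _edge_weights_for_measure(fc)
    r = fc.n_rois
    cand = [(float(w[i, j]), i, j) for i in range(r) for j in range(i + 1, r)
            if w[i, j] > 0]
    if not cand:
        raise ValidationError("FC matrix has no positive edge weights")
    cand.sort(key=lambda t: (-t[0], t[1], t[2]))
    k = max(1, int(round(sparsify_top_fraction * len(cand))))
    kept = cand[:k]
    degree = np.zeros(r, dtype=int)
    kept_keys = set()
    for wt, i, j in kept:
        degree[i] += 1
        degree[j] += 1
        kept_keys.add((i, j))
    best_edge: dict[int, tuple[float, int, int]] = {}
    for wt, i, j in cand:
        for node in (i, j):
            if node not in best_edge:
                best_edge[node] = (wt, i, j)
    for node in range(r):
        if degree[node] == 0:
            if node not in best_edge:
                continue  # node has no positive edge at all; stays isolated
            wt, i, j = best_edge[node]
            if (i, j) not in kept_keys:
                kept.append((wt, i, j))
                kept_keys.add((i, j))
                degree[i] += 1
                degree[j] += 1
    edges = [(i, j, wt) for wt, i, j in kept]
    return BrainGraph(n_nodes=r, edges=edges, node_order=list(fc.roi_labels))


def simulate_walks(graph: BrainGraph, cfg: Node2VecConfig) -> list[list[int]]:
    """node2vec second-order random walks, ``walks_per_node`` from each node.

    Unnormalized probability of stepping from v to x given the previous node
    t is weight(v, x) * alpha with alpha = 1/p if x == t, 1 if x neighbors
    t, 1/q otherwise.  With p = q = 1 this reduces to first-order
    weight-proportional walks (fast path).
    """
    if not graph.is_connected():
        raise ValidationError("graph is not connected; cannot simulate walks")
    nbrs, wts, nbr_sets = graph.adjacency()
    cums = [np.cumsum(w) for w in wts]
    rng = np.random.Generator(np.random.PCG64(cfg.seed))
    first_order = cfg.p == 1.0 and cfg.q == 1.0
    walks: list[list[int]] = []
    for _ in range(cfg.walks_per_node):
        for start in range(graph.n_nodes):
            walk = [start]
            while len(walk) < cfg.walk_length:
                v = walk[-1]
                if nbrs[v].size == 0:
                    break
                if first_order or len(walk) == 1:
                    cw = cums[v]
                    x = nbrs[v][np.searchsorted(cw, rng.random() * cw[-1],
                                                side="right")]
                else:
                    t = walk[-2]
                    alpha = np.where(
                        nbrs[v] == t,
                        1.0 / cfg.p,
                        np.where([u in nbr_sets[t] for u in nbrs[v]],
                                 1.0, 1.0 / cfg.q),
                    )
                    probs = wts[v] * alpha
                    cw = np.cumsum(probs)
                    x = nbrs[v][np.searchsorted(cw, rng.random() * cw[-1],
                                                side="right")]
                walk.append(int(x))
            walks.append(walk)
    return walks


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -30, 30)))


def train_embeddings(
    walks: list[list[int]], cfg: Node2VecConfig, n_nodes: int,
    batch_size: int = 1024,
) -> np.ndarray:
    """Skip-gram with negative sampling over walk windows.

    Batched SGD with linear learning-rate decay; negative samples drawn
    from the unigram distribution raised to 3/4.  Deterministic given
    ``cfg.seed`` (single-threaded numpy, scatter-adds via ``np.add.at``).
    """
    if not walks:
        raise ValidationError("no walks to train on")
    counts = np.zeros(n_nodes, dtype=float)
    for w in walks:
        for node in w:
            counts[node] += 1
    if np.any(counts == 0):
        missing = np.flatnonzero(counts == 0)
        raise ValidationError(f"nodes absent from all walks: {missing.tolist()}")
    centers_l: list[int] = []
    contexts_l: list[int] = []
    for w in walks:
        ln = len(w)
        for i, c in enumerate(w):
            lo = max(0, i - cfg.window)
            hi = min(ln, i + cfg.window + 1)
            for j in range(lo, hi):
                if j != i:
                    centers_l.append(c)
                    contexts_l.append(w[j])
    centers = np.asarray(centers_l, dtype=np.int64)
    contexts = np.asarray(contexts_l, dtype=np.int64)
    noise = counts**0.75
    noise_cum = np.cumsum(noise / noise.sum())
    rng = np.random.Generator(np.random.PCG64(cfg.seed + 1))
    d = cfg.dimensions
    w_in = (rng.random((n_nodes, d)) - 0.5) / d
    w_out = np.zeros((n_nodes, d))
    n_pairs = centers.size
    n_batches_per_epoch = (n_pairs + batch_size - 1) // batch_size
    total_batches = cfg.epochs * n_batches_per_epoch
    t = 0
    for _ in range(cfg.epochs):
        perm = rng.permutation(n_pairs)
        for b0 in range(0, n_pairs, batch_size):
            sel = perm[b0:b0 + batch_size]
            c = centers[sel]
            o = contexts[sel]
            neg = np.searchsorted(
                noise_cum, rng.random((sel.size, cfg.negative_samples))
            )
            lr = cfg.learning_rate * max(1e-4, 1.0 - t / total_batches)
            v = w_in[c]
            u_pos = w_out[o]
            u_neg = w_out[neg]
            g_pos = _sigmoid((v * u_pos).sum(axis=1)) - 1.0
            g_neg = _sigmoid(np.einsum("bd,bkd->bk", v, u_neg))
            grad_v = g_pos[:, None] * u_pos + np.einsum("bk,bkd->bd", g_neg, u_neg)
            # the vocabulary is tiny (R nodes), so each node collects many
            # pair-gradients per batch; applying their SUM at full lr
            # diverges — average the accumulated gradient per index instead
            gin = np.zeros_like(w_in)
            np.add.at(gin, c, grad_v)
            cnt_in = np.bincount(c, minlength=n_nodes).astype(float)
            nz = cnt_in > 0
            w_in[nz] -= lr * gin[nz] / cnt_in[nz, None]
            gout = np.zeros_like(w_out)
            np.add.at(gout, o, g_pos[:, None] * v)
            np.add.at(gout, neg.ravel(),
                      (g_neg[..., None] * v[:, None, :]).reshape(-1, d))
            cnt_out = (np.bincount(o, minlength=n_nodes)
                       + np.bincount(neg.ravel(), minlength=n_nodes)).astype(float)
            nz = cnt_out > 0
            w_out[nz] -= lr * gout[nz] / cnt_out[nz, None]
            t += 1
    if not np.all(np.isfinite(w_in)):
        raise ValidationError("embedding training diverged to non-finite values")
    return w_in


@dataclass
class EmbeddingSet:
    """Per-subject node embeddings plus the flattened feature vector."""

    subject_id: str
    vectors: np.ndarray
    node_order: list[str]
    feature_vector: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2 or self.vectors.shape[0] != len(self.node_order):
            raise ValidationError("vectors must be R x d in node_order")
        if not np.all(np.isfinite(self.vectors)):
            raise ValidationError("non-finite embedding values")
        self.feature_vector = self.vectors.reshape(-1).copy()


def embed_graph(graph: BrainGraph, cfg: Node2VecConfig, subject_id: str) -> EmbeddingSet:
    walks = simulate_walks(graph, cfg)
    vectors = train_embeddings(walks, cfg, graph.n_nodes)
    return EmbeddingSet(subject_id=subject_id, vectors=vectors,
                        node_order=list(graph.node_order))


def subject_features(emb: EmbeddingSet, node_order: list[str] | None = None) -> np.ndarray:
    """Row-major concatenation of node vectors in fixed ROI order."""
    if node_order is not None and list(emb.node_order) != list(node_order):
        raise ValidationError(
            f"subject {emb.subject_id}: node order does not match reference"
        )
    return emb.feature_vector.copy()


def fc_flatten_features(fc: FCMatrix) -> np.ndarray:
    """Ablation feature mode: the FC matrix's upper triangle, row-major."""
    r = fc.n_rois
    iu = np.triu_indices(r, k=1)
    return fc.values[iu].copy()


def write_edge_list(graph: BrainGraph, path: str | Path) -> None:
    pd.DataFrame(graph.edges, columns=["i", "j", "weight"]).to_csv(
        Path(path), sep="\t", index=False, float_format="%.17g"
    )


def write_embeddings(emb: EmbeddingSet, path: str | Path) -> None:
    pd.DataFrame(emb.vectors, index=emb.node_order).to_csv(
        Path(path), sep="\t", header=False, float_format="%.17g"
    )
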