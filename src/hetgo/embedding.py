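"""LINE graph embedding: first- and second-order proximity with negative sampling.

Nodes of the weighted heterogeneous graph are embedded twice — once
preserving first-order proximity (the weight of the direct edge) and once
preserving second-order proximity (shared neighbourhoods, via a separate
context-vector table) — and the two halves are L2-normalized per node and
concatenated.

Training follows the original LINE conventions: asynchronous SGD over
``total_samples`` weighted edge draws (alias method, O(1) per draw), a
sigmoid negative-sampling objective with noise nodes drawn proportionally to
(weighted degree)^0.75, a learning rate decaying linearly from ``rho0`` to a
small floor, and uniform(-0.5/dim, 0.5/dim) initialization of node vectors
(context vectors start at zero).  The per-sample loop is numba-compiled;
given a seed the result is bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numba import njit

from .networks import HeterogeneousNetwork

NEG_POWER = 0.75        # exponent of the noise distribution over nodes
RHO_FLOOR_FRAC = 1e-4   # learning rate floor, as a fraction of rho0
N_LOSS_BLOCKS = 50      # resolution of the recorded training-loss trace


@dataclass
class EmbeddingConfig:
    """Hyper-parameters of the embedding step.

    ``dim`` is the total dimension (split equally between the two proximity
    orders, so it must be even); ``total_samples`` is the number of SGD edge
    draws per order — the source method used 1e11 at full scale, the default
    here is a desk-scale 1e6.
    """

    dim: int = 64
    n_negative: int = 10
    total_samples: int = 1_000_000
    rho0: float = 0.025
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dim <= 0 or self.dim % 2 != 0:
            raise ValueError(f"dim must be a positive even integer, got {self.dim}")
        if self.n_negative < 1:
            raise ValueError("n_negative must be >= 1")
        if self.total_samples < 0:
            raise ValueError("total_samples must be >= 0")


@dataclass
class EmbeddingMatrix:
    """Per-node vectors; columns [0, dim/2) are first-order, the rest second-order."""

    node_ids: list[str]
    vectors: np.ndarray
    halves: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        if self.vectors.shape[0] != len(self.node_ids):
            raise ValueError("row count does not match node_ids")
        if not np.isfinite(self.vectors).all():
            raise ValueError("embedding contains non-finite entries")
        self._index = {n: i for i, n in enumerate(self.node_ids)}

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def __contains__(self, node: str) -> bool:
        return node in self._index

    def vector(self, node: str) -> np.ndarray:
        return self.vectors[self._index[node]]

    def write_word2vec(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.node_ids)} {self.dim}\n")
            for node, row in zip(self.node_ids, self.vectors):
                fh.write(node + " " + " ".join(f"{x:.8g}" for x in row) + "\n")

    @classmethod
    def read_word2vec(cls, path: str | Path) -> "EmbeddingMatrix":
        with open(path) as fh:
            n, dim = (int(x) for x in fh.readline().split())
            ids, rows = [], []
            for line in fh:
                parts = line.rstrip("\n").split(" ")
                ids.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
        if len(ids) != n:
            raise ValueError(f"header says {n} nodes, file has {len(ids)}")
        half = dim // 2
        return cls(ids, np.asarray(rows), {"first": (0, half), "second": (half, dim)})


@dataclass
class HalfEmbedding:
    """One proximity order's trained vectors plus its training-loss trace."""

    node_ids: list[str]
    vectors: np.ndarray
    order: str
    loss_blocks: np.ndarray = field(default_factory=lambda: np.empty(0))


# ---------------------------------------------------------------------------
# alias sampling
# ---------------------------------------------------------------------------

def _alias_setup(probs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Walker alias tables for O(1) draws from a discrete distribution."""
    n = probs.size
    scaled = probs * n / probs.sum()
    prob = np.zeros(n)
    alias = np.zeros(n, dtype=np.int64)
    small = [i for i in range(n) if scaled[i] < 1.0]
    large = [i for i in range(n) if scaled[i] >= 1.0]
    while small and large:
        s, l = small.pop(), large.pop()
        prob[s] = scaled[s]
        alias[s] = l
        scaled[l] = scaled[l] - (1.0 - scaled[s])
        (small if scaled[l] < 1.0 else large).append(l)
    for rest in (large, small):
        for i in rest:
            prob[i] = 1.0
    return prob, alias


class EdgeSampler:
    """Sampler state for LINE: directed edge arrays plus alias tables.

    Every undirected edge becomes two directed edges; edge draws are
    proportional to weight, noise-node draws to (weighted degree)^0.75.
    Nodes incident to no edge are absent (they receive no embedding).
    """

    def __init__(self, net: HeterogeneousNetwork):
        if not net.edges:
            raise ValueError("cannot embed an edgeless graph")
        self.node_ids = sorted({n for e in net.edges for n in (e.u, e.v)})
        idx = {n: i for i, n in enumerate(self.node_ids)}
        src, dst, w = [], [], []
        for e in sorted(net.edges, key=lambda e: (e.u, e.v, e.layer)):
            i, j = idx[e.u], idx[e.v]
            src += [i, j]
            dst += [j, i]
            w += [e.weight, e.weight]
        self.src = np.asarray(src, dtype=np.int64)
        self.dst = np.asarray(dst, dtype=np.int64)
        self.weights = np.asarray(w, dtype=np.float64)
        self.edge_prob, self.edge_alias = _alias_setup(self.weights.copy())
        degree = np.zeros(len(self.node_ids))
        np.add.at(degree, self.src, self.weights)
        self.node_prob, self.node_alias = _alias_setup(degree**NEG_POWER)

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def sample_edges(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n directed edge indices (for inspection/testing)."""
        k = rng.integers(0, self.src.size, size=n)
        flip = rng.random(n) >= self.edge_prob[k]
        return np.where(flip, self.edge_alias[k], k)

    def sample_nodes(self, n: int, rng: np.random.Generator) -> np.ndarray:
        k = rng.integers(0, self.n_nodes, size=n)
        flip = rng.random(n) >= self.node_prob[k]
        return np.where(flip, self.node_alias[k], k)


def build_alias_tables(net: HeterogeneousNetwork, cfg: EmbeddingConfig | None = None) -> EdgeSampler:
    return EdgeSampler(net)


# ---------------------------------------------------------------------------
# SGD training loop
# ---------------------------------------------------------------------------

@njit(cache=True)
def _sgd_loop(src, dst, edge_prob, edge_alias, node_prob, node_alias,
              emb, ctx, total_samples, n_negative, rho0, seed, loss_blocks):
    np.random.seed(seed)
    n_edges = src.size
    n_nodes = emb.shape[0]
    dim = emb.shape[1]
    rho_floor = rho0 * RHO_FLOOR_FRAC
    n_blocks = loss_blocks.shape[0]
    block = max(1, total_samples // n_blocks) if n_blocks else 1
    gi = np.empty(dim)
    for s in range(total_samples):
        rho = rho0 * (1.0 - s / total_samples)
        if rho < rho_floor:
            rho = rho_floor
        k = int(np.random.random() * n_edges)
        if np.random.random() >= edge_prob[k]:
            k = edge_alias[k]
        i = src[k]
        j = dst[k]
        gi[:] = 0.0
        loss = 0.0
        for m in range(n_negative + 1):
            if m == 0:
                t = j
                label = 1.0
            else:
                t = int(np.random.random() * n_nodes)
                if np.random.random() >= node_prob[t]:
                    t = node_alias[t]
                if t == i or t == j:
                    continue
                label = 0.0
            f = 0.0
            for d in range(dim):
                f += emb[i, d] * ctx[t, d]
            if f > 15.0:
                f = 15.0
            elif f < -15.0:
                f = -15.0
            sig = 1.0 / (1.0 + np.exp(-f))
            g = (label - sig) * rho
            if label > 0.5:
                loss -= np.log(sig + 1e-12)
            else:
                loss -= np.log(1.0 - sig + 1e-12)
            for d in range(dim):
                gi[d] += g * ctx[t, d]
                ctx[t, d] += g * emb[i, d]
        for d in range(dim):
            emb[i, d] += gi[d]
        if n_blocks:
            b = s // block
            if b >= n_blocks:
                b = n_blocks - 1
            loss_blocks[b] += loss
    if n_blocks:
        for b in range(n_blocks):
            loss_blocks[b] /= block


def train_line(
    net: HeterogeneousNetwork, cfg: EmbeddingConfig, order: str
) -> HalfEmbedding:
    """Train one proximity order's half-embedding (dim/2 columns).

    order="first" optimizes the joint edge probability directly (node vectors
    double as context vectors); order="second" keeps a separate context table,
    discarded after training.
    """
    if order not in ("first", "second"):
        raise ValueError(f"order must be 'first' or 'second', got {order!r}")
    sampler = EdgeSampler(net)
    half = cfg.dim // 2
    rng = np.random.default_rng(cfg.seed)
    emb = rng.uniform(-0.5, 0.5, size=(sampler.n_nodes, half)) / half
    ctx = emb if order == "first" else np.zeros_like(emb)
    n_blocks = N_LOSS_BLOCKS if cfg.total_samples >= N_LOSS_BLOCKS else 0
    loss_blocks = np.zeros(n_blocks)
    if cfg.total_samples > 0:
        _sgd_loop(
            sampler.src, sampler.dst, sampler.edge_prob, sampler.edge_alias,
            sampler.node_prob, sampler.node_alias, emb, ctx,
            cfg.total_samples, cfg.n_negative, cfg.rho0,
            int(cfg.seed) % (2**31 - 1), loss_blocks,
        )
    if not np.isfinite(emb).all():
        raise FloatingPointError("embedding diverged to non-finite values")
    return HalfEmbedding(sampler.node_ids, emb, order, loss_blocks)


def embed(net: HeterogeneousNetwork, cfg: EmbeddingConfig) -> EmbeddingMatrix:
    """Train both orders and concatenate their per-node L2-normalized halves."""
    first = train_line(net, cfg, "first")
    second_cfg = EmbeddingConfig(
        dim=cfg.dim, n_negative=cfg.n_negative, total_samples=cfg.total_samples,
        rho0=cfg.rho0, seed=(cfg.seed + 1) % (2**31 - 1),
    )
    second = train_line(net, second_cfg, "second")
    assert first.node_ids == second.node_ids
    vecs = np.hstack([_l2_rows(first.vectors), _l2_rows(second.vectors)])
    half = cfg.dim // 2
    return EmbeddingMatrix(first.node_ids, vecs, {"first": (0, half), "second": (half, cfg.dim)})


def _l2_rows(x: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(x, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return x / norms
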