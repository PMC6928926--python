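"""Construction and integration of the heterogeneous miRNA–protein–disease network.

Three entity networks (miRNA co-expression, protein–protein interaction,
disease phenotype similarity) and three bipartite association networks
(miRNA–target, miRNA–disease, protein–disease) are assembled into a single
weighted undirected graph.  Co-expression edges are Pearson correlations of
expression profiles with non-positive correlations screened out; PPI edges
carry STRING-style confidence scores rescaled to [0, 1]; similarity edges
carry their similarity score; association edges carry unit weight.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("hetgo")

MIRNA = "miRNA"
PROTEIN = "protein"
DISEASE = "disease"

#: endpoint types per layer, in role order (first column, second column)
LAYER_TYPES: dict[str, tuple[str, str]] = {
    "coexpr": (MIRNA, MIRNA),
    "ppi": (PROTEIN, PROTEIN),
    "disease_sim": (DISEASE, DISEASE),
    "mirna_target": (MIRNA, PROTEIN),
    "mirna_disease": (MIRNA, DISEASE),
    "protein_disease": (PROTEIN, DISEASE),
}

DISEASE_LAYERS = ("disease_sim", "mirna_disease", "protein_disease")

WEIGHT_TRANSFORMS = ("identity", "divide_by_1000", "unit")


@dataclass
class ExpressionMatrix:
    """Entities-by-conditions expression values (miRNA expression profiles)."""

    entity_ids: list[str]
    condition_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.entity_ids), len(self.condition_ids)):
            raise ValueError(
                f"expression matrix shape {self.values.shape} does not match "
                f"{len(self.entity_ids)} entities x {len(self.condition_ids)} conditions"
            )
        if len(self.condition_ids) < 2:
            raise ValueError("need at least two conditions to correlate profiles")
        if np.isnan(self.values).all(axis=1).any():
            raise ValueError("expression matrix contains entirely missing rows")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)), df.to_numpy(float))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.entity_ids, columns=self.condition_ids).to_csv(
            path, sep="\t", float_format="%.6g"
        )


@dataclass(frozen=True)
class NetworkEdge:
    """One weighted undirected edge, stored once in canonical order.

    Same-type layers store endpoints lexicographically; bipartite layers store
    them in layer role order (e.g. miRNA first for ``mirna_target``) so the
    endpoint types remain identifiable from the edge itself.
    """

    u: str
    v: str
    weight: float
    layer: str


def make_edge(u: str, v: str, weight: float, layer: str) -> NetworkEdge:
    if layer not in LAYER_TYPES:
        raise ValueError(f"unknown layer {layer!r}")
    if u == v:
        raise ValueError(f"self-edge {u!r} in layer {layer}")
    if not weight > 0:
        raise ValueError(f"edge weight must be > 0, got {weight}")
    tu, tv = LAYER_TYPES[layer]
    if tu == tv and v < u:
        u, v = v, u
    return NetworkEdge(u, v, float(weight), layer)


@dataclass
class HeterogeneousNetwork:
    """Typed vertices and weighted undirected edges; the graph the embedding consumes."""

    vertices: dict[str, str]
    edges: list[NetworkEdge] = field(default_factory=list)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def layer_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for e in self.edges:
            out[e.layer] = out.get(e.layer, 0) + 1
        return out

    def without_layers(self, layers: Iterable[str]) -> "HeterogeneousNetwork":
        """Return a copy with the given layers removed (used for ablation)."""
        drop = set(layers)
        kept = [e for e in self.edges if e.layer not in drop]
        if not kept:
            return HeterogeneousNetwork({}, [])
        return build_global_network(
            [[e for e in kept if e.layer == l] for l in sorted({e.layer for e in kept})]
        )

    def write_tsv(self, path: str | Path) -> None:
        rows = sorted(self.edges, key=lambda e: (e.layer, e.u, e.v))
        with open(path, "w") as fh:
            fh.write("u\tv\tweight\tlayer\n")
            for e in rows:
                fh.write(f"{e.u}\t{e.v}\t{e.weight:.6g}\t{e.layer}\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "HeterogeneousNetwork":
        df = pd.read_csv(path, sep="\t")
        layers: dict[str, list[NetworkEdge]] = {}
        for u, v, w, layer in df.itertuples(index=False):
            layers.setdefault(layer, []).append(make_edge(str(u), str(v), float(w), layer))
        return build_global_network(list(layers.values()))


# ---------------------------------------------------------------------------
# co-expression network
# ---------------------------------------------------------------------------

def average_homolog_profiles(
    expr: ExpressionMatrix, homolog_map: Mapping[str, str]
) -> ExpressionMatrix:
    """Average precursor profiles that produce the same mature miRNA.

    ``homolog_map`` maps precursor id -> mature id.  Every precursor must be a
    row of ``expr``; rows of ``expr`` absent from the map are dropped.  The
    mature profile is the arithmetic mean of its precursors' profiles.
    """
    missing = [p for p in homolog_map if p not in set(expr.entity_ids)]
    if missing:
        raise ValueError(f"homolog map references absent precursors: {sorted(missing)[:5]}")
    row_of = {e: i for i, e in enumerate(expr.entity_ids)}
    groups: dict[str, list[int]] = {}
    for prec in expr.entity_ids:  # preserve first-appearance order of matures
        if prec in homolog_map:
            groups.setdefault(homolog_map[prec], []).append(row_of[prec])
    mature_ids = list(groups)
    values = np.vstack([expr.values[groups[m]].mean(axis=0) for m in mature_ids])
    return ExpressionMatrix(mature_ids, list(expr.condition_ids), values)


def compute_pcc_network(expr: ExpressionMatrix) -> list[NetworkEdge]:
    """Pairwise Pearson correlation edges; non-positive correlations screened out.

    Pairs involving a zero-variance profile (PCC undefined) are skipped with a
    warning rather than aborting the build.
    """
    X = expr.values
    sd = X.std(axis=1)
    degenerate = np.flatnonzero(sd == 0)
    if degenerate.size:
        logger.warning(
            "skipping %d zero-variance expression profiles: %s",
            degenerate.size,
            [expr.entity_ids[i] for i in degenerate[:5]],
        )
    ok = np.flatnonzero(sd > 0)
    edges: list[NetworkEdge] = []
    if ok.size >= 2:
        R = np.corrcoef(X[ok])
        for a in range(ok.size):
            for b in range(a + 1, ok.size):
                r = R[a, b]
                if np.isfinite(r) and r > 0:
                    edges.append(
                        make_edge(
                            expr.entity_ids[ok[a]], expr.entity_ids[ok[b]], min(r, 1.0), "coexpr"
                        )
                    )
    return edges


# ---------------------------------------------------------------------------
# edge-list I/O
# ---------------------------------------------------------------------------

def load_weighted_edges(
    path: str | Path, layer: str, weight_transform: str = "identity"
) -> list[NetworkEdge]:
    """Read a TSV edge list (``u<TAB>v[<TAB>weight]``) into one network layer.

    ``weight_transform``: ``identity`` keeps the third column; ``divide_by_1000``
    rescales STRING-style 0–999 confidence scores; ``unit`` forces weight 1
    (association layers, where the weight column may be absent).  Zero or
    negative transformed weights are dropped (absence of an edge); duplicate
    pairs collapse to their maximum weight.
    """
    if weight_transform not in WEIGHT_TRANSFORMS:
        raise ValueError(f"unknown weight_transform {weight_transform!r}")
    best: dict[tuple[str, str], float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "u" and lineno == 1:  # optional header
                continue
            if len(parts) < 2 or (weight_transform != "unit" and len(parts) < 3):
                raise ValueError(f"{path}:{lineno}: malformed row {line!r}")
            u, v = parts[0], parts[1]
            if weight_transform == "unit":
                w = 1.0
            else:
                try:
                    w = float(parts[2])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: bad weight {parts[2]!r}") from exc
                if weight_transform == "divide_by_1000":
                    w /= 1000.0
            if w < 0:
                logger.warning("%s:%d: negative weight %.4g dropped", path, lineno, w)
                continue
            if w == 0:
                continue
            if u == v:
                logger.warning("%s:%d: self-edge %s dropped", path, lineno, u)
                continue
            e = make_edge(u, v, w, layer)
            key = (e.u, e.v)
            best[key] = max(best.get(key, 0.0), e.weight)
    return [make_edge(u, v, w, layer) for (u, v), w in best.items()]


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

def build_global_network(
    layers: list[list[NetworkEdge]] | list[set[NetworkEdge]],
    vertex_types: Mapping[str, str] | None = None,
) -> HeterogeneousNetwork:
    """Union the per-layer edge sets into one heterogeneous graph.

    Vertex types are inferred from the layers' endpoint roles; an id that
    appears with two different types is an input error.  ``vertex_types``, if
    given, is validated against the inferred assignment.
    """
    if not layers:
        raise ValueError("no layers")
    vertices: dict[str, str] = {}

    def assign(node: str, typ: str) -> None:
        prev = vertices.setdefault(node, typ)
        if prev != typ:
            raise ValueError(f"vertex {node!r} appears as both {prev} and {typ}")

    best: dict[tuple[str, str, str], float] = {}
    for layer_edges in layers:
        for e in sorted(layer_edges, key=lambda e: (e.layer, e.u, e.v)):
            tu, tv = LAYER_TYPES[e.layer]
            assign(e.u, tu)
            assign(e.v, tv)
            key = (e.u, e.v, e.layer)
            best[key] = max(best.get(key, 0.0), e.weight)
    if vertex_types is not None:
        for node, typ in vertex_types.items():
            if node in vertices and vertices[node] != typ:
                raise ValueError(
                    f"vertex {node!r} declared {typ} but inferred {vertices[node]}"
                )
    edges = [make_edge(u, v, w, layer) for (u, v, layer), w in sorted(best.items())]
    over = [e for e in edges if e.weight > 1.0 + 1e-9]
    if over:
        logger.warning(
            "%d edges have weight > 1 after transforms; layers are meant to share a [0,1] scale",
            len(over),
        )
    net = HeterogeneousNetwork(vertices, edges)
    _log_components(net)
    return net


def _log_components(net: HeterogeneousNetwork) -> None:
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(net.vertices)
    g.add_edges_from((e.u, e.v) for e in net.edges)
    sizes = sorted((len(c) for c in nx.connected_components(g)), reverse=True)
    logger.info(
        "global network: %d vertices, %d edges, %d components (largest %d)",
        net.n_vertices,
        net.n_edges,
        len(sizes),
        sizes[0] if sizes else 0,
    )
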