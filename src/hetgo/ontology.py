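"""Gene Ontology handling: DAG parsing, true-path propagation, label matrices.

Annotating an entity to a term implies annotation to every ancestor of that
term (the true-path rule), so raw annotation tables are closed under the
ancestor relation before training or evaluation.  Each namespace (biological
process, molecular function, cellular component) is handled independently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import obonet

logger = logging.getLogger("hetgo")

NAMESPACES = {"biological_process": "BP", "molecular_function": "MF", "cellular_component": "CC"}
RELATIONS = ("is_a", "part_of")


@dataclass
class GODag:
    """Rooted DAG of ontology terms with per-term namespace labels.

    ``parents`` holds the is_a (and, by default, part_of) parents of each
    term; ``roots`` maps each namespace code (BP/MF/CC) to its root term.
    """

    terms: set[str]
    parents: dict[str, set[str]]
    namespace: dict[str, str]
    roots: dict[str, str]
    alt_ids: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._children: dict[str, set[str]] = {t: set() for t in self.terms}
        for t, ps in self.parents.items():
            for p in ps:
                self._children[p].add(t)
        self._anc_cache: dict[str, frozenset[str]] = {}

    def resolve(self, term: str) -> str:
        """Map an alt_id to its primary id; primary ids pass through."""
        if term in self.terms:
            return term
        if term in self.alt_ids:
            return self.alt_ids[term]
        raise KeyError(f"unknown term {term!r}")

    def children(self, term: str) -> set[str]:
        return self._children[term]

    def ancestors(self, term: str) -> frozenset[str]:
        """All strict ancestors of a term (transitive closure of parents)."""
        got = self._anc_cache.get(term)
        if got is not None:
            return got
        out: set[str] = set()
        stack = list(self.parents[term])
        while stack:
            p = stack.pop()
            if p not in out:
                out.add(p)
                stack.extend(self.parents[p])
        result = frozenset(out)
        self._anc_cache[term] = result
        return result

    def reverse_topological(self, terms: Iterable[str] | None = None) -> list[str]:
        """Terms ordered children-before-parents (deterministic tie-break)."""
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        g.add_edges_from((t, p) for t, ps in self.parents.items() for p in ps)
        order = list(nx.lexicographical_topological_sort(g))
        if terms is None:
            return order
        keep = set(terms)
        return [t for t in order if t in keep]


def parse_obo(path: str | Path, include_part_of: bool = True) -> GODag:
    """Parse an OBO 1.2 file into a GODag.

    Obsolete terms are dropped, alt_ids are mapped to their primary term, and
    only is_a (plus, optionally, part_of) relations are kept.  Parent links
    that cross namespaces are discarded with a warning, and a cycle among the
    retained relations is a hard error.
    """
    graph = obonet.read_obo(path, ignore_obsolete=True)
    keep = set(RELATIONS) if include_part_of else {"is_a"}
    terms: set[str] = set()
    namespace: dict[str, str] = {}
    parents: dict[str, set[str]] = {}
    alt_ids: dict[str, str] = {}
    for node, data in graph.nodes(data=True):
        ns = data.get("namespace")
        if ns not in NAMESPACES:
            logger.warning("term %s has unknown namespace %r; skipped", node, ns)
            continue
        terms.add(node)
        namespace[node] = NAMESPACES[ns]
        parents[node] = set()
        for alt in data.get("alt_id", []):
            alt_ids[alt] = node
    for child, parent, rel in graph.edges(keys=True):
        if rel not in keep or child not in terms or parent not in terms:
            continue
        if namespace[child] != namespace[parent]:
            logger.warning("cross-namespace link %s -> %s dropped", child, parent)
            continue
        parents[child].add(parent)
    _check_acyclic(parents)
    roots: dict[str, str] = {}
    for t in sorted(terms):
        if not parents[t]:
            ns = namespace[t]
            if ns in roots:
                raise ValueError(f"namespace {ns} has multiple roots: {roots[ns]}, {t}")
            roots[ns] = t
    dag = GODag(terms, parents, namespace, roots, alt_ids)
    for t in terms:
        ns = namespace[t]
        if t != roots[ns] and roots[ns] not in dag.ancestors(t):
            raise ValueError(f"term {t} does not reach its namespace root {roots[ns]}")
    return dag


def _check_acyclic(parents: Mapping[str, set[str]]) -> None:
    g = nx.DiGraph()
    g.add_nodes_from(parents)
    g.add_edges_from((t, p) for t, ps in parents.items() for p in ps)
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise ValueError(f"ontology contains a cycle: {cycle}")


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

@dataclass
class AnnotationSet:
    """Entity -> set-of-terms map; ``propagated`` marks ancestor closure."""

    annotations: dict[str, set[str]]
    propagated: bool = False

    def term_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for terms in self.annotations.values():
            for t in terms:
                counts[t] = counts.get(t, 0) + 1
        return counts


def load_annotations(
    path: str | Path, exclude_evidence: tuple[str, ...] = ("IEA",)
) -> AnnotationSet:
    """Read a TSV annotation table ``entity<TAB>term[<TAB>evidence]``.

    When an evidence column is present, rows whose code is in
    ``exclude_evidence`` (default: IEA, inferred from electronic annotation)
    are filtered out.
    """
    annots: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: malformed row {line!r}")
            if len(parts) >= 3 and parts[2] in exclude_evidence:
                continue
            annots.setdefault(parts[0], set()).add(parts[1])
    return AnnotationSet({e: s for e, s in annots.items() if s})


def write_annotations(annots: AnnotationSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for entity in sorted(annots.annotations):
            for term in sorted(annots.annotations[entity]):
                fh.write(f"{entity}\t{term}\n")


def propagate(dag: GODag, annots: AnnotationSet) -> AnnotationSet:
    """Close every entity's term set under the ancestor relation (idempotent)."""
    out: dict[str, set[str]] = {}
    for entity, terms in annots.annotations.items():
        closed: set[str] = set()
        for term in terms:
            try:
                primary = dag.resolve(term)
            except KeyError:
                raise KeyError(f"entity {entity!r} annotated to unknown term {term!r}")
            closed.add(primary)
            closed |= dag.ancestors(primary)
        out[entity] = closed
    return AnnotationSet(out, propagated=True)


def select_terms(
    dag: GODag, annots: AnnotationSet, min_count: int, namespace: str
) -> list[str]:
    """Trainable term subset: namespace terms annotated to >= min_count entities.

    The namespace root is excluded; the result is ordered children-before-
    parents so label columns and merge layers can share one fixed order.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    if namespace not in set(NAMESPACES.values()):
        raise ValueError(f"unknown namespace {namespace!r}")
    if not annots.propagated:
        raise ValueError("select_terms requires propagated annotations")
    counts = annots.term_counts()
    root = dag.roots.get(namespace)
    chosen = {
        t
        for t, c in counts.items()
        if c >= min_count and dag.namespace.get(t) == namespace and t != root
    }
    return dag.reverse_topological(chosen)


@dataclass
class LabelMatrix:
    """Binary entity-by-term matrix whose column order is reverse-topological."""

    entity_ids: list[str]
    term_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.entity_ids), len(self.term_ids)):
            raise ValueError("label matrix shape mismatch")

    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(self.values, index=self.entity_ids, columns=self.term_ids).to_csv(
            path, sep="\t"
        )


def build_labels(
    annots: AnnotationSet, terms: list[str], entity_ids: list[str] | None = None
) -> LabelMatrix:
    """Binary membership matrix of propagated annotations over the selected terms."""
    if not annots.propagated:
        raise ValueError("build_labels requires propagated annotations")
    if entity_ids is None:
        entity_ids = sorted(annots.annotations)
    col = {t: j for j, t in enumerate(terms)}
    values = np.zeros((len(entity_ids), len(terms)), dtype=np.uint8)
    for i, entity in enumerate(entity_ids):
        for t in annots.annotations.get(entity, ()):
            j = col.get(t)
            if j is not None:
                values[i, j] = 1
    return LabelMatrix(list(entity_ids), list(terms), values)
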