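"""Synthetic desk-scale benchmark with planted functional modules.

The generator emulates every input the pipeline consumes: a precursor-level
miRNA expression matrix (module archetype profiles plus Gaussian noise, so
co-expression recovers the modules), planted-partition PPI and disease-
similarity edge lists (edge probability ``p_in`` within a module, ``p_out``
across), three bipartite association lists preferentially linking
same-module entities, a rooted random GO-like DAG in OBO format, and
annotation tables in which each entity carries its module's characteristic
terms with probability ``annotation_signal`` plus uniform noise terms.
Everything is driven by one seed and writes byte-identical files on re-run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np

from .ontology import AnnotationSet

#: bipartite layers are sparser than within-type layers by this factor
ASSOC_SCALE = 1.0 / 3.0


@dataclass
class SynthConfig:
    n_mirna: int = 120
    n_protein: int = 150
    n_disease: int = 40
    n_modules: int = 4
    p_in: float = 0.3
    p_out: float = 0.02
    n_conditions: int = 24
    n_terms: int = 60
    terms_per_module: int = 4
    annotation_signal: float = 0.9
    noise_term_rate: float = 0.3     # Poisson mean of random extra terms per entity
    expression_noise: float = 0.5    # sd of Gaussian noise on archetype profiles
    homolog_fraction: float = 0.2    # fraction of miRNAs with two precursors
    #: optional overrides of the miRNA-target layer's module contrast; when
    #: None the global p_in/p_out apply.  Setting both to the same value makes
    #: targeting uninformative, leaving disease layers as the module signal
    #: carriers (the disease-ablation contrast fixture).
    target_p_in: float | None = None
    target_p_out: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_mirna, self.n_protein, self.n_disease) < self.n_modules:
            raise ValueError("n_modules exceeds the size of an entity type")
        if not 0 <= self.p_out < self.p_in <= 1:
            raise ValueError("need 0 <= p_out < p_in <= 1")
        if not 0 < self.annotation_signal <= 1:
            raise ValueError("annotation_signal must be in (0, 1]")
        if self.expression_noise < 0 or self.noise_term_rate < 0:
            raise ValueError("noise parameters must be non-negative")
        per_branch = 1 + (self.n_terms - 1 - self.n_modules) // self.n_modules
        if per_branch - per_branch // 2 < self.terms_per_module:
            raise ValueError("not enough deep terms per branch for module term sets")


@dataclass
class SynthTruth:
    """Ground truth of one generated benchmark (module structure + tallies)."""

    modules: dict[str, int]
    module_terms: dict[int, list[str]]
    files: dict[str, str]
    counts: dict[str, int]

    def write(self, path: str | Path) -> None:
        payload = {
            "modules": self.modules,
            "module_terms": {str(k): v for k, v in self.module_terms.items()},
            "files": self.files,
            "counts": self.counts,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    @classmethod
    def read(cls, path: str | Path) -> "SynthTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            {k: int(v) for k, v in d["modules"].items()},
            {int(k): v for k, v in d["module_terms"].items()},
            d["files"],
            d["counts"],
        )


def _term_id(i: int) -> str:
    return f"GO:{i:07d}"


def _planted_partition_edges(
    ids: list[str], modules: np.ndarray, p_in: float, p_out: float,
    rng: np.random.Generator, weights: str,
) -> list[tuple[str, str, float]]:
    edges = []
    n = len(ids)
    for a in range(n):
        for b in range(a + 1, n):
            p = p_in if modules[a] == modules[b] else p_out
            if rng.random() < p:
                if weights == "string":
                    w = float(rng.integers(500, 1000))
                else:
                    w = round(float(rng.uniform(0.5, 1.0)), 4)
                edges.append((ids[a], ids[b], w))
    return edges


def _bipartite_edges(
    left: list[str], right: list[str], lmod: np.ndarray, rmod: np.ndarray,
    p_in: float, p_out: float, rng: np.random.Generator,
) -> list[tuple[str, str]]:
    edges = []
    for a, u in enumerate(left):
        for b, v in enumerate(right):
            p = (p_in if lmod[a] == rmod[b] else p_out) * ASSOC_SCALE
            if rng.random() < p:
                edges.append((u, v))
    return edges


def _write_edges(path: Path, edges, weighted: bool) -> None:
    with open(path, "w") as fh:
        for e in edges:
            if weighted:
                u, v, w = e
                fh.write(f"{u}\t{v}\t{w:g}\n")
            else:
                fh.write(f"{e[0]}\t{e[1]}\n")


def _write_obo(path: Path, parents: dict[str, list[str]], namespace: dict[str, str]) -> None:
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: synthetic-go\n")
        for term in sorted(parents):
            fh.write(f"\n[Term]\nid: {term}\nname: synthetic term {term[3:]}\n")
            fh.write(f"namespace: {namespace[term]}\n")
            for p in sorted(parents[term]):
                fh.write(f"is_a: {p} ! synthetic term {p[3:]}\n")


def _random_dag(
    n_terms: int, rng: np.random.Generator, start: int, n_branches: int = 1
) -> tuple[list[str], dict[str, list[str]], dict[str, int]]:
    """Rooted random GO-like DAG with distinct top-level branches.

    The root has ``n_branches`` children; the remaining terms are assigned
    round-robin to branches, each taking a primary parent drawn with a bias
    toward recently added terms of its branch (yielding deep subtrees, as in
    the real ontology, rather than a shallow fan below the root) plus,
    occasionally, a second parent anywhere in the DAG.  Returns the term
    list, the parent map, and each term's branch index (root: -1).
    """
    if n_terms < n_branches + 1:
        raise ValueError("n_terms too small for the requested branch count")
    terms = [_term_id(start + i) for i in range(n_terms)]
    parents: dict[str, list[str]] = {terms[0]: []}
    branch: dict[str, int] = {terms[0]: -1}
    by_branch: list[list[int]] = []
    for b in range(n_branches):
        parents[terms[1 + b]] = [terms[0]]
        branch[terms[1 + b]] = b
        by_branch.append([1 + b])
    for i in range(1 + n_branches, n_terms):
        b = (i - 1 - n_branches) % n_branches
        pool = by_branch[b]
        primary = pool[int(max(rng.integers(0, len(pool)), rng.integers(0, len(pool))))]
        ps = {primary}
        if rng.random() < 0.2:
            ps.add(int(rng.integers(1, i)))
        parents[terms[i]] = [terms[p] for p in sorted(ps)]
        branch[terms[i]] = b
        by_branch[b].append(i)
    return terms, parents, branch


def generate_benchmark(cfg: SynthConfig, out_dir: str | Path) -> SynthTruth:
    """Write the full synthetic input set to ``out_dir`` and return its truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    mirnas = [f"mir-{i:04d}" for i in range(cfg.n_mirna)]
    proteins = [f"PROT{i:04d}" for i in range(cfg.n_protein)]
    diseases = [f"DIS{i:03d}" for i in range(cfg.n_disease)]
    m_mod = np.arange(cfg.n_mirna) % cfg.n_modules
    p_mod = np.arange(cfg.n_protein) % cfg.n_modules
    d_mod = np.arange(cfg.n_disease) % cfg.n_modules

    # --- expression: archetype per module + noise; some matures get 2 precursors
    archetypes = rng.normal(0.0, 2.0, size=(cfg.n_modules, cfg.n_conditions))
    profiles = archetypes[m_mod] + rng.normal(0.0, cfg.expression_noise,
                                              size=(cfg.n_mirna, cfg.n_conditions))
    two_prec = rng.random(cfg.n_mirna) < cfg.homolog_fraction
    prec_rows, prec_ids, homolog = [], [], []
    for i, mat in enumerate(mirnas):
        n_prec = 2 if two_prec[i] else 1
        for c in range(n_prec):
            pid = f"{mat}-p{c + 1}"
            prec_ids.append(pid)
            prec_rows.append(profiles[i] + rng.normal(0.0, 0.1, cfg.n_conditions))
            homolog.append((pid, mat))
    cond = [f"tissue_{j:02d}" for j in range(cfg.n_conditions)]
    with open(out / "expression.tsv", "w") as fh:
        fh.write("precursor\t" + "\t".join(cond) + "\n")
        for pid, row in zip(prec_ids, prec_rows):
            fh.write(pid + "\t" + "\t".join(f"{x:.5g}" for x in row) + "\n")
    with open(out / "homolog_map.tsv", "w") as fh:
        for pid, mat in homolog:
            fh.write(f"{pid}\t{mat}\n")

    # --- entity networks
    ppi = _planted_partition_edges(proteins, p_mod, cfg.p_in, cfg.p_out, rng, "string")
    dis = _planted_partition_edges(diseases, d_mod, cfg.p_in, cfg.p_out, rng, "uniform")
    _write_edges(out / "ppi.tsv", ppi, weighted=True)
    _write_edges(out / "disease_sim.tsv", dis, weighted=True)

    # --- bipartite association networks (unit weight, written as 2 columns)
    t_in = cfg.p_in if cfg.target_p_in is None else cfg.target_p_in
    t_out = cfg.p_out if cfg.target_p_out is None else cfg.target_p_out
    mt = _bipartite_edges(mirnas, proteins, m_mod, p_mod, t_in, t_out, rng)
    md = _bipartite_edges(mirnas, diseases, m_mod, d_mod, cfg.p_in, cfg.p_out, rng)
    pd_ = _bipartite_edges(proteins, diseases, p_mod, d_mod, cfg.p_in, cfg.p_out, rng)
    _write_edges(out / "mirna_target.tsv", mt, weighted=False)
    _write_edges(out / "mirna_disease.tsv", md, weighted=False)
    _write_edges(out / "protein_disease.tsv", pd_, weighted=False)

    # --- ontology: one BP DAG (+ a token MF namespace for filter coverage)
    bp_terms, bp_parents, bp_branch = _random_dag(
        cfg.n_terms, rng, start=1, n_branches=cfg.n_modules
    )
    mf_terms, mf_parents, _ = _random_dag(5, rng, start=9000001)
    namespace = {t: "biological_process" for t in bp_terms}
    namespace |= {t: "molecular_function" for t in mf_terms}
    _write_obo(out / "ontology.obo", bp_parents | mf_parents, namespace)

    # --- characteristic terms: deep terms of each module's own BP branch
    module_terms = {}
    for m in range(cfg.n_modules):
        members = [t for t in bp_terms if bp_branch[t] == m]
        deep = members[len(members) // 2:]  # later additions sit deeper
        pick = rng.choice(len(deep), size=cfg.terms_per_module, replace=False)
        module_terms[m] = sorted(deep[int(j)] for j in pick)

    def annotate(ids: list[str], mods: np.ndarray, path: Path) -> None:
        non_root = bp_terms[1:]
        with open(path, "w") as fh:
            for i, entity in enumerate(ids):
                chosen = [t for t in module_terms[int(mods[i])]
                          if rng.random() < cfg.annotation_signal]
                n_noise = rng.poisson(cfg.noise_term_rate)
                for _ in range(n_noise):
                    chosen.append(non_root[int(rng.integers(len(non_root)))])
                if not chosen:
                    chosen = [module_terms[int(mods[i])][0]]
                for t in sorted(set(chosen)):
                    fh.write(f"{entity}\t{t}\tEXP\n")
                # decoy electronically-inferred rows, filtered at load time
                if rng.random() < 0.2:
                    fh.write(f"{entity}\t{non_root[int(rng.integers(len(non_root)))]}\tIEA\n")

    annotate(proteins, p_mod, out / "annotations_protein.tsv")
    annotate(mirnas, m_mod, out / "annotations_mirna.tsv")

    modules = (
        {m: int(v) for m, v in zip(mirnas, m_mod)}
        | {p: int(v) for p, v in zip(proteins, p_mod)}
        | {d: int(v) for d, v in zip(diseases, d_mod)}
    )
    files = {
        "expression": "expression.tsv", "homolog_map": "homolog_map.tsv",
        "ppi": "ppi.tsv", "disease_sim": "disease_sim.tsv",
        "mirna_target": "mirna_target.tsv", "mirna_disease": "mirna_disease.tsv",
        "protein_disease": "protein_disease.tsv", "obo": "ontology.obo",
        "annotations_protein": "annotations_protein.tsv",
        "annotations_mirna": "annotations_mirna.tsv",
    }
    counts = {
        "n_mirna": cfg.n_mirna, "n_protein": cfg.n_protein, "n_disease": cfg.n_disease,
        "n_ppi_edges": len(ppi), "n_disease_sim_edges": len(dis),
        "n_mirna_target_edges": len(mt), "n_mirna_disease_edges": len(md),
        "n_protein_disease_edges": len(pd_),
    }
    truth = SynthTruth(modules, module_terms, files, counts)
    truth.write(out / "truth.json")
    (out / "synth_config.json").write_text(json.dumps(asdict(cfg), indent=2) + "\n")
    return truth


def permute_labels(annots: AnnotationSet, seed: int) -> AnnotationSet:
    """Null control: permute entity -> term-set assignments across entities."""
    entities = sorted(annots.annotations)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(entities))
    sets = [set(annots.annotations[entities[i]]) for i in perm]
    return AnnotationSet(dict(zip(entities, sets)), propagated=annots.propagated)
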