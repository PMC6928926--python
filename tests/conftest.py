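import numpy as np
import pytest

from hetgo.ontology import AnnotationSet, GODag
from hetgo.synthetic import SynthConfig, generate_benchmark


def make_dag(parents: dict[str, list[str]], namespace: str = "BP") -> GODag:
    """Build a GODag directly from a parent map (single namespace)."""
    terms = set(parents)
    ns = {t: namespace for t in terms}
    roots = {namespace: next(t for t in sorted(terms) if not parents[t])}
    return GODag(terms, {t: set(p) for t, p in parents.items()}, ns, roots)


def random_parent_map(rng: np.random.Generator, n_terms: int) -> dict[str, list[str]]:
    """Random rooted DAG over GO-like ids: term i>0 gets 1-2 earlier parents."""
    ids = [f"GO:{i + 1:07d}" for i in range(n_terms)]
    parents: dict[str, list[str]] = {ids[0]: []}
    for i in range(1, n_terms):
        k = 1 if i == 1 else int(rng.integers(1, 3))
        ps = rng.choice(i, size=min(k, i), replace=False)
        parents[ids[i]] = [ids[int(p)] for p in ps]
    return parents


@pytest.fixture
def chain_dag() -> GODag:
    return make_dag({"GO:0000001": [], "GO:0000002": ["GO:0000001"],
                     "GO:0000003": ["GO:0000002"]})


@pytest.fixture
def diamond_dag() -> GODag:
    # two parents sharing a grandparent (the root)
    return make_dag({
        "GO:0000001": [],
        "GO:0000002": ["GO:0000001"],
        "GO:0000003": ["GO:0000001"],
        "GO:0000004": ["GO:0000002", "GO:0000003"],
    })


@pytest.fixture(scope="session")
def bench_dir(tmp_path_factory):
    """One default synthetic benchmark shared across tests."""
    out = tmp_path_factory.mktemp("bench")
    truth = generate_benchmark(SynthConfig(seed=11), out)
    return out, truth
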