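"""End-to-end pipeline: simulate -> build-net -> embed -> train -> predict -> evaluate.

One global seed fans out deterministically to per-stage seeds; a run
directory collects the integrated network, embeddings, trained model,
predictions, P-R curve and a summary JSON.  Timings go to the log only, so
identical configs and seeds produce byte-identical artifacts.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import networks as nets
from .embedding import EmbeddingConfig, EmbeddingMatrix, embed
from .evaluation import EvalConfig, EvalResult, evaluate, pr_curve
from .hmc import HierarchicalModel, ModelConfig, featurize, forward, train
from .ontology import (AnnotationSet, build_labels, load_annotations, parse_obo,
                       propagate, select_terms)
from .synthetic import SynthConfig, generate_benchmark

logger = logging.getLogger("hetgo")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    h = 0
    for ch in stage:
        h = (h * 131 + ord(ch)) % 1_000_003
    return (global_seed * 1_000_003 + h) % (2**31 - 1)


@dataclass
class PipelineConfig:
    data_dir: str = "."
    namespace: str = "BP"
    min_term_count: int = 5
    seed: int = 0
    ablate_disease: bool = False
    synth: SynthConfig | None = None
    embedding: EmbeddingConfig = field(default_factory=EmbeddingConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    threshold_step: float = 0.01

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        if kwargs.get("synth") is not None:
            kwargs["synth"] = SynthConfig(**kwargs["synth"])
        if "embedding" in kwargs:
            kwargs["embedding"] = EmbeddingConfig(**kwargs["embedding"])
        if "model" in kwargs:
            kwargs["model"] = ModelConfig(**kwargs["model"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def build_network_from_dir(
    data_dir: str | Path, ablate_disease: bool = False
) -> nets.HeterogeneousNetwork:
    """Load the six input files and integrate them into the global network."""
    d = Path(data_dir)
    expr = nets.ExpressionMatrix.read_tsv(d / "expression.tsv")
    homolog = {}
    with open(d / "homolog_map.tsv") as fh:
        for line in fh:
            prec, mat = line.rstrip("\n").split("\t")
            homolog[prec] = mat
    mature = nets.average_homolog_profiles(expr, homolog)
    layers = [
        nets.compute_pcc_network(mature),
        nets.load_weighted_edges(d / "ppi.tsv", "ppi", "divide_by_1000"),
        nets.load_weighted_edges(d / "mirna_target.tsv", "mirna_target", "unit"),
    ]
    if not ablate_disease:
        layers += [
            nets.load_weighted_edges(d / "disease_sim.tsv", "disease_sim", "identity"),
            nets.load_weighted_edges(d / "mirna_disease.tsv", "mirna_disease", "unit"),
            nets.load_weighted_edges(d / "protein_disease.tsv", "protein_disease", "unit"),
        ]
    return nets.build_global_network(layers)


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute all stages; returns (and writes) the summary dictionary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
    timings: dict[str, float] = {}

    def timed(stage):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()

            def __exit__(self, exc_type, exc, tb):
                timings[stage] = time.perf_counter() - self.t0
                if exc_type is not None:
                    logger.error("stage %r failed", stage)
                else:
                    logger.info("stage %r done in %.2fs", stage, timings[stage])

        return _T()

    data_dir = Path(cfg.data_dir)
    if cfg.synth is not None:
        with timed("simulate"):
            synth_cfg = SynthConfig(**{**asdict(cfg.synth),
                                       "seed": stage_seed(cfg.seed, "simulate")})
            data_dir = out / "data"
            generate_benchmark(synth_cfg, data_dir)

    with timed("build-net"):
        net = build_network_from_dir(data_dir, cfg.ablate_disease)
        net.write_tsv(out / "network.tsv")

    with timed("embed"):
        emb_cfg = EmbeddingConfig(**{**asdict(cfg.embedding),
                                     "seed": stage_seed(cfg.seed, "embed")})
        emb = embed(net, emb_cfg)
        emb.write_word2vec(out / "embeddings.txt")

    with timed("train"):
        dag = parse_obo(data_dir / "ontology.obo")
        prot_annots = propagate(dag, load_annotations(data_dir / "annotations_protein.tsv"))
        terms = select_terms(dag, prot_annots, cfg.min_term_count, cfg.namespace)
        if not terms:
            raise RuntimeError("stage 'train' failed: no trainable terms selected")
        labels = build_labels(prot_annots, terms)
        feats = featurize(labels.entity_ids, emb)
        model_cfg = ModelConfig(**{**asdict(cfg.model),
                                   "seed": stage_seed(cfg.seed, "train")})
        model = train(feats, labels, dag, model_cfg)
        model.save(out / "model.npz")

    with timed("predict"):
        mirna_annots = propagate(dag, load_annotations(data_dir / "annotations_mirna.tsv"))
        mirnas = sorted(mirna_annots.annotations)
        pred = forward(model, featurize(mirnas, emb), mirnas)
        pred.write_tsv(out / "predictions.tsv")

    with timed("evaluate"):
        eval_cfg = EvalConfig(namespace=cfg.namespace)
        result = evaluate(pred, mirna_annots, dag, eval_cfg)
        result.write(out / "thresholds.tsv")
        pr_curve(result, csv_path=out / "pr_curve.csv")

    summary = {
        **result.summary(),
        "namespace": cfg.namespace,
        "n_vertices": net.n_vertices,
        "n_edges": net.n_edges,
        "layer_counts": net.layer_counts(),
        "n_terms_trained": len(terms),
        "ablate_disease": cfg.ablate_disease,
        "seed": cfg.seed,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    logger.info("pipeline timings: %s", {k: round(v, 2) for k, v in timings.items()})
    return summary
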