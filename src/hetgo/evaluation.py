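"""Protein-centric (CAFA-style) evaluation: precision/recall sweep and Fmax.

For each entity i and threshold t, the predicted set P_i(t) holds the terms
scoring >= t and R_i the experimentally supported (propagated) terms:

    Pre_i(t) = |P_i(t) ∩ R_i| / |P_i(t)|      Rec_i(t) = |P_i(t) ∩ R_i| / |R_i|

Pre(t) averages Pre_i(t) over the m(t) entities with at least one prediction
at t; Rec(t) averages Rec_i(t) over all N evaluated entities.  Fmax is the
maximum harmonic mean of Pre(t) and Rec(t) over the threshold grid.
Namespace roots are vacuous predictions and are excluded by default.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .hmc import PredictionMatrix
from .ontology import AnnotationSet, GODag

logger = logging.getLogger("hetgo")


def default_thresholds(step: float = 0.01) -> np.ndarray:
    n = int(round(1.0 / step))
    return np.round(np.linspace(0.0, 1.0, n + 1), 10)


@dataclass
class EvalConfig:
    thresholds: np.ndarray = field(default_factory=default_thresholds)
    namespace: str | None = "BP"
    include_roots: bool = False

    def __post_init__(self) -> None:
        t = np.asarray(self.thresholds, dtype=float)
        if t.size == 0 or (np.diff(t) < 0).any() or t.min() < 0 or t.max() > 1:
            raise ValueError("thresholds must be a sorted grid within [0, 1]")
        self.thresholds = t


@dataclass
class EvalResult:
    """Per-threshold sweep plus the headline numbers.

    ``coverage`` is m(t*): entities with at least one prediction at the Fmax
    threshold.  ``pre_at_max``/``rec_at_max`` are the averaged precision and
    recall at that threshold.
    """

    table: pd.DataFrame  # columns: t, pre, rec, f, m
    fmax: float
    t_max: float
    pre_at_max: float
    rec_at_max: float
    n_entities: int
    coverage: int

    def summary(self) -> dict:
        return {
            "Fmax": round(self.fmax, 6),
            "t_max": round(self.t_max, 6),
            "avg_precision": round(self.pre_at_max, 6),
            "avg_recall": round(self.rec_at_max, 6),
            "N": self.n_entities,
            "coverage": self.coverage,
        }

    def write(self, tsv_path: str | Path, json_path: str | Path | None = None) -> None:
        self.table.to_csv(tsv_path, sep="\t", index=False, float_format="%.6g")
        if json_path is not None:
            Path(json_path).write_text(json.dumps(self.summary(), indent=2) + "\n")


def _eval_terms(term_ids: list[str], dag: GODag, cfg: EvalConfig) -> list[str]:
    keep = []
    roots = set(dag.roots.values())
    for t in term_ids:
        if cfg.namespace is not None and dag.namespace.get(t) != cfg.namespace:
            continue
        if not cfg.include_roots and t in roots:
            continue
        keep.append(t)
    return keep


def per_entity_pr(
    scores: dict[str, float], truth: set[str], t: float
) -> tuple[float | None, float]:
    """Precision (None when no term reaches t) and recall for one entity."""
    if not truth:
        raise ValueError("recall is undefined for an empty truth set")
    predicted = {g for g, s in scores.items() if s >= t}
    tp = len(predicted & truth)
    precision = tp / len(predicted) if predicted else None
    recall = tp / len(truth)
    return precision, recall


def evaluate(
    pred: PredictionMatrix, truth: AnnotationSet, dag: GODag, cfg: EvalConfig | None = None
) -> EvalResult:
    """Threshold sweep of averaged precision/recall and the resulting Fmax.

    Entities must appear in both the prediction matrix and the truth set and
    carry at least one truth term in the evaluated namespace; others are
    excluded (with a log message), and fully disjoint entity sets are an
    error.  Thresholds where no entity predicts anything, or where
    Pre + Rec = 0, are skipped in the Fmax scan.
    """
    cfg = cfg or EvalConfig()
    if not pred.merged:
        raise ValueError("predictions must be max-merged before evaluation")
    if not truth.propagated:
        raise ValueError("truth annotations must be propagated before evaluation")

    terms = _eval_terms(pred.term_ids, dag, cfg)
    col = [pred.term_ids.index(t) for t in terms]
    roots = set(dag.roots.values())

    entities = []
    truth_sets = []
    for i, e in enumerate(pred.entity_ids):
        if e not in truth.annotations:
            continue
        r = {
            t
            for t in truth.annotations[e]
            if (cfg.namespace is None or dag.namespace.get(t) == cfg.namespace)
            and (cfg.include_roots or t not in roots)
        }
        if r:
            entities.append(i)
            truth_sets.append(r)
    if not entities:
        raise ValueError("prediction and truth share no evaluable entities")
    skipped = len(pred.entity_ids) - len(entities)
    if skipped:
        logger.info("evaluate: %d entities without usable truth excluded", skipped)

    S = pred.scores[np.ix_(entities, col)]
    T = np.asarray([[t in r for t in terms] for r in truth_sets], dtype=bool)
    N = len(entities)
    # |R_i| counts every truth term, including those the predictor never
    # scores; unpredictable terms cap attainable recall rather than vanish.
    n_true = np.asarray([len(r) for r in truth_sets])

    rows = []
    for t in cfg.thresholds:
        P = S >= t
        tp = (P & T).sum(axis=1)
        n_pred = P.sum(axis=1)
        has_pred = n_pred > 0
        m = int(has_pred.sum())
        pre = float((tp[has_pred] / n_pred[has_pred]).mean()) if m else np.nan
        rec = float((tp / n_true).mean())
        if m and pre + rec > 0:
            f = 2 * pre * rec / (pre + rec)
        else:
            f = np.nan
        rows.append((float(t), pre, rec, f, m))
    table = pd.DataFrame(rows, columns=["t", "pre", "rec", "f", "m"])

    valid = table["f"].notna()
    if not valid.any():
        raise ValueError("F-measure undefined at every threshold")
    best = table.loc[valid, "f"].idxmax()
    return EvalResult(
        table=table,
        fmax=float(table.loc[best, "f"]),
        t_max=float(table.loc[best, "t"]),
        pre_at_max=float(table.loc[best, "pre"]),
        rec_at_max=float(table.loc[best, "rec"]),
        n_entities=N,
        coverage=int(table.loc[best, "m"]),
    )


def coverage(
    pred: PredictionMatrix, t: float, namespace: str, dag: GODag,
    include_roots: bool = False,
) -> int:
    """Number of entities with >= 1 term of the namespace scoring >= t."""
    if not pred.merged:
        raise ValueError("coverage expects merged predictions")
    cfg = EvalConfig(namespace=namespace, include_roots=include_roots)
    terms = _eval_terms(pred.term_ids, dag, cfg)
    if not terms:
        return 0
    col = [pred.term_ids.index(x) for x in terms]
    return int((pred.scores[:, col] >= t).any(axis=1).sum())


def pr_curve(
    result: EvalResult, csv_path: str | Path | None = None,
    plot_path: str | Path | None = None,
) -> pd.DataFrame:
    """(recall, precision) pairs in threshold order; optional CSV/plot export."""
    curve = result.table[["t", "rec", "pre"]].copy()
    if csv_path is not None:
        curve.to_csv(csv_path, index=False, float_format="%.6g")
    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        ok = curve.dropna()
        fig, ax = plt.subplots(figsize=(4.5, 4))
        ax.plot(ok["rec"], ok["pre"], marker=".", lw=1)
        ax.set_xlabel("average recall")
        ax.set_ylabel("average precision")
        ax.set_xlim(0, 1.02)
        ax.set_ylim(0, 1.02)
        fig.tight_layout()
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
    return curve
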