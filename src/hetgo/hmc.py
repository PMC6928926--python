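"""Hierarchical multi-label classifier over the GO DAG.

Architecture: one fully connected hidden layer shared by all terms, a
dropout layer, and one sigmoid output unit per selected term.  A maximum-
merge step then replaces each non-leaf term's score by the maximum of its own
score and its children's merged scores, so predictions are consistent with
the ontology (a parent always scores at least its children).  Training uses
multi-output binary cross-entropy on the merged outputs, an RMSprop
optimizer, and an internal random hold-out split whose lowest-validation-loss
epoch checkpoint is the returned model.

Trained on protein annotations, applied to miRNAs: the model sees only
feature vectors and is agnostic to entity type.  Entities missing from the
embedding are featurized as zero vectors.
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np

from .embedding import EmbeddingMatrix
from .ontology import GODag, LabelMatrix

logger = logging.getLogger("hetgo")

RMSPROP_DECAY = 0.9
RMSPROP_EPS = 1e-8


@dataclass
class ModelConfig:
    hidden_units: int = 1024
    minibatch: int = 64
    learning_rate: float = 0.01
    dropout_rate: float = 0.2
    max_epochs: int = 100
    patience: int = 10
    holdout_fraction: float = 0.2
    seed: int = 0
    #: >0 adds a small per-term dense layer of this width between the shared
    #: hidden layer and each sigmoid unit.
    head_hidden: int = 0
    #: if False, the cross-entropy is computed on the raw head outputs
    #: instead of the merged outputs.
    loss_on_merged: bool = True

    def __post_init__(self) -> None:
        if self.hidden_units < 1 or self.minibatch < 1:
            raise ValueError("hidden_units and minibatch must be positive")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if not 0 < self.holdout_fraction < 1:
            raise ValueError("holdout_fraction must be in (0, 1)")
        if self.max_epochs < 0 or self.patience < 1:
            raise ValueError("max_epochs must be >= 0 and patience >= 1")


@dataclass
class PredictionMatrix:
    """Entity-by-term scores in [0, 1]; ``merged`` marks DAG consistency."""

    entity_ids: list[str]
    term_ids: list[str]
    scores: np.ndarray
    merged: bool = False

    def __post_init__(self) -> None:
        if self.scores.shape != (len(self.entity_ids), len(self.term_ids)):
            raise ValueError("prediction matrix shape mismatch")
        if self.scores.size and (self.scores.min() < 0 or self.scores.max() > 1):
            raise ValueError("scores must lie in [0, 1]")

    def row(self, entity: str) -> dict[str, float]:
        i = self.entity_ids.index(entity)
        return dict(zip(self.term_ids, self.scores[i]))

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("entity\tterm\tscore\n")
            for i, entity in enumerate(self.entity_ids):
                for j, term in enumerate(self.term_ids):
                    fh.write(f"{entity}\t{term}\t{self.scores[i, j]:.6g}\n")

    @classmethod
    def read_tsv(cls, path: str | Path, merged: bool = True) -> "PredictionMatrix":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        wide = df.pivot(index="entity", columns="term", values="score").fillna(0.0)
        return cls(list(wide.index), list(wide.columns), wide.to_numpy(float), merged=merged)


def featurize(entity_ids: list[str], emb: EmbeddingMatrix) -> np.ndarray:
    """Look up embedding rows; entities absent from the graph get zero vectors."""
    out = np.zeros((len(entity_ids), emb.dim))
    n_missing = 0
    for i, entity in enumerate(entity_ids):
        if entity in emb:
            out[i] = emb.vector(entity)
        else:
            n_missing += 1
    if n_missing:
        logger.info("featurize: %d/%d entities missing from embedding, zero-filled",
                    n_missing, len(entity_ids))
    return out


def _descendant_lists(dag: GODag, term_ids: list[str]) -> list[np.ndarray]:
    """For each selected term, indices of its selected strict descendants.

    Max-merging over all selected descendants equals the bottom-up merge over
    immediate children (max is associative), and needs no transitive
    reduction of the selected sub-DAG.
    """
    col = {t: j for j, t in enumerate(term_ids)}
    desc: list[list[int]] = [[] for _ in term_ids]
    for t in term_ids:
        for anc in dag.ancestors(t):
            j = col.get(anc)
            if j is not None:
                desc[j].append(col[t])
    return [np.asarray(sorted(d), dtype=np.int64) for d in desc]


def merge_scores(raw: np.ndarray, desc: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Max-merge raw scores; also return the source term index of each maximum."""
    n, t = raw.shape
    merged = raw.copy()
    source = np.tile(np.arange(t, dtype=np.int64), (n, 1))
    for j, d in enumerate(desc):
        if d.size == 0:
            continue
        idx = np.concatenate([d, [j]])
        sub = raw[:, idx]
        am = sub.argmax(axis=1)
        merged[:, j] = sub[np.arange(n), am]
        source[:, j] = idx[am]
    return merged, source


@dataclass
class HierarchicalModel:
    term_ids: list[str]
    feature_dim: int
    config: ModelConfig
    weights: dict[str, np.ndarray]
    desc: list[np.ndarray] = field(repr=False, default_factory=list)

    # -- forward ----------------------------------------------------------
    def _hidden(self, X: np.ndarray) -> np.ndarray:
        return np.maximum(X @ self.weights["W1"] + self.weights["b1"], 0.0)

    def _logits(self, H: np.ndarray) -> np.ndarray:
        w = self.weights
        if self.config.head_hidden > 0:
            k = self.config.head_hidden
            T = len(self.term_ids)
            A = np.maximum(H @ w["W2"] + w["b2"], 0.0).reshape(H.shape[0], T, k)
            return np.einsum("btk,tk->bt", A, w["W3"]) + w["b3"]
        return H @ w["W2"] + w["b2"]

    def forward_raw(
        self, X: np.ndarray, dropout_rng: np.random.Generator | None = None
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (hidden activations, dropout mask, raw sigmoid scores)."""
        if X.shape[1] != self.feature_dim:
            raise ValueError(f"feature dim {X.shape[1]} != model dim {self.feature_dim}")
        H = self._hidden(X)
        if dropout_rng is not None and self.config.dropout_rate > 0:
            keep = 1.0 - self.config.dropout_rate
            mask = (dropout_rng.random(H.shape) < keep) / keep
        else:
            mask = np.ones_like(H)
        z = self._logits(H * mask)
        return H, mask, _sigmoid(z)

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        """Merged scores in inference mode (dropout off)."""
        _, _, raw = self.forward_raw(X)
        merged, _ = merge_scores(raw, self.desc)
        return merged

    # -- persistence ------------------------------------------------------
    def save(self, path: str | Path) -> None:
        meta = {"term_ids": self.term_ids, "feature_dim": self.feature_dim,
                "config": asdict(self.config)}
        arrays = {k: v for k, v in self.weights.items()}
        arrays["_meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path, dag: GODag) -> "HierarchicalModel":
        data = np.load(path)
        meta = json.loads(bytes(data["_meta"]).decode())
        weights = {k: data[k] for k in data.files if k != "_meta"}
        cfg = ModelConfig(**meta["config"])
        model = cls(meta["term_ids"], meta["feature_dim"], cfg, weights)
        model.desc = _descendant_lists(dag, model.term_ids)
        return model


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -30, 30)))


def _bce(p: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())


def _init_model(
    term_ids: list[str], feature_dim: int, cfg: ModelConfig, dag: GODag,
    rng: np.random.Generator,
) -> HierarchicalModel:
    """Uniform (Glorot-range) weight initialization."""
    h, T = cfg.hidden_units, len(term_ids)

    def uni(fan_in: int, fan_out: int, shape: tuple[int, ...]) -> np.ndarray:
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, size=shape)

    weights = {"W1": uni(feature_dim, h, (feature_dim, h)), "b1": np.zeros(h)}
    if cfg.head_hidden > 0:
        k = cfg.head_hidden
        weights["W2"] = uni(h, k, (h, T * k))
        weights["b2"] = np.zeros(T * k)
        weights["W3"] = uni(k, 1, (T, k))
        weights["b3"] = np.zeros(T)
    else:
        weights["W2"] = uni(h, 1, (h, T))
        weights["b2"] = np.zeros(T)
    model = HierarchicalModel(list(term_ids), feature_dim, cfg, weights)
    model.desc = _descendant_lists(dag, term_ids)
    return model


def train(
    features: np.ndarray, labels: LabelMatrix, dag: GODag, cfg: ModelConfig
) -> HierarchicalModel:
    """Fit the classifier with RMSprop on multi-output binary cross-entropy.

    An internal random 80/20 (``holdout_fraction``) split monitors validation
    loss after every epoch; the best-epoch weights are returned, with early
    stopping after ``patience`` epochs without improvement.
    """
    X = np.asarray(features, dtype=float)
    Y = labels.values.astype(float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("features and labels disagree on entity count")
    if X.shape[0] < 2:
        raise ValueError("need at least two training entities")
    if Y.sum() == 0:
        raise ValueError("no positive labels")
    rng = np.random.default_rng(cfg.seed)
    model = _init_model(labels.term_ids, X.shape[1], cfg, dag, rng)
    if cfg.max_epochs == 0:
        return model

    n = X.shape[0]
    perm = rng.permutation(n)
    n_val = max(1, int(round(cfg.holdout_fraction * n)))
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    if tr_idx.size == 0:
        raise ValueError("holdout_fraction leaves no training entities")
    cache = {k: np.zeros_like(v) for k, v in model.weights.items()}
    best_loss = np.inf
    best_weights = {k: v.copy() for k, v in model.weights.items()}
    stale = 0

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(tr_idx.size)
        for start in range(0, tr_idx.size, cfg.minibatch):
            batch = tr_idx[order[start : start + cfg.minibatch]]
            _sgd_step(model, X[batch], Y[batch], cache, rng)
        val_pred = model.predict_scores(X[val_idx])
        val_loss = _bce(val_pred, Y[val_idx])
        if val_loss < best_loss - 1e-9:
            best_loss = val_loss
            best_weights = {k: v.copy() for k, v in model.weights.items()}
            stale = 0
        else:
            stale += 1
            if stale >= cfg.patience:
                logger.info("early stop at epoch %d (best val loss %.4f)", epoch, best_loss)
                break
    model.weights = best_weights
    return model


def _sgd_step(
    model: HierarchicalModel, Xb: np.ndarray, Yb: np.ndarray,
    cache: dict[str, np.ndarray], rng: np.random.Generator,
) -> None:
    cfg = model.config
    w = model.weights
    B, T = Xb.shape[0], len(model.term_ids)
    H, mask, raw = model.forward_raw(Xb, dropout_rng=rng)
    Hd = H * mask
    if cfg.loss_on_merged:
        merged, source = merge_scores(raw, model.desc)
        D = (merged - Yb) / B  # dL/dz at each merge source (sigmoid+BCE)
        Gz = np.zeros_like(raw)
        flat = np.arange(B)[:, None] * T + source
        np.add.at(Gz.reshape(-1), flat.ravel(), D.ravel())
    else:
        Gz = (raw - Yb) / B

    grads: dict[str, np.ndarray] = {}
    if cfg.head_hidden > 0:
        k = cfg.head_hidden
        A_pre = Hd @ w["W2"] + w["b2"]
        A = np.maximum(A_pre, 0.0).reshape(B, T, k)
        grads["W3"] = np.einsum("bt,btk->tk", Gz, A)
        grads["b3"] = Gz.sum(axis=0)
        GA = (Gz[:, :, None] * w["W3"][None]) * (A > 0)
        GA_flat = GA.reshape(B, T * k)
        grads["W2"] = Hd.T @ GA_flat
        grads["b2"] = GA_flat.sum(axis=0)
        GH = (GA_flat @ w["W2"].T) * mask * (H > 0)
    else:
        grads["W2"] = Hd.T @ Gz
        grads["b2"] = Gz.sum(axis=0)
        GH = (Gz @ w["W2"].T) * mask * (H > 0)
    grads["W1"] = Xb.T @ GH
    grads["b1"] = GH.sum(axis=0)

    for key, g in grads.items():
        c = cache[key]
        c *= RMSPROP_DECAY
        c += (1 - RMSPROP_DECAY) * g * g
        w[key] -= cfg.learning_rate * g / (np.sqrt(c) + RMSPROP_EPS)


def forward(
    model: HierarchicalModel, features: np.ndarray, entity_ids: list[str]
) -> PredictionMatrix:
    """Merged predictions for a feature matrix (inference mode)."""
    scores = model.predict_scores(np.asarray(features, dtype=float))
    return PredictionMatrix(list(entity_ids), list(model.term_ids), scores, merged=True)


def predict(
    model: HierarchicalModel, entity_ids: list[str], emb: EmbeddingMatrix
) -> PredictionMatrix:
    """Featurize entities (zero-vector fallback) and run merged inference."""
    return forward(model, featurize(entity_ids, emb), entity_ids)
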