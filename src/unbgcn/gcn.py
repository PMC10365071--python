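"""Attention-augmented graph convolutional network for transductive diagnosis.

The classifier is a whole-graph (transductive) GCN over the phenotype
population graph: node features are the per-ROI biomarker scores, layers
follow the first-order spectral propagation rule

    H^(k+1) = relu(P H^(k) Theta^(k)),

with a softmax output layer, trained by masked cross-entropy on the labeled
nodes only.  The propagation operator P is the symmetric normalized
Laplacian L = I - D^{-1/2} W D^{-1/2} by default.  On phenotype-similarity
graphs — which are dense, with integer edge weights counting matched
phenotypes — the low-pass averaging operator Dt^{-1/2}(W+I)Dt^{-1/2}
collapses every node toward the global mean within a few hops and erases
the between-subject signal; L instead acts as a (high-pass) difference
filter that preserves it.  The averaging operator remains available via
``ModelConfig.propagation = "renormalized"``.

The attention module refines the input features before the first layer:
pairwise node dot products Y = X X^T are row-standardized, passed through a
linear map and a per-row softmax over the feature axis, giving a
nonnegative weight map A whose rows sum to 1 and refined features
Z = X (Hadamard) A.  The network consumes M*Z so that a uniform attention
map (the zero-parameter initial state) is exactly the identity, making the
module a no-op until the loss gradient moves it.  Attention parameters are
updated by plain gradient descent (step ``attention_lr``) rather than Adam:
the adaptive rescaling would amplify per-coordinate gradient noise and
drown the systematic feature-relevance signal the map is meant to
accumulate.  The column means of A rank ROIs by their contribution to the
discrimination.

Everything is plain numpy with hand-derived gradients; models are small
(a few hundred nodes, width 16) and runs are exactly reproducible from the
seed.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, replace, asdict

import numpy as np
import pandas as pd

from .popgraph import (
    EdgeSpec,
    PopulationGraph,
    build_adjacency,
    normalized_laplacian,
    renormalized_propagation,
)
from .stats import classification_report, mann_whitney_auc

ATTENTION_DISPLAY_THRESHOLD = 0.05


@dataclass
class ModelConfig:
    hidden_layers: int = 3
    hidden_width: int = 16
    dropout: float = 0.3
    learning_rate: float = 0.01
    epochs: int = 200
    weight_decay: float = 5e-4
    seed: int = 0
    attention_enabled: bool = True
    attention_lr: float = 0.05
    propagation: str = "laplacian"  # or "renormalized"

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.hidden_layers < 1:
            raise ValueError("need at least one hidden layer")
        if self.propagation not in ("laplacian", "renormalized"):
            raise ValueError(f"unknown propagation {self.propagation!r}")


@dataclass
class TrainedModel:
    thetas: list[np.ndarray]
    attn_w: np.ndarray | None
    attn_b: np.ndarray | None
    history: list[float]
    config: ModelConfig
    classes: np.ndarray  # original label codes, position = output column

    @property
    def n_parameters(self) -> int:
        n = sum(t.size for t in self.thetas)
        if self.attn_w is not None:
            n += self.attn_w.size + self.attn_b.size
        return n


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------


def _softmax_rows(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _standardize_rows(Y: np.ndarray) -> np.ndarray:
    return (Y - Y.mean(axis=1, keepdims=True)) / (Y.std(axis=1, keepdims=True) + 1e-12)


def propagation_operator(W: np.ndarray, kind: str = "laplacian") -> np.ndarray:
    if kind == "laplacian":
        return normalized_laplacian(W)
    if kind == "renormalized":
        return renormalized_propagation(W)
    raise ValueError(f"unknown propagation {kind!r}")


def attention_forward(
    X: np.ndarray, attn_w: np.ndarray, attn_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Refined features and attention map: A = softmax(Linear(std(X X^T))).

    The pairwise dot-product map is row-standardized before the linear layer
    (the raw inner products scale with the feature dimension and would
    saturate the softmax); the softmax runs over the feature axis, so each
    subject's ROI weights form a distribution (rows of A sum to 1).
    Returns ``(Z, A)`` with ``Z = X * A`` elementwise.
    """
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("node features must be finite")
    Yn = _standardize_rows(X @ X.T)
    A = _softmax_rows(Yn @ attn_w + attn_b)
    return X * A, A


def gcn_layer(
    S: np.ndarray, H: np.ndarray, theta: np.ndarray, activation: str = "relu"
) -> np.ndarray:
    """One propagation step H' = activation(S H Theta)."""
    if S.shape[1] != H.shape[0] or H.shape[1] != theta.shape[0]:
        raise ValueError(
            f"shape mismatch: S {S.shape}, H {H.shape}, theta {theta.shape}"
        )
    pre = S @ H @ theta
    if activation == "relu":
        return np.maximum(pre, 0.0)
    if activation == "none":
        return pre
    raise ValueError(f"unknown activation {activation!r}")


def masked_cross_entropy(
    probs: np.ndarray, labels: np.ndarray, mask: np.ndarray
) -> float:
    """Mean negative log-probability of the true class over masked nodes."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask selects no nodes")
    p = probs[mask, np.asarray(labels)[mask]]
    return float(-np.log(np.clip(p, 1e-300, None)).mean())


# ---------------------------------------------------------------------------
# forward / training
# ---------------------------------------------------------------------------


def _input_features(X: np.ndarray, model: TrainedModel) -> np.ndarray:
    if model.attn_w is None:
        return X
    Z, _ = attention_forward(X, model.attn_w, model.attn_b)
    # rows of A sum to 1, so scaling by M makes uniform attention the identity
    return X.shape[1] * Z


def forward(graph: PopulationGraph, model: TrainedModel) -> np.ndarray:
    """Class probabilities per node; rows sum to 1."""
    S = propagation_operator(graph.W, model.config.propagation)
    H = _input_features(graph.X, model)
    for theta in model.thetas[:-1]:
        H = gcn_layer(S, H, theta, "relu")
    return _softmax_rows(S @ H @ model.thetas[-1])


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def train(graph: PopulationGraph, config: ModelConfig) -> TrainedModel:
    """Fit by Adam on the masked cross-entropy; reproducible from the seed.

    The graph is transductive: all nodes (labeled and unlabeled) participate
    in propagation, but only ``train_mask`` nodes enter the loss, so test
    labels cannot influence the gradients.  Dropout masks the input of every
    hidden layer during training only.  GCN weights follow Adam with L2
    weight decay; attention parameters follow plain gradient descent with
    step ``attention_lr`` from a zero (uniform-map) initialization.
    """
    mask = graph.train_mask
    if not mask.any():
        raise ValueError("empty training mask")
    classes = np.unique(graph.labels[mask])
    if classes.size < 2:
        raise ValueError("training mask must contain at least 2 classes")

    X = graph.X
    N, M = X.shape
    C = classes.size
    code = {c: i for i, c in enumerate(classes)}
    y = np.array([code.get(l, -1) for l in graph.labels])
    onehot = np.zeros((N, C))
    onehot[mask, y[mask]] = 1.0

    S = propagation_operator(graph.W, config.propagation)
    rng = np.random.default_rng(config.seed)

    if config.attention_enabled:
        attn_w = np.zeros((N, M))
        attn_b = np.zeros(M)
        Yn = _standardize_rows(X @ X.T)
    else:
        attn_w = attn_b = None
    widths = [M] + [config.hidden_width] * config.hidden_layers + [C]
    thetas = [_glorot(rng, a, b) for a, b in zip(widths[:-1], widths[1:])]

    m_adam = [np.zeros_like(t) for t in thetas]
    v_adam = [np.zeros_like(t) for t in thetas]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    p_drop = config.dropout
    n_lab = int(mask.sum())
    history: list[float] = []

    for epoch in range(config.epochs):
        # ---- forward (training mode) ----
        if attn_w is not None:
            A = _softmax_rows(Yn @ attn_w + attn_b)
            H = M * X * A
        else:
            H = X
        caches = []
        for theta in thetas[:-1]:
            if p_drop > 0:
                D = (rng.random(H.shape) >= p_drop) / (1.0 - p_drop)
            else:
                D = np.ones_like(H)
            Hd = H * D
            SHd = S @ Hd
            pre = SHd @ theta
            caches.append((D, SHd, pre))
            H = np.maximum(pre, 0.0)
        SH_last = S @ H
        P = _softmax_rows(SH_last @ thetas[-1])
        history.append(masked_cross_entropy(P, y, mask))

        # ---- backward ----
        G = (P - onehot) * mask[:, None] / n_lab
        grads = [np.zeros_like(t) for t in thetas]
        grads[-1] = SH_last.T @ G
        dH = S.T @ G @ thetas[-1].T
        for k in range(len(thetas) - 2, -1, -1):
            D, SHd, pre = caches[k]
            dpre = dH * (pre > 0)
            grads[k] = SHd.T @ dpre
            dH = (S.T @ dpre @ thetas[k].T) * D
        if attn_w is not None:
            dA = dH * X * M
            dlogit = A * (dA - (dA * A).sum(axis=1, keepdims=True))
            attn_w -= config.attention_lr * (
                Yn.T @ dlogit + config.weight_decay * attn_w
            )
            attn_b -= config.attention_lr * dlogit.sum(axis=0)

        # ---- Adam with L2 weight decay on the GCN weights ----
        t = epoch + 1
        for i, (p, g) in enumerate(zip(thetas, grads)):
            g = g + config.weight_decay * p
            m_adam[i] = beta1 * m_adam[i] + (1 - beta1) * g
            v_adam[i] = beta2 * v_adam[i] + (1 - beta2) * g * g
            mhat = m_adam[i] / (1 - beta1**t)
            vhat = v_adam[i] / (1 - beta2**t)
            p -= config.learning_rate * mhat / (np.sqrt(vhat) + eps)

    return TrainedModel(
        thetas=thetas,
        attn_w=attn_w,
        attn_b=attn_b,
        history=history,
        config=replace(config),
        classes=classes,
    )


def predict(
    graph: PopulationGraph, model: TrainedModel, mask: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Argmax labels (ties -> lowest class index) and probabilities.

    Returns ``(labels, probs)`` restricted to ``mask`` when given.
    """
    if not model.thetas:
        raise ValueError("model has no trained weights")
    probs = forward(graph, model)
    labels = model.classes[np.argmax(probs, axis=1)]
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        return labels[mask], probs[mask]
    return labels, probs


# ---------------------------------------------------------------------------
# evaluation protocols
# ---------------------------------------------------------------------------


def _stratified_split(
    labels: np.ndarray, test_fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Boolean test mask with >=1 test and >=1 train node per class."""
    test = np.zeros(labels.size, dtype=bool)
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        n_test = max(1, int(round(test_fraction * idx.size)))
        if idx.size - n_test < 1:
            raise ValueError(f"class {c!r} too small for a {test_fraction:.0%} split")
        test[rng.permutation(idx)[:n_test]] = True
    return test


def cross_validate(
    features: np.ndarray | pd.DataFrame,
    phenotypes: pd.DataFrame,
    labels,
    config: ModelConfig,
    edge_spec: EdgeSpec | None = None,
    n_repeats: int = 10,
    test_fraction: float = 0.1,
    positive_class=None,
) -> dict:
    """Repeated stratified 90/10 splits, trained transductively.

    Each repeat holds out ``test_fraction`` of the labeled subjects per
    class; held-out nodes stay in the graph but are unlabeled during
    training.  Reports ACC/SEN/SPE (and, for two classes, rank AUC from the
    positive-class probability) per split with mean and standard deviation.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if positive_class is None:
        positive_class = "AD" if "AD" in classes else classes[-1]
    W = build_adjacency(phenotypes, edge_spec or EdgeSpec.default())

    master = np.random.default_rng(config.seed)
    seeds = master.integers(0, 2**31 - 1, size=n_repeats)
    rows = []
    for r in range(n_repeats):
        for attempt in range(100):
            try:
                test = _stratified_split(y, test_fraction, master)
                break
            except ValueError:
                warnings.warn(f"resampling split {r}: class missing from a side")
        else:
            raise ValueError("could not build a valid stratified split in 100 tries")
        # integer-encode labels; -1 marks test nodes as unlabeled
        code = {c: i for i, c in enumerate(classes)}
        enc = np.array([code[v] for v in y])
        graph = PopulationGraph(
            X=X,
            W=W,
            labels=np.where(test, -1, enc),
            train_mask=~test,
            test_mask=test,
            phenotypes=phenotypes,
        )
        model = train(graph, replace(config, seed=int(seeds[r])))
        pred_codes, probs = predict(graph, model, mask=test)
        pred = classes[pred_codes]
        rep = classification_report(pred, y[test], positive_class)
        row = {
            "split": r,
            "acc": rep.acc,
            "sen": rep.sen,
            "spe": rep.spe,
            "auc": np.nan,
        }
        if classes.size == 2:
            pos_col = int(np.flatnonzero(model.classes == code[positive_class])[0])
            row["auc"] = mann_whitney_auc(
                probs[:, pos_col], (y[test] == positive_class).astype(int)
            )
        rows.append(row)
    table = pd.DataFrame(rows).set_index("split")
    return {
        "per_split": table,
        "mean": table.mean(),
        "sd": table.std(ddof=1),
    }


def grid_search(
    features,
    phenotypes: pd.DataFrame,
    labels,
    grid: dict[str, list],
    base_config: ModelConfig | None = None,
    **cv_kwargs,
) -> tuple[ModelConfig, pd.DataFrame]:
    """Exhaustive search over the grid via :func:`cross_validate`.

    Best = highest mean accuracy; ties broken by smaller parameter count,
    then by grid order.  Returns the winning config and the full score table.
    """
    if not grid:
        raise ValueError("empty grid")
    base = base_config or ModelConfig()
    keys = list(grid.keys())
    X = np.asarray(features, dtype=float)
    n_classes = np.unique(np.asarray(labels)).size

    def model_size(cfg: ModelConfig) -> int:
        N, M = X.shape
        widths = [M] + [cfg.hidden_width] * cfg.hidden_layers + [n_classes]
        n = sum(a * b for a, b in zip(widths[:-1], widths[1:]))
        if cfg.attention_enabled:
            n += N * M + M
        return n

    rows = []
    best = None  # ((mean_acc, -size), config)
    for combo in itertools.product(*(grid[k] for k in keys)):
        cfg = replace(base, **dict(zip(keys, combo)))
        res = cross_validate(features, phenotypes, labels, cfg, **cv_kwargs)
        acc = float(res["mean"]["acc"])
        rows.append({**dict(zip(keys, combo)), "mean_acc": acc,
                     "sd_acc": float(res["sd"]["acc"])})
        key = (acc, -model_size(cfg))
        if best is None or key > best[0]:
            best = (key, cfg)
    return best[1], pd.DataFrame(rows)


def rank_roi_attention(
    model: TrainedModel, X: np.ndarray, roi_names: list[str]
) -> pd.DataFrame:
    """Rank ROIs by mean attention weight over subjects.

    Weights are the column means of the attention map A, normalized to sum
    to 1, sorted descending.  Rows below the 0.05 display threshold are
    flagged (``display=False``) rather than removed.
    """
    if model.attn_w is None:
        raise ValueError("model was trained without the attention module")
    _, A = attention_forward(np.asarray(X, dtype=float), model.attn_w, model.attn_b)
    raw = A.mean(axis=0)
    norm = raw / raw.sum()
    table = pd.DataFrame(
        {
            "roi": roi_names,
            "raw_weight": raw,
            "normalized_weight": norm,
            "display": norm >= ATTENTION_DISPLAY_THRESHOLD,
        }
    ).sort_values("normalized_weight", ascending=False, kind="mergesort")
    return table.reset_index(drop=True)


def model_to_dict(model: TrainedModel) -> dict:
    """JSON-serializable checkpoint (weights + config + classes)."""
    return {
        "config": asdict(model.config),
        "classes": model.classes.tolist(),
        "thetas": [t.tolist() for t in model.thetas],
        "attn_w": None if model.attn_w is None else model.attn_w.tolist(),
        "attn_b": None if model.attn_b is None else model.attn_b.tolist(),
        "history": list(map(float, model.history)),
    }


def model_from_dict(d: dict) -> TrainedModel:
    return TrainedModel(
        thetas=[np.asarray(t) for t in d["thetas"]],
        attn_w=None if d["attn_w"] is None else np.asarray(d["attn_w"]),
        attn_b=None if d["attn_b"] is None else np.asarray(d["attn_b"]),
        history=list(d["history"]),
        config=ModelConfig(**d["config"]),
        classes=np.asarray(d["classes"]),
    )
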