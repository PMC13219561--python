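"""Fisher-information-driven scoring and selection of backbone layers.

Per-dimension Fisher scores are unreliable when each class has only a few
samples, so layer discriminativeness is measured instead by a gradient-based
proxy: attach one fixed, randomly initialized linear head to a layer's pooled
features, and average the squared L2 norm of the gradient of the
cross-entropy loss with respect to the feature vector within each class,

    F_c(layer) = mean over class-c support of || d L_CE / d f ||^2 ,

the diagonal empirical Fisher information of the representation. A layer's
raw score is the maximum class-wise proxy (so a layer is kept if it is
informative for at least one class), and raw scores are z-normalized across
layers before the top-K_s are selected. The same head (same weights) is
shared across classes and layers so proxies are directly comparable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import softmax as _softmax
from sklearn.linear_model import LogisticRegression

from . import autodiff as ad
from .backbone import Backbone
from .episodes import Episode
from .metrics import accuracy, multiclass_auroc

#: sentinel returned by the classical score when within-class variance vanishes
ZERO_VARIANCE_SENTINEL = 1e12

#: numerical-stability constant added to the across-layer score std
DEFAULT_EPSILON = 1e-8


def classical_fisher_score(features, labels) -> np.ndarray:
    """Per-dimension Fisher score: between-class over within-class variance.

    S_j = sum_c n_c (mu_cj - mu_j)^2 / sum_c n_c sigma_cj^2 with population
    (biased) class variances. Dimensions whose denominator is zero return a
    large sentinel with a warning, since a zero-variance dimension that moves
    between classes is (degenerately) perfectly discriminative.
    """
    features = np.asarray(features, dtype=np.float64)
    if features.ndim == 1:
        features = features[:, None]
    labels = np.ravel(labels)
    if features.shape[0] != len(labels):
        raise ValueError("features and labels disagree in length")
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("Fisher score requires at least two classes")
    mu = features.mean(axis=0)
    num = np.zeros(features.shape[1])
    den = np.zeros(features.shape[1])
    for c in classes:
        fc = features[labels == c]
        nc = len(fc)
        num += nc * (fc.mean(axis=0) - mu) ** 2
        den += nc * fc.var(axis=0)  # population variance
    scores = np.empty_like(num)
    zero = den == 0.0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} dimension(s) have zero within-class variance; "
            "returning sentinel score", stacklevel=2,
        )
    scores[zero] = ZERO_VARIANCE_SENTINEL
    scores[~zero] = num[~zero] / den[~zero]
    return scores


@dataclass(frozen=True)
class ProbeHead:
    """A fixed (never trained) linear map d -> C used only for probing."""

    weight: np.ndarray  # [C, d]
    bias: np.ndarray    # [C]

    @classmethod
    def create(cls, feature_dim: int, n_classes: int, seed: int) -> "ProbeHead":
        rng = np.random.default_rng(seed)
        scale = feature_dim**-0.5
        return cls(
            weight=rng.normal(0.0, scale, size=(n_classes, feature_dim)),
            bias=np.zeros(n_classes),
        )

    @property
    def n_classes(self) -> int:
        return self.weight.shape[0]


def fisher_proxy(pooled_features, labels, head: ProbeHead) -> np.ndarray:
    """Class-wise gradient proxies F_c of one layer's pooled features.

    The gradient of the cross-entropy loss with respect to a feature vector f
    at the fixed head is W^T (softmax(W f + b) - onehot(y)); the head's bias
    shifts the logits but contributes no extra term. Classes absent from
    `labels` get NaN (proxy undefined).
    """
    feats = np.asarray(pooled_features, dtype=np.float64)
    labels = np.ravel(labels)
    logits = feats @ head.weight.T + head.bias
    probs = _softmax(logits, axis=1)
    resid = probs.copy()
    resid[np.arange(len(labels)), labels] -= 1.0
    grads = resid @ head.weight          # [n, d]
    sqnorm = (grads**2).sum(axis=1)
    proxies = np.full(head.n_classes, np.nan)
    for c in range(head.n_classes):
        mask = labels == c
        if mask.any():
            proxies[c] = sqnorm[mask].mean()
    if np.isnan(proxies).any():
        missing = np.flatnonzero(np.isnan(proxies)).tolist()
        warnings.warn(
            f"classes {missing} absent from labels; proxies undefined",
            stacklevel=2,
        )
    return proxies


@dataclass
class LayerScoreTable:
    """Per-layer, per-class proxies and their normalized layer scores."""

    per_class: np.ndarray    # [L, C], NaN where undefined
    raw_scores: np.ndarray   # [L], max over classes
    normalized: np.ndarray   # [L], z-scored across layers
    mean: float
    std: float               # population std across layers
    epsilon: float

    @property
    def n_layers(self) -> int:
        return len(self.raw_scores)

    def to_json(self) -> str:
        return json.dumps({
            "per_class": self.per_class.tolist(),
            "raw_scores": self.raw_scores.tolist(),
            "normalized": self.normalized.tolist(),
            "mean": self.mean,
            "std": self.std,
            "epsilon": self.epsilon,
        })


def layer_scores(per_layer_proxies, epsilon: float = DEFAULT_EPSILON) -> LayerScoreTable:
    """Aggregate class proxies to layer scores and z-normalize across layers.

    `per_layer_proxies` maps 1-based layer index -> per-class proxy vector.
    score_l = max_c F_c(l); zhat_l = (score_l - mean) / (std + epsilon).
    """
    if not per_layer_proxies:
        raise ValueError("no layer proxies supplied")
    layers = sorted(per_layer_proxies)
    if layers != list(range(1, len(layers) + 1)):
        raise ValueError("layer indices must be contiguous and 1-based")
    per_class = np.vstack([np.ravel(per_layer_proxies[l]) for l in layers])
    raw = np.nanmax(per_class, axis=1)
    mean = float(raw.mean())
    std = float(raw.std())  # population
    normalized = (raw - mean) / (std + epsilon)
    return LayerScoreTable(per_class=per_class, raw_scores=raw,
                           normalized=normalized, mean=mean, std=std,
                           epsilon=epsilon)


@dataclass
class SelectionResult:
    """The ordered top-K_s layer set together with its score table."""

    selected: list[int]      # 1-based, descending normalized score
    table: LayerScoreTable
    seed: int

    @property
    def n_selected(self) -> int:
        return len(self.selected)

    def to_json(self) -> str:
        return json.dumps({
            "selected": self.selected,
            "seed": self.seed,
            "scores": json.loads(self.table.to_json()),
        })


def select_layers(table: LayerScoreTable, n_selected: int,
                  seed: int = 0) -> SelectionResult:
    """Pick the K_s layers of highest normalized score.

    Ordered by descending score; ties break toward the lower layer index.
    """
    L = table.n_layers
    if not 1 <= n_selected <= L:
        raise ValueError(f"n_selected={n_selected} outside 1..{L}")
    idx = np.lexsort((np.arange(L), -table.normalized))
    selected = [int(i) + 1 for i in idx[:n_selected]]
    return SelectionResult(selected=selected, table=table, seed=seed)


def probe_backbone(backbone: Backbone, support, n_selected: int,
                   seed: int = 0,
                   epsilon: float = DEFAULT_EPSILON) -> SelectionResult:
    """Score all layers on the support set and select the top K_s.

    One forward pass through the frozen backbone caches every layer's pooled
    features; a single fixed seeded head (shared across layers and classes)
    provides the loss gradients. No weight of the backbone is touched.
    `support` is an Episode (its support split is used) or an
    (images, labels) pair.
    """
    if isinstance(support, Episode):
        images, labels = support.support
    else:
        images, labels = support
    labels = np.ravel(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("probing requires a support set with >= 2 classes")
    with ad.no_grad():
        feats = backbone.forward_features(images)
    head = ProbeHead.create(backbone.config.hidden_dim, len(classes), seed)
    proxies = {
        l + 1: fisher_proxy(feats.pooled[l].numpy(), labels, head)
        for l in range(len(feats))
    }
    table = layer_scores(proxies, epsilon=epsilon)
    return select_layers(table, n_selected, seed=seed)


def linear_probe_eval(backbone: Backbone, episode: Episode, layer: int,
                      C: float = 1.0, max_iter: int = 1000) -> dict:
    """Fit a linear classifier on one layer's support features; score queries.

    Returns a record with the layer index, query AUROC (macro one-vs-rest)
    and accuracy. A query whose labels are all one class has no defined
    AUROC; the record flags it with auroc=None.
    """
    L = backbone.config.n_layers
    if not 1 <= layer <= L:
        raise ValueError(f"layer {layer} outside 1..{L}")
    with ad.no_grad():
        sup = backbone.forward_features(episode.support_images)
        qry = backbone.forward_features(episode.query_images)
    fs = sup.pooled[layer - 1].numpy()
    fq = qry.pooled[layer - 1].numpy()
    clf = LogisticRegression(C=C, max_iter=max_iter)
    clf.fit(fs, episode.support_labels)
    raw = clf.predict_proba(fq)
    # align probability columns to label ids
    scores = np.zeros((len(fq), episode.n_way))
    for j, cls_id in enumerate(clf.classes_):
        scores[:, int(cls_id)] = raw[:, j]
    record = {"layer": layer, "accuracy": accuracy(episode.query_labels, scores)}
    if len(np.unique(episode.query_labels)) < 2:
        warnings.warn("query has a single class; AUROC undefined", stacklevel=2)
        record["auroc"] = None
    else:
        record["auroc"] = multiclass_auroc(episode.query_labels, scores)
    return record


def linear_probe_sweep(backbone: Backbone, episode: Episode, **kw) -> list[dict]:
    """Per-layer linear-probe utilities: exactly L records."""
    return [linear_probe_eval(backbone, episode, l, **kw)
            for l in range(1, backbone.config.n_layers + 1)]


def selection_frequencies(results, n_layers: int) -> np.ndarray:
    """How many times each layer (1..L) appears across SelectionResults."""
    counts = np.zeros(n_layers, dtype=np.intp)
    for res in results:
        sel = res.selected if isinstance(res, SelectionResult) else res
        for layer in sel:
            counts[layer - 1] += 1
    return counts


def frequencies_to_frame(counts: np.ndarray, shot: int | None = None) -> pd.DataFrame:
    """CSV-ready table with columns layer, shot, count."""
    return pd.DataFrame({
        "layer": np.arange(1, len(counts) + 1),
        "shot": shot if shot is not None else -1,
        "count": counts,
    })
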