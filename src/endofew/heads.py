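"""Embedding-space classifiers and the class-variance diagnostic.

Three discrimination hypotheses over the learned latent space, in
increasing complexity: nearest neighbour (1-nn), nearest class mean
(centroid), and an RBF-kernel support vector machine fitted on the
training embeddings.  For 1-nn and centroid the training embeddings are
the latent-space population; distances are l2, the metric the encoder
was trained under.

``class_variances`` reports mean squared l2 deviation within each class
and between class means, with the inter-class variance normalised to 1 —
a quick read on whether classes form compact, separated clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.svm import SVC

from .errors import ValidationError

HEAD_KINDS = ("one_nn", "centroid", "svm_rbf")


@dataclass
class ClassifierHead:
    kind: str
    classes: list[str]
    dim: int
    state: dict = field(default_factory=dict)


@dataclass
class VarianceReport:
    """Intra-/inter-class variances, inter normalised to exactly 1."""

    intra: dict[str, float]        # normalised by raw inter
    inter: float                   # always 1.0 when raw_inter > 0
    raw_intra: dict[str, float]
    raw_inter: float


def fit_head(kind: str, embeddings: np.ndarray, labels: Sequence[str],
             params: Optional[dict] = None) -> ClassifierHead:
    """Fit a discriminator on training embeddings.

    ``params`` for ``svm_rbf`` are forwarded to scikit-learn's SVC
    (defaults: C=1, variance-scaled kernel width); for ``centroid``,
    ``rule`` selects ``"class_mean"`` (default) or ``"mean_distance"``
    (smallest average distance to the class members).
    """
    params = dict(params or {})
    X = np.asarray(embeddings, dtype=np.float64)
    y = np.asarray(labels)
    if X.ndim != 2 or len(X) != len(y):
        raise ValidationError("embeddings must be (n, d) with one label per row")
    classes = sorted(set(y.tolist()))
    if len(classes) < 2:
        raise ValidationError("fitting needs >= 2 classes")
    if kind not in HEAD_KINDS:
        raise ValidationError(f"unknown head kind {kind!r}")

    head = ClassifierHead(kind=kind, classes=classes, dim=X.shape[1])
    if kind == "one_nn":
        head.state = {"X": X.copy(), "y": y.copy()}
    elif kind == "centroid":
        rule = params.pop("rule", "class_mean")
        if rule not in ("class_mean", "mean_distance"):
            raise ValidationError(f"unknown centroid rule {rule!r}")
        head.state = {"rule": rule,
                      "means": np.stack([X[y == c].mean(axis=0)
                                         for c in classes])}
        if rule == "mean_distance":
            head.state.update(X=X.copy(), y=y.copy())
    else:
        svm = SVC(kernel="rbf", C=params.pop("C", 1.0),
                  gamma=params.pop("gamma", "scale"), **params)
        svm.fit(X, y)
        head.state = {"svm": svm}
    return head


def predict(head: ClassifierHead, embeddings: np.ndarray) -> list[str]:
    """One label per query row; deterministic (ties break to the lowest
    training-sample index for 1-nn, lowest class index for centroid)."""
    Q = np.asarray(embeddings, dtype=np.float64)
    if Q.ndim != 2 or Q.shape[1] != head.dim:
        raise ValidationError(
            f"query dimensionality {Q.shape} does not match head dim {head.dim}")
    if head.kind == "one_nn":
        d = cdist(Q, head.state["X"])
        return head.state["y"][d.argmin(axis=1)].tolist()
    if head.kind == "centroid":
        if head.state["rule"] == "class_mean":
            d = cdist(Q, head.state["means"])
        else:
            dd = cdist(Q, head.state["X"])
            y = head.state["y"]
            d = np.stack([dd[:, y == c].mean(axis=1)
                          for c in head.classes], axis=1)
        return [head.classes[i] for i in d.argmin(axis=1)]
    return head.state["svm"].predict(Q).tolist()


def save_head(head: ClassifierHead, path) -> None:
    """Serialize a fitted head (kind + state) to a versioned container."""
    import pickle
    from pathlib import Path

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "wb") as fh:
        pickle.dump({"format_version": 1, "kind": head.kind,
                     "classes": head.classes, "dim": head.dim,
                     "state": head.state}, fh)


def load_head(path) -> ClassifierHead:
    import pickle

    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    if payload.get("format_version") != 1:
        raise ValidationError(
            f"unsupported head container version {payload.get('format_version')}")
    return ClassifierHead(kind=payload["kind"], classes=payload["classes"],
                          dim=payload["dim"], state=payload["state"])


def export_predictions(path, sample_ids: Sequence[str],
                       y_true: Sequence[str], y_pred: Sequence[str]) -> None:
    """CSV of (sample id, true label, predicted label)."""
    import pandas as pd

    if not len(sample_ids) == len(y_true) == len(y_pred):
        raise ValidationError("id/true/pred lists differ in length")
    pd.DataFrame({"sample_id": list(sample_ids), "true_label": list(y_true),
                  "predicted_label": list(y_pred)}).to_csv(path, index=False)


def class_variances(embeddings: np.ndarray,
                    labels: Sequence[str]) -> VarianceReport:
    """Intra-/inter-class variance report, inter normalised to 1.

    intra(c) = mean squared l2 deviation of class-c embeddings from the
    class-c mean; inter = mean squared l2 deviation of class means from
    the (unweighted) global mean of class means.  Variances are total
    squared deviations summed over dimensions — only the ratios matter.
    """
    X = np.asarray(embeddings, dtype=np.float64)
    y = np.asarray(labels)
    classes = sorted(set(y.tolist()))
    if len(classes) < 2:
        raise ValidationError("class_variances needs >= 2 classes")
    means = {}
    raw_intra = {}
    for c in classes:
        Xc = X[y == c]
        if len(Xc) == 0:
            raise ValidationError(f"class {c!r} is empty")
        means[c] = Xc.mean(axis=0)
        raw_intra[c] = float(((Xc - means[c]) ** 2).sum(axis=1).mean())
    M = np.stack([means[c] for c in classes])
    raw_inter = float(((M - M.mean(axis=0)) ** 2).sum(axis=1).mean())
    if raw_inter == 0.0:
        raise ValidationError(
            "inter-class variance is zero (all class means coincide); "
            "normalisation to 1 is undefined")
    return VarianceReport(
        intra={c: v / raw_inter for c, v in raw_intra.items()},
        inter=1.0, raw_intra=raw_intra, raw_inter=raw_inter)
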