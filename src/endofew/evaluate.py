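"""Repeated specimen-disjoint evaluation of embedding classifiers.

Because each polyp contributes exactly one image, splits are made at the
specimen level, so train and test can never share a polyp.  The default
protocol mirrors standard practice for very small medical image sets:
100 random 75/25 splits with a class-balanced test side, metrics
averaged over repeats with 90% confidence intervals (mean ± 1.6449·sd
under the normal approximation; percentile intervals available).

Per-class precision / recall / F1 / accuracy follow the one-vs-rest
counting convention; macro values are unweighted class means.  On a
class-balanced test set plain accuracy coincides with macro recall.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .data import Dataset
from .errors import SplitError, ValidationError
from .heads import VarianceReport, class_variances, fit_head, predict
from .metric import TrainConfig, TripletLossConfig, embed, finetune
from .nn import EmbeddingModel


@dataclass
class SplitSpec:
    train_fraction: float = 0.75
    balanced_test: bool = True
    n_repeats: int = 100
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ValidationError("train_fraction must be in (0, 1)")
        if self.n_repeats < 1:
            raise ValidationError("n_repeats must be >= 1")


@dataclass
class MetricsReport:
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    per_class: dict[str, dict[str, float]]
    confusion: np.ndarray  # class x class counts, rows = true
    classes: list[str]

    def as_dict(self) -> dict[str, float]:
        return {"accuracy": self.accuracy, "precision": self.macro_precision,
                "recall": self.macro_recall, "f1": self.macro_f1}


@dataclass
class EvalReport:
    per_repeat: list[MetricsReport]
    mean: dict[str, float]
    ci_half_width: dict[str, float]
    variance_report: Optional[VarianceReport] = None
    projection_2d: Optional[np.ndarray] = None
    history: list[dict] = field(default_factory=list)

    def to_jsonable(self) -> dict:
        out = {
            "n_repeats": len(self.per_repeat),
            "mean": self.mean,
            "ci_half_width": self.ci_half_width,
            "per_repeat": [m.as_dict() for m in self.per_repeat],
        }
        if self.variance_report is not None:
            v = self.variance_report
            out["variances"] = {"intra": v.intra, "inter": v.inter}
        return out


# ---------------------------------------------------------------- splits

def _polyp_table(dataset: Dataset) -> dict[str, list[str]]:
    """class -> polyp ids (labelled samples only); validates consistency."""
    cls_of: dict[str, str] = {}
    for s in dataset.labeled():
        if isinstance(s.label, frozenset):
            raise ValidationError("splitting expects single-label samples")
        if s.polyp_id in cls_of and cls_of[s.polyp_id] != s.label:
            raise ValidationError(
                f"polyp {s.polyp_id!r} carries conflicting labels")
        cls_of[s.polyp_id] = s.label
    by_class: dict[str, list[str]] = {}
    for pid, c in cls_of.items():
        by_class.setdefault(c, []).append(pid)
    for ids in by_class.values():
        ids.sort()
    return by_class


def make_splits(dataset: Dataset,
                spec: SplitSpec) -> list[tuple[list[str], list[str]]]:
    """``n_repeats`` specimen-disjoint (train ids, test ids) pairs.

    With ``balanced_test`` on, every class contributes the same number of
    test polyps (the smallest per-class test allocation); the excess of
    larger classes returns to the train side.
    """
    by_class = _polyp_table(dataset)
    if len(by_class) < 2:
        raise SplitError("need >= 2 classes to split")
    test_alloc = {c: max(1, int(round((1 - spec.train_fraction) * len(ids))))
                  for c, ids in by_class.items()}
    for c, ids in by_class.items():
        if test_alloc[c] >= len(ids):
            raise SplitError(f"class {c!r} too small for a non-empty train side")
    n_test = min(test_alloc.values()) if spec.balanced_test else None

    rng = np.random.default_rng(spec.seed)
    splits = []
    for _ in range(spec.n_repeats):
        train: list[str] = []
        test: list[str] = []
        for c in sorted(by_class):
            ids = by_class[c]
            k = n_test if n_test is not None else test_alloc[c]
            order = rng.permutation(len(ids))
            test += [ids[i] for i in order[:k]]
            train += [ids[i] for i in order[k:]]
        splits.append((sorted(train), sorted(test)))
    return splits


def _subset(dataset: Dataset, polyp_ids: Sequence[str]) -> Dataset:
    wanted = set(polyp_ids)
    return Dataset(samples=[s for s in dataset.samples if s.polyp_id in wanted],
                   class_vocabulary=list(dataset.class_vocabulary))


# --------------------------------------------------------------- metrics

def compute_metrics(y_true: Sequence[str], y_pred: Sequence[str],
                    class_vocabulary: Sequence[str]) -> MetricsReport:
    """One-vs-rest per-class counts and the derived metrics.

    Per class: precision = TP/(TP+FP), recall = TP/(TP+FN),
    F1 = 2TP/(2TP+FP+FN), accuracy = (TP+TN)/n.  Empty denominators give
    0.  The reported top-level accuracy is plain multiclass accuracy
    (confusion-matrix trace over total).
    """
    y_true = list(y_true)
    y_pred = list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValidationError("label lists differ in length")
    classes = list(class_vocabulary)
    index = {c: i for i, c in enumerate(classes)}
    for lab in set(y_true) | set(y_pred):
        if lab not in index:
            raise ValidationError(f"label {lab!r} outside vocabulary")
    n = len(y_true)
    conf = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        conf[index[t], index[p]] += 1

    # exact rational arithmetic so that identities such as
    # accuracy == macro recall on balanced test sets hold bit-exactly
    from fractions import Fraction

    per_class: dict[str, dict[str, float]] = {}
    per_class_frac: dict[str, dict[str, Fraction]] = {}
    for c, i in index.items():
        tp = int(conf[i, i])
        fp = int(conf[:, i].sum()) - tp
        fn = int(conf[i, :].sum()) - tp
        tn = n - tp - fp - fn
        fr = {
            "precision": Fraction(tp, tp + fp) if tp + fp else Fraction(0),
            "recall": Fraction(tp, tp + fn) if tp + fn else Fraction(0),
            "f1": (Fraction(2 * tp, 2 * tp + fp + fn)
                   if 2 * tp + fp + fn else Fraction(0)),
            "accuracy": Fraction(tp + tn, n) if n else Fraction(0),
        }
        per_class_frac[c] = fr
        per_class[c] = {k: float(v) for k, v in fr.items()}
        per_class[c]["support"] = float(tp + fn)
    macro = {m: float(sum(per_class_frac[c][m] for c in classes)
                      / len(classes))
             for m in ("precision", "recall", "f1")}
    accuracy = float(Fraction(int(np.trace(conf)), n)) if n else 0.0
    return MetricsReport(accuracy=accuracy,
                         macro_precision=macro["precision"],
                         macro_recall=macro["recall"], macro_f1=macro["f1"],
                         per_class=per_class, confusion=conf, classes=classes)


def confidence_interval(values: Sequence[float], level: float = 0.90,
                        method: str = "normal") -> tuple[float, float]:
    """Mean and symmetric half-width over repeats.

    ``normal``: half-width = z(level) · sample sd (ddof=1), z(0.90) ≈
    1.6449 — the spread of per-split scores, matching the symmetric
    ``(± x)`` convention.  ``percentile``: half the (5th, 95th) spread.
    """
    v = np.asarray(values, dtype=np.float64)
    if v.size < 2:
        raise ValidationError("confidence interval needs >= 2 values")
    mean = float(v.mean())
    if np.ptp(v) == 0.0:  # constant input: exactly zero spread
        return float(v[0]), 0.0
    if method == "normal":
        z = float(stats.norm.ppf(0.5 + level / 2.0))
        return mean, float(z * v.std(ddof=1))
    if method == "percentile":
        lo, hi = np.percentile(v, [50 * (1 - level), 50 * (1 + level)])
        return mean, float((hi - lo) / 2.0)
    raise ValidationError(f"unknown CI method {method!r}")


# ------------------------------------------------------------ experiment

def run_experiment(dataset: Dataset, encoder: EmbeddingModel, head_kind: str,
                   split_spec: SplitSpec, fine_tune: bool = False,
                   train_cfg: Optional[TrainConfig] = None,
                   aug=None, loss_cfg: Optional[TripletLossConfig] = None,
                   head_params: Optional[dict] = None,
                   with_variances: bool = True,
                   splits: Optional[list] = None) -> EvalReport:
    """Repeat over splits: (optionally fine-tune on the train side),
    embed, fit the head on train embeddings, predict the test side.

    The split sequence is a pure function of the dataset and
    ``split_spec`` (or passed explicitly), so compared configurations
    share identical splits when given the same seed.
    """
    train_cfg = train_cfg or TrainConfig()
    loss_cfg = loss_cfg or TripletLossConfig()
    if splits is None:
        splits = make_splits(dataset, split_spec)
    seed_seq = np.random.SeedSequence(split_spec.seed)
    split_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                   for s in seed_seq.spawn(len(splits))]

    reports: list[MetricsReport] = []
    histories: list[dict] = []
    for k, (train_ids, test_ids) in enumerate(splits):
        train_ds = _subset(dataset, train_ids)
        test_ds = _subset(dataset, test_ids)
        model = encoder.copy()
        if fine_tune:
            cfg_k = TrainConfig(**{**train_cfg.__dict__, "seed": split_seeds[k]})
            try:
                model, hist = finetune(model, train_ds, cfg_k, aug, loss_cfg)
            except Exception as exc:
                raise type(exc)(f"split {k}: {exc}") from exc
            histories.append(hist)
        Ztr = embed(model, train_ds.samples)
        Zte = embed(model, test_ds.samples)
        head = fit_head(head_kind, Ztr, [s.label for s in train_ds.samples],
                        head_params)
        y_pred = predict(head, Zte)
        y_true = [s.label for s in test_ds.samples]
        reports.append(compute_metrics(y_true, y_pred,
                                       dataset.class_vocabulary))

    mean: dict[str, float] = {}
    half: dict[str, float] = {}
    for m in ("accuracy", "precision", "recall", "f1"):
        vals = [r.as_dict()[m] for r in reports]
        if len(vals) >= 2:
            mean[m], half[m] = confidence_interval(vals)
        else:
            mean[m], half[m] = float(vals[0]), 0.0

    var_report = None
    if with_variances:
        labeled = dataset.labeled()
        Z = embed(encoder, labeled)
        var_report = class_variances(Z, [s.label for s in labeled])
    return EvalReport(per_repeat=reports, mean=mean, ci_half_width=half,
                      variance_report=var_report, history=histories)


def project_2d(embeddings: np.ndarray, seed: int = 0,
               perplexity: Optional[float] = None) -> np.ndarray:
    """t-SNE projection of embeddings into 2-D, for inspection only."""
    from sklearn.manifold import TSNE

    X = np.asarray(embeddings, dtype=np.float64)
    if X.ndim != 2 or len(X) < 3:
        raise ValidationError("project_2d needs an (n >= 3, d) matrix")
    if perplexity is None:
        perplexity = min(30.0, max(2.0, (len(X) - 1) / 3.0))
    tsne = TSNE(n_components=2, random_state=seed, perplexity=perplexity,
                init="pca")
    return tsne.fit_transform(X)
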