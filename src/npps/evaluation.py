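"""Performance metrics, k-fold cross-validation and jackknife evaluation.

Metrics are the standard binary-classification quartet

    Sn  = TP / (TP + FN)                      (sensitivity / recall)
    Sp  = TN / (TN + FP)                      (specificity)
    Acc = (TP + TN) / (TP + TN + FP + FN)
    MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN))

with MCC defined as 0 when any denominator factor is 0, and Sn/Sp reported as
absent (``None``) when the corresponding class is empty. On a balanced
evaluation set Acc = (Sn + Sp) / 2 exactly. Ranking quality is summarized by
AUROC (Mann–Whitney pair-counting formulation, ties counted 1/2) and AUPRC
(step-wise precision-recall integral).

Cross-validation is leakage-free by default: inside each fold the NPPS
profiles are fitted only on the training portion, the (C, γ) grid search runs
nested on training-portion features only, and the held-out portion is encoded
with the training-fold profiles. A ``refit_per_fold=False`` reproduction mode
fits the encoder once on the full dataset before splitting; this mirrors how
published whole-dataset accuracies may have been produced but leaks encoder
information into validation folds, so it is off by default. The jackknife is
leave-one-out cross-validation (k = n) and is fully deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import average_precision_score
from sklearn.model_selection import StratifiedKFold

from . import classifier as _clf
from .exceptions import ContractError, ParameterError
from .profiles import NPPSProfileSet
from .seqio import SequenceDataset

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "compute_metrics",
    "ranking_metrics",
    "kfold_cv",
    "jackknife",
    "FoldResult",
    "CVResult",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ContractError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.tn + other.tn,
            self.fp + other.fp,
            self.fn + other.fn,
        )

    @classmethod
    def from_labels(cls, y_true, y_pred) -> "ConfusionCounts":
        y_true = np.asarray(y_true, dtype=np.int64)
        y_pred = np.asarray(y_pred, dtype=np.int64)
        if y_true.shape != y_pred.shape:
            raise ContractError("y_true and y_pred must have equal length")
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            tn=int(np.sum((y_true == -1) & (y_pred == -1))),
            fp=int(np.sum((y_true == -1) & (y_pred == 1))),
            fn=int(np.sum((y_true == 1) & (y_pred == -1))),
        )


@dataclass
class MetricsReport:
    """Derived metrics as proportions in [0, 1] (``summary()`` prints %)."""

    confusion: ConfusionCounts
    sn: float | None
    sp: float | None
    acc: float
    mcc: float
    precision: float | None
    recall: float | None
    f_score: float
    auroc: float | None = None
    auprc: float | None = None

    def as_dict(self) -> dict:
        return {
            "TP": self.confusion.tp,
            "TN": self.confusion.tn,
            "FP": self.confusion.fp,
            "FN": self.confusion.fn,
            "Sn": self.sn,
            "Sp": self.sp,
            "Acc": self.acc,
            "MCC": self.mcc,
            "precision": self.precision,
            "recall": self.recall,
            "F_score": self.f_score,
            "AUROC": self.auroc,
            "AUPRC": self.auprc,
        }

    def summary(self) -> str:
        def pct(x):
            return "absent" if x is None else f"{100 * x:.2f}%"

        lines = [
            f"samples: {self.confusion.total}  "
            f"(TP={self.confusion.tp} TN={self.confusion.tn} "
            f"FP={self.confusion.fp} FN={self.confusion.fn})",
            f"Sn={pct(self.sn)}  Sp={pct(self.sp)}  Acc={pct(self.acc)}  "
            f"MCC={self.mcc:.4f}  F1={self.f_score:.4f}",
        ]
        if self.auroc is not None:
            lines.append(f"AUROC={self.auroc:.4f}  AUPRC={self.auprc:.4f}")
        return "\n".join(lines)


def compute_metrics(
    confusion: ConfusionCounts,
    labels=None,
    scores=None,
) -> MetricsReport:
    """Derive Sn/Sp/Acc/MCC/F1 (and AUROC/AUPRC when scores are given)."""
    c = confusion
    if c.total == 0:
        raise ContractError("cannot compute metrics on zero samples")

    sn = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    sp = c.tn / (c.tn + c.fp) if (c.tn + c.fp) > 0 else None
    acc = (c.tp + c.tn) / c.total

    denom_factors = (c.tp + c.fp, c.tp + c.fn, c.tn + c.fp, c.tn + c.fn)
    if any(f == 0 for f in denom_factors):
        mcc = 0.0
    else:
        mcc = (c.tp * c.tn - c.fp * c.fn) / float(
            np.sqrt(np.prod(np.asarray(denom_factors, dtype=float)))
        )

    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else None
    recall = sn
    if 2 * c.tp + c.fp + c.fn == 0:
        f_score = 0.0
    else:
        f_score = 2 * c.tp / (2 * c.tp + c.fp + c.fn)

    auroc = auprc = None
    if scores is not None and labels is not None:
        labels = np.asarray(labels)
        if len(np.unique(labels)) == 2:
            auroc, auprc = ranking_metrics(labels, scores)

    return MetricsReport(
        confusion=c,
        sn=sn,
        sp=sp,
        acc=acc,
        mcc=mcc,
        precision=precision,
        recall=recall,
        f_score=f_score,
        auroc=auroc,
        auprc=auprc,
    )


def ranking_metrics(labels, scores) -> tuple[float, float]:
    """AUROC (Mann–Whitney with ties counted 1/2) and AUPRC (step integral)."""
    y = np.asarray(labels, dtype=np.int64)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ContractError("labels and scores must have equal length")
    if not np.isfinite(s).all():
        raise ContractError("scores must be finite")
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == -1))
    if n_pos == 0 or n_neg == 0:
        raise ContractError("ranking metrics need both classes present")
    ranks = rankdata(s)  # average ranks handle ties as 1/2
    auroc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    auprc = float(average_precision_score(y, s, pos_label=1))
    return float(auroc), auprc


# ---------------------------------------------------------------------------
# Cross-validation


@dataclass
class FoldResult:
    fold: int
    test_indices: tuple
    C: float
    gamma: float
    grid_f_score: float
    confusion: ConfusionCounts
    metrics: MetricsReport


@dataclass
class CVResult:
    """Per-fold and pooled cross-validation outcome."""

    folds: list
    pooled: MetricsReport
    mean_metrics: dict
    k: int
    seed: int | None
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "seed": self.seed,
            "config": self.config,
            "pooled": self.pooled.as_dict(),
            "mean_over_folds": self.mean_metrics,
            "folds": [
                {
                    "fold": f.fold,
                    "test_indices": list(f.test_indices),
                    "C": f.C,
                    "gamma": f.gamma,
                    "grid_f_score": (
                        None if np.isnan(f.grid_f_score) else f.grid_f_score
                    ),
                    "metrics": f.metrics.as_dict(),
                }
                for f in self.folds
            ],
        }

    def to_json(self, path=None) -> str:
        def default(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            raise TypeError(f"not JSON serializable: {type(o)}")

        text = json.dumps(self.to_dict(), indent=1, sort_keys=True,
                          default=default, allow_nan=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def to_tsv(self, path) -> None:
        cols = ["fold", "C", "gamma", "Sn", "Sp", "Acc", "MCC", "F_score"]
        with open(path, "w") as fh:
            fh.write("\t".join(cols) + "\n")

            def row(tag, C, gamma, m):
                d = m.as_dict()
                vals = [tag, repr(C), repr(gamma)] + [
                    "NA" if d[c] is None else repr(float(d[c]))
                    for c in ("Sn", "Sp", "Acc", "MCC", "F_score")
                ]
                fh.write("\t".join(str(v) for v in vals) + "\n")

            for f in self.folds:
                row(f.fold, f.C, f.gamma, f.metrics)
            row("pooled", "NA", "NA", self.pooled)


def _nested_grid_search(
    train_ds: SequenceDataset,
    y_train: np.ndarray,
    intervals,
    pseudocount: float,
    config: _clf.SVMConfig,
) -> _clf.GridSearchResult:
    """Encoder-aware (C, γ) search on an outer training fold.

    Feature-level grid search would score inner-validation samples on
    encodings whose profiles were fitted with those same samples included,
    which systematically favours overfitting (large C, large γ) grid points.
    Here the NPPS profiles are refitted inside every inner fold, so the inner
    F1 estimate is leakage-free at both levels. Tie-breaking and determinism
    match :func:`npps.classifier.grid_search`.
    """
    if len(config.c_grid) == 1 and len(config.gamma_grid) == 1:
        return _clf.GridSearchResult(
            config.c_grid[0], config.gamma_grid[0], float("nan")
        )
    n = len(train_ds)
    if n < 2 * config.inner_folds:
        raise ParameterError(
            f"need at least {2 * config.inner_folds} training samples for "
            f"{config.inner_folds}-fold inner CV"
        )
    skf = StratifiedKFold(
        n_splits=config.inner_folds, shuffle=True, random_state=config.seed
    )
    encoded = []
    for inner_train, inner_val in skf.split(np.zeros(n), y_train):
        inner_profiles = NPPSProfileSet.fit_dataset(
            train_ds.subset(inner_train), intervals, pseudocount
        )
        encoded.append(
            (
                inner_profiles.encode_dataset(train_ds.subset(inner_train)).values,
                y_train[inner_train],
                inner_profiles.encode_dataset(train_ds.subset(inner_val)).values,
                y_train[inner_val],
            )
        )
    best: _clf.GridSearchResult | None = None
    for C in config.c_grid:
        for gamma in config.gamma_grid:
            scores = []
            for X_tr, y_tr, X_va, y_va in encoded:
                model = _clf.train(X_tr, y_tr, C, gamma)
                pred, _ = _clf.predict(model, X_va)
                scores.append(_clf._f1_positive(y_va, pred))
            mean_f1 = float(np.mean(scores))
            if best is None or mean_f1 > best.f_score:
                best = _clf.GridSearchResult(C, gamma, mean_f1)
    assert best is not None
    return best


def _loo_folds(n: int):
    """Deterministic leave-one-out partition, ascending order."""
    all_idx = np.arange(n)
    for i in range(n):
        yield np.delete(all_idx, i), np.array([i])


def kfold_cv(
    dataset: SequenceDataset,
    k: int = 10,
    intervals: Iterable[int] = range(7),
    pseudocount: float = 0.0,
    svm_config: _clf.SVMConfig | None = None,
    seed: int = 0,
    refit_per_fold: bool = True,
) -> CVResult:
    """Stratified k-fold cross-validation with per-fold encoder refitting.

    Every sample is validated exactly once. ``k == len(dataset)`` degrades to
    deterministic leave-one-out (the jackknife), where stratification is
    impossible. The pooled report aggregates the k confusion counts and uses
    the pooled decision scores for AUROC/AUPRC.
    """
    svm_config = svm_config or _clf.SVMConfig()
    intervals = tuple(sorted(set(int(x) for x in intervals)))
    n = len(dataset)
    if k < 2:
        raise ParameterError("k must be ≥ 2")
    y = dataset.label_vector()
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == -1))

    if k == n:
        if n < 3:
            raise ParameterError("jackknife needs at least 3 samples")
        folds = list(_loo_folds(n))
    else:
        if min(n_pos, n_neg) < k:
            raise ParameterError(
                f"each class needs ≥ k={k} members "
                f"(have {n_pos} positive, {n_neg} negative)"
            )
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        folds = list(skf.split(np.zeros(n), y))

    if not refit_per_fold:
        global_profiles = NPPSProfileSet.fit_dataset(
            dataset, intervals, pseudocount
        )

    fold_results: list[FoldResult] = []
    pooled_conf = ConfusionCounts(0, 0, 0, 0)
    all_scores = np.empty(n)
    all_true = np.empty(n, dtype=np.int64)

    for fold_no, (train_idx, test_idx) in enumerate(folds):
        train_ds = dataset.subset(train_idx)
        test_ds = dataset.subset(test_idx)
        if refit_per_fold:
            profiles = NPPSProfileSet.fit_dataset(train_ds, intervals, pseudocount)
        else:
            profiles = global_profiles
        X_train = profiles.encode_dataset(train_ds).values
        X_test = profiles.encode_dataset(test_ds).values
        y_train, y_test = y[train_idx], y[test_idx]

        if refit_per_fold:
            gs = _nested_grid_search(
                train_ds, y_train, intervals, pseudocount, svm_config
            )
        else:
            gs = _clf.grid_search(X_train, y_train, svm_config)
        model = _clf.train(X_train, y_train, gs.C, gs.gamma)
        pred, scores = _clf.predict(model, X_test)

        conf = ConfusionCounts.from_labels(y_test, pred)
        pooled_conf = pooled_conf + conf
        all_scores[test_idx] = scores
        all_true[test_idx] = y_test
        fold_results.append(
            FoldResult(
                fold=fold_no,
                test_indices=tuple(int(i) for i in test_idx),
                C=gs.C,
                gamma=gs.gamma,
                grid_f_score=gs.f_score,
                confusion=conf,
                metrics=compute_metrics(conf),
            )
        )

    pooled = compute_metrics(pooled_conf, labels=all_true, scores=all_scores)

    mean_metrics: dict = {}
    for key in ("Sn", "Sp", "Acc", "MCC", "F_score"):
        vals = [f.metrics.as_dict()[key] for f in fold_results]
        present = [v for v in vals if v is not None]
        mean_metrics[key] = float(np.mean(present)) if present else None

    return CVResult(
        folds=fold_results,
        pooled=pooled,
        mean_metrics=mean_metrics,
        k=k,
        seed=seed,
        config={
            "intervals": list(intervals),
            "pseudocount": pseudocount,
            "C_grid": list(svm_config.c_grid),
            "gamma_grid": list(svm_config.gamma_grid),
            "inner_folds": svm_config.inner_folds,
            "inner_seed": svm_config.seed,
            "refit_per_fold": refit_per_fold,
        },
    )


def jackknife(
    dataset: SequenceDataset,
    intervals: Iterable[int] = range(7),
    pseudocount: float = 0.0,
    svm_config: _clf.SVMConfig | None = None,
    refit_per_fold: bool = True,
) -> CVResult:
    """Leave-one-out cross-validation; deterministic, no randomness remains."""
    return kfold_cv(
        dataset,
        k=len(dataset),
        intervals=intervals,
        pseudocount=pseudocount,
        svm_config=svm_config,
        seed=0,
        refit_per_fold=refit_per_fold,
    )
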