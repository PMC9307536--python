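"""Evaluation of frame-wise workflow predictions.

Two families of quantity are computed:

* classification quality — per-class precision/recall/F1 with the
  support-weighted means (weighted-F1 is the headline score; weighted recall
  is algebraically the overall frame accuracy), plus *mean-accuracy*, read
  here as the macro-average of per-class recall over classes present in the
  ground truth;

* stability — *prediction volatility*, the ratio of the number of class
  changes in the prediction track to the number of class changes in the
  ground-truth track.  A perfectly stable, perfectly timed prediction scores
  1.0; flickery predictions score far above 1.  When the ground truth never
  changes class the ratio is undefined and reported as ``None`` (such videos
  are excluded from aggregation and logged).

The confusion matrix is normalised over the *predicted* class: row ``o``
holds the percentage of frames predicted ``o`` broken down by their ground
truth, so the diagonal is the precision of each class and the off-diagonals
its false discovery rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import precision_recall_fscore_support

from .errors import AggregationError
from .sequences import LabelSequence, SequencePair

logger = logging.getLogger(__name__)


def count_changes(seq: LabelSequence | np.ndarray) -> int:
    """Number of frames whose label differs from the previous frame's."""
    x = seq.frames if isinstance(seq, LabelSequence) else np.asarray(seq)
    if x.size <= 1:
        return 0
    return int(np.count_nonzero(x[1:] != x[:-1]))


def prediction_volatility(
    pred: LabelSequence, gt: LabelSequence
) -> float | None:
    """changes(pred) / changes(gt); ``None`` when the ground truth never changes."""
    if len(pred) != len(gt):
        raise ValueError(
            f"length mismatch: prediction {len(pred)}, ground truth {len(gt)}"
        )
    denom = count_changes(gt)
    if denom == 0:
        logger.info(
            "video %s: ground truth has no class changes; volatility undefined",
            gt.video_id,
        )
        return None
    return count_changes(pred) / denom


@dataclass(frozen=True)
class ClassMetrics:
    label: str
    precision: float
    recall: float
    f1: float
    support: int


@dataclass
class EvaluationReport:
    """Frame-wise evaluation of one prediction (or one pooled fold).

    ``confusion`` is a K×K array of percentages; cell ``[o, s]`` is the
    percentage of frames predicted as class ``o`` whose ground truth is
    ``s``.  Rows for classes never predicted are all zero.
    """

    labels: tuple[str, ...]
    weighted_f1: float
    weighted_precision: float
    weighted_recall: float
    mean_accuracy: float
    volatility: float | None
    per_class: list[ClassMetrics]
    confusion: np.ndarray = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "weighted_f1": self.weighted_f1,
            "weighted_precision": self.weighted_precision,
            "weighted_recall": self.weighted_recall,
            "mean_accuracy": self.mean_accuracy,
            "volatility": self.volatility,
            "per_class": [
                {
                    "label": c.label,
                    "precision": c.precision,
                    "recall": c.recall,
                    "f1": c.f1,
                    "support": c.support,
                }
                for c in self.per_class
            ],
            "confusion": {
                "labels": list(self.labels),
                "rows_percent": np.round(self.confusion, 1).tolist(),
            },
        }


def evaluate(pair: SequencePair) -> EvaluationReport:
    """Full evaluation report for one ground-truth/prediction pair.

    Weighted metrics are support-weighted means over classes present in the
    ground truth; classes predicted but absent from the ground truth appear
    in ``per_class`` with zero support and are excluded from the weighted
    means.
    """
    gt = pair.ground_truth
    pred = pair.prediction
    vocab = gt.vocabulary
    K = vocab.K
    labels = np.arange(K)
    prec, rec, f1, support = precision_recall_fscore_support(
        gt.frames, pred.frames, labels=labels, zero_division=0
    )
    present = support > 0
    weights = support[present] / support[present].sum()
    weighted_f1 = float(np.dot(f1[present], weights))
    weighted_precision = float(np.dot(prec[present], weights))
    weighted_recall = float(np.dot(rec[present], weights))
    mean_accuracy = float(rec[present].mean())

    cm = _sk_confusion(gt.frames, pred.frames, labels=labels).T  # [pred, true]
    row_sums = cm.sum(axis=1, keepdims=True)
    confusion = np.divide(
        100.0 * cm,
        row_sums,
        out=np.zeros_like(cm, dtype=float),
        where=row_sums > 0,
    )

    per_class = [
        ClassMetrics(
            label=vocab.labels[i],
            precision=float(prec[i]),
            recall=float(rec[i]),
            f1=float(f1[i]),
            support=int(support[i]),
        )
        for i in range(K)
    ]
    return EvaluationReport(
        labels=vocab.labels,
        weighted_f1=weighted_f1,
        weighted_precision=weighted_precision,
        weighted_recall=weighted_recall,
        mean_accuracy=mean_accuracy,
        volatility=prediction_volatility(pred, gt),
        per_class=per_class,
        confusion=confusion,
    )


def evaluate_fold(pairs: list[SequencePair]) -> EvaluationReport:
    """Pooled evaluation of one validation fold.

    Classification metrics are computed on all frames concatenated;
    volatility is the mean of per-video volatilities over videos where it is
    defined (``None`` if no video has a ground-truth class change).
    """
    if not pairs:
        raise AggregationError("cannot evaluate an empty fold")
    vocab = pairs[0].ground_truth.vocabulary
    gt_all = np.concatenate([p.ground_truth.frames for p in pairs])
    pred_all = np.concatenate([p.prediction.frames for p in pairs])
    pooled = evaluate(
        SequencePair(
            ground_truth=LabelSequence("fold", vocab, gt_all),
            prediction=LabelSequence("fold", vocab, pred_all),
        )
    )
    vols = [
        v
        for p in pairs
        if (v := prediction_volatility(p.prediction, p.ground_truth)) is not None
    ]
    pooled.volatility = float(np.mean(vols)) if vols else None
    return pooled


_SCALAR_METRICS = (
    "weighted_f1",
    "weighted_precision",
    "weighted_recall",
    "mean_accuracy",
    "volatility",
)


@dataclass(frozen=True)
class FoldSummary:
    """Mean and population standard deviation of each metric across folds."""

    n_folds: int
    stats: dict[str, tuple[float, float]]

    def __getitem__(self, metric: str) -> tuple[float, float]:
        return self.stats[metric]


def aggregate_folds(reports: list[EvaluationReport]) -> FoldSummary:
    """Summarise per-fold reports as mean ± population std per metric.

    Volatility is averaged over the folds where it is defined; the other
    metrics use every fold.
    """
    if len(reports) < 2:
        raise AggregationError(
            f"cross-fold aggregation requires >= 2 folds, got {len(reports)}"
        )
    stats: dict[str, tuple[float, float]] = {}
    for metric in _SCALAR_METRICS:
        values = [getattr(r, metric) for r in reports]
        values = [v for v in values if v is not None]
        if not values:
            continue
        arr = np.asarray(values, dtype=float)
        stats[metric] = (float(arr.mean()), float(arr.std(ddof=0)))
    return FoldSummary(n_folds=len(reports), stats=stats)
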