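"""Evaluation metrics and classifier statistics.

Covers the full reporting suite for ordinal slide grading: accuracy, binary
(non-neoplastic vs all) accuracy, sensitivity (positives = low- plus
high-grade), quadratic weighted kappa, normal-approximation binomial
confidence intervals, McNemar's paired test with continuity correction,
precision-recall curves, confidence density analysis of correct vs
incorrect predictions, and the disagreement-export / label-correction
round trip used for second-round reviews.

The confidence interval treats each prediction as a Bernoulli trial: for a
proportion-valued metric m on n samples, SE = sqrt(m(1-m)/n) and the
half-width is z * SE with z the standard-normal quantile at (1+c)/2
(z ~= 1.96 at c = 0.95).  The same interval is also printed for QWK and
sensitivity for comparability, flagged as not strictly Bernoulli.

McNemar's test tallies, for a paired pair of classifiers, a = both wrong,
b = only the second wrong, c = only the first wrong, d = both right, and
computes X^2 = (|b-c|-1)^2 / (b+c) (continuity-corrected), significant at
the 0.95 chi-squared(1) quantile 3.841.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import cohen_kappa_score, confusion_matrix, precision_recall_curve

from .synthetic import NNEO

K = 3
CHI2_CRITICAL_95 = 3.841


@dataclass
class MetricWithCI:
    """A proportion-valued metric with its normal-approximation 95% CI."""

    value: float
    n: int
    z: float
    se: float
    half_width: float
    flag: str = ""

    @property
    def percent(self) -> float:
        return 100.0 * self.value

    @property
    def half_width_percent(self) -> float:
        return 100.0 * self.half_width

    def __str__(self) -> str:
        return f"{self.percent:.2f}% ± {self.half_width_percent:.2f}"


def binomial_ci(m: float, n: int, c: float = 0.95) -> MetricWithCI:
    """SE = sqrt(m(1-m)/n); half-width = z * SE with z = Phi^-1((1+c)/2)."""
    if not (0.0 <= m <= 1.0):
        raise ValueError("m must be a proportion in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0.0 < c < 1.0):
        raise ValueError("confidence level must be in (0, 1)")
    z = float(sps.norm.ppf((1.0 + c) / 2.0))
    se = float(np.sqrt(m * (1.0 - m) / n))
    return MetricWithCI(value=float(m), n=int(n), z=z, se=se, half_width=z * se)


def quadratic_weighted_kappa(truth: np.ndarray, preds: np.ndarray) -> float:
    """QWK with weights (i-j)^2/(K-1)^2 over classes {1..3}; NaN when the
    truth holds a single class (agreement by chance is undefined)."""
    truth = np.asarray(truth)
    preds = np.asarray(preds)
    if len(np.unique(truth)) < 2 or len(np.unique(preds)) < 2:
        return float("nan")
    return float(
        cohen_kappa_score(truth, preds, weights="quadratic", labels=[1, 2, 3])
    )


@dataclass
class EvalReport:
    """All slide-level metrics for one evaluated cohort."""

    n: int
    confusion: np.ndarray  # K x K, rows = truth, cols = prediction
    accuracy: MetricWithCI
    binary_accuracy: MetricWithCI
    sensitivity: MetricWithCI
    qwk: float
    qwk_ci: Optional[MetricWithCI]
    per_class_recall: dict[int, float]
    qwk_flag: str = ""

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy.value,
            "accuracy_ci": self.accuracy.half_width,
            "binary_accuracy": self.binary_accuracy.value,
            "binary_accuracy_ci": self.binary_accuracy.half_width,
            "sensitivity": self.sensitivity.value,
            "sensitivity_ci": self.sensitivity.half_width,
            "qwk": None if np.isnan(self.qwk) else self.qwk,
            "qwk_flag": self.qwk_flag,
            "per_class_recall": {str(k): v for k, v in self.per_class_recall.items()},
        }

    def to_text(self) -> str:
        lines = [
            f"n = {self.n}",
            f"accuracy         {self.accuracy}",
            f"binary accuracy  {self.binary_accuracy}  (NNeo vs all)",
            f"sensitivity      {self.sensitivity.value:.3f} ± "
            f"{self.sensitivity.half_width:.3f}  (LG+HG vs NNeo)",
            f"QWK              "
            + ("undefined" if np.isnan(self.qwk) else f"{self.qwk:.3f}")
            + (f"  [{self.qwk_flag}]" if self.qwk_flag else ""),
            "confusion (rows=truth NNeo/LG/HG):",
        ]
        for row in self.confusion:
            lines.append("  " + " ".join(f"{v:5d}" for v in row))
        return "\n".join(lines)


def _as_pred_array(preds) -> np.ndarray:
    vals = [p.pred if hasattr(p, "pred") else p for p in preds]
    return np.asarray(vals, dtype=np.int64)


def evaluate(preds, truth: Sequence[int], c: float = 0.95) -> EvalReport:
    """Compute the full metric suite from predictions and true slide labels.

    ``preds`` may be SlidePrediction objects or plain class indices; binary
    metrics collapse {LG, HG} to positive and NNeo to negative.
    """
    y_pred = _as_pred_array(preds)
    y_true = np.asarray(truth, dtype=np.int64)
    if len(y_pred) == 0 or len(y_pred) != len(y_true):
        raise ValueError("predictions and truth must be non-empty and aligned")
    if not np.isin(y_true, [1, 2, 3]).all():
        raise ValueError("truth labels must be in {1,2,3}")
    n = len(y_true)
    cm = confusion_matrix(y_true, y_pred, labels=[1, 2, 3])
    acc = float((y_true == y_pred).mean())
    pos_true = y_true > NNEO
    pos_pred = y_pred > NNEO
    binary_acc = float((pos_true == pos_pred).mean())
    n_pos = int(pos_true.sum())
    sensitivity = float(pos_pred[pos_true].mean()) if n_pos else float("nan")
    qwk = quadratic_weighted_kappa(y_true, y_pred)
    qwk_flag = "" if not np.isnan(qwk) else "undefined: single-class input"
    qwk_ci = None
    if not np.isnan(qwk) and 0.0 <= qwk <= 1.0:
        qwk_ci = binomial_ci(qwk, n, c)
        qwk_ci.flag = "not a Bernoulli mean"
    recalls = {}
    for k in (1, 2, 3):
        total = cm[k - 1].sum()
        recalls[k] = float(cm[k - 1, k - 1] / total) if total else float("nan")
    sens_ci = (
        binomial_ci(sensitivity, n_pos, c)
        if n_pos
        else MetricWithCI(float("nan"), 0, float("nan"), float("nan"), float("nan"))
    )
    sens_ci.flag = "not a Bernoulli mean over all samples"
    return EvalReport(
        n=n,
        confusion=cm,
        accuracy=binomial_ci(acc, n, c),
        binary_accuracy=binomial_ci(binary_acc, n, c),
        sensitivity=sens_ci,
        qwk=qwk,
        qwk_ci=qwk_ci,
        per_class_recall=recalls,
        qwk_flag=qwk_flag,
    )


# ---------------------------------------------------------------------------
# McNemar's paired test
# ---------------------------------------------------------------------------


@dataclass
class McNemarResult:
    a: int  # both wrong
    b: int  # only the second classifier wrong
    c: int  # only the first classifier wrong
    d: int  # both right
    chi2: float
    p_value: float
    significant: bool

    def __str__(self) -> str:
        return f"X2 = {self.chi2:.2f} (p = {self.p_value:.3f})"


def mcnemar_test(
    correct_a: Sequence[bool], correct_b: Sequence[bool]
) -> McNemarResult:
    """Continuity-corrected McNemar test on paired correctness flags.

    X^2 = (|b-c|-1)^2/(b+c); the degenerate b+c = 0 case is defined as
    X^2 = 0, p = 1.  The p-value is the right tail of chi-squared(1).
    """
    fa = np.asarray(correct_a, dtype=bool)
    fb = np.asarray(correct_b, dtype=bool)
    if len(fa) != len(fb) or len(fa) == 0:
        raise ValueError("correctness flags must be non-empty and aligned")
    a = int((~fa & ~fb).sum())
    b = int((fa & ~fb).sum())
    c = int((~fa & fb).sum())
    d = int((fa & fb).sum())
    if b + c == 0:
        chi2, p = 0.0, 1.0
    else:
        chi2 = (abs(b - c) - 1) ** 2 / (b + c)
        p = float(sps.chi2.sf(chi2, df=1))
    return McNemarResult(
        a=a, b=b, c=c, d=d, chi2=float(chi2), p_value=p,
        significant=chi2 > CHI2_CRITICAL_95,
    )


def mcnemar_p_from_chi2(chi2: float) -> float:
    """Right-tail chi-squared(1) p-value for a given X^2 statistic."""
    return float(sps.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# Precision-recall and confidence densities
# ---------------------------------------------------------------------------


@dataclass
class PRCurve:
    precision: np.ndarray
    recall: np.ndarray
    thresholds: np.ndarray
    f1: float
    f1_source: str  # "operating_point" or "best_threshold"


def pr_curve(
    positive_scores: Sequence[float],
    truth: Sequence[bool],
    predicted_positive: Optional[Sequence[bool]] = None,
) -> PRCurve:
    """Precision-recall over all score thresholds, for the binary positive-
    vs-NNeo problem; the positive score is 1 - y_hat(NNeo) at the
    diagnostic tile.

    F1 is reported at the discrete classifier's operating point when
    ``predicted_positive`` is given, else at the best curve threshold.
    """
    scores = np.asarray(positive_scores, dtype=np.float64)
    y = np.asarray(truth, dtype=bool)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    if y.all() or (~y).all():
        raise ValueError("both classes must be present")
    precision, recall, thresholds = precision_recall_curve(y, scores)
    if predicted_positive is not None:
        yp = np.asarray(predicted_positive, dtype=bool)
        tp = int((yp & y).sum())
        fp = int((yp & ~y).sum())
        fn = int((~yp & y).sum())
        denom = 2 * tp + fp + fn
        f1 = 2 * tp / denom if denom else 0.0
        source = "operating_point"
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            f1s = 2 * precision * recall / (precision + recall)
        f1 = float(np.nanmax(f1s))
        source = "best_threshold"
    return PRCurve(
        precision=precision, recall=recall, thresholds=thresholds,
        f1=float(f1), f1_source=source,
    )


@dataclass
class ConfidenceDensity:
    grid: np.ndarray
    density_correct: Optional[np.ndarray]
    density_incorrect: Optional[np.ndarray]
    mean_correct: float
    mean_incorrect: float
    skipped: tuple[str, ...] = ()


def _kde_on_grid(values: np.ndarray, grid: np.ndarray) -> np.ndarray:
    if np.ptp(values) == 0:  # all values identical
        # degenerate point mass: a normalised spike at the nearest grid point
        density = np.zeros_like(grid)
        j = int(np.argmin(np.abs(grid - values[0])))
        dx = grid[1] - grid[0]
        density[j] = 1.0 / dx
        return density
    return sps.gaussian_kde(values)(grid)  # Scott's-rule bandwidth


def confidence_density(
    confidences: Sequence[float], correct: Sequence[bool], grid_size: int = 201
) -> ConfidenceDensity:
    """Gaussian-kernel density of predicted-class confidence, split by
    correctness, on a [0, 1] grid; group means are reported alongside.

    Groups with fewer than 2 samples are skipped with a flag.
    """
    conf = np.asarray(confidences, dtype=np.float64)
    flags = np.asarray(correct, dtype=bool)
    if len(conf) == 0:
        raise ValueError("no confidences given")
    grid = np.linspace(0.0, 1.0, grid_size)
    out = {}
    means = {}
    skipped = []
    for name, values in (("correct", conf[flags]), ("incorrect", conf[~flags])):
        means[name] = float(values.mean()) if len(values) else float("nan")
        if len(values) < 2:
            out[name] = None
            skipped.append(name)
        else:
            out[name] = _kde_on_grid(values, grid)
    if out["correct"] is None and out["incorrect"] is None:
        raise ValueError("both groups have fewer than 2 samples")
    return ConfidenceDensity(
        grid=grid,
        density_correct=out["correct"],
        density_incorrect=out["incorrect"],
        mean_correct=means["correct"],
        mean_incorrect=means["incorrect"],
        skipped=tuple(skipped),
    )


# ---------------------------------------------------------------------------
# Disagreement export and label correction
# ---------------------------------------------------------------------------


def export_disagreements(
    slide_ids: Sequence[str],
    preds,
    truth: Sequence[int],
    confidences: Sequence[float],
    out: Optional[Path | str] = None,
) -> pd.DataFrame:
    """TSV of slides where prediction != label, with confidences, for a
    second labelling round."""
    y_pred = _as_pred_array(preds)
    y_true = np.asarray(truth, dtype=np.int64)
    frame = pd.DataFrame(
        {
            "slide_id": list(slide_ids),
            "label": y_true,
            "pred": y_pred,
            "confidence": np.asarray(confidences, dtype=np.float64),
        }
    )
    table = frame.loc[frame.label != frame.pred].reset_index(drop=True)
    if out is not None:
        table.to_csv(out, sep="\t", index=False)
    return table


def apply_label_corrections(
    slide_ids: Sequence[str],
    truth: Sequence[int],
    corrections: pd.DataFrame,
) -> np.ndarray:
    """Replace labels per a review table (slide_id, corrected_label).

    Unknown slide ids are an error; the corrected labels feed straight back
    into ``evaluate`` to rectify every metric.
    """
    ids = list(slide_ids)
    index = {sid: i for i, sid in enumerate(ids)}
    corrected = np.asarray(truth, dtype=np.int64).copy()
    for row in corrections.itertuples():
        if row.slide_id not in index:
            raise KeyError(f"corrected-label file references unknown slide "
                           f"{row.slide_id!r}")
        corrected[index[row.slide_id]] = int(row.corrected_label)
    return corrected
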