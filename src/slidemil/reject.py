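"""Percentile-based selective prediction (the reject option).

A grading model deployed as a second-opinion system should refuse the
slides it is least sure about.  Confidence is the predicted-class
probability at the diagnostic tile; given a requested rejection rate r, the
threshold is the empirical r-quantile of all confidences and every slide
with confidence strictly below it is left to the pathologist.

The quantile uses lower interpolation of the inverted CDF
(t = sorted_conf[floor(r * n)]) with strict "<" rejection, so r = 0 rejects
nothing, the rejected fraction never exceeds r + 1/n, and — for distinct
confidences — never falls more than 1/n short of r.  When confidences tie
at the threshold, all tied samples are retained.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class RejectPolicy:
    """A rejection rate with the confidence threshold derived from it."""

    rate: float
    threshold: float
    n: int
    interpolation: str = "lower"

    def rejects(self, confidences: Sequence[float]) -> np.ndarray:
        return np.asarray(confidences, dtype=np.float64) < self.threshold


def reject_threshold(confidences: Sequence[float], r: float) -> RejectPolicy:
    """Threshold = the empirical r-quantile (lower interpolation) of the
    confidence values; samples strictly below it are rejected."""
    conf = np.asarray(confidences, dtype=np.float64)
    if len(conf) == 0:
        raise ValueError("confidences must be non-empty")
    if not (0.0 <= r < 1.0):
        raise ValueError("rejection rate must be in [0, 1)")
    k = int(np.floor(r * len(conf)))
    threshold = float(np.sort(conf)[k])
    return RejectPolicy(rate=float(r), threshold=threshold, n=len(conf))


def accuracy_rejection_curve(
    confidences: Sequence[float],
    correct: Sequence[bool],
    rates: Sequence[float],
) -> pd.DataFrame:
    """Accuracy on the retained samples at each requested rejection rate.

    Returns a frame (rate, threshold, retained_n, rejected_fraction,
    accuracy); a rate retaining zero samples yields NaN accuracy with the
    ``undefined`` flag set.
    """
    conf = np.asarray(confidences, dtype=np.float64)
    flags = np.asarray(correct, dtype=bool)
    if len(conf) != len(flags) or len(conf) == 0:
        raise ValueError("confidences and correctness flags must align")
    rows = []
    for r in rates:
        policy = reject_threshold(conf, float(r))
        keep = ~policy.rejects(conf)
        retained = int(keep.sum())
        rows.append(
            {
                "rate": float(r),
                "threshold": policy.threshold,
                "retained_n": retained,
                "rejected_fraction": 1.0 - retained / len(conf),
                "accuracy": float(flags[keep].mean()) if retained else float("nan"),
                "undefined": retained == 0,
            }
        )
    return pd.DataFrame(rows)
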