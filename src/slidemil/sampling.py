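"""Expected-severity scoring, tile ranking and the one-time top-M bag cut.

A slide is a bag of tiles with a single ordinal label.  Each tile's class
probabilities are collapsed to an expected severity E = sum_i i * y_hat(i)
in [1, K]; ranking a bag by E and keeping the top M tiles (M = 200 at full
scale) shrinks the training set roughly six-fold without discarding the
tiles the weakly-supervised stage would actually learn from.  The cut is
made exactly once — with the supervised model's scores from the first full
inference pass — and bags smaller than M pass through unsampled.

``relevance_loss`` quantifies what a cut throws away: the percentage of
"relevant" tiles (tiles sharing the slide label, plus the current top-n
training tiles) that fall outside the retained set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .scorer import ScorerModel, predict_proba

DEFAULT_M = 200
DEFAULT_N_SELECT = 5
K = 3
_CLASS_INDICES = np.arange(1, K + 1, dtype=np.float64)


@dataclass
class Bag:
    """All tiles of one slide: pixel stack, grid indices, optional labels."""

    slide_id: str
    pixels: np.ndarray  # (n_s, px, px, 3)
    tile_n: np.ndarray  # row-major grid index per tile
    label: Optional[int] = None  # slide label C_s when known
    tile_labels: Optional[np.ndarray] = None  # per-tile classes when annotated

    @property
    def n_tiles(self) -> int:
        return len(self.pixels)


@dataclass
class SampledBag:
    """The frozen top-M subset of a bag, with the scores that fixed it."""

    slide_id: str
    pixels: np.ndarray
    tile_n: np.ndarray
    label: Optional[int]
    scores: np.ndarray  # severity at sampling time, aligned with pixels
    sampling_epoch: int = 1
    tile_labels: Optional[np.ndarray] = None

    @property
    def n_tiles(self) -> int:
        return len(self.pixels)


def expected_severity(probs: np.ndarray) -> np.ndarray:
    """E = sum_{i=1..K} i * y_hat(i), elementwise over rows; range [1, K].

    Accepts a single simplex vector or an (N, K) stack.
    """
    p = np.asarray(probs, dtype=np.float64)
    single = p.ndim == 1
    p = np.atleast_2d(p)
    if p.shape[1] != K:
        raise ValueError(f"expected {K}-class probability vectors")
    if (p < -1e-9).any() or np.abs(p.sum(axis=1) - 1.0).max() > 1e-6:
        raise ValueError("input rows must lie on the probability simplex")
    e = p @ _CLASS_INDICES
    return float(e[0]) if single else e


def severity_order(scores: np.ndarray) -> np.ndarray:
    """Indices sorting scores descending, ties broken by ascending position."""
    scores = np.asarray(scores, dtype=np.float64)
    return np.lexsort((np.arange(len(scores)), -scores))


def rank_bag(model: ScorerModel, bag: Bag | SampledBag) -> np.ndarray:
    """Tile positions of the bag ordered by descending expected severity.

    Ties are broken by ascending tile position, so the ordering is stable
    and deterministic.
    """
    if bag.n_tiles == 0:
        raise ValueError("cannot rank an empty bag")
    scores = expected_severity(predict_proba(model, bag.pixels))
    return severity_order(scores)


def sample_bag(
    model: ScorerModel, bag: Bag, M: int = DEFAULT_M, sampling_epoch: int = 1
) -> SampledBag:
    """Top-k cut: retain the min(M, n_s) most severe tiles of the bag.

    Bags with n_s <= M pass through unsampled (all tiles retained).  The
    retained subset keeps severity order and is frozen after creation.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    if bag.n_tiles == 0:
        raise ValueError(f"empty bag {bag.slide_id!r}")
    scores = expected_severity(predict_proba(model, bag.pixels))
    keep = severity_order(scores)[: min(M, bag.n_tiles)]
    return SampledBag(
        slide_id=bag.slide_id,
        pixels=bag.pixels[keep],
        tile_n=bag.tile_n[keep],
        label=bag.label,
        scores=scores[keep],
        sampling_epoch=sampling_epoch,
        tile_labels=None if bag.tile_labels is None else bag.tile_labels[keep],
    )


def relevance_loss(
    bag: Bag,
    sampled: SampledBag,
    model: ScorerModel,
    top_n: int = DEFAULT_N_SELECT,
) -> float:
    """Percentage of relevant tiles that the sampling cut discards.

    A tile is relevant if it carries the same label as the slide, or if it
    is among the current top-``top_n`` tiles of the full bag's severity
    ranking (i.e. it would be selected for weakly-supervised training).
    Requires per-tile ground-truth labels on the bag.
    """
    if bag.tile_labels is None:
        raise ValueError("relevance_loss needs per-tile labels on the full bag")
    if bag.label is None:
        raise ValueError("relevance_loss needs the slide label")
    order = rank_bag(model, bag)
    relevant = set(np.flatnonzero(bag.tile_labels == bag.label).tolist())
    relevant.update(order[:top_n].tolist())
    if not relevant:
        warnings.warn("no relevant tiles in bag; relevance loss defined as 0%")
        return 0.0
    retained = set(np.searchsorted(bag.tile_n, sampled.tile_n).tolist())
    # tile_n is sorted ascending within a bag (row-major extraction order)
    lost = relevant - retained
    return 100.0 * len(lost) / len(relevant)


def sampling_cap(n_slides: int, M: int = DEFAULT_M) -> int:
    """Upper bound on the cohort-wide tile count after the top-M cut:
    sum_s min(M, n_s) <= M * n_slides."""
    return int(M) * int(n_slides)
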