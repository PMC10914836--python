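"""Two-stage weakly supervised training and slide-level prediction.

Each MIL epoch has two stages: (a) severity analysis — the current model
scores every tile of every bag (the full bags in epoch 1, the frozen top-M
sampled bags thereafter); (b) training — the ``n_select`` most severe tiles
of each bag are trained for one epoch of cross-entropy with the slide label
as every selected tile's target.  The sampling cut is executed exactly once,
from epoch 1's inference scores, and never refreshed.

Slide-level prediction supports two aggregation rules that the ordinal MIL
formulation admits:

* ``top_tile`` (default, used for validation/evaluation): the diagnostic
  tile is the one with the highest expected severity; the slide class is
  that tile's argmax class.
* ``hard_max``: the slide class is the maximum over per-tile argmax classes
  — the literal "most severe tile label" definition.

The two can disagree (a tile may top the expected-severity ranking while
another tile's argmax class is higher); both are exposed.  No sampling is
ever applied at prediction time.

An optional aggregation head concatenates the scorer's hidden features of
the seven most severe tiles (padding by repeating the most severe tile for
smaller bags) and feeds them to a one-hidden-layer MLP.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from . import tessellation
from .sampling import (
    Bag,
    SampledBag,
    DEFAULT_M,
    DEFAULT_N_SELECT,
    expected_severity,
    sample_bag,
    severity_order,
)
from .scorer import (
    MLP,
    ScorerModel,
    DEFAULT_BATCH_SIZE,
    DEFAULT_LR,
    hidden_features,
    predict_proba,
    tile_features,
)
from .synthetic import CohortManifest

UNCLASSIFIABLE = 0  # distinct from every class index
AGG_N_TILES = 7


@dataclass
class SlidePrediction:
    """Slide class with its provenance: the diagnostic tile, the predicted-
    class probability at that tile, and the full per-tile map."""

    slide_id: str
    pred: int  # 1..3, or UNCLASSIFIABLE for an empty bag
    diagnostic_tile: Optional[int]  # grid index n of the diagnostic tile
    confidence: float
    rule: str
    tile_classes: Optional[np.ndarray] = None
    tile_probs: Optional[np.ndarray] = None
    tile_n: Optional[np.ndarray] = None


@dataclass
class TrainingHistory:
    """Per-epoch validation metrics and the best-checkpoint selector state."""

    records: pd.DataFrame
    best_epoch: int
    select_metric: str


def predict_slide(
    model: ScorerModel, bag: Bag | SampledBag, rule: str = "top_tile"
) -> SlidePrediction:
    """Aggregate per-tile outputs into one slide prediction (no sampling)."""
    if rule not in ("top_tile", "hard_max"):
        raise ValueError(f"unknown rule {rule!r}")
    if bag.n_tiles == 0:
        return SlidePrediction(
            slide_id=bag.slide_id, pred=UNCLASSIFIABLE, diagnostic_tile=None,
            confidence=float("nan"), rule=rule,
        )
    probs = predict_proba(model, bag.pixels)
    tile_classes = probs.argmax(axis=1) + 1
    if rule == "top_tile":
        j = int(severity_order(expected_severity(probs))[0])
        pred = int(tile_classes[j])
    else:
        pred = int(tile_classes.max())
        candidates = np.flatnonzero(tile_classes == pred)
        j = int(candidates[np.argmax(probs[candidates, pred - 1])])
    return SlidePrediction(
        slide_id=bag.slide_id,
        pred=pred,
        diagnostic_tile=int(bag.tile_n[j]),
        confidence=float(probs[j, pred - 1]),
        rule=rule,
        tile_classes=tile_classes,
        tile_probs=probs,
        tile_n=np.asarray(bag.tile_n),
    )


def _select_training_tiles(
    probs: np.ndarray, n_select: int
) -> np.ndarray:
    """Positions of the top-n_select tiles by expected severity."""
    order = severity_order(expected_severity(probs))
    return order[: min(n_select, len(order))]


def _validation_metrics(
    model: ScorerModel, bags: Sequence[Bag | SampledBag], rule: str
) -> tuple[float, float]:
    from .stats import quadratic_weighted_kappa  # local import to avoid cycle

    truth, preds = [], []
    for bag in bags:
        if bag.label is None or bag.n_tiles == 0:
            continue
        truth.append(bag.label)
        preds.append(predict_slide(model, bag, rule=rule).pred)
    truth_a, preds_a = np.asarray(truth), np.asarray(preds)
    acc = float((truth_a == preds_a).mean()) if len(truth_a) else float("nan")
    qwk = quadratic_weighted_kappa(truth_a, preds_a)
    return acc, qwk


def mil_train(
    model: ScorerModel,
    train_bags: Sequence[Bag],
    val_bags: Sequence[Bag],
    *,
    epochs: int = 10,
    n_select: int = DEFAULT_N_SELECT,
    M: Optional[int] = DEFAULT_M,
    seed: int = 0,
    lr: float = DEFAULT_LR,
    weight_decay: float = 0.0,
    batch_size: int = DEFAULT_BATCH_SIZE,
    sample_validation: bool = True,
    rule: str = "top_tile",
    select_metric: str = "accuracy",
) -> tuple[ScorerModel, TrainingHistory]:
    """Weakly-supervised training loop on slide-labelled bags.

    ``M=None`` disables sampling entirely (every epoch runs on the full
    bags).  The best checkpoint maximises validation accuracy, ties broken
    by QWK.  Deterministic under fixed seed and configuration.
    """
    if n_select < 1:
        raise ValueError("n_select must be >= 1")
    usable = []
    for bag in train_bags:
        if bag.n_tiles == 0:
            warnings.warn(f"skipping empty bag {bag.slide_id!r}")
        elif bag.label is None:
            warnings.warn(f"skipping unlabelled bag {bag.slide_id!r}")
        else:
            usable.append(bag)
    if not usable:
        raise ValueError("no usable training bags")

    model = model.copy()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 303]))
    current_train: list[Bag | SampledBag] = list(usable)
    current_val: list[Bag | SampledBag] = list(val_bags)
    best = None  # (acc, qwk, epoch, model copy)
    rows = []
    for epoch in range(1, epochs + 1):
        # stage (a): severity analysis over the current tile sets
        bag_probs = [predict_proba(model, b.pixels) for b in current_train]
        if epoch == 1 and M is not None:
            # one-time top-M cut with the same (supervised) model used for
            # this epoch's severity analysis
            current_train = [sample_bag(model, b, M) for b in usable]
            if sample_validation:
                current_val = [
                    sample_bag(model, b, M) if b.n_tiles else b for b in val_bags
                ]
        # stage (b): train one epoch on the n_select most severe tiles per bag
        xs, ys = [], []
        for bag, probs in zip(usable if epoch == 1 else current_train, bag_probs):
            sel = _select_training_tiles(probs, n_select)
            xs.append(tile_features(bag.pixels[sel]))
            ys.append(np.full(len(sel), bag.label - 1, dtype=np.int64))
        X, y = np.concatenate(xs), np.concatenate(ys)
        loss = model.mlp.train_epoch(X, y, rng, lr, weight_decay, batch_size)
        model.epochs_trained += 1
        val_acc, val_qwk = _validation_metrics(model, current_val, rule)
        rows.append(
            {"epoch": epoch, "train_loss": loss,
             "val_accuracy": val_acc, "val_qwk": val_qwk}
        )
        key = (
            -np.inf if np.isnan(val_acc) else val_acc,
            -np.inf if np.isnan(val_qwk) else val_qwk,
        )
        if best is None or key > best[0]:
            best = (key, epoch, model.copy())

    history = TrainingHistory(
        records=pd.DataFrame(rows), best_epoch=best[1], select_metric=select_metric
    )
    return best[2], history


# ---------------------------------------------------------------------------
# Optional 7-tile aggregation head
# ---------------------------------------------------------------------------


@dataclass
class AggregationHead:
    """MLP over the concatenated hidden features of the 7 most severe tiles."""

    mlp: MLP
    n_tiles: int = AGG_N_TILES
    feature_dim: int = 0


def _aggregation_features(
    model: ScorerModel, bag: Bag | SampledBag, n_tiles: int = AGG_N_TILES
) -> np.ndarray:
    """Concatenated hidden features in severity order; bags smaller than
    ``n_tiles`` are padded by repeating the most severe tile."""
    if bag.n_tiles == 0:
        raise ValueError("cannot featurise an empty bag")
    probs = predict_proba(model, bag.pixels)
    order = severity_order(expected_severity(probs))[:n_tiles]
    if len(order) < n_tiles:
        order = np.concatenate(
            [order, np.full(n_tiles - len(order), order[0], dtype=order.dtype)]
        )
    feats = hidden_features(model, bag.pixels[order])
    return feats.reshape(-1)


def fit_aggregation_head(
    model: ScorerModel,
    bags: Sequence[Bag],
    *,
    epochs: int = 50,
    lr: float = 1e-2,
    seed: int = 0,
    batch_size: int = DEFAULT_BATCH_SIZE,
) -> AggregationHead:
    """Train the head on frozen scorer features with slide labels as targets."""
    labelled = [b for b in bags if b.label is not None and b.n_tiles > 0]
    if not labelled:
        raise ValueError("no labelled bags to train the aggregation head")
    X = np.stack([_aggregation_features(model, b) for b in labelled])
    y = np.asarray([b.label - 1 for b in labelled], dtype=np.int64)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 404]))
    hidden = X.shape[1]  # one hidden layer, width = feature dim
    mlp = MLP.init(X.shape[1], hidden, 3, rng)
    for _ in range(epochs):
        mlp.train_epoch(X, y, rng, lr, 0.0, batch_size)
    return AggregationHead(mlp=mlp, feature_dim=X.shape[1])


def aggregation_predict(
    model: ScorerModel, head: AggregationHead, bag: Bag | SampledBag
) -> SlidePrediction:
    """Slide class from the head's softmax over the 7-tile feature vector."""
    feats = _aggregation_features(model, bag, head.n_tiles)
    if len(feats) != head.feature_dim:
        raise ValueError(
            f"feature dimension {len(feats)} does not match head {head.feature_dim}"
        )
    _, probs = head.mlp.forward(feats[None, :])
    pred = int(probs[0].argmax()) + 1
    order = severity_order(expected_severity(predict_proba(model, bag.pixels)))
    return SlidePrediction(
        slide_id=bag.slide_id,
        pred=pred,
        diagnostic_tile=int(bag.tile_n[order[0]]),
        confidence=float(probs[0, pred - 1]),
        rule="aggregation",
    )


# ---------------------------------------------------------------------------
# Cohort loading: manifest -> bags
# ---------------------------------------------------------------------------


def bags_from_manifest(
    manifest: CohortManifest,
    split: Optional[str] = None,
    *,
    tile_px: Optional[int] = None,
    downsample_factor: Optional[int] = None,
    tissue_threshold: float = tessellation.DEFAULT_TISSUE_THRESHOLD,
    with_planted_labels: bool = False,
) -> list[Bag]:
    """Tessellate every slide of a manifest (optionally one split) into bags.

    Per-tile labels are attached from each slide's annotation mask when one
    exists; ``with_planted_labels=True`` additionally reads every slide's
    planted labels (synthetic ground truth) for relevance diagnostics, by
    regenerating the cell layout from the cohort spec.
    """
    frame = manifest.frame if split is None else manifest.subset(split)
    spec = manifest.spec
    tile_px = tile_px or spec.tile_px
    factor = downsample_factor or min(tessellation.DEFAULT_DOWNSAMPLE, tile_px)
    bags = []
    for row in frame.itertuples():
        img = np.asarray(Image.open(manifest.root / row.image).convert("RGB"))
        mask = tessellation.slide_tissue_mask(img, factor)
        records = tessellation.extract_tiles(
            img, mask, tile_px, tissue_threshold, slide_id=row.slide_id
        )
        mask_rel = getattr(row, "mask")
        if mask_rel:
            label_mask = np.asarray(Image.open(manifest.root / mask_rel))
            tessellation.annotate_tiles(records, label_mask)
        elif with_planted_labels:
            from .synthetic import _plant_slide  # synthetic ground truth

            i = int(row.slide_id.split("_")[-1])
            rng = np.random.default_rng(np.random.SeedSequence([spec.seed, i]))
            cells = _plant_slide(spec, int(row.label), rng)
            planted = np.kron(
                cells, np.ones((spec.tile_px, spec.tile_px), dtype=np.uint8)
            )
            tessellation.annotate_tiles(records, planted)
        tile_labels = None
        if records and all(r.label is not None for r in records):
            tile_labels = np.asarray([r.label for r in records], dtype=np.int64)
        bags.append(
            Bag(
                slide_id=row.slide_id,
                pixels=tessellation.tile_pixels(img, records),
                tile_n=np.asarray([r.n for r in records], dtype=np.int64),
                label=int(row.label),
                tile_labels=tile_labels,
            )
        )
    return bags


def annotated_tiles(bags: Sequence[Bag]) -> tuple[np.ndarray, np.ndarray]:
    """Pool (tiles, labels) from every bag carrying per-tile annotations."""
    xs, ys = [], []
    for bag in bags:
        if bag.tile_labels is not None and bag.n_tiles:
            xs.append(bag.pixels)
            ys.append(bag.tile_labels)
    if not xs:
        raise ValueError("no annotated tiles in the given bags")
    return np.concatenate(xs), np.concatenate(ys)
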