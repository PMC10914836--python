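"""The trainable tile classifier Phi: tile image -> class probabilities.

The backbone is deliberately small: each tile is reduced to an 8x8 RGB
summary by block averaging (192 features in [0, 1]) and fed to a one-hidden-
layer MLP trained with Adam on the cross-entropy.  At desk scale this
separates the synthetic appearance classes in seconds on one CPU while
keeping every contract a larger backbone would honour: probability outputs
on the 3-simplex, batch-size invariance, exact save/load round-trips, and
fully deterministic training under a fixed seed.

The hidden-layer activations double as the per-tile feature vector consumed
by the 7-tile aggregation head.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

CLASS_ORDER = (1, 2, 3)  # NNeo, LG, HG
FEATURE_PX = 8
DEFAULT_HIDDEN = 32
DEFAULT_LR = 5e-3
DEFAULT_WEIGHT_DECAY = 3e-4
DEFAULT_BATCH_SIZE = 32
DEFAULT_EPOCHS = 40


# ---------------------------------------------------------------------------
# Generic one-hidden-layer MLP with Adam (shared with the aggregation head)
# ---------------------------------------------------------------------------


@dataclass
class MLP:
    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    adam_m: dict = field(default_factory=dict)
    adam_v: dict = field(default_factory=dict)
    adam_t: int = 0

    @classmethod
    def init(cls, in_dim: int, hidden: int, out_dim: int, rng: np.random.Generator):
        return cls(
            W1=rng.normal(0.0, np.sqrt(2.0 / in_dim), size=(in_dim, hidden)),
            b1=np.zeros(hidden),
            W2=rng.normal(0.0, np.sqrt(2.0 / hidden), size=(hidden, out_dim)),
            b2=np.zeros(out_dim),
        )

    def forward(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (hidden activations, class probabilities)."""
        h = np.maximum(X @ self.W1 + self.b1, 0.0)
        logits = h @ self.W2 + self.b2
        logits = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        return h, e / e.sum(axis=1, keepdims=True)

    def _adam_step(self, grads: dict, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.adam_t += 1
        for name, g in grads.items():
            m = self.adam_m.setdefault(name, np.zeros_like(g))
            v = self.adam_v.setdefault(name, np.zeros_like(g))
            m[:] = beta1 * m + (1 - beta1) * g
            v[:] = beta2 * v + (1 - beta2) * g * g
            m_hat = m / (1 - beta1**self.adam_t)
            v_hat = v / (1 - beta2**self.adam_t)
            p = getattr(self, name)
            p -= lr * m_hat / (np.sqrt(v_hat) + eps)

    def train_epoch(
        self,
        X: np.ndarray,
        y_index: np.ndarray,
        rng: np.random.Generator,
        lr: float,
        weight_decay: float = 0.0,
        batch_size: int = DEFAULT_BATCH_SIZE,
    ) -> float:
        """One shuffled pass of cross-entropy minimisation; returns mean loss."""
        order = rng.permutation(len(X))
        total, seen = 0.0, 0
        for start in range(0, len(X), batch_size):
            idx = order[start : start + batch_size]
            xb, yb = X[idx], y_index[idx]
            h, p = self.forward(xb)
            loss = -np.log(np.clip(p[np.arange(len(idx)), yb], 1e-12, None)).mean()
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at Adam step {self.adam_t}"
                )
            total += loss * len(idx)
            seen += len(idx)
            d_logits = p.copy()
            d_logits[np.arange(len(idx)), yb] -= 1.0
            d_logits /= len(idx)
            gW2 = h.T @ d_logits + weight_decay * self.W2
            gb2 = d_logits.sum(axis=0)
            dh = (d_logits @ self.W2.T) * (h > 0)
            gW1 = xb.T @ dh + weight_decay * self.W1
            gb1 = dh.sum(axis=0)
            self._adam_step({"W1": gW1, "b1": gb1, "W2": gW2, "b2": gb2}, lr)
        return total / max(seen, 1)

    def copy(self) -> "MLP":
        return MLP(
            W1=self.W1.copy(), b1=self.b1.copy(),
            W2=self.W2.copy(), b2=self.b2.copy(),
            adam_m={k: v.copy() for k, v in self.adam_m.items()},
            adam_v={k: v.copy() for k, v in self.adam_v.items()},
            adam_t=self.adam_t,
        )


# ---------------------------------------------------------------------------
# Tile featurisation and the scorer model
# ---------------------------------------------------------------------------


def tile_features(tiles: np.ndarray) -> np.ndarray:
    """(N, px, px, 3) uint8 tiles -> (N, 192) block-mean features in [0, 1].

    Requires tile_px to be a multiple of 8 (all supported tile sizes are).
    """
    tiles = np.asarray(tiles)
    if tiles.ndim != 4 or tiles.shape[3] != 3 or tiles.shape[1] != tiles.shape[2]:
        raise ValueError("expected tiles of shape (N, px, px, 3)")
    px = tiles.shape[1]
    if px % FEATURE_PX != 0:
        raise ValueError(f"tile_px={px} must be a multiple of {FEATURE_PX}")
    b = px // FEATURE_PX
    n = tiles.shape[0]
    x = tiles.reshape(n, FEATURE_PX, b, FEATURE_PX, b, 3).mean(axis=(2, 4))
    return (x / 255.0).reshape(n, FEATURE_PX * FEATURE_PX * 3)


@dataclass
class ScorerModel:
    """Trained tile classifier Phi (opaque parameter state + metadata)."""

    mlp: MLP
    tile_px: int
    seed: int
    epochs_trained: int = 0
    backbone: str = "blockmean8-mlp"
    class_order: tuple[int, ...] = CLASS_ORDER
    loss_history: list = field(default_factory=list)

    def copy(self) -> "ScorerModel":
        return ScorerModel(
            mlp=self.mlp.copy(), tile_px=self.tile_px, seed=self.seed,
            epochs_trained=self.epochs_trained, backbone=self.backbone,
            class_order=self.class_order, loss_history=list(self.loss_history),
        )


def supervised_fit(
    tiles: np.ndarray,
    labels: Sequence[int],
    *,
    epochs: int = DEFAULT_EPOCHS,
    lr: float = DEFAULT_LR,
    weight_decay: float = DEFAULT_WEIGHT_DECAY,
    batch_size: int = DEFAULT_BATCH_SIZE,
    hidden: int = DEFAULT_HIDDEN,
    seed: int = 0,
    checkpoint_dir: Optional[Path] = None,
    checkpoint_every: Optional[int] = None,
) -> ScorerModel:
    """Supervised pre-training on annotated tiles (labels in {1,2,3}).

    Training is deterministic under a fixed seed: initialisation, batch
    shuffling and every Adam step derive from ``seed`` alone.  Optionally
    writes a checkpoint every ``checkpoint_every`` epochs.
    """
    tiles = np.asarray(tiles)
    labels = np.asarray(labels, dtype=np.int64)
    if len(tiles) == 0 or len(tiles) != len(labels):
        raise ValueError("need a non-empty, aligned set of tiles and labels")
    bad = set(labels.tolist()) - set(CLASS_ORDER)
    if bad:
        raise ValueError(f"labels outside {{1,2,3}}: {sorted(bad)}")
    X = tile_features(tiles)
    y = labels - 1
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    model = ScorerModel(
        mlp=MLP.init(X.shape[1], hidden, len(CLASS_ORDER), rng),
        tile_px=int(tiles.shape[1]),
        seed=seed,
    )
    train_rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
    for epoch in range(1, epochs + 1):
        loss = model.mlp.train_epoch(X, y, train_rng, lr, weight_decay, batch_size)
        model.loss_history.append(loss)
        model.epochs_trained = epoch
        if checkpoint_dir and checkpoint_every and epoch % checkpoint_every == 0:
            save_model(model, Path(checkpoint_dir) / f"scorer_epoch{epoch:03d}")
    return model


def predict_proba(model: ScorerModel, tiles: np.ndarray) -> np.ndarray:
    """Per-tile probability vectors on the 3-simplex, shape (N, 3).

    Pure function of (model, tile): batching does not change values.
    """
    tiles = np.asarray(tiles)
    if len(tiles) == 0:
        raise ValueError("empty tile batch")
    if tiles.shape[1] != model.tile_px:
        raise ValueError(
            f"tile size {tiles.shape[1]} does not match model tile_px {model.tile_px}"
        )
    _, probs = model.mlp.forward(tile_features(tiles))
    return probs


def hidden_features(model: ScorerModel, tiles: np.ndarray) -> np.ndarray:
    """Hidden-layer activations per tile (the aggregation head's features)."""
    h, _ = model.mlp.forward(tile_features(np.asarray(tiles)))
    return h


def save_model(model: ScorerModel, path: Path | str) -> Path:
    """Write ``<path>.npz`` (parameters) and ``<path>.json`` (metadata)."""
    path = Path(path)
    np.savez(
        path.with_suffix(".npz"),
        W1=model.mlp.W1, b1=model.mlp.b1, W2=model.mlp.W2, b2=model.mlp.b2,
    )
    meta = {
        "backbone": model.backbone,
        "class_order": list(model.class_order),
        "tile_px": model.tile_px,
        "seed": model.seed,
        "epochs_trained": model.epochs_trained,
    }
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(meta, fh, indent=2)
        fh.write("\n")
    return path.with_suffix(".npz")


def load_model(path: Path | str) -> ScorerModel:
    path = Path(path)
    arrays = np.load(path.with_suffix(".npz"))
    with open(path.with_suffix(".json")) as fh:
        meta = json.load(fh)
    return ScorerModel(
        mlp=MLP(W1=arrays["W1"], b1=arrays["b1"], W2=arrays["W2"], b2=arrays["b2"]),
        tile_px=int(meta["tile_px"]),
        seed=int(meta["seed"]),
        epochs_trained=int(meta["epochs_trained"]),
        backbone=meta["backbone"],
        class_order=tuple(meta["class_order"]),
    )
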