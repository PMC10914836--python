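"""Synthetic slide cohorts with planted tile-level classes.

Real whole-slide cohorts of colorectal samples are gigapixel images with
slide-level grades (non-neoplastic / low-grade / high-grade dysplasia) and
spatial annotations on only a small fraction of slides.  This module emulates
that structure at desk scale: each synthetic slide is a grid of square cells,
some rendered as saturation-poor near-white background and the rest as
"tissue" tiles drawn from class-conditional appearance recipes.  The slide
label is, by construction, the maximum planted tile label — the ordinal
multiple-instance assumption every downstream stage relies on.

The appearance recipes are a stand-in, not a histology simulation: each class
shifts the mean tile colour along one monotone axis (darker and more purple
with increasing severity, loosely mimicking haematoxylin-dense dysplastic
epithelium), scaled by a ``separability`` knob.  At ``separability=0`` the
three classes are indistinguishable; at 1 a per-tile mean-intensity threshold
already separates them almost perfectly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from PIL import Image

NNEO, LG, HG = 1, 2, 3
CLASS_NAMES = {NNEO: "NNeo", LG: "LG", HG: "HG"}
SPLITS = ("train", "val", "test")

# Tissue appearance: eosin-pink base, shifted darker/more purple per severity
# step.  Background stays near-white with HSV saturation < 0.05 so the
# Otsu-on-saturation mask separates it cleanly.
_BASE_RGB = np.array([205.0, 150.0, 185.0])
_CLASS_STEP = np.array([28.0, 22.0, 6.0])
_TEXTURE_SD = 14.0


class CohortSpecError(ValueError):
    """A CohortSpec field is outside its valid range."""


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    Defaults are the desk-scale study conditions used throughout the test
    suite: 150 slides on 8x8 grids of 32 px tiles, slide-class frequencies
    matching a large colorectal cohort (16.6 % NNeo, 51.3 % LG, 32.1 % HG),
    9 % of slides carrying tile-level annotation masks.
    """

    n_slides: int = 150
    grid_rows: int = 8
    grid_cols: int = 8
    tile_px: int = 32
    class_mix: tuple[float, float, float] = (0.166, 0.513, 0.321)
    lesion_fraction: float = 0.3
    background_fraction: float = 0.25
    separability: float = 0.8
    annotated_fraction: float = 0.09
    split_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    seed: int = 0

    def validate(self) -> None:
        if self.n_slides < 1:
            raise CohortSpecError("n_slides must be >= 1")
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise CohortSpecError("grid_rows/grid_cols must be >= 1")
        if self.tile_px < 8:
            raise CohortSpecError("tile_px must be >= 8")
        if len(self.class_mix) != 3 or any(p < 0 for p in self.class_mix):
            raise CohortSpecError("class_mix must be 3 non-negative frequencies")
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise CohortSpecError("class_mix must sum to 1")
        if not (0.0 < self.lesion_fraction <= 1.0):
            raise CohortSpecError("lesion_fraction must be in (0, 1]")
        if not (0.0 <= self.background_fraction < 1.0):
            raise CohortSpecError("background_fraction must be in [0, 1)")
        if not (0.0 <= self.separability <= 1.0):
            raise CohortSpecError("separability must be in [0, 1]")
        if not (0.0 <= self.annotated_fraction <= 1.0):
            raise CohortSpecError("annotated_fraction must be in [0, 1]")
        if len(self.split_fractions) != 3 or abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise CohortSpecError("split_fractions must be 3 values summing to 1")


@dataclass
class CohortManifest:
    """Per-slide table (slide_id, image, mask, label, split) plus its root dir."""

    frame: pd.DataFrame
    root: Path
    spec: CohortSpec

    def image_path(self, slide_id: str) -> Path:
        row = self.frame.loc[self.frame.slide_id == slide_id].iloc[0]
        return self.root / row.image

    def mask_path(self, slide_id: str) -> Optional[Path]:
        row = self.frame.loc[self.frame.slide_id == slide_id].iloc[0]
        return self.root / row["mask"] if row["mask"] else None

    def subset(self, split: str) -> pd.DataFrame:
        return self.frame.loc[self.frame.split == split].reset_index(drop=True)

    @classmethod
    def read(cls, root: Path | str) -> "CohortManifest":
        root = Path(root)
        frame = pd.read_csv(root / "cohort.tsv", sep="\t", keep_default_na=False)
        with open(root / "cohort_spec.json") as fh:
            raw = json.load(fh)
        for key in ("class_mix", "split_fractions"):
            raw[key] = tuple(raw[key])
        return cls(frame=frame, root=root, spec=CohortSpec(**raw))


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def render_tile(
    class_index: int,
    tile_px: int,
    rng: np.random.Generator,
    separability: float = 0.8,
) -> np.ndarray:
    """Draw one tissue tile (uint8 RGB) from the class-conditional recipe.

    The class shifts the mean colour by ``(class_index - 1) * separability``
    steps along a fixed axis; pixel texture is i.i.d. Gaussian noise.  The
    mean channel statistics are therefore strictly monotone in the class
    whenever separability > 0, and class-blind at separability = 0.
    """
    if class_index not in (NNEO, LG, HG):
        raise ValueError(f"class_index must be in {{1,2,3}}, got {class_index}")
    mean = _BASE_RGB - (class_index - 1) * separability * _CLASS_STEP
    img = rng.normal(loc=mean, scale=_TEXTURE_SD, size=(tile_px, tile_px, 3))
    return np.clip(img, 0, 255).astype(np.uint8)


def render_background(tile_px: int, rng: np.random.Generator) -> np.ndarray:
    """Near-white, saturation-poor background cell (HSV V>0.9, S<0.05)."""
    gray = rng.uniform(240.0, 253.0, size=(tile_px, tile_px, 1))
    jitter = rng.uniform(-2.0, 2.0, size=(tile_px, tile_px, 3))
    return np.clip(gray + jitter, 0, 255).astype(np.uint8)


def _plant_slide(
    spec: CohortSpec, slide_class: int, rng: np.random.Generator
) -> np.ndarray:
    """Plant per-cell labels (0=background, 1..3=tissue class) for one slide.

    Every LG/HG slide receives at least one cell of its own class and none of
    a higher class; NNeo slides are entirely NNeo tissue (plus background).
    """
    n_cells = spec.grid_rows * spec.grid_cols
    labels = np.full(n_cells, NNEO, dtype=np.uint8)
    n_bg = min(_round_half_up(spec.background_fraction * n_cells), n_cells - 1)
    cells = rng.permutation(n_cells)
    bg_cells, tissue_cells = cells[:n_bg], cells[n_bg:]
    labels[bg_cells] = 0
    if slide_class > NNEO:
        n_lesion = max(1, _round_half_up(spec.lesion_fraction * len(tissue_cells)))
        lesion_cells = rng.choice(tissue_cells, size=n_lesion, replace=False)
        labels[lesion_cells] = slide_class
        rest = np.setdiff1d(tissue_cells, lesion_cells)
        if slide_class == HG and len(rest):
            # non-lesion tissue on HG slides mixes the two lower grades
            labels[rest] = rng.choice([NNEO, LG], size=len(rest))
    return labels.reshape(spec.grid_rows, spec.grid_cols)


def _render_slide(
    spec: CohortSpec, cell_labels: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    h = spec.grid_rows * spec.tile_px
    w = spec.grid_cols * spec.tile_px
    img = np.empty((h, w, 3), dtype=np.uint8)
    t = spec.tile_px
    for r in range(spec.grid_rows):
        for c in range(spec.grid_cols):
            lab = int(cell_labels[r, c])
            tile = (
                render_background(t, rng)
                if lab == 0
                else render_tile(lab, t, rng, spec.separability)
            )
            img[r * t : (r + 1) * t, c * t : (c + 1) * t] = tile
    return img


def _assign_splits(
    slide_classes: np.ndarray, fractions: Sequence[float], rng: np.random.Generator
) -> np.ndarray:
    """Stratified disjoint train/val/test assignment."""
    split = np.empty(len(slide_classes), dtype=object)
    for k in (NNEO, LG, HG):
        idx = np.flatnonzero(slide_classes == k)
        if len(idx) == 0:
            continue
        idx = rng.permutation(idx)
        n = len(idx)
        n_train = _round_half_up(fractions[0] * n)
        n_val = _round_half_up(fractions[1] * n)
        n_val = min(n_val, n - n_train)
        split[idx[:n_train]] = "train"
        split[idx[n_train : n_train + n_val]] = "val"
        split[idx[n_train + n_val :]] = "test"
    return split


def _choose_annotated(
    train_idx: np.ndarray,
    slide_classes: np.ndarray,
    n_ann: int,
    rng: np.random.Generator,
) -> set[int]:
    """Pick the annotated slides from the training split, stratified so the
    supervised stage sees every slide class present in training (annotated
    cohorts cover all grades in practice)."""
    if n_ann == 0:
        return set()
    by_class = {
        k: rng.permutation(train_idx[slide_classes[train_idx] == k])
        for k in (NNEO, LG, HG)
        if (slide_classes[train_idx] == k).any()
    }
    chosen: list[int] = []
    # round-robin over classes, most frequent first, until n_ann slides
    order = sorted(by_class, key=lambda k: -len(by_class[k]))
    cursors = {k: 0 for k in by_class}
    while len(chosen) < n_ann:
        progressed = False
        for k in order:
            if len(chosen) >= n_ann:
                break
            if cursors[k] < len(by_class[k]):
                chosen.append(int(by_class[k][cursors[k]]))
                cursors[k] += 1
                progressed = True
        if not progressed:
            break
    return set(chosen)


def generate_cohort(spec: CohortSpec, out_dir: Path | str) -> CohortManifest:
    """Generate images, masks and a manifest TSV under ``out_dir``.

    Regeneration with the same spec is byte-identical: slide-level randomness
    is drawn from a stream seeded by (cohort seed, slide index), independent
    of generation order, and cohort-level choices (slide classes, splits,
    which slides are annotated) come from a separate fixed stream.
    """
    spec.validate()
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)

    cohort_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2**20]))
    slide_classes = cohort_rng.choice(
        [NNEO, LG, HG], size=spec.n_slides, p=np.asarray(spec.class_mix)
    )
    splits = _assign_splits(slide_classes, spec.split_fractions, cohort_rng)

    n_ann = _round_half_up(spec.annotated_fraction * spec.n_slides)
    train_idx = np.flatnonzero(splits == "train")
    if n_ann > len(train_idx):
        raise CohortSpecError(
            f"annotated_fraction requests {n_ann} annotated slides but the "
            f"training split holds only {len(train_idx)}"
        )
    annotated = _choose_annotated(train_idx, slide_classes, n_ann, cohort_rng)

    rows = []
    for i in range(spec.n_slides):
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, i]))
        cells = _plant_slide(spec, int(slide_classes[i]), rng)
        tissue = cells[cells > 0]
        label = int(tissue.max()) if tissue.size else NNEO
        assert label == int(slide_classes[i])
        img = _render_slide(spec, cells, rng)
        sid = f"slide_{i:04d}"
        img_rel = f"images/{sid}.png"
        Image.fromarray(img).save(out_dir / img_rel)
        mask_rel = ""
        if i in annotated:
            mask = np.kron(cells, np.ones((spec.tile_px, spec.tile_px), dtype=np.uint8))
            mask_rel = f"masks/{sid}.png"
            Image.fromarray(mask, mode="L").save(out_dir / mask_rel)
        rows.append(
            {"slide_id": sid, "image": img_rel, "mask": mask_rel,
             "label": label, "split": splits[i]}
        )

    frame = pd.DataFrame(rows, columns=["slide_id", "image", "mask", "label", "split"])
    frame.to_csv(out_dir / "cohort.tsv", sep="\t", index=False)
    with open(out_dir / "cohort_spec.json", "w") as fh:
        json.dump(asdict(spec), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return CohortManifest(frame=frame, root=out_dir, spec=spec)
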