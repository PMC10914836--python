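# slidemil

Mixed-supervision ordinal multiple-instance learning (MIL) for grading
whole-slide images (WSI) into **non-neoplastic (NNeo)**, **low-grade (LG)**
and **high-grade (HG)** dysplasia — the workflow used for computer-aided
colorectal sample diagnosis, runnable end-to-end at desk scale on synthetic
cohorts.

It is written for people who build or study weakly-supervised pathology
pipelines: every stage is an importable, deterministic, tested component,
and a built-in synthetic-cohort generator makes the whole system
exercisable without any slide downloads, GPUs or external data.

## The model

A slide `S_s` is a bag of tiles `T_{s,n}` with one ordinal label equal to
the most severe tile label, `C_s = max_n C_{s,n}`.  A tile classifier `Φ`
outputs class probabilities `ŷ_{s,n}` over (NNeo, LG, HG); tiles are ranked
by the **expected severity**

    E(Ĉ_{s,n}) = Σ_{i=1..K} i · ŷ_{s,n}(i),  K = 3.

Training mixes supervision: `Φ` is first fit on the ~9 % of slides with
tile-level annotations, then trained weakly from slide labels — each epoch
scores all tiles, takes the 5 most severe per bag, and trains them with the
slide label as target.  After the first epoch each bag is cut **once** to
its top-`M` tiles (`M = 200` at full scale), shrinking the tile stream
roughly six-fold without changing what the training stage would select.
At evaluation the most severe tile alone grades the slide, and its
predicted-class probability is the slide confidence, which drives a
percentile-threshold **reject option** for second-opinion use.

The statistics suite reports accuracy / binary accuracy / sensitivity /
quadratic weighted kappa with normal-approximation binomial confidence
intervals (`SE = sqrt(m(1−m)/n)`, half-width `1.96·SE`), McNemar's
continuity-corrected paired test (`X² = (|b−c|−1)²/(b+c)`, significant
above 3.841), precision-recall curves, confidence-density analysis and a
disagreement-export / label-correction round trip.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

```python
import numpy as np, slidemil as sm

# 150 synthetic slides on 8x8 grids, 9% annotated, stratified splits
manifest = sm.generate_cohort(sm.CohortSpec(seed=0), "cohort/")
bags = {s: sm.bags_from_manifest(manifest, s) for s in ("train", "val", "test")}

tiles, labels = sm.annotated_tiles(bags["train"])        # supervised subset
model = sm.supervised_fit(tiles, labels, seed=0)          # pre-train Phi

best, history = sm.mil_train(model, bags["train"], bags["val"],
                             epochs=10, M=24, seed=0)     # weak supervision
preds = [sm.predict_slide(best, b) for b in bags["test"]]
report = sm.evaluate(preds, [b.label for b in bags["test"]])
print(report.to_text())
```

Output:

```
n = 30
accuracy         100.00% ± 0.00
binary accuracy  100.00% ± 0.00  (NNeo vs all)
sensitivity      1.000 ± 0.000  (LG+HG vs NNeo)
QWK              1.000
confusion (rows=truth NNeo/LG/HG):
      6     0     0
      0    14     0
      0     0    10
```

All 30 held-out slides are graded correctly (the `±` columns are the 95 %
binomial CI half-widths; they collapse to 0 at a proportion of 1.0), every
dysplastic slide is flagged positive, and the diagonal confusion matrix
yields a quadratic weighted kappa of 1.0 — the planted slide grades are
fully recovered from slide-level supervision plus the small annotated
subset.

The same pipeline is available as a CLI over a YAML config:

```sh
slidemil synth      --config run.yaml   # generate the cohort
slidemil tessellate --config run.yaml   # tissue masks + tile index
slidemil pretrain   --config run.yaml   # supervised tile classifier
slidemil sample     --config run.yaml   # one-time top-M bag cut (TSV)
slidemil train-mil  --config run.yaml   # weakly-supervised training
slidemil predict    --config run.yaml --overlays   # per-slide CSV + maps
slidemil evaluate   --config run.yaml   # metric report + disagreements
slidemil reject-curve --config run.yaml # accuracy vs rejection rate
```

`predict --overlays` renders per-tile class maps (green/amber/red for
NNeo/LG/HG) alpha-blended over each slide; `feedback`/`report` maintain an
append-only reviewer log merged into the exported results.

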