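# discgap

Automatic detection of narrowed intervertebral disc spaces in lateral
spine radiographs, starting from vertebral-body segmentation masks.

The pipeline quantifies the disc spaces geometrically and classifies
them with a large-kernel 1D convolutional sequence labeler:

1. **quantify** — resize the label mask to 1024 × 512, skeletonize each
   vertebral-body component, fit a 4th-order polynomial centerline
   x(y), sample the mask along it into a length-1024 binary profile,
   and measure every inter-body gap by counting pixels (plus each gap's
   ratio to the image's mean gap width).
2. **model** — a 1D CNN (kernel 151, 64 channels, stride 1; a stem
   convolution plus five residual conv→batch-norm→ReLU blocks and a
   width-1 classification head) labels every profile position as
   no-disc-space / normal / narrowed.  It trains with a combined
   cross-entropy + focal loss (α = 0.25, γ = 2) under Adam.  The network
   is implemented in pure NumPy (FFT-based convolutions) — no deep
   learning framework required.
3. **evaluate** — Cohen's and Fleiss' kappa, sensitivity / specificity /
   PPV / NPV / accuracy from pooled 2 × 2 tables, and ROC/AUC with
   Youden-index threshold selection on the width-to-mean ratio.
4. **phantom** — synthetic lateral-spine masks and pre-quantified
   profile datasets with exact ground truth (gap table, centerline
   coefficients, per-position labels) for testing and training.

## CLI

```sh
# synthetic data with ground truth
discgap simulate --out sim/ --n 20 --seed 1

# gap tables from mask images (indexed PNG, labels 0-3)
discgap quantify sim/mask_*.png --out gaps/ --overlay

# train the narrowing detector on annotated masks
discgap train sim/mask_*.png --checkpoint model.npz --history history.jsonl

# label gaps of new images with a trained model
discgap detect sim/mask_*.png --checkpoint model.npz --out detected/

# agreement report (kappa + diagnostic metrics) between two table sets
discgap evaluate --model-tables detected/ --reference-tables reference/ \
    --out report.json
```

All subcommands accept `--config config.json` (a single JSON document;
unknown keys are rejected) and `--seed`.  Per-image failures in batch
runs are logged and summarized without aborting the batch.

## Layout

```
src/discgap/
  phantom.py    synthetic spine masks + ground truth
  quantify.py   mask -> centerline -> profile -> gap table
  nn.py         NumPy conv / batch-norm / Adam primitives
  model.py      architecture, loss, training, per-gap decisions
  evaluate.py   kappa, diagnostic metrics, ROC / Youden
  io.py         PNG / CSV / JSON / NPZ formats
  config.py     RunConfig (JSON)
  cli.py        click command group
```
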