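# kneeoa

Adaptive early stopping and gradual cross-entropy for ordinal radiograph
grading, packaged as a complete desk-scale image-classification pipeline:

- **`kneeoa.patience`** — adaptive-patience early stopping. The stop
  threshold is the running average of successive validation-loss
  differences instead of a fixed epoch count. Two controllers share the
  state machine: a *macro* controller (epoch level, aborts the run) and a
  *micro* controller (batch level, aborts only the current epoch).
- **`kneeoa.losses`** — categorical cross-entropy plus the *gradual*
  variant (GCE): when an epoch is aborted after consuming `l` of `N`
  examples, the logged loss is rescaled by `delta = N / l` so it reflects
  only the data actually seen.
- **`kneeoa.netplan`** — a symbolic ten-row layer plan for the dense-block
  classifier (stem conv, max-pool, four dense blocks, three transitions,
  classification head) with verified tensor-size calculus, the reference
  SGD update, and `instantiate_network`, which builds a runnable NumPy
  model (manual im2col backprop — no deep-learning framework required)
  whose probed shapes match the plan.
- **`kneeoa.patches`** — optional ViT-style patch extraction and linear +
  positional embedding (auxiliary representation; off by default).
- **`kneeoa.data`** — ingestion (class-folder tree or CSV manifest),
  seeded flip/rotate/shift/zoom augmentation, augmentation-based class
  balancing to an exact per-class target, stratified splitting, and
  5-to-3 / 5-to-2 label regrouping.
- **`kneeoa.metrics`** — confusion matrix and micro/macro accuracy,
  precision, recall, F1 (micro = pooled one-vs-rest counts).
- **`kneeoa.synthetic`** — a deterministic synthetic knee-radiograph
  generator: joint-space gap narrows with grade, bright lesions grow with
  grade, adjacent grades overlap, so the full pipeline runs with no
  external dataset.
- **`kneeoa.trainer`** / **`kneeoa.cli`** — the training loop wiring it
  all together, with trace CSV / metrics JSON / checkpoint outputs.

## CLI

```sh
kneeoa generate --out data/raw --image-size 64 --seed 0
kneeoa prepare  --data data/raw/manifest.csv --out data/prepared --target 500
kneeoa plan     --input-size 224 --num-classes 5
kneeoa train    --data data/prepared/manifest.csv --out runs/two --task two \
                --config run.yaml --seed 1
kneeoa evaluate --checkpoint runs/two/checkpoint.npz \
                --data data/prepared/manifest.csv --out runs/two/eval --task two
```

`run.yaml` may override any `RunConfig` field (`max_epochs`, `batch_size`,
`micro_check_every`, `macro_window`, `micro_window`, `min_epochs`,
`learning_rate`, `image_size`, `growth_rate`, `block_layers`, ...).

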