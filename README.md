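# mfafuse

Multi-scale attention-based fusion and segmentation of co-registered
single-channel images, with:

- a **fusion/segmentation network**: shared multi-scale convolutional encoder
  (stride-2 downsampling, batch normalization + GELU), per-scale spatial-softmax
  attention with residual modulation, per-scale convex fusion driven by either
  saliency-softmax or learned-softmax weights, an alpha-gated global-context
  refinement stage, and a transposed-convolution decoder with skip
  concatenation and 1x1 fusion/segmentation heads;
- a **dynamic refinement toolkit** (`mfafuse.dfrs`): gradient-based saliency
  scores, simplex fusion weights, global context aggregation, gated context
  attention;
- **preprocessing** (`mfafuse.preprocess`): min-max and z-score normalization
  plus rank-preserving histogram calibration of a modality stack to its pooled
  intensity distribution;
- a classical **Laplacian-pyramid fusion baseline** with perfect
  single-input reconstruction;
- **quality metrics** (`mfafuse.metrics`): SSIM-sum spatial consistency,
  histogram entropy, gradient-consistency error, and Dice/IoU/Precision/Recall;
- a **synthetic phantom generator** (`mfafuse.phantoms`): registered
  multi-pseudo-modality stacks of branching (vessel-like) or blob (polyp-like)
  structures with ground-truth masks, photometric offsets, complementary
  rendering, and degradation simulators (low light, JPEG, Gaussian blur,
  additive noise) — everything derived deterministically from one seed;
- a **CPU-scale training harness** (`mfafuse.training`): Adam, linear warm-up +
  cosine annealing, early stopping on validation Dice, Dice+cross-entropy loss,
  morphological post-processing, ablation and robustness harnesses.

The network runs on a small numpy reverse-mode autodiff core (`mfafuse.nn`) —
no deep-learning framework is required; everything trains on one CPU in
minutes at phantom scale.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria; its training-based
tests share a module-scoped benchmark fixture (4 variants x 3 seeds on 32x32
phantoms) and take several minutes on one CPU.

## CLI

```bash
mfafuse simulate  --config cfg.yaml --out data/ --seed 1   # phantom dataset + manifest
mfafuse fuse      --config cfg.yaml --inputs a.png b.png --out fused.png [--baseline laplacian] [--debug]
mfafuse train     --config cfg.yaml --data data/ --out runs/
mfafuse evaluate  --pred preds/ --truth masks/ --out report.csv
mfafuse ablate    --config cfg.yaml --data data/ --out ablation.json
mfafuse robustness --config cfg.yaml --data data/ --out robustness.json
```

Configurations are YAML or JSON with strict schema validation (unknown keys
are rejected); every artifact-producing run writes `resolved_config.yaml` and
`provenance.json` beside its outputs. A minimal config is just `seed: 1`;
see `mfafuse/config.py` for all sections and defaults
(`preprocess`, `encoder` — including the full-scale `preset: paper` —,
`attention`, `dfrs`, `fusion`, `train`, `eval`, `simulate`).

## Library example

```python
import numpy as np
from mfafuse import PhantomConfig, generate_phantom, ModelConfig, build_model
from mfafuse.training import TrainConfig, train

stack, mask = generate_phantom(PhantomConfig(height=32, width=32, seed=0))
model = build_model(ModelConfig(), seed=0)
out = model(stack[None])           # {'fused', 'seg_probs', 'weights', ...}
probs = out["seg_probs"].data[0, 0]
```
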