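# sdd — single-class dense detection toolkit

A pure-Python (numpy) implementation of an occlusion-aware single-class
detector and its surrounding tooling, built to train and evaluate at toy
scale on one CPU:

- **geometry** — box algebra, IoU/IoG, the per-image Overlap Ratio (OR)
  occlusion statistic (exact union-of-intersections via coordinate
  compression), and the dense-subset filter (OR > 0.5 and > 40 objects).
- **wavelet** — orthonormal Haar analysis/synthesis with perfect
  reconstruction, wavelet-domain depthwise convolution (`WTConv`), and the
  `WEConv` downsampling block (1×1 stride-2 reduction → wavelet enrichment →
  additive fusion).
- **opam** — attention fusion of stride-4 detail features with the stride-8
  neck branch through position/channel attention and a sigmoid pixel gate:
  `F_out = F_low⊙F_pixel + Conv1×1(F_high)⊙(1−F_pixel)`.
- **ls_head** — lightweight shared head: per-level 1×1 reductions to a
  common middle channel (default 128), two 3×3 group-normalized blocks and
  prediction convolutions shared across the stride-8/16/32 levels.
- **losses** — CIoU attraction plus RepGT/RepBox repulsion through the
  piecewise `Smooth_ln`, combined as `L = L_CIoU + 0.4·L_RepGT +
  0.6·L_RepBox`, with BCE classification and optional DFL regression.
- **model** — backbone (WEConv + C2f + SPPF), PAN neck, n/s/m variants,
  task-aligned assignment, DFL decoding, greedy NMS, AdamW training loop,
  and parameter/FLOP accounting.
- **evaluation** — COCO-style AP50/AP75/AP50:95 (101-point interpolation)
  with dense-subset stratified reporting.
- **synthetic** — deterministic generator of dense occluded scenes (10–80
  convex instances, tunable target OR in 0–0.8, edge truncation, blur,
  illumination fields) with YOLO-format labels, so everything is testable
  without external data.

Because the stack has to run where only numpy/scipy are available, the
networks sit on a small vectorized reverse-mode autodiff engine
(`sdd.autograd`, im2col grouped convolutions) rather than a deep-learning
framework.

## CLI

```bash
sdd generate -n 50 -o data/demo --or 0.0..0.8 --objects 10..80 --seed 7
sdd or-stats data/demo --subset-or 0.5 --subset-min-objects 40 --out or.json
sdd params -c config.yaml
sdd train -c config.yaml --data data/demo -o ckpt.npz --iterations 300
sdd eval -c config.yaml -w ckpt.npz --data data/demo --out report.json
sdd eval --data data/demo --dets detections.json --out report.json
```

Configuration is YAML with strict validation; defaults follow the reference
recipe (AdamW, lr 2e-3, weight decay 5e-4, 3 warm-up epochs, batch 16,
α=0.4/β=0.6, 7:1:2 split, NMS IoU 0.65). See `sdd/config.py` for the full
schema, including the ablation switches `model.use_weconv`,
`model.use_opam`, `model.use_ls_head` and `loss.repulsion`.

## Built-to-scale notes

Parameter accounting of the full-size variants closely brackets the
published totals (n/s/m ≈ 2.60/9.29/22.16 M vs 2.6/9.0/22.0 M reported;
baseline s ≈ 11.14 M vs 11.2 M); FLOP estimates count 2×MACs of
convolutions only.
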