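# maskfuse

Adaptive fusion of binary segmentation masks for head-series (skull-stripping
/ brain tissue segmentation) pipelines, with exact IoU and Hausdorff-distance
evaluation and a synthetic phantom benchmark.

Deep segmentation models trained on the same task make *directional* errors:
some systematically over-segment (label non-brain pixels as brain, e.g. at the
skull base or periorbital region), others under-segment (miss true brain
pixels). `maskfuse` exploits this: it profiles each model's error direction on
a labeled calibration set and then combines the models' output masks with the
set operation that can only cancel the dominant error.

## The method

For each model, total over a calibration dataset

- `num_overseg` — predicted-foreground pixels the ground truth calls
  background (false positives), and
- `num_miss` — ground-truth foreground pixels the model missed
  (false negatives).

The fusion strategy *F* for a pair of masks is

```
F = mask1 ∪ mask2   if num_miss > num_overseg for both models
F = mask1 ∩ mask2   if num_overseg > num_miss for both models
```

Union can only recover misses; intersection can only remove false alarms.
When two models disagree in direction, a third model resolves the tie by
pairing with whichever model shares its direction; if no two models agree,
the plan defaults to intersection (U-Net-family segmenters in practice
produce more false positives than misses) and the decision trace records
that the default was taken.

Evaluation uses IoU (overlap pixels / union pixels) and the exact symmetric
Hausdorff distance between contours, `HD(A,B) = max(h(A,B), h(B,A))` with
`h(A,B) = max_{a∈A} min_{b∈B} ‖a−b‖`, computed over 4-connectivity boundary
pixels in pixel units. An optional post-processing step smooths a mask with a
9×9 Gaussian kernel (σ = 1) and re-binarizes at 0.5, which deletes isolated
specks and fills pinholes without moving large-region boundaries.

Because clinical CT data cannot ship with the package, the `synthetic` module
generates phantom head series — per-slice brain cross-sections that grow from
the skull base to mid-head and vanish at the vertex, plus non-brain distractor
structures on low slices — and simulated segmenters with controllable
dilation/erosion bias, spurious blobs, dropout bites, and boundary jitter.

## Worked example

```python
from maskfuse import (PhantomConfig, paper_like_profiles, generate_phantom_series,
                      simulate_model_output, accumulate_profile, select_strategy,
                      fuse_series, evaluate_series)

cfg = PhantomConfig(seed=1)                      # 31 slices, 128x128
gt, distractors = generate_phantom_series(cfg)
preds = {p.model_id: simulate_model_output(gt, distractors, p)
         for p in paper_like_profiles(1)}

profiles = [accumulate_profile(s, gt, m) for m, s in preds.items()]
plan = select_strategy(profiles)
fused = fuse_series(preds, plan)
```

Printing the profiles, plan, and evaluations yields:

```
unet     num_overseg=  7214 num_miss=   98 -> OVER
unet2p   num_overseg= 15785 num_miss=  213 -> OVER
unet3p   num_overseg=  6269 num_miss=    0 -> OVER
plan: intersection over unet,unet2p,unet3p
unet     mean IoU 0.8924  mean HD 10.63 px
unet2p   mean IoU 0.8191  mean HD 26.05 px
unet3p   mean IoU 0.9349  mean HD  5.70 px
fusion   mean IoU 0.9446  mean HD  4.55 px
```

All three simulated models over-segment, so the selector chooses
intersection over all of them; the fused series beats the best single model
on both metrics because the models' false alarms rarely coincide, while the
brain region they agree on is nearly complete.

The same pipeline is available from the shell:

```
maskfuse simulate -c config.json -o bundle/
maskfuse profile --gt bundle/gt --pred unet=bundle/unet --pred unet3p=bundle/unet3p -o profile.csv
maskfuse fuse-eval --gt bundle/gt --pred unet=bundle/unet --pred unet3p=bundle/unet3p -o out/
```

`fuse-eval` writes the fused masks (raw and Gaussian-filtered), a per-slice
IoU/HD CSV, and a JSON summary comparing each model against the fusion.

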