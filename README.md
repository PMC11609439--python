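# unwseg

Nucleus segmentation for stained pathology images that keeps working when
the *appearance* of the images changes — a different scanner, a heavier
stain, another lab's protocol — without ever seeing the new appearance
during training.

Digital pathology models are usually trained on images from one site and
then fail on tiles whose colour statistics differ, because convolutional
features absorb stain style along with morphology. `unwseg` implements a
U-shaped encoder–decoder (**UNW**) with two plug-and-play feature-alignment
blocks at the bottleneck that strip per-image style while preserving class
semantics:

* **FCA (Feature Center Alignment)** — class-region instance
  normalization. With labels, each class region of each channel is
  standardised by its own statistics and affine-restored
  (`(F − μ_c)/√(σ_c² + β) · α_c + ε_c`). Label-free inference uses a
  pre-segmentation branch (1×1 softmax classifier producing class maps
  `M`): highlight `F ⊙ M^c`, refine with a pooled-descriptor attention
  gate (FR), region-normalise inside a thresholded region mask
  (`t = 0.8`), and sum branches to `F̄`. Loss:
  `CE(M, L) + ‖F̄ − FC‖₁`.
* **FDA (Feature Distribution Alignment)** — grouped instance whitening.
  Channels are ranked by the pre-segmentation classifier weights
  `w ∈ R^{C×K}`, grouped one-channel-per-class into `⌊K/C⌋` disjoint
  groups, and each group's weight-scaled channel covariance is pulled to
  the identity: `L_FDA = (1/N) Σ_n Σ_m ‖Σ(P_n^m) − I‖₁`.

Evaluation uses the standard confusion-matrix metrics (Acc, Pre, Recall,
IOU, DSC with `DSC = 2·IOU/(1+IOU)`). Because clinical pathology data is
hard to share, the package ships a seeded generator of stained-tissue-like
images (elliptical nuclei, stain styles, noise, texture) with paired
masks, giving a fully reproducible cross-style benchmark. The network runs
on the package's own NumPy reverse-mode autodiff — no GPU or deep-learning
framework required.

## Worked example

`examples/03_train_and_segment.py` generates 60 styled images, splits 7:3,
trains the full model for ten desk-scale epochs and evaluates held-out
in-style images. It prints (exactly, at its fixed seeds):

```
model parameters: 5646
training loss: 2.067 (epoch 1) -> 0.662 (epoch 10)
  acc     0.951 ± 0.016
  pre     0.905 ± 0.025
  recall  0.909 ± 0.021
  iou     0.829 ± 0.025
  dsc     0.906 ± 0.015
```

The training loss falls steadily and the held-out in-style Dice
coefficient reaches 0.906 after only ten epochs of a 5,646-parameter
model — the task is learnable when the staining appearance matches
training. The interesting case is when it does not:

```bash
python examples/04_cross_style_ablation.py
```

trains the four ablation variants on the warm H&E style and evaluates on
the unseen dark heavily-stained style (about three minutes; printed
output at its fixed seed):

```
        method   acc   pre  recall   iou   dsc
      Baseline 0.616 0.416   1.000 0.416 0.582
Baseline + FCA 0.946 0.838   0.988 0.829 0.906
Baseline + FDA 0.838 0.624   0.998 0.623 0.765
           All 0.933 0.809   0.979 0.795 0.885
```

The unaligned Baseline keeps finding all nuclei (recall 1.0) but floods
the prediction with false positives on the shifted stain (precision
0.42, DSC 0.582); each alignment block recovers most of the lost
accuracy, and across seeds the full model is the strongest variant. The
other `examples/` scripts demonstrate the generator, the alignment
primitives on controlled covariance fixtures, and training.

There is also a thin CLI (`unwseg simulate|train|evaluate|predict|ablate`)
for shell use; every command takes `--config`, `--seed`, `--out` and
writes its effective configuration next to its outputs.

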