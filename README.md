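# tmaseg

Superpixel-based segmentation of tissue-microarray (TMA) core images into
**tumor**, **non-tumor** and **background**.

Digitized TMA cores are circular tissue discs on a light-gray background,
routinely used to score immunohistochemical markers across many patients at
once. `tmaseg` implements a computer-aided-diagnosis pipeline that treats
segmentation as a supervised classification problem over superpixels: it is
aimed at researchers in digital pathology who want a transparent,
fully-reproducible baseline rather than a deep-learning black box.

## Method

1. **Pre-processing.** Cores (natively ≈6000×6000 px) are rescaled to 25%
   and optionally enhanced by one of three transforms: contrast
   normalization (quantile stretch), per-channel histogram equalization, or
   histogram matching against a reference core.
2. **Superpixels.** SLIC — localized k-means over combined color+position —
   partitions the image into quasi-regular regions, governed by the initial
   grid size *S* (default 30 px) and a regularization *r* ∈ [0, 1] (default
   0.20) mapping to the compactness weight *m* = 40·*r* in the distance
   *D* = *d*<sub>color</sub> + (*m*/*S*)·*d*<sub>xy</sub>.
3. **Features.** Each superpixel is described by **69 features**: 17
   first-order histogram statistics and the 6 Tamura perceptual texture
   features (coarseness, contrast, directionality, line-likeness,
   regularity, roughness) on each RGB channel (23 × 3).
4. **Labels.** Expert tumor markings (ImageJ polygon `.roi` files) are
   rasterized into three-code label images {0 background, 2 tumor,
   3 non-tumor}; each superpixel receives the class of the plurality of its
   pixels (ties favor tumor).
5. **Learning & evaluation.** Five classifier families (random forest, SVM,
   LogitBoost-style stumps, entropy tree, Gaussian naive Bayes) are compared
   by leave-one-image-out cross-validation, scored per class one-vs-rest:

   PPV = TP/(TP+FP)  TPR = TP/(TP+FN)  F1 = 2·PPV·TPR/(PPV+TPR)  ACC = correct/N

6. **Segmentation.** The best (enhancement, classifier) pair is retrained
   and its superpixel predictions are reassembled into a label image,
   colorized red (tumor) / green (non-tumor) / white (background).

A built-in synthetic generator (`tmaseg.synthetic`) produces TMA-like cores
with exact paired ground truth, so the entire pipeline can be exercised and
validated without any slide data.

## Worked example

```python
import json
from tmaseg.pipeline import run_experiment

report = run_experiment({"n_images": 3, "size": 256, "seed": 42,
                         "enhancements": ["none", "equalize"],
                         "classifiers": ["random_forest", "bayes_net"]})
print(json.dumps(report["grid"][0], indent=2))
print(report["best"], report["mean_pixel_accuracy"])
```

prints (grid sorted best-first; values are means over the three
leave-one-image-out folds):

```
{
  "enhancement": "none",
  "classifier": "random_forest",
  "mean_accuracy": 0.9948717948717949,
  "mean_macro_f1": 0.9957831085650635
}
{'enhancement': 'none', 'classifier': 'random_forest'} 1.0
```

i.e. the random forest classifies ~99.5% of held-out superpixels correctly
on the 3-core synthetic study, and the final model retrained on all cores
reproduces the superpixel-resolution ground truth exactly
(`mean_pixel_accuracy` is the pixel-level hit rate of the reassembled
segmentations).

The same workflow is available from the shell:

```sh
tmaseg simulate --n 10 --seed 42 --size 512 --out data/
tmaseg run --config run.toml --out results/
```

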