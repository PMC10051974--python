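"""End-to-end experiment orchestration.

``run_experiment`` drives the full study from one flat configuration
mapping: acquire images (synthetic generation or an input directory of
image/label PNG pairs), rescale, apply each configured enhancement, partition
into superpixels, extract features, assign ground-truth classes by majority
vote, cross-validate every enhancement × classifier pair, select the best
pair, retrain it on all images and segment every image, scoring each
segmentation against the superpixel-resolution ground truth.

The report is a plain JSON-serializable dict: identical configuration and
seed give an identical report.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
from skimage.transform import resize

from . import dataio, ground_truth, learning, preprocess, segmentation, superpixels, texture
from ._util import as_label_image, round_half_up
from .synthetic import SyntheticParams, generate_dataset

log = logging.getLogger(__name__)

SCHEMA_VERSION = 1

DEFAULTS = {
    "n_images": 3,
    "size": 256,
    "seed": 42,
    "scale": 1.0,
    "enhancements": ["none"],
    "classifiers": ["random_forest"],
    "grid_size": 30,
    "regularization": 0.20,
    "saturation": preprocess.DEFAULT_SATURATION,
}


def _rescale_labels(labels: np.ndarray, factor: float) -> np.ndarray:
    if factor == 1.0:
        return labels
    h, w = labels.shape
    out_h = max(1, int(round_half_up(h * factor)))
    out_w = max(1, int(round_half_up(w * factor)))
    out = resize(labels, (out_h, out_w), order=0, mode="edge",
                 anti_aliasing=False, preserve_range=True)
    return as_label_image(out.astype(np.uint8))


def _load_inputs(config: dict):
    if "input_dir" in config:
        d = Path(config["input_dir"])
        images = sorted(d.glob("image_*.png"))
        if not images:
            raise ValueError(f"pipeline/load: no image_*.png files in {d}")
        pairs = []
        for img_path in images:
            lbl_path = d / img_path.name.replace("image_", "labels_")
            if not lbl_path.exists():
                raise ValueError(f"pipeline/load: missing label file {lbl_path}")
            pairs.append((dataio.read_image(img_path),
                          dataio.read_label_image(lbl_path)))
        return pairs
    params = SyntheticParams(size=int(config["size"]))
    return generate_dataset(int(config["n_images"]), base_seed=int(config["seed"]),
                            params=params)


def run_experiment(config: dict, out_dir=None) -> dict:
    """Run the full comparison experiment described by ``config``.

    Recognized keys (all optional, see ``DEFAULTS``): input_dir | n_images &
    size, seed, scale, enhancements, classifiers, grid_size, regularization,
    saturation. Returns the machine-readable report dict; with ``out_dir``
    set, also writes the report, segmented label rasters and colorized
    previews.
    """
    cfg = {**DEFAULTS, **config}
    seed = int(cfg["seed"])
    pairs = _load_inputs(cfg)
    scale = float(cfg["scale"])
    if scale != 1.0:
        pairs = [(preprocess.rescale(img, scale), _rescale_labels(lbl, scale))
                 for img, lbl in pairs]

    slic_params = superpixels.SlicParams(
        grid_size=int(cfg["grid_size"]), regularization=float(cfg["regularization"]))
    specs = [learning.ClassifierSpec(family=f, seed=seed) for f in cfg["classifiers"]]

    # per enhancement: enhanced images, superpixel maps, labeled feature tables
    stage = {}
    reference = pairs[0][0]  # histogram-matching reference: first image
    for kind in cfg["enhancements"]:
        enhanced, maps, tables = [], [], []
        for i, (img, lbl) in enumerate(pairs):
            e = preprocess.enhance(img, kind, reference=reference,
                                   saturation=float(cfg["saturation"]))
            m = superpixels.slic(e, slic_params)
            t = texture.extract_feature_table(e, m, image_id=i, labels=lbl)
            enhanced.append(e)
            maps.append(m)
            tables.append(t)
        stage[kind] = {"images": enhanced, "maps": maps, "tables": tables}

    grid = learning.compare_grid({k: v["tables"] for k, v in stage.items()}, specs)
    best_enh, best_clf = learning.select_best(grid)
    log.info("best pair: enhancement=%s classifier=%s", best_enh, best_clf)

    best = stage[best_enh]
    best_spec = next(s for s in specs if s.family == best_clf)
    import pandas as pd
    model = learning.train(pd.concat(best["tables"], ignore_index=True), best_spec)

    per_image = []
    segmented = []
    for i, (img, lbl) in enumerate(pairs):
        table = best["tables"][i]
        predicted = model.predict_table(table)
        classes = pd.DataFrame({"superpixel_id": table["superpixel_id"], "class": predicted})
        seg = segmentation.reconstruct(best["maps"][i], classes)
        truth = ground_truth.quantized_label_image(best["maps"][i], lbl)
        report = segmentation.pixel_score(seg, truth)
        per_image.append({"image_id": i, "pixel_accuracy": report.accuracy,
                          "pixel_macro_f1": report.macro_f1})
        segmented.append(seg)

    report = {
        "schema_version": SCHEMA_VERSION,
        "config": {k: cfg[k] for k in sorted(cfg)},
        "grid": grid.to_dict(orient="records"),
        "best": {"enhancement": best_enh, "classifier": best_clf},
        "segmentation": per_image,
        "mean_pixel_accuracy": float(np.mean([r["pixel_accuracy"] for r in per_image])),
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for i, seg in enumerate(segmented):
            dataio.write_label_image(seg, out_dir / f"segmented_{i:02d}.png")
            dataio.write_image(segmentation.colorize(seg), out_dir / f"segmented_{i:02d}_rgb.png")
            dataio.write_image(
                superpixels.boundary_overlay(stage[best_enh]["images"][i],
                                             stage[best_enh]["maps"][i]),
                out_dir / f"superpixels_{i:02d}.png")
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return report
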