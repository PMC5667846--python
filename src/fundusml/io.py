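"""Readers and writers for the pipeline's on-disk formats.

Images travel as one PNG per image plus a CSV manifest (columns
``filename, label_index, class_name``); feature matrices as a
tab-delimited values file with a parallel one-column label file;
confusion matrices as CSV with class names on both margins.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from fundusml.datatypes import FeatureMatrix, LabeledImageSet
from fundusml.metrics import ConfusionMatrix, RocResult


def write_image_dataset(dataset: LabeledImageSet, out_dir: str | Path) -> Path:
    """One 8-bit PNG per image plus ``manifest.csv``; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["filename", "label_index", "class_name"])
        for i, (img, lab) in enumerate(zip(dataset.images, dataset.labels)):
            fname = f"img_{i:06d}.png"
            arr8 = np.clip(np.rint(np.asarray(img) * 255), 0, 255).astype(np.uint8)
            Image.fromarray(arr8).save(out / fname)
            w.writerow([fname, int(lab), dataset.class_names[int(lab)]])
    return manifest


def read_image_dataset(manifest_path: str | Path) -> LabeledImageSet:
    manifest = Path(manifest_path)
    df = pd.read_csv(manifest)
    base = manifest.parent
    images, labels = [], []
    names: dict[int, str] = {}
    for _, row in df.iterrows():
        arr = np.asarray(Image.open(base / row["filename"]).convert("RGB"), dtype=float) / 255.0
        images.append(arr)
        labels.append(int(row["label_index"]))
        names[int(row["label_index"])] = str(row["class_name"])
    k = max(names) + 1 if names else 0
    class_names = [names.get(i, f"class_{i}") for i in range(k)]
    return LabeledImageSet(images=images, labels=np.asarray(labels, dtype=int),
                           class_names=class_names)


def write_feature_matrix(fm: FeatureMatrix, values_path: str | Path,
                         labels_path: str | Path | None = None) -> None:
    np.savetxt(values_path, fm.values, delimiter="\t", fmt="%.10g")
    if labels_path is not None and fm.labels is not None:
        np.savetxt(labels_path, fm.labels, fmt="%d")


def read_feature_matrix(values_path: str | Path,
                        labels_path: str | Path | None = None) -> FeatureMatrix:
    values = np.loadtxt(values_path, delimiter="\t", ndmin=2)
    labels = None
    if labels_path is not None:
        labels = np.loadtxt(labels_path, dtype=int, ndmin=1)
    return FeatureMatrix(values=values, labels=labels)


def write_confusion(cm: ConfusionMatrix, path: str | Path) -> None:
    names = cm.class_names or [f"class_{i}" for i in range(cm.q.shape[0])]
    pd.DataFrame(cm.q, index=names, columns=names).to_csv(path)


def read_confusion(path: str | Path) -> ConfusionMatrix:
    df = pd.read_csv(path, index_col=0)
    return ConfusionMatrix(q=df.to_numpy(dtype=float), class_names=list(df.columns))


def write_roc_points(roc: RocResult, path: str | Path) -> None:
    pd.DataFrame({
        "threshold": roc.thresholds,
        "sensitivity": roc.sensitivity,
        "specificity": roc.specificity,
    }).to_csv(path, index=False)
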