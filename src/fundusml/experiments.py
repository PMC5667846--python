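"""Experiment harnesses for the multi-categorical classification study.

Each harness mirrors one analysis of the study design at a configurable
(desk-scale) problem size:

* **category sweep** — classification performance as disease categories
  are added one at a time in order of clinical importance, under
  stratified 5-fold cross-validation;
* **pairwise binary** — binary CV accuracy for every unordered pair of
  categories;
* **screening ROC** — normal-vs-abnormal discrimination on a single
  stratified 70/30 train/test split, with Youden-index cut-off;
* **scenarios** — the four clinically motivated class groupings around
  diabetic retinopathy and macular degeneration;
* **ensemble comparison** — the single SVM, optional pluggable
  baselines, and the clustering-and-voting ensemble on identical folds;
* **feature-selection sweep** — CV accuracy for each ranking method ×
  top-k subset size, with rankings fitted on training folds only.

Metrics are computed on pooled out-of-fold predictions (one confusion
matrix across folds); per-fold values are reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

from fundusml.classifiers import BinaryLearnerSpec, train_multiclass
from fundusml.datatypes import CLASS_ORDER, FeatureMatrix
from fundusml.ensemble import GridSpec, build_ensemble, build_model_pool, ensemble_predict
from fundusml.metrics import accuracy, confusion, kappa, rci, roc_auc_youden
from fundusml.selection import rank_features, select_top_k
from fundusml.synthetic import generate_feature_dataset

#: Clinically motivated scenario groupings (diabetic retinopathy, DMR,
#: and age-related macular degeneration, AMD).
SCENARIOS: dict[str, tuple[str, ...]] = {
    "screening early diseases": ("normal", "BDR", "dry AMD"),
    "DMR + AMD": ("normal", "BDR", "PDR", "dry AMD", "wet AMD"),
    "DMR staging": ("normal", "BDR", "PDR"),
    "AMD staging": ("normal", "dry AMD", "wet AMD"),
}


@dataclass(frozen=True)
class ExperimentConfig:
    """Shared settings for all harnesses.

    The synthetic feature generator stands in for the image pipeline at
    a desk-friendly size; ``n_per_class``, ``dim`` and ``separation``
    control it.  ``class_order`` fixes the category-sweep ordering.
    """

    n_classes: int = 10
    n_per_class: int = 100
    dim: int = 256
    separation: float = 2.0
    n_folds: int = 5
    roc_train_fraction: float = 0.70
    validation_fraction: float = 0.20
    data_seed: int = 0
    split_seed: int = 0
    learner: BinaryLearnerSpec = field(default_factory=BinaryLearnerSpec)
    scheme: str = "OVO"
    grid: GridSpec = field(default_factory=GridSpec)
    target_clusters: int = 7
    k_values: tuple[int, ...] = (1024, 2048, 3072, 4096)
    class_order: tuple[str, ...] = CLASS_ORDER

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if not (0.0 < self.roc_train_fraction < 1.0):
            raise ValueError("roc_train_fraction must be in (0, 1)")


def make_dataset(config: ExperimentConfig) -> FeatureMatrix:
    return generate_feature_dataset(
        n_classes=config.n_classes, n_per_class=config.n_per_class,
        dim=config.dim, separation=config.separation, seed=config.data_seed)


def stratified_folds(y: np.ndarray, n_folds: int, seed: int):
    """(train_idx, test_idx) pairs from seeded stratified K-fold."""
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(y)), y))


def _metric_row(q) -> dict:
    return {"accuracy": accuracy(q), "rci": rci(q), "kappa": kappa(q)}


def cross_validate(x: np.ndarray, y: np.ndarray, config: ExperimentConfig,
                   fit_predict=None) -> dict:
    """Pooled-confusion CV of a fit/predict routine on (x, y).

    ``fit_predict(x_train, y_train, x_test) -> predicted labels``
    defaults to the configured single multiclass SVM.  Labels must be
    0..K−1.  Returns pooled metrics, the pooled confusion matrix, and
    per-fold accuracies.
    """
    if fit_predict is None:
        def fit_predict(xt, yt, xe):
            m = train_multiclass(xt, yt, scheme=config.scheme, spec=config.learner)
            return m.predict_labels(xe)
    k = int(y.max()) + 1
    folds = stratified_folds(y, config.n_folds, config.split_seed)
    true_all, pred_all, fold_acc = [], [], []
    for tr, te in folds:
        pred = fit_predict(x[tr], y[tr], x[te])
        true_all.append(y[te])
        pred_all.append(pred)
        fold_acc.append(float(np.mean(pred == y[te])))
    cm = confusion(np.concatenate(true_all), np.concatenate(pred_all), k)
    out = _metric_row(cm)
    out["confusion"] = cm
    out["fold_accuracies"] = fold_acc
    out["mean_fold_accuracy"] = float(np.mean(fold_acc))
    return out


def _subset(x: np.ndarray, y: np.ndarray, keep: list[int]):
    """Rows of the kept classes, labels remapped to 0..len(keep)−1."""
    remap = {c: i for i, c in enumerate(keep)}
    mask = np.isin(y, keep)
    return x[mask], np.array([remap[v] for v in y[mask]])


def run_category_sweep(config: ExperimentConfig,
                       dataset: FeatureMatrix | None = None) -> pd.DataFrame:
    """Accuracy/RCI/kappa as categories are added in the documented order."""
    fm = dataset or make_dataset(config)
    x, y = fm.values, fm.labels
    rows = []
    for k in range(2, config.n_classes + 1):
        xs, ys = _subset(x, y, list(range(k)))
        res = cross_validate(xs, ys, config)
        rows.append({"n_categories": k,
                     "classes": " + ".join(config.class_order[:k]),
                     **{m: res[m] for m in ("accuracy", "rci", "kappa")},
                     "fold_accuracies": res["fold_accuracies"],
                     "mean_fold_accuracy": res["mean_fold_accuracy"]})
    return pd.DataFrame(rows)


def run_pairwise_binary(config: ExperimentConfig,
                        dataset: FeatureMatrix | None = None) -> pd.DataFrame:
    """Binary CV accuracy for every unordered pair of categories."""
    fm = dataset or make_dataset(config)
    x, y = fm.values, fm.labels
    rows = []
    for a in range(config.n_classes):
        for b in range(a + 1, config.n_classes):
            xs, ys = _subset(x, y, [a, b])
            res = cross_validate(xs, ys, config)
            rows.append({"class_a": config.class_order[a],
                         "class_b": config.class_order[b],
                         "accuracy": res["accuracy"]})
    return pd.DataFrame(rows)


def run_screening_roc(config: ExperimentConfig,
                      dataset: FeatureMatrix | None = None) -> dict:
    """Normal-vs-abnormal ROC on a stratified 70/30 split.

    The multiclass model is trained on the training side; the abnormal
    score of a test sample is 1 minus its normal-class score.
    """
    fm = dataset or make_dataset(config)
    x, y = fm.values, fm.labels
    y_bin = (y != 0).astype(int)
    if y_bin.min() == y_bin.max():
        raise ValueError("both normal and abnormal samples are required")
    idx = np.arange(len(y))
    tr, te = train_test_split(idx, train_size=config.roc_train_fraction,
                              stratify=y, random_state=config.split_seed)
    model = train_multiclass(x[tr], y[tr], scheme=config.scheme, spec=config.learner)
    scores = model.predict_scores(x[te])
    abnormal_score = 1.0 - scores[:, 0]
    roc = roc_auc_youden(abnormal_score, y_bin[te])
    return {"roc": roc, "auc": roc.auc,
            "sensitivity": roc.sensitivity_at_cutoff,
            "specificity": roc.specificity_at_cutoff,
            "youden_cutoff": roc.youden_cutoff,
            "n_train": len(tr), "n_test": len(te)}


def run_scenarios(config: ExperimentConfig,
                  dataset: FeatureMatrix | None = None) -> pd.DataFrame:
    """The four DMR/AMD class-grouping scenarios under CV."""
    fm = dataset or make_dataset(config)
    x, y = fm.values, fm.labels
    name_to_idx = {n: i for i, n in enumerate(config.class_order)}
    rows = []
    for scen, names in SCENARIOS.items():
        unknown = [n for n in names if n not in name_to_idx]
        if unknown:
            raise ValueError(f"unknown class names in scenario {scen!r}: {unknown}")
        keep = [name_to_idx[n] for n in names]
        xs, ys = _subset(x, y, keep)
        res = cross_validate(xs, ys, config)
        rows.append({"scenario": scen, "n_categories": len(names),
                     "classes": " + ".join(names),
                     **{m: res[m] for m in ("accuracy", "rci", "kappa")}})
    return pd.DataFrame(rows)


def _ensemble_fit_predict(config: ExperimentConfig):
    """fit/predict closure running pool → clustering → voting per fold."""
    def fit_predict(xt, yt, xe):
        sub_tr, val = train_test_split(
            np.arange(len(yt)), test_size=config.validation_fraction,
            stratify=yt, random_state=config.split_seed)
        pool = build_model_pool(xt, yt, grid=config.grid, eval_indices=val,
                                train_indices=sub_tr)
        ens = build_ensemble(pool, xt[val], yt[val],
                             target_clusters=min(config.target_clusters, len(pool.members)))
        _, pred = ensemble_predict(ens, xe)
        return pred
    return fit_predict


def run_ensemble_comparison(config: ExperimentConfig,
                            dataset: FeatureMatrix | None = None,
                            baselines: dict | None = None) -> pd.DataFrame:
    """Single SVM vs clustering-and-voting ensemble on identical folds.

    ``baselines`` maps a row name to a zero-argument factory returning a
    scikit-learn-style estimator run through the pluggable scheme.
    """
    fm = dataset or make_dataset(config)
    x, y = fm.values, fm.labels
    rows = []
    res = cross_validate(x, y, config)
    rows.append({"model": f"single {config.scheme} SVM",
                 **{m: res[m] for m in ("accuracy", "rci", "kappa")}})
    for name, factory in (baselines or {}).items():
        def fp(xt, yt, xe, factory=factory):
            m = train_multiclass(xt, yt, scheme="pluggable", estimator=factory())
            return m.predict_labels(xe)
        res = cross_validate(x, y, config, fit_predict=fp)
        rows.append({"model": name,
                     **{m: res[m] for m in ("accuracy", "rci", "kappa")}})
    res = cross_validate(x, y, config, fit_predict=_ensemble_fit_predict(config))
    rows.append({"model": "clustering-and-voting ensemble",
                 **{m: res[m] for m in ("accuracy", "rci", "kappa")}})
    return pd.DataFrame(rows)


def run_feature_selection_sweep(config: ExperimentConfig,
                                dataset: FeatureMatrix | None = None,
                                methods: tuple[str, ...] = ("KW", "BW", "MRMD"),
                                ) -> pd.DataFrame:
    """CV accuracy per (ranking method, top-k) cell.

    Rankings are fitted on each fold's training rows only, so no test
    information leaks into the subset choice.  k values above the
    feature dimension are truncated to it.
    """
    fm = dataset or make_dataset(config)
    x, y = fm.values, fm.labels
    d = x.shape[1]
    ks = sorted({min(k, d) for k in config.k_values})
    rows = []
    for method in methods:
        for k in ks:
            def fp(xt, yt, xe, method=method, k=k):
                ranking = rank_features(xt, yt, method=method)
                cols = select_top_k(ranking, k)
                m = train_multiclass(xt[:, cols], yt, scheme=config.scheme,
                                     spec=config.learner)
                return m.predict_labels(xe[:, cols])
            res = cross_validate(x, y, config, fit_predict=fp)
            rows.append({"method": method, "k": k,
                         **{m: res[m] for m in ("accuracy", "rci", "kappa")}})
    return pd.DataFrame(rows)
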