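"""Evaluation protocol: confusion metrics, ROC/AUC, splits, and experiment harnesses.

Metrics follow the usual confusion-count definitions — accuracy
(TP+TN)/total, precision TP/(TP+FP), recall TP/(TP+FN), F1 their harmonic
mean — with zero-denominator cells returned as flagged zeros so batch
experiments never abort.  ROC curves sweep the distinct score thresholds
(ties grouped) and AUC is the trapezoidal area, identical to the
Mann-Whitney pairwise-concordance statistic with half credit for ties.

The data protocol is a stratified 60/20/20 train/validation/test split
plus stratified k-fold cross-validation.  Two harnesses mirror the study
designs: a segmentation-method benchmark (three segmenters x one LR
classifier on the layer-1 task) and a selector x model accuracy grid on
the layer-2 task.  A PCA decision-boundary plot is provided for visual
diagnostics.

Positive classes are fixed: layer 1 = {P,F}, layer 2 = P.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA
from sklearn.metrics import auc as sk_auc
from sklearn.metrics import roc_curve as sk_roc_curve
from sklearn.model_selection import StratifiedKFold

from . import classify as clf_mod
from . import features as feat_mod
from . import segmentation as seg_mod
from .classify import ModelSpec, train
from .features import FeatureConfig, FeatureTable
from .roi import Layer
from .synthetic import LabeledImage


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_predictions(cls, y_true, y_pred, positive=1) -> "ConfusionCounts":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        pos_t = y_true == positive
        pos_p = y_pred == positive
        return cls(
            tp=int((pos_t & pos_p).sum()), tn=int((~pos_t & ~pos_p).sum()),
            fp=int((~pos_t & pos_p).sum()), fn=int((pos_t & ~pos_p).sum()),
        )


@dataclass
class MetricSet:
    accuracy: float
    precision: float
    recall: float
    f1: float
    flags: set = field(default_factory=set)


def metrics(counts: ConfusionCounts) -> MetricSet:
    """Accuracy / precision / recall / F1 from confusion counts.

    A zero denominator yields a flagged 0.0 (flag names the metric) rather
    than an exception; all-zero counts are rejected.
    """
    if counts.total == 0:
        raise ValueError("all confusion counts are zero")
    flags: set = set()

    def safe(num, den, name):
        if den == 0:
            flags.add(name)
            return 0.0
        return num / den

    acc = (counts.tp + counts.tn) / counts.total
    prec = safe(counts.tp, counts.tp + counts.fp, "precision")
    rec = safe(counts.tp, counts.tp + counts.fn, "recall")
    f1 = safe(2 * prec * rec, prec + rec, "f1")
    return MetricSet(accuracy=acc, precision=prec, recall=rec, f1=f1, flags=flags)


def roc_auc(scores, labels) -> tuple[list[tuple[float, float]], float]:
    """ROC points (FPR, TPR) and trapezoidal AUC for binary labels.

    Thresholds sweep the distinct scores with ties grouped, so the AUC
    equals the pairwise-concordance (Mann-Whitney) statistic with half
    credit for tied scores.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("both classes must be present for a ROC curve")
    fpr, tpr, _ = sk_roc_curve(labels, scores, drop_intermediate=False)
    points = list(zip(fpr.tolist(), tpr.tolist()))
    return points, float(sk_auc(fpr, tpr))


@dataclass
class EvalReport:
    counts: ConfusionCounts
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float
    roc_points: list[tuple[float, float]]
    split_id: str = ""
    seed: int = 0
    model: str = ""
    flags: set = field(default_factory=set)
    runtime_s: float | None = None   # reported, never asserted

    def as_dict(self) -> dict:
        return {
            "model": self.model, "split_id": self.split_id, "seed": self.seed,
            "tp": self.counts.tp, "tn": self.counts.tn,
            "fp": self.counts.fp, "fn": self.counts.fn,
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "f1": self.f1, "auc": self.auc,
            "flags": sorted(self.flags), "runtime_s": self.runtime_s,
        }


def evaluate_predictions(y_true, y_pred, scores, *, positive=1, split_id="",
                         seed=0, model="", runtime_s=None) -> EvalReport:
    counts = ConfusionCounts.from_predictions(y_true, y_pred, positive)
    m = metrics(counts)
    if np.unique(np.asarray(y_true)).size >= 2:
        points, area = roc_auc(scores, np.asarray(y_true) == positive)
    else:
        points, area = [(0.0, 0.0), (1.0, 1.0)], 0.0
        m.flags.add("auc")
    return EvalReport(
        counts=counts, accuracy=m.accuracy, precision=m.precision, recall=m.recall,
        f1=m.f1, auc=area, roc_points=points, split_id=split_id, seed=seed,
        model=model, flags=m.flags, runtime_s=runtime_s,
    )


def stratified_split(labels, ratios=(0.6, 0.2, 0.2), seed: int = 0):
    """Deterministic stratified train/validation/test index partition.

    Per-class proportions are preserved to rounding; the three index arrays
    are disjoint and exhaustive.
    """
    ratios = tuple(float(r) for r in ratios)
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train_idx, val_idx, test_idx = [], [], []
    for cls in sorted(np.unique(labels).tolist()):
        idx = np.flatnonzero(labels == cls)
        if idx.size < 3:
            raise ValueError(f"class {cls!r} has fewer than 3 members")
        idx = rng.permutation(idx)
        n = idx.size
        n_tr = int(round(ratios[0] * n))
        n_val = int(round(ratios[1] * n))
        n_tr = min(n_tr, n)
        n_val = min(n_val, n - n_tr)
        train_idx.append(idx[:n_tr])
        val_idx.append(idx[n_tr:n_tr + n_val])
        test_idx.append(idx[n_tr + n_val:])
    return (np.sort(np.concatenate(train_idx)),
            np.sort(np.concatenate(val_idx)),
            np.sort(np.concatenate(test_idx)))


def cross_validate(model_spec: ModelSpec, table: FeatureTable,
                   folds: int = 5, seed: int = 0) -> tuple[list[EvalReport], dict]:
    """Stratified k-fold evaluation: per-fold reports plus mean/std summary."""
    y = np.asarray(table.labels)
    _, class_counts = np.unique(y, return_counts=True)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if folds > class_counts.min():
        raise ValueError("folds cannot exceed the smallest class size")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    reports = []
    for i, (tr, te) in enumerate(skf.split(table.matrix, y)):
        model = train(model_spec, table.subset_rows(tr))
        te_tab = table.subset_rows(te)
        y_pred = model.predict_table(te_tab)
        scores = model.predict_scores(te_tab.matrix, te_tab.feature_names)
        reports.append(evaluate_predictions(
            te_tab.labels, y_pred, scores, split_id=f"fold{i}", seed=seed,
            model=model_spec.algorithm,
        ))
    summary = {}
    for name in ("accuracy", "precision", "recall", "f1", "auc"):
        vals = np.array([getattr(r, name) for r in reports])
        summary[name] = {"mean": float(vals.mean()), "std": float(vals.std())}
    return reports, summary


def _fit_eval_on_split(model_spec, table, seed, ratios=(0.6, 0.2, 0.2)):
    tr, _va, te = stratified_split(table.labels, ratios, seed)
    model = train(model_spec, table.subset_rows(tr))
    te_tab = table.subset_rows(te)
    y_pred = model.predict_table(te_tab)
    scores = model.predict_scores(te_tab.matrix, te_tab.feature_names)
    return evaluate_predictions(
        te_tab.labels, y_pred, scores, split_id="test", seed=seed,
        model=model_spec.algorithm,
    )


def segmentation_benchmark(
    corpus: Sequence[LabeledImage],
    methods: Sequence[str] = seg_mod.METHODS,
    classifier_spec: ModelSpec | None = None,
    seed: int = 0,
    feature_config: FeatureConfig | None = None,
    max_failure_fraction: float = 0.1,
) -> list[dict]:
    """Layer-1 accuracy of one classifier under each segmentation method.

    For each method: segment the corpus, extract the 14 layer-1 factors,
    fit the classifier (logistic regression by default, study weighting
    1/1/2) on the stratified train split and report test metrics plus
    wall-clock processing time (reported, never asserted).  A method
    failing on more than ``max_failure_fraction`` of images is flagged and
    skipped; the others proceed.
    """
    classifier_spec = classifier_spec or ModelSpec("lr", seed=seed)
    fcfg = feature_config or FeatureConfig()
    rows = []
    for method in methods:
        t0 = time.perf_counter()
        usable, segs, failures = [], [], 0
        for img in corpus:
            try:
                seg = seg_mod.segment(img.pixels, method, fcfg.seg_params)
                if seg.degenerate or not seg.mask.any():
                    raise ValueError("degenerate mask")
                usable.append(img)
                segs.append(seg)
            except Exception:
                failures += 1
        if failures > max_failure_fraction * len(corpus):
            rows.append({"method": method, "flagged": True,
                         "failures": failures, "n": len(corpus)})
            continue
        table = feat_mod.build_feature_table(usable, Layer.L1, config=fcfg,
                                             seg_results=segs)
        report = _fit_eval_on_split(classifier_spec, table, seed)
        elapsed = time.perf_counter() - t0
        rows.append({
            "method": method, "flagged": False, "failures": failures,
            "n": len(corpus), "accuracy": report.accuracy,
            "precision": report.precision, "recall": report.recall,
            "f1": report.f1, "auc": report.auc, "processing_time_s": elapsed,
        })
    return rows


def grid_experiment(
    table: FeatureTable,
    selectors: Sequence[str] = ("rf_mda", "rfe", "lasso", "ridge"),
    models: Sequence[str] = ("svm", "rf", "lr", "knn", "s_rf", "s_lr"),
    seed: int = 0,
    include_identity: bool = False,
    detail_floor: float = 0.85,
    selector_config: dict | None = None,
) -> tuple[dict, dict]:
    """Selector x model test-accuracy grid on the layer-2 (P vs F) task.

    Selection is fit on the training split only (no leakage).  Returns
    (accuracy matrix keyed [selector][model], detail reports for cells at
    or above ``detail_floor``).  An empty selector output flags its row's
    cells rather than aborting the grid.
    """
    from . import selection as sel_mod

    selector_config = selector_config or {}
    tr, _va, te = stratified_split(table.labels, seed=seed)
    train_tab = table.subset_rows(tr)
    test_tab = table.subset_rows(te)
    selector_list = list(selectors) + (["identity"] if include_identity else [])
    matrix: dict = {}
    details: dict = {}
    for sel_name in selector_list:
        if sel_name == "identity":
            kept = list(table.feature_names)
        else:
            cfg = dict(selector_config.get(sel_name, {}))
            cfg.setdefault("seed", seed)
            result = sel_mod.select(train_tab, sel_name, cfg)
            kept = result.selected
        matrix[sel_name] = {}
        if not kept:
            for model_name in models:
                matrix[sel_name][model_name] = None  # flagged cell
            continue
        tr_sub = train_tab.subset_columns(kept)
        te_sub = test_tab.subset_columns(kept)
        for model_name in models:
            spec = ModelSpec(model_name, seed=seed)
            model = train(spec, tr_sub)
            y_pred = model.predict_table(te_sub)
            scores = model.predict_scores(te_sub.matrix, te_sub.feature_names)
            report = evaluate_predictions(
                te_sub.labels, y_pred, scores, split_id="test", seed=seed,
                model=f"{sel_name}+{model_name}",
            )
            matrix[sel_name][model_name] = report.accuracy
            if report.accuracy >= detail_floor:
                details[(sel_name, model_name)] = report
    return matrix, details


def pca_boundary_plot(table: FeatureTable, model_spec: ModelSpec, out_path,
                      grid_res: int = 200) -> str:
    """2-D PCA projection with the model's decision regions rasterized.

    Purely diagnostic: fits a 2-component PCA on the standardized features,
    trains the model on the scores, and writes a PNG of decision regions
    with the projected samples scattered on top.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    X = table.matrix
    if X.shape[1] < 2:
        raise ValueError("need at least two features for a PCA plot")
    if np.allclose(X.std(axis=0), 0):
        raise ValueError("constant feature table; PCA undefined")
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    pca = PCA(n_components=2, random_state=model_spec.seed)
    Z = pca.fit_transform((X - mu) / sd)
    table2 = FeatureTable(
        matrix=Z, labels=table.labels, weights=table.weights,
        feature_names=["PC1", "PC2"], layer=table.layer, task=table.task,
    )
    model = train(model_spec, table2)
    x0, x1 = Z[:, 0].min() - 1, Z[:, 0].max() + 1
    y0, y1 = Z[:, 1].min() - 1, Z[:, 1].max() + 1
    xx, yy = np.meshgrid(np.linspace(x0, x1, grid_res), np.linspace(y0, y1, grid_res))
    grid = np.column_stack([xx.ravel(), yy.ravel()])
    zz = model.predict(grid).reshape(xx.shape).astype(float)
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.contourf(xx, yy, zz, alpha=0.25, levels=[-0.5, 0.5, 1.5], colors=["tab:blue", "tab:red"])
    for cls, color in zip(sorted(np.unique(table.labels).tolist()), ("tab:blue", "tab:red")):
        sel = table.labels == cls
        ax.scatter(Z[sel, 0], Z[sel, 1], s=12, c=color, label=str(cls), edgecolors="none")
    ax.set_xlabel(f"PC1 ({pca.explained_variance_ratio_[0]:.0%} var)")
    ax.set_ylabel(f"PC2 ({pca.explained_variance_ratio_[1]:.0%} var)")
    ax.legend(title="class")
    ax.set_title(f"{model_spec.algorithm} decision regions in PCA space")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return str(out_path)
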