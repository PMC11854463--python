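"""Model zoo and the two-layer grade classifier.

Layer 1 separates second-grade blocks from the rest ({P,F} vs S, 14
features, class weights 1/2 to balance the 2:1 image counts); layer 2
separates premium from first-grade (P vs F) on a selected subset of the 38
layer-2 features.  Base learners are SVM (RBF), random forest, logistic
regression and KNN; the two stacking variants feed out-of-fold class
probabilities of RF/LR/KNN into a random-forest (S-RF) or logistic (S-LR)
meta-learner.

SVM, LR and KNN consume standardized features (train-set mean/variance);
tree ensembles consume raw features.  All randomness is seeded through
:class:`ModelSpec`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from . import features as feat_mod
from . import segmentation as seg_mod
from . import selection as sel_mod
from .features import FeatureConfig, FeatureTable
from .roi import Layer
from .synthetic import GradeLabel, LabeledImage

ALGORITHMS = ("svm", "rf", "lr", "knn", "s_rf", "s_lr")
STACKING_BASES = ("rf", "lr", "knn")
_NEEDS_SCALING = {"svm", "lr", "knn"}


@dataclass(frozen=True)
class ModelSpec:
    algorithm: str
    hyperparams: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(
                f"unknown algorithm {self.algorithm!r}; choose from {ALGORITHMS}"
            )


def _make_estimator(spec: ModelSpec):
    hp = dict(spec.hyperparams)
    if spec.algorithm == "svm":
        return SVC(kernel=hp.get("kernel", "rbf"), C=hp.get("C", 1.0),
                   gamma=hp.get("gamma", "scale"), random_state=spec.seed)
    if spec.algorithm == "rf":
        return RandomForestClassifier(
            n_estimators=hp.get("n_estimators", 500), random_state=spec.seed)
    if spec.algorithm == "lr":
        return LogisticRegression(C=hp.get("C", 1.0), max_iter=hp.get("max_iter", 2000),
                                  random_state=spec.seed)
    if spec.algorithm == "knn":
        return KNeighborsClassifier(n_neighbors=hp.get("k", 5))
    raise ValueError(f"{spec.algorithm} is not a base algorithm")


class _Scaler:
    """Train-set standardization, population variance; zero-variance safe."""

    def fit(self, X: np.ndarray) -> "_Scaler":
        self.mu_ = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        self.sd_ = sd
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mu_) / self.sd_


@dataclass
class TrainedModel:
    """A fitted classifier bound to a feature-name order.

    ``predict``/``predict_scores`` require the exact feature set, in the
    same order, as seen at fit time.
    """

    spec: ModelSpec
    estimator: object
    scaler: Optional[_Scaler]
    feature_names: tuple[str, ...]
    classes: tuple

    def _prepare(self, X: np.ndarray, feature_names: Sequence[str] | None) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if feature_names is not None and tuple(feature_names) != self.feature_names:
            raise ValueError("feature names/order differ from those bound at fit time")
        if X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"expected {len(self.feature_names)} features, got {X.shape[1]}"
            )
        return self.scaler.transform(X) if self.scaler is not None else X

    def predict(self, X, feature_names: Sequence[str] | None = None) -> np.ndarray:
        return self.estimator.predict(self._prepare(X, feature_names))

    def predict_scores(self, X, feature_names: Sequence[str] | None = None) -> np.ndarray:
        """Real-valued score for the positive (larger) class, for ROC curves."""
        Xp = self._prepare(X, feature_names)
        if hasattr(self.estimator, "predict_proba"):
            proba = self.estimator.predict_proba(Xp)
            return proba[:, int(np.argmax(self.estimator.classes_))]
        return self.estimator.decision_function(Xp)

    def predict_table(self, table: FeatureTable) -> np.ndarray:
        return self.predict(table.matrix, table.feature_names)


def train_base(spec: ModelSpec, table: FeatureTable) -> TrainedModel:
    """Fit one base learner (svm/rf/lr/knn) on a binary feature table."""
    y = np.asarray(table.labels)
    if np.unique(y).size < 2:
        raise ValueError("single-class table; nothing to separate")
    est = _make_estimator(spec)
    scaler = _Scaler().fit(table.matrix) if spec.algorithm in _NEEDS_SCALING else None
    X = scaler.transform(table.matrix) if scaler is not None else table.matrix
    if spec.algorithm == "knn":
        est.fit(X, y)  # KNN has no sample_weight support
    else:
        est.fit(X, y, sample_weight=table.weights)
    return TrainedModel(
        spec=spec, estimator=est, scaler=scaler,
        feature_names=tuple(table.feature_names), classes=tuple(np.unique(y)),
    )


class _StackedEstimator:
    """RF+LR+KNN base layer feeding a meta learner on out-of-fold probabilities."""

    def __init__(self, meta: str, folds: int, seed: int, use_proba: bool = True):
        self.meta = meta
        self.folds = folds
        self.seed = seed
        self.use_proba = use_proba

    def fit(self, X: np.ndarray, y: np.ndarray, sample_weight: np.ndarray | None = None):
        n = len(y)
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.folds > n:
            raise ValueError("folds cannot exceed the number of samples")
        self.classes_ = np.unique(y)
        base_specs = [
            ModelSpec(a, seed=self.seed + i + 1) for i, a in enumerate(STACKING_BASES)
        ]
        skf = StratifiedKFold(n_splits=self.folds, shuffle=True, random_state=self.seed)
        meta_X = np.zeros((n, len(base_specs)))
        for tr, te in skf.split(X, y):
            sub = FeatureTable(
                matrix=X[tr], labels=y[tr],
                weights=np.ones(len(tr)) if sample_weight is None else sample_weight[tr],
                feature_names=[f"x{j}" for j in range(X.shape[1])],
                layer="L2", task="stack",
            )
            for b, spec in enumerate(base_specs):
                model = train_base(spec, sub)
                if self.use_proba:
                    meta_X[te, b] = model.predict_scores(X[te])
                else:
                    meta_X[te, b] = (model.predict(X[te]) == self.classes_.max())
        self.meta_features_ = meta_X
        full = FeatureTable(
            matrix=X, labels=y,
            weights=np.ones(n) if sample_weight is None else sample_weight,
            feature_names=[f"x{j}" for j in range(X.shape[1])], layer="L2", task="stack",
        )
        self.base_models_ = [train_base(spec, full) for spec in base_specs]
        if self.meta == "rf":
            self.meta_model_ = RandomForestClassifier(n_estimators=500,
                                                      random_state=self.seed)
        elif self.meta == "lr":
            self.meta_model_ = LogisticRegression(max_iter=2000, random_state=self.seed)
        else:
            raise ValueError("meta must be 'rf' or 'lr'")
        self.meta_model_.fit(meta_X, y, sample_weight=sample_weight)
        return self

    def _meta_features(self, X: np.ndarray) -> np.ndarray:
        cols = []
        for model in self.base_models_:
            if self.use_proba:
                cols.append(model.predict_scores(X))
            else:
                cols.append(model.predict(X) == self.classes_.max())
        return np.column_stack(cols)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.meta_model_.predict(self._meta_features(X))

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.meta_model_.predict_proba(self._meta_features(X))


def train_stacking(meta: str, table: FeatureTable, folds: int = 5,
                   seed: int = 0, use_proba: bool = True) -> TrainedModel:
    """Fit an S-RF (meta='rf') or S-LR (meta='lr') stacking classifier."""
    y = np.asarray(table.labels)
    if np.unique(y).size < 2:
        raise ValueError("single-class table; nothing to separate")
    est = _StackedEstimator(meta=meta, folds=folds, seed=seed, use_proba=use_proba)
    est.fit(table.matrix, y, sample_weight=table.weights)
    spec = ModelSpec(f"s_{meta}", {"folds": folds, "use_proba": use_proba}, seed=seed)
    return TrainedModel(
        spec=spec, estimator=est, scaler=None,
        feature_names=tuple(table.feature_names), classes=tuple(np.unique(y)),
    )


def train(spec: ModelSpec, table: FeatureTable) -> TrainedModel:
    """Fit any algorithm in the zoo, dispatching stacking variants."""
    if spec.algorithm in ("s_rf", "s_lr"):
        hp = spec.hyperparams
        return train_stacking(
            spec.algorithm.split("_")[1], table,
            folds=hp.get("folds", 5), seed=spec.seed,
            use_proba=hp.get("use_proba", True),
        )
    return train_base(spec, table)


@dataclass(frozen=True)
class TwoLayerConfig:
    """Everything the two-layer pipeline needs, seeds included."""

    seg_method: str = "morph_fusion"
    seg_params: seg_mod.SegParams | None = None
    feature_config: FeatureConfig | None = None
    layer1_spec: ModelSpec = field(default_factory=lambda: ModelSpec("rf"))
    selector_method: str = "rf_mda"
    selector_config: dict = field(default_factory=dict)
    layer2_spec: ModelSpec = field(default_factory=lambda: ModelSpec("s_rf"))

    def resolved_feature_config(self) -> FeatureConfig:
        base = self.feature_config or FeatureConfig()
        return replace(base, seg_method=self.seg_method, seg_params=self.seg_params)


@dataclass
class TwoLayerClassifier:
    layer1: TrainedModel               # {P,F}=1 vs S=0, 14 features
    selector: sel_mod.SelectionResult
    layer2: TrainedModel               # P=1 vs F=0, selected features
    config: TwoLayerConfig
    layer2_call_count: int = 0


def train_two_layer(images: Sequence[LabeledImage],
                    config: TwoLayerConfig | None = None) -> TwoLayerClassifier:
    """Fit the full hierarchy: segment -> L1 model -> selector -> L2 model."""
    config = config or TwoLayerConfig()
    grades = {img.grade for img in images}
    if grades != {GradeLabel.P, GradeLabel.F, GradeLabel.S}:
        raise ValueError("training corpus must contain all three grades")
    fcfg = config.resolved_feature_config()
    try:
        segs = [seg_mod.segment(img.pixels, config.seg_method, config.seg_params)
                for img in images]
    except Exception as exc:
        raise RuntimeError(f"segmentation stage failed: {exc}") from exc
    try:
        l1 = feat_mod.build_feature_table(images, Layer.L1, config=fcfg, seg_results=segs)
    except Exception as exc:
        raise RuntimeError(f"layer-1 feature stage failed: {exc}") from exc
    layer1 = train(config.layer1_spec, l1)

    pf = [(img, seg) for img, seg in zip(images, segs) if img.grade != GradeLabel.S]
    try:
        l2 = feat_mod.build_feature_table(
            [img for img, _ in pf], Layer.L2, config=fcfg,
            seg_results=[seg for _, seg in pf],
        )
    except Exception as exc:
        raise RuntimeError(f"layer-2 feature stage failed: {exc}") from exc
    try:
        selector = sel_mod.select(l2, config.selector_method, config.selector_config)
    except Exception as exc:
        raise RuntimeError(f"feature-selection stage failed: {exc}") from exc
    if not selector.selected:
        raise RuntimeError("feature-selection stage retained no features")
    layer2 = train(config.layer2_spec, l2.subset_columns(selector.selected))
    return TwoLayerClassifier(layer1=layer1, selector=selector, layer2=layer2,
                              config=config)


def predict_grade(model: TwoLayerClassifier, image) -> tuple[GradeLabel, dict]:
    """Route one image through the hierarchy.

    Layer 1 decides S vs {P,F}; an S verdict returns immediately without
    invoking layer 2.  Returns the grade plus per-layer scores.
    """
    pixels = image.pixels if isinstance(image, LabeledImage) else np.asarray(image)
    cfg = model.config
    fcfg = cfg.resolved_feature_config()
    seg = seg_mod.segment(pixels, cfg.seg_method, cfg.seg_params)
    if seg.degenerate or not seg.mask.any():
        raise ValueError("segmentation stage: degenerate mask; cannot grade image")
    v1 = feat_mod.extract_features(pixels, seg, Layer.L1, fcfg)
    X1 = v1.values[None, :]
    pred1 = int(model.layer1.predict(X1, v1.names)[0])
    info = {"layer1_score": float(model.layer1.predict_scores(X1, v1.names)[0]),
            "layer2_invoked": False, "layer2_score": None}
    if pred1 == 0:
        return GradeLabel.S, info
    v2 = feat_mod.extract_features(pixels, seg, Layer.L2, fcfg)
    name_to_idx = {n: i for i, n in enumerate(v2.names)}
    idx = [name_to_idx[n] for n in model.layer2.feature_names]
    X2 = v2.values[idx][None, :]
    model.layer2_call_count += 1
    pred2 = int(model.layer2.predict(X2)[0])
    info["layer2_invoked"] = True
    info["layer2_score"] = float(model.layer2.predict_scores(X2)[0])
    return (GradeLabel.P if pred2 == 1 else GradeLabel.F), info
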