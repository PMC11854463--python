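"""Pipeline configuration and end-to-end orchestration.

A :class:`PipelineConfig` round-trips through YAML without loss, fills
every default, and fans a single master seed out to per-stage seeds via a
stable stage-name hash so each stage is independently reproducible.
``run_pipeline`` executes generate/ingest -> segment -> ROI -> features ->
select -> train two-layer -> evaluate and stamps every artifact with the
config hash and seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import joblib
import numpy as np
import yaml

from . import classify as clf_mod
from . import features as feat_mod
from . import segmentation as seg_mod
from . import synthetic as syn_mod
from .classify import ModelSpec, TwoLayerConfig, predict_grade, train_two_layer
from .evaluation import stratified_split
from .features import FeatureConfig
from .roi import Layer
from .synthetic import GenParams, GradeLabel

logger = logging.getLogger("daqugrade")


@dataclass
class PipelineConfig:
    working_size: tuple[int, int] = (400, 600)
    seg_method: str = "morph_fusion"
    seg_params: dict = field(default_factory=dict)
    roi_scale: float | None = None          # None -> derived from working_size
    dark_v_threshold: float = 0.25
    selector_method: str = "rf_mda"
    selector_config: dict = field(default_factory=dict)
    layer1_model: dict = field(default_factory=lambda: {"algorithm": "rf"})
    layer2_model: dict = field(default_factory=lambda: {"algorithm": "s_rf"})
    split_ratios: tuple[float, float, float] = (0.6, 0.2, 0.2)
    master_seed: int = 0
    n_per_grade: int = 30
    gen_params: dict = field(default_factory=dict)
    out_dir: str = "daqugrade_out"

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed: (master_seed + crc32(stage)) mod 2^31."""
        return int((self.master_seed + zlib.crc32(stage.encode())) % (2 ** 31))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["working_size"] = list(self.working_size)
        d["split_ratios"] = list(self.split_ratios)
        return d

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def seg_params_obj(self) -> seg_mod.SegParams:
        return seg_mod.SegParams(**self.seg_params) if self.seg_params else seg_mod.SegParams(
            seed=self.stage_seed("segment"))

    def gen_params_obj(self) -> GenParams:
        kwargs = dict(self.gen_params)
        kwargs.setdefault("image_size", tuple(self.working_size))
        if "image_size" in kwargs:
            kwargs["image_size"] = tuple(kwargs["image_size"])
        return GenParams(**kwargs)

    def feature_config(self) -> FeatureConfig:
        return FeatureConfig(
            dark_v_threshold=self.dark_v_threshold, roi_scale=self.roi_scale,
            seg_method=self.seg_method, seg_params=self.seg_params_obj(),
        )

    def two_layer_config(self) -> TwoLayerConfig:
        return TwoLayerConfig(
            seg_method=self.seg_method, seg_params=self.seg_params_obj(),
            feature_config=self.feature_config(),
            layer1_spec=_model_spec(self.layer1_model, self.stage_seed("layer1")),
            selector_method=self.selector_method,
            selector_config={"seed": self.stage_seed("select"), **self.selector_config},
            layer2_spec=_model_spec(self.layer2_model, self.stage_seed("layer2")),
        )


def _model_spec(d: dict, seed: int) -> ModelSpec:
    d = dict(d)
    algo = d.pop("algorithm", "rf")
    explicit_seed = d.pop("seed", None)
    return ModelSpec(algo, hyperparams=d, seed=seed if explicit_seed is None else explicit_seed)


def validate_config(path_or_dict) -> PipelineConfig:
    """Load + validate a config file (or dict), gathering *all* errors.

    An empty file yields the full-default configuration.  Raises
    ``ValueError`` whose message lists every problem found.
    """
    if isinstance(path_or_dict, dict):
        raw = dict(path_or_dict)
    else:
        path = Path(path_or_dict)
        try:
            loaded = yaml.safe_load(path.read_text())
        except yaml.YAMLError as exc:
            raise ValueError(f"malformed config file {path}: {exc}") from exc
        raw = loaded or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")

    errors: list[str] = []
    known = set(PipelineConfig.__dataclass_fields__)
    for key in raw:
        if key not in known:
            errors.append(f"unknown key {key!r}")
    kwargs = {k: v for k, v in raw.items() if k in known}
    if "working_size" in kwargs:
        kwargs["working_size"] = tuple(kwargs["working_size"])
    if "split_ratios" in kwargs:
        kwargs["split_ratios"] = tuple(kwargs["split_ratios"])

    seg_method = kwargs.get("seg_method", "morph_fusion")
    if seg_method not in seg_mod.METHODS:
        errors.append(f"unknown segmentation method {seg_method!r}")
    selector = kwargs.get("selector_method", "rf_mda")
    from . import selection as sel_mod
    if selector not in sel_mod.METHODS:
        errors.append(f"unknown selector method {selector!r}")
    for key in ("layer1_model", "layer2_model"):
        algo = (kwargs.get(key) or {}).get("algorithm")
        if algo is not None and algo not in clf_mod.ALGORITHMS:
            errors.append(f"{key}: unknown algorithm {algo!r}")
    ratios = kwargs.get("split_ratios", (0.6, 0.2, 0.2))
    if abs(sum(ratios) - 1.0) > 1e-9:
        errors.append("ratios must sum to 1")
    if kwargs.get("n_per_grade", 30) < 1:
        errors.append("n_per_grade must be >= 1")
    if not 0 <= kwargs.get("dark_v_threshold", 0.25) <= 1:
        errors.append("dark_v_threshold must lie in [0, 1]")
    if errors:
        raise ValueError("invalid configuration: " + "; ".join(errors))
    cfg = PipelineConfig(**kwargs)
    try:
        cfg.gen_params_obj()
        cfg.seg_params_obj()
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid configuration: {exc}") from exc
    return cfg


def _load_corpus(data_dir: Path, working_params: GenParams) -> list[syn_mod.LabeledImage]:
    import csv as _csv

    manifest = data_dir / "manifest.csv"
    if not manifest.exists():
        raise FileNotFoundError(f"{manifest} not found; expected a generated dataset")
    images = []
    with open(manifest) as fh:
        for rec in _csv.DictReader(fh):
            pixels = syn_mod.load_image(data_dir / rec["path"])
            images.append(syn_mod.LabeledImage(
                pixels=pixels, grade=GradeLabel(rec["grade"]),
                seed=int(rec["seed"]), params=working_params, image_id=rec["id"],
            ))
    return images


def run_pipeline(config: PipelineConfig, data_dir=None) -> dict:
    """Execute the full grading pipeline and write its artifacts.

    Artifacts (under ``config.out_dir``): the effective config + hash,
    dataset manifest, layer-1/-2 feature CSVs, selection CSV/JSON, the
    trained two-layer model (joblib), and evaluation JSON with three-class
    test accuracy and per-stage counts/durations.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": config.config_hash(), "master_seed": config.master_seed}
    config.to_yaml(out / "config.yaml")
    log: dict = {"stages": {}}

    def stage(name):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, exc_type, exc, tb):
                log["stages"][name] = {"seconds": time.perf_counter() - self.t0}
                if exc is not None:
                    logger.error("stage %s failed: %s", name, exc)
                return False
        return _T()

    gp = config.gen_params_obj()
    with stage("generate"):
        if data_dir is None:
            images, manifest = syn_mod.generate_dataset(
                config.n_per_grade, gp, config.stage_seed("generate"))
            syn_mod.write_dataset(images, manifest, out / "images")
        else:
            images = _load_corpus(Path(data_dir), gp)
    log["stages"]["generate"]["n_images"] = len(images)

    grades = np.array([img.grade.value for img in images])
    tr, va, te = stratified_split(grades, config.split_ratios,
                                  config.stage_seed("split"))
    fcfg = config.feature_config()

    with stage("train"):
        model = train_two_layer([images[i] for i in tr], config.two_layer_config())

    with stage("features"):
        segs = [seg_mod.segment(images[i].pixels, config.seg_method,
                                config.seg_params_obj()) for i in tr]
        l1 = feat_mod.build_feature_table([images[i] for i in tr], Layer.L1,
                                          config=fcfg, seg_results=segs)
        l1.to_csv(out / "features_l1.csv")
        pf = [(images[i], s) for i, s in zip(tr, segs)
              if images[i].grade != GradeLabel.S]
        l2 = feat_mod.build_feature_table([im for im, _ in pf], Layer.L2,
                                          config=fcfg, seg_results=[s for _, s in pf])
        l2.to_csv(out / "features_l2.csv")

    with stage("selection"):
        sel = model.selector
        import pandas as pd
        pd.DataFrame({
            "feature": list(sel.feature_names),
            "score": sel.scores,
            "selected": [n in sel.selected for n in sel.feature_names],
        }).to_csv(out / "selection.csv", index=False)
        (out / "selection.json").write_text(json.dumps({
            "method": sel.method, "lambda_opt": sel.lambda_opt,
            "cv_curve": sel.cv_curve, **stamp,
        }, indent=2))

    with stage("evaluate"):
        correct = 0
        confusion: dict = {}
        for i in te:
            pred, _info = predict_grade(model, images[i])
            truth = images[i].grade
            confusion[(truth.value, pred.value)] = confusion.get(
                (truth.value, pred.value), 0) + 1
            correct += int(pred == truth)
        accuracy = correct / len(te)

    joblib.dump({"model": model, **stamp}, out / "model.joblib")
    summary = {
        **stamp,
        "n_images": len(images),
        "splits": {"train": len(tr), "val": len(va), "test": len(te)},
        "selected_features": list(model.selector.selected),
        "test_accuracy_3class": accuracy,
        "confusion": {f"{t}->{p}": c for (t, p), c in sorted(confusion.items())},
        "stages": log["stages"],
    }
    (out / "evaluation.json").write_text(json.dumps(summary, indent=2))
    logger.info("pipeline done: accuracy=%.3f artifacts=%s", accuracy, out)
    return summary
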