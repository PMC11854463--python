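"""Color and pixel feature factors of a segmented Daqu cross-section.

Two fixed feature sets feed the two classification layers:

* **Layer 1 (14 factors)** — RGB means/stds, HSV means/stds (hue treated
  circularly) over the center ROI, plus two pixel factors on the whole
  block: the area of the minimum bounding rectangle (RectArea) and the
  count of dark foreground pixels (DarkArea, HSV value below a threshold).
* **Layer 2 (38 factors)** — the same 14 at the narrower layer-2 center
  geometry, plus 4-bin RGB histograms (bin edges 0–63 / 64–127 / 128–191 /
  192–255, stored as proportions) for both the center and the Pizhang ROI:
  2 ROIs x 3 channels x 4 bins = 24 histogram factors.

Feature order is frozen; tables keep labels and per-sample weights next to
the matrix and round-trip through CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats
from skimage import color as skcolor

from . import roi as roi_mod
from . import segmentation as seg_mod
from .roi import Layer
from .synthetic import GradeLabel, LabeledImage

COLOR_STAT_NAMES = (
    "MeanRed", "MeanGreen", "MeanBlue", "StdRed", "StdGreen", "StdBlue",
    "MeanHue", "MeanSaturation", "MeanValue", "StdHue", "StdSaturation", "StdValue",
)
PIXEL_NAMES = ("RectArea", "DarkArea")
_CHANNELS = ("Red", "Green", "Blue")


def histogram_names(prefix: str) -> tuple[str, ...]:
    return tuple(f"{prefix}_{ch}_Bin{b}" for ch in _CHANNELS for b in range(1, 5))


FEATURE_NAMES_L1: tuple[str, ...] = COLOR_STAT_NAMES + PIXEL_NAMES
FEATURE_NAMES_L2: tuple[str, ...] = (
    FEATURE_NAMES_L1 + histogram_names("Center") + histogram_names("Pizhang")
)
assert len(FEATURE_NAMES_L1) == 14 and len(FEATURE_NAMES_L2) == 38


@dataclass(frozen=True)
class FeatureConfig:
    dark_v_threshold: float = 0.25   # HSV value below this counts as "dark"
    roi_scale: float | None = None   # None -> derived from image size
    seg_method: str = "morph_fusion"
    seg_params: seg_mod.SegParams | None = None


@dataclass
class FeatureVector:
    values: np.ndarray
    names: tuple[str, ...]
    layer: Layer

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        expected = FEATURE_NAMES_L1 if self.layer == Layer.L1 else FEATURE_NAMES_L2
        if tuple(self.names) != expected:
            raise ValueError("feature names do not match the frozen order for this layer")
        if self.values.shape != (len(expected),):
            raise ValueError(f"expected {len(expected)} values, got {self.values.shape}")


@dataclass
class FeatureTable:
    """n x p feature matrix with labels, sample weights and frozen column order."""

    matrix: np.ndarray
    labels: np.ndarray            # binary task labels (1 = positive class)
    weights: np.ndarray
    feature_names: Sequence[str]
    layer: str | Layer
    task: str = ""
    grades: np.ndarray | None = None   # original grade letters, when known

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D")
        n, p = self.matrix.shape
        if len(self.labels) != n or len(self.weights) != n:
            raise ValueError("labels/weights length must match the number of rows")
        if len(self.feature_names) != p:
            raise ValueError("feature_names length must match the number of columns")
        if not np.isfinite(self.matrix).all():
            raise ValueError("feature matrix contains non-finite values")
        if (self.weights <= 0).any():
            raise ValueError("weights must be positive")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def p(self) -> int:
        return self.matrix.shape[1]

    def data_point_counts(self) -> dict:
        """Weighted data points per class: sum over rows of weight x p."""
        out: dict = {}
        for cls in np.unique(self.labels):
            sel = self.labels == cls
            out[cls.item() if hasattr(cls, "item") else cls] = float(
                self.weights[sel].sum() * self.p
            )
        return out

    def subset_columns(self, names: Sequence[str]) -> "FeatureTable":
        idx = [list(self.feature_names).index(n) for n in names]
        return FeatureTable(
            matrix=self.matrix[:, idx], labels=self.labels, weights=self.weights,
            feature_names=list(names), layer=self.layer, task=self.task,
            grades=self.grades,
        )

    def subset_rows(self, idx) -> "FeatureTable":
        idx = np.asarray(idx)
        return FeatureTable(
            matrix=self.matrix[idx], labels=self.labels[idx], weights=self.weights[idx],
            feature_names=list(self.feature_names), layer=self.layer, task=self.task,
            grades=None if self.grades is None else self.grades[idx],
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, columns=list(self.feature_names))
        df.insert(0, "weight", self.weights)
        df.insert(0, "label", self.labels)
        if self.grades is not None:
            df.insert(0, "grade", self.grades)
        return df

    def to_csv(self, path) -> Path:
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path, layer, task: str = "") -> "FeatureTable":
        df = pd.read_csv(path)
        grades = df.pop("grade").to_numpy() if "grade" in df.columns else None
        labels = df.pop("label").to_numpy()
        weights = df.pop("weight").to_numpy()
        return cls(
            matrix=df.to_numpy(dtype=np.float64), labels=labels, weights=weights,
            feature_names=list(df.columns), layer=layer, task=task, grades=grades,
        )


def _masked_pixels(image: np.ndarray, roi_mask: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an HxWx3 image")
    if image.shape[:2] != roi_mask.shape:
        raise ValueError("mask shape does not match image")
    if not roi_mask.any():
        raise ValueError("ROI mask is empty")
    return image[roi_mask]


def color_stats(image: np.ndarray, roi_mask: np.ndarray) -> np.ndarray:
    """The 12 color factors over the masked pixels.

    RGB statistics are on the 0–255 scale; HSV on [0, 1].  Standard
    deviations use the population (n) divisor.  Hue is circular, so its
    mean and std are the circular versions (a hue of 0.99 and 0.01 average
    to 0, not 0.5).
    """
    px = _masked_pixels(image, roi_mask).astype(np.float64)
    rgb_mean = px.mean(axis=0)
    rgb_std = px.std(axis=0)
    hsv = skcolor.rgb2hsv(px[None, :, :] / 255.0)[0]
    hue = hsv[:, 0]
    mean_hue = float(sstats.circmean(hue, high=1.0, low=0.0))
    std_hue = float(sstats.circstd(hue, high=1.0, low=0.0))
    mean_s, mean_v = hsv[:, 1].mean(), hsv[:, 2].mean()
    std_s, std_v = hsv[:, 1].std(), hsv[:, 2].std()
    return np.array([
        rgb_mean[0], rgb_mean[1], rgb_mean[2],
        rgb_std[0], rgb_std[1], rgb_std[2],
        mean_hue, mean_s, mean_v, std_hue, std_s, std_v,
    ])


def pixel_features(mask: np.ndarray, image: np.ndarray,
                   dark_v_threshold: float = 0.25) -> np.ndarray:
    """(RectArea, DarkArea) on the whole-block mask.

    RectArea is the pixel area of the minimum bounding rectangle; DarkArea
    counts foreground pixels whose HSV value channel (max RGB / 255) falls
    below ``dark_v_threshold``.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    rect = roi_mod.min_bounding_rect(mask)
    px = _masked_pixels(image, mask).astype(np.float64)
    value = px.max(axis=1) / 255.0
    dark = int((value < dark_v_threshold).sum())
    return np.array([float(rect.area), float(dark)])


def rgb_histogram_4bin(image: np.ndarray, roi_mask: np.ndarray) -> np.ndarray:
    """Per-channel 4-bin histogram proportions (bins 0–63/64–127/128–191/192–255)."""
    px = _masked_pixels(image, roi_mask)
    out = np.empty(12)
    n = px.shape[0]
    for c in range(3):
        bins = np.bincount(px[:, c].astype(np.int64) // 64, minlength=4)[:4]
        out[4 * c:4 * c + 4] = bins / n
    return out


def extract_features(
    image,
    seg_result: seg_mod.SegmentationResult,
    layer,
    config: FeatureConfig | None = None,
) -> FeatureVector:
    """Full feature factor vector for one image: 14 (L1) or 38 (L2) values."""
    config = config or FeatureConfig()
    layer = roi_mod._as_layer(layer)
    pixels = image.pixels if isinstance(image, LabeledImage) else np.asarray(image)
    if seg_result.degenerate or not seg_result.mask.any():
        raise ValueError(
            f"segmentation ({seg_result.method}) is degenerate; no foreground to measure"
        )
    part = roi_mod.partition(seg_result.mask, layer, config.roi_scale)
    if not part.center_mask.any():
        raise ValueError("center ROI contains no foreground pixels")
    values = [
        color_stats(pixels, part.center_mask),
        pixel_features(seg_result.mask, pixels, config.dark_v_threshold),
    ]
    names: tuple[str, ...] = FEATURE_NAMES_L1
    if layer == Layer.L2:
        if part.pizhang_empty:
            raise ValueError("Pizhang ROI is empty; layer-2 histograms undefined")
        values.append(rgb_histogram_4bin(pixels, part.center_mask))
        values.append(rgb_histogram_4bin(pixels, part.pizhang_mask))
        names = FEATURE_NAMES_L2
    return FeatureVector(values=np.concatenate(values), names=names, layer=layer)


DEFAULT_L1_WEIGHTS = {"P": 1.0, "F": 1.0, "S": 2.0}

TASKS = {"L1": "PF_vs_S", "L2": "P_vs_F"}


def build_feature_table(
    dataset: Sequence[LabeledImage],
    layer,
    task: str | None = None,
    weight_map: Mapping[str, float] | None = None,
    config: FeatureConfig | None = None,
    seg_results: Sequence[seg_mod.SegmentationResult] | None = None,
) -> FeatureTable:
    """Segment + extract features for a corpus and assemble the task table.

    Layer 1 uses all images with labels {P,F} -> 1, S -> 0 and default
    class weights (1, 1, 2) so the two sides of the task carry equal
    weighted data points; layer 2 uses only P/F images (P -> 1) with unit
    weights.  Pass ``weight_map={}`` for all-unit weights.
    """
    config = config or FeatureConfig()
    layer = roi_mod._as_layer(layer)
    if task is None:
        task = TASKS[layer.value]
    if seg_results is None:
        seg_results = [
            seg_mod.segment(img.pixels, config.seg_method, config.seg_params)
            for img in dataset
        ]
    if len(seg_results) != len(dataset):
        raise ValueError("seg_results length must match dataset")

    if weight_map is None:
        weight_map = DEFAULT_L1_WEIGHTS if layer == Layer.L1 else {}

    rows, labels, weights, grades = [], [], [], []
    for img, seg in zip(dataset, seg_results):
        grade = img.grade
        if layer == Layer.L2 and grade == GradeLabel.S:
            continue
        vec = extract_features(img, seg, layer, config)
        rows.append(vec.values)
        if layer == Layer.L1:
            labels.append(1 if grade in (GradeLabel.P, GradeLabel.F) else 0)
        else:
            labels.append(1 if grade == GradeLabel.P else 0)
        weights.append(float(weight_map.get(grade.value, 1.0)))
        grades.append(grade.value)
    if not rows:
        raise ValueError("no usable images for this layer/task")
    names = FEATURE_NAMES_L1 if layer == Layer.L1 else FEATURE_NAMES_L2
    return FeatureTable(
        matrix=np.vstack(rows), labels=np.array(labels), weights=np.array(weights),
        feature_names=list(names), layer=layer.value, task=task,
        grades=np.array(grades),
    )
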