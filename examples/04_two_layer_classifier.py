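"""Train the full two-layer grade classifier and grade held-out images.

Layer 1 separates second-grade blocks from the rest on 14 features; for
blocks that pass, layer 2 separates premium from first-grade on a selected
subset of 38 features.  Here: morphological-fusion segmentation, RF-MDA
selection, and an S-RF (stacked random-forest) layer-2 model.
"""

import numpy as np

import daqugrade as dq
from daqugrade.classify import ModelSpec, TwoLayerConfig
from daqugrade.evaluation import stratified_split

images, _ = dq.generate_dataset(n_per_grade=30, seed=5)
grades = np.array([img.grade.value for img in images])
train_idx, _val_idx, test_idx = stratified_split(grades, seed=5)

config = TwoLayerConfig(
    seg_method="morph_fusion",
    selector_method="rf_mda",
    selector_config={"n_trees": 100, "seed": 0},
    layer2_spec=ModelSpec("s_rf", seed=0),
)
model = dq.train_two_layer([images[i] for i in train_idx], config)
print(f"layer 2 uses {len(model.layer2.feature_names)} selected features: "
      + ", ".join(model.layer2.feature_names[:5]) + ", ...")

correct = 0
for i in test_idx:
    pred, info = dq.predict_grade(model, images[i])
    correct += int(pred == images[i].grade)
print(f"three-class test accuracy: {correct / len(test_idx):.2%} "
      f"on {len(test_idx)} held-out images")
print(f"layer 2 consulted for {model.layer2_call_count} of them "
      "(second-grade verdicts stop at layer 1)")
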