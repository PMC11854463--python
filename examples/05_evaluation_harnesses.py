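"""Run the two experiment harnesses: segmentation benchmark and model grid.

The benchmark scores a logistic-regression classifier on the layer-1 task
under each segmentation method; the grid crosses the four feature
selectors with the six classifiers on the layer-2 task.
"""

import daqugrade as dq
from daqugrade.evaluation import grid_experiment, segmentation_benchmark

images, _ = dq.generate_dataset(n_per_grade=10, seed=9)

print("segmentation benchmark (layer-1 task, LR classifier):")
for row in segmentation_benchmark(images, seed=0):
    if row["flagged"]:
        print(f"  {row['method']:13s}: flagged ({row['failures']} failures)")
    else:
        print(f"  {row['method']:13s}: accuracy={row['accuracy']:.2f} "
              f"F1={row['f1']:.2f} AUC={row['auc']:.2f} "
              f"time={row['processing_time_s']:.1f}s")

pf = [img for img in images if img.grade.value != "S"]
table = dq.build_feature_table(pf, "L2")
matrix, _ = grid_experiment(
    table, selectors=["rf_mda", "ridge"], models=["lr", "rf", "s_rf"], seed=0,
    selector_config={"rf_mda": {"n_trees": 50}, "ridge": {"cv_folds": 4}},
)
print("\nselector x model test accuracy (layer-2 task):")
for sel, row in matrix.items():
    cells = "  ".join(f"{m}={a:.2f}" for m, a in row.items())
    print(f"  {sel:7s}: {cells}")

# Each accuracy is measured on the held-out 20% test split; times are
# wall-clock per segmentation run and vary by machine.
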