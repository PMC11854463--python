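"""Generate a small synthetic Daqu corpus and inspect its structure.

Each image mimics a photographed block cross-section: a bright light-box
background, a rectangular block with a raw "Pizhang" rim whose thickness
grows with grade number, and grade-specific center structure (grayish-blue
for premium, a red spot for first-grade, cracks and dark patches for
second-grade).
"""

import numpy as np

import daqugrade as dq

images, manifest = dq.generate_dataset(n_per_grade=3, seed=0)
print(f"generated {len(images)} images ({len(images) // 3} per grade)")

for img in images[::3]:
    px = img.pixels[img.true_mask].astype(float)
    dark = (px.max(axis=1) / 255 < 0.25).mean()
    print(
        f"grade {img.grade.value}: rim thickness {img.rim_thickness:2d} px, "
        f"mean block RGB = ({px[:, 0].mean():5.1f}, {px[:, 1].mean():5.1f}, "
        f"{px[:, 2].mean():5.1f}), dark-pixel fraction = {dark:.3f}"
    )

# The rim widens and the dark fraction rises from premium (P) to
# second-grade (S) — exactly the cues a human grader uses.

regen = dq.generate_daqu_image(manifest[0]["grade"], images[0].params,
                               manifest[0]["seed"])
print("manifest regenerates image 0 bit-identically:",
      np.array_equal(regen.pixels, images[0].pixels))
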