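"""Segment image statistics on procedurally generated toy paintings.

No painting images ship with the repository, so this driver synthesises a
small set of textured toy paintings with segment masks, builds the square
context-box stimuli (1.25 x margin, mean-colour overflow fill), computes the
four histogram statistics per segment, and correlates a colourfulness-coupled
synthetic attribute with the statistics to illustrate the image-statistics
analysis path.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import matsig as ms
from matsig import imstats, stimprep

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 9


def toy_painting(rng, colorful):
    """A 120x160 'painting': smooth colour field, optionally multicoloured."""
    base = rng.integers(40, 216, 3)
    img = np.tile(base, (120, 160, 1)).astype(float)
    for _ in range(8 if colorful else 2):
        r, c = rng.integers(0, 100), rng.integers(0, 140)
        patch_color = rng.integers(0, 256, 3)
        img[r:r + 30, c:c + 30] = 0.5 * img[r:r + 30, c:c + 30] + 0.5 * patch_color
    img += rng.normal(0, 6 if colorful else 2, img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


def main() -> None:
    rng = np.random.default_rng(SEED)
    rows = []
    for i in range(40):
        colorful = i % 2 == 0
        painting = toy_painting(rng, colorful)
        mask = np.zeros((120, 160), bool)
        r0, c0 = rng.integers(0, 60), rng.integers(0, 80)
        mask[r0:r0 + 50, c0:c0 + 70] = True
        seg = stimprep.SegmentMask(mask)
        stim = stimprep.render_stimulus(painting, seg)
        s = imstats.segment_stats(painting, mask)
        rows.append({"stimulus_id": f"toy_{i:02d}", "material": "toy",
                     "multicolored_truth": 70.0 if colorful else 30.0,
                     "contrast": s.contrast, "skewness": s.skewness,
                     "colorfulness": s.colorfulness,
                     "mean_luminance": s.mean_luminance,
                     "box_side": stim.box.side,
                     "overflow_px": stimprep.overflow_area(stim.box, mask.shape)})
    table = pd.DataFrame(rows).set_index("stimulus_id")
    table.to_csv(OUT / "image_statistics.csv", float_format="%.4f")

    means = table[["material"]].assign(multicolored=table["multicolored_truth"]
                                       + rng.normal(0, 5, len(table)))
    stats = table[["contrast", "skewness", "colorfulness", "mean_luminance"]]
    res = ms.imagestat_correlations(means, stats)
    r = res.r.loc["colorfulness", "multicolored"]
    stars = "*" * int(res.tiers.loc["colorfulness", "multicolored"])
    print(f"{len(table)} toy segments; colorfulness vs multicoloured attribute: "
          f"r={r:.2f}{stars} (Bonferroni tiers at alpha/{4 * 1})")
    print(f"context boxes: median side {table.box_side.median():.0f} px, "
          f"{(table.overflow_px > 0).sum()} of {len(table)} with overflow fill")


if __name__ == "__main__":
    main()
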