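"""Segment the pollen region of a synthetic image and score it against the
generator's ground truth.

The pollen region is texturally busy, so thresholding the local-entropy map
with Otsu's criterion isolates it; near-gray shadow pixels are then removed
using each pixel's distance to the achromatic diagonal of the RGB cube.
"""

import numpy as np

from pollentrace import preprocess, synth

config = synth.SynthConfig(n_producers=1, image_size=(256, 256), seed=4)
palette = synth.make_producer_palettes(config)[0]
sample = synth.render_sample_image(palette, visit=1, config=config, seed=1)

raw = preprocess.segment_pollen(sample.image, radius=5)
refined = preprocess.remove_shadows(sample.image, raw, rule="remove_low")


def iou(a, b):
    return (a & b).sum() / (a | b).sum()


shadow_in_raw = (raw & sample.shadow_mask).sum()
shadow_in_refined = (refined & sample.shadow_mask).sum()

print(f"ground-truth grain coverage: {sample.grain_mask.mean():.1%}")
print(f"raw entropy/Otsu mask:       {raw.mean():.1%} of pixels")
print(f"after shadow removal:        {refined.mean():.1%} of pixels")
print(f"IoU vs ground-truth grains:  raw {iou(raw, sample.grain_mask):.3f}, "
      f"refined {iou(refined, sample.grain_mask):.3f}")
print(f"shadow pixels retained:      {shadow_in_raw} -> {shadow_in_refined}")
# The refined mask should overlap the true grain pixels much better than the
# raw one, because the raw mask still contains the high-entropy shadow rims.
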