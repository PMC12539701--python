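"""Turn an image's pixels into a color-codebook frequency histogram.

Masked pixels are mapped to the chroma-only (u*, v*) plane of CIE L*u*v*,
quantized against a k-means codebook, and counted; the resulting k-vector
is the classifier's input feature.  With the codebook anchored at the
generator's own palette colors, the histogram estimates the producer's
mixture weights.
"""

import numpy as np

from pollentrace import features, synth
from pollentrace.colorspace import rgb_to_representation

config = synth.SynthConfig(
    n_producers=1, palette_size=16, image_size=(256, 256),
    separation=1.0, visit_drift=0.0, seed=12,
)
palette = synth.make_producer_palettes(config)[0]
sample = synth.render_sample_image(palette, visit=1, config=config, seed=3)

# codebook = the true palette colors, projected to (u*, v*)
codebook = features.ColorCodebook(
    rgb_to_representation(palette.base_colors, "uv"), "uv"
)
histogram = features.histogram_features(sample.image, sample.grain_mask, codebook)

l1 = np.abs(histogram - palette.mixture_weights).sum()
print("codebook size:", codebook.k)
print("top-5 mixture weights:", np.sort(palette.mixture_weights)[-5:].round(3))
print("top-5 histogram freqs:", np.sort(histogram)[-5:].round(3))
print(f"L1 distance histogram vs true mixture: {l1:.3f}")
# A small L1 distance means the color histogram is a faithful estimate of
# the producer's floral color composition -- the signal the classifier uses.
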