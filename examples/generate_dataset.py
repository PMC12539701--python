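"""Generate a small synthetic pollen-image dataset and inspect its structure.

Each producer gets a characteristic mixture of colors over a shared floral
palette; images are gray templates covered with colored elliptical grains
plus cast shadows, written as PNGs with a CSV manifest and ground-truth
masks.
"""

from collections import Counter

from pollentrace import synth

config = synth.SynthConfig(
    n_producers=4,          # 4 beekeepers, paired into 2 municipalities
    n_visits=2,             # 2 seasonal sampling visits
    samples_per_visit=3,
    images_per_sample=4,    # 2 acquisition rounds x 2 images, as in the field protocol
    image_size=(128, 128),
    separation=0.5,         # how distinctive producer color mixtures are
    seed=0,
)

manifest = synth.generate_dataset(config, "example_dataset")

print(f"images written: {len(manifest)}")
print(f"producer -> municipality: {manifest.producer_to_municipality}")
splits = Counter((r.split, r.acquisition_round) for r in manifest.records)
print(f"(split, acquisition round) counts: {dict(splits)}")
# Roughly 2/3 of each producer's images train the model; test images are
# split evenly between the two acquisition rounds so the classifier's
# stability over time (test-retest reliability) can be measured.
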