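"""The synthetic pollen-image generator: palettes, rendering, datasets."""

from collections import Counter

import numpy as np
import pytest

from pollentrace import model_select as ms
from pollentrace import pipeline, synth
from pollentrace.errors import ConfigError
from pollentrace.io import load_image, read_manifest


def small_config(**kw):
    base = dict(
        n_producers=4,
        n_visits=2,
        samples_per_visit=2,
        images_per_sample=4,
        image_size=(96, 96),
        seed=7,
    )
    base.update(kw)
    return synth.SynthConfig(**base)


class TestPalettes:
    def test_zero_separation_gives_identical_weights(self):
        pals = synth.make_producer_palettes(small_config(separation=0.0))
        for p in pals[1:]:
            np.testing.assert_array_equal(p.mixture_weights, pals[0].mixture_weights)

    def test_deterministic_given_seed(self):
        a = synth.make_producer_palettes(small_config())
        b = synth.make_producer_palettes(small_config())
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.mixture_weights, y.mixture_weights)
            np.testing.assert_array_equal(x.base_colors, y.base_colors)

    def test_separation_increases_weight_distance(self):
        def mean_pairwise_l1(sep):
            pals = synth.make_producer_palettes(
                small_config(n_producers=20, separation=sep)
            )
            w = np.array([p.mixture_weights for p in pals])
            dist = np.abs(w[:, None, :] - w[None, :, :]).sum(axis=2)
            return dist[np.triu_indices(20, 1)].mean()

        assert mean_pairwise_l1(0.5) > mean_pairwise_l1(0.0)

    def test_weights_are_distributions(self):
        for p in synth.make_producer_palettes(small_config(separation=0.9)):
            assert p.mixture_weights.min() >= 0
            assert abs(p.mixture_weights.sum() - 1) < 1e-9

    def test_palette_size_out_of_range_rejected(self):
        with pytest.raises(ConfigError):
            small_config(palette_size=10)
        with pytest.raises(ConfigError):
            small_config(palette_size=40)

    def test_shared_base_pool(self):
        pals = synth.make_producer_palettes(small_config())
        for p in pals[1:]:
            np.testing.assert_array_equal(p.base_colors, pals[0].base_colors)


class TestVisitWeights:
    def test_zero_drift_unchanged(self):
        cfg = small_config(visit_drift=0.0)
        pal = synth.make_producer_palettes(cfg)[0]
        np.testing.assert_array_equal(
            synth.visit_weights(pal, 2, cfg), pal.mixture_weights
        )

    def test_drift_shared_across_producers(self):
        """The seasonal tilt is global: the per-visit weight ratio w_v/w is
        the same multiplicative field for every producer."""
        cfg = small_config(visit_drift=0.2, separation=0.8)
        pals = synth.make_producer_palettes(cfg)
        r0 = synth.visit_weights(pals[0], 2, cfg) / pals[0].mixture_weights
        r1 = synth.visit_weights(pals[1], 2, cfg) / pals[1].mixture_weights
        np.testing.assert_allclose(r0 / r0.sum(), r1 / r1.sum(), rtol=1e-9)

    def test_invalid_visit_rejected(self):
        cfg = small_config()
        pal = synth.make_producer_palettes(cfg)[0]
        with pytest.raises(ConfigError):
            synth.visit_weights(pal, 3, cfg)


class TestRender:
    def test_deterministic(self):
        cfg = small_config()
        pal = synth.make_producer_palettes(cfg)[0]
        a = synth.render_sample_image(pal, 1, cfg, seed=5)
        b = synth.render_sample_image(pal, 1, cfg, seed=5)
        np.testing.assert_array_equal(a.image, b.image)
        np.testing.assert_array_equal(a.grain_mask, b.grain_mask)

    def test_no_darkening_without_shadows(self):
        cfg = small_config(
            shadow_strength=0.0, illumination_jitter=0.0, pixel_noise=0.0
        )
        pal = synth.make_producer_palettes(cfg)[0]
        s = synth.render_sample_image(pal, 1, cfg, seed=3)
        outside = s.image[~s.grain_mask]
        np.testing.assert_allclose(outside, cfg.background_gray, atol=1e-12)
        assert not s.shadow_mask.any()

    def test_coverage_fraction_within_band(self):
        cfg = small_config(image_size=(512, 512), coverage=0.3)
        pal = synth.make_producer_palettes(cfg)[0]
        s = synth.render_sample_image(pal, 1, cfg, seed=9)
        assert 0.15 <= s.grain_mask.mean() <= 0.45

    def test_shadows_are_achromatic_and_darker(self):
        cfg = small_config(pixel_noise=0.0, illumination_jitter=0.0)
        pal = synth.make_producer_palettes(cfg)[0]
        s = synth.render_sample_image(pal, 1, cfg, seed=4)
        shadow_px = s.image[s.shadow_mask]
        assert shadow_px.size > 0
        np.testing.assert_allclose(shadow_px.std(axis=1), 0.0, atol=1e-12)
        assert (shadow_px[:, 0] < cfg.background_gray).all()

    def test_oversized_grains_rejected(self):
        with pytest.raises(ConfigError):
            small_config(grain_radius_range=(4.0, 60.0))


@pytest.fixture(scope="module")
def dataset(tmp_path_factory):
    out = tmp_path_factory.mktemp("ds")
    cfg = small_config(n_producers=4, n_visits=4, samples_per_visit=3)
    return cfg, synth.generate_dataset(cfg, out)


class TestGenerateDataset:
    def test_image_and_record_counts(self, dataset):
        cfg, manifest = dataset
        assert len(manifest) == 4 * 4 * 3 * 4
        assert all(manifest.resolve(r).exists() for r in manifest.records)

    def test_round_balance_in_test_split(self, dataset):
        _, manifest = dataset
        counts = Counter(
            (r.producer_id, r.acquisition_round)
            for r in manifest.records
            if r.split == "test"
        )
        for pid in manifest.producer_to_municipality:
            assert counts[(pid, 1)] == counts[(pid, 2)] > 0

    def test_train_fraction_near_two_thirds(self, dataset):
        _, manifest = dataset
        per_producer = Counter()
        train = Counter()
        for r in manifest.records:
            per_producer[r.producer_id] += 1
            train[r.producer_id] += r.split == "train"
        for pid, n in per_producer.items():
            assert abs(train[pid] - 2 * n / 3) <= 1

    def test_train_fraction_when_not_divisible(self, tmp_path):
        cfg = small_config(
            n_producers=1, n_visits=4, samples_per_visit=5, image_size=(64, 64)
        )
        manifest = synth.generate_dataset(cfg, tmp_path)
        n = len(manifest)
        n_train = sum(r.split == "train" for r in manifest.records)
        assert abs(n_train - 2 * n / 3) <= 1
        rounds = Counter(
            r.acquisition_round for r in manifest.records if r.split == "test"
        )
        assert rounds[1] == rounds[2]

    def test_manifest_round_trips_through_csv(self, dataset):
        _, manifest = dataset
        back = read_manifest(manifest.root / "manifest.csv")
        assert back.records == manifest.records

    def test_ground_truth_saved(self, dataset):
        _, manifest = dataset
        root = manifest.root
        assert (root / "ground_truth" / "palettes.csv").exists()
        name = manifest.records[0].image_path.split("/")[-1]
        assert (root / "ground_truth" / "masks" / name).exists()

    def test_full_determinism(self, tmp_path):
        cfg = small_config(n_producers=2, samples_per_visit=1, image_size=(64, 64))
        m1 = synth.generate_dataset(cfg, tmp_path / "a")
        m2 = synth.generate_dataset(cfg, tmp_path / "b")
        assert [r.image_path for r in m1.records] == [r.image_path for r in m2.records]
        for r1, r2 in zip(m1.records, m2.records):
            np.testing.assert_array_equal(
                load_image(m1.resolve(r1)), load_image(m2.resolve(r2))
            )


class TestSeparationMonotonicity:
    def test_accuracy_nondecreasing_in_separation_on_average(self, tmp_path):
        """End-to-end accuracy averaged over 3 seeds does not decrease when
        producer palettes move from indistinguishable to fully separated."""
        grid = ms.default_grid(
            representations=("uv",),
            k_values=(32,),
            svm_degrees=(4,),
            rf_trees=(),
            mlp_hidden=(),
        )

        def mean_acc(sep):
            accs = []
            for seed in (21, 22, 23):
                cfg = small_config(separation=sep, seed=seed)
                man = synth.generate_dataset(cfg, tmp_path / f"s{sep}_{seed}")
                res = pipeline.run_pipeline(
                    man, grid, pipeline.PipelineConfig(seed=seed, n_folds=4)
                )
                accs.append(res.producer_report().accuracy)
            return np.mean(accs)

        assert mean_acc(0.0) <= mean_acc(1.0)
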