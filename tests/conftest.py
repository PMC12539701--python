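"""Shared fixtures: synthetic datasets and cached end-to-end pipeline runs."""

import numpy as np
import pytest

from pollentrace import model_select as ms
from pollentrace import pipeline, synth

# Desk-scale study conditions: 10 producers (5 municipalities), 4 visits,
# 3 samples per visit, 4 images per sample -> 480 images of 256x256.
DESK_SEED = 3
RELIABILITY_SEEDS = (1, 2, 3)


def desk_config(seed: int, separation: float = 0.28) -> synth.SynthConfig:
    return synth.SynthConfig(
        n_producers=10,
        n_visits=4,
        samples_per_visit=3,
        images_per_sample=4,
        image_size=(256, 256),
        separation=separation,
        seed=seed,
    )


def svm_grid(degrees=(4, 6)):
    return ms.default_grid(
        representations=("uv",),
        k_values=(32,),
        svm_degrees=degrees,
        rf_trees=(),
        mlp_hidden=(),
    )


def run_desk(tmp_dir, seed: int, separation: float = 0.28) -> pipeline.PipelineResult:
    config = desk_config(seed, separation)
    manifest = synth.generate_dataset(config, tmp_dir)
    return pipeline.run_pipeline(
        manifest, svm_grid(), pipeline.PipelineConfig(seed=seed)
    )


@pytest.fixture(scope="session")
def desk_runs(tmp_path_factory):
    """End-to-end pipeline results at desk scale, one per reliability seed.

    Computed lazily and cached for the whole session; seed 3 doubles as the
    fixed-seed headline run.
    """
    cache = {}

    def get(seed: int) -> pipeline.PipelineResult:
        if seed not in cache:
            out = tmp_path_factory.mktemp(f"desk_{seed}")
            cache[seed] = run_desk(out, seed)
        return cache[seed]

    return get


@pytest.fixture(scope="session")
def desk_run(desk_runs):
    """The fixed-seed desk-scale run (moderate separation)."""
    return desk_runs(DESK_SEED)


@pytest.fixture(scope="session")
def zero_separation_run(tmp_path_factory):
    """Same conditions and seed as the headline run but separation = 0."""
    out = tmp_path_factory.mktemp("desk_zero")
    return run_desk(out, DESK_SEED, separation=0.0)


@pytest.fixture(scope="session")
def tiny_manifest(tmp_path_factory):
    """A small fast dataset: 4 producers x 2 visits x 2 samples x 4 images, 96x96."""
    config = synth.SynthConfig(
        n_producers=4,
        n_visits=2,
        samples_per_visit=2,
        images_per_sample=4,
        image_size=(96, 96),
        seed=7,
    )
    out = tmp_path_factory.mktemp("tiny")
    return synth.generate_dataset(config, out)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
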