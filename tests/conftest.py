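"""Shared fixtures: synthetic datasets generated at test time."""

from dataclasses import replace

import pytest

import leafcount as lc
from leafcount.sim import EASY

#: study conditions for the desk-scale experiments: easy rosette regime
#: (3-8 leaves, low overlap, soil background), 64x64 canvas, 200/50/100 split
DESK_N = 350
DESK_SPLIT = lc.SplitSpec(200 / 350, 50 / 350, 100 / 350, seed=11)
DESK_SEED = 11


@pytest.fixture(scope="session")
def desk_manifest(tmp_path_factory) -> lc.DatasetManifest:
    """Easy-preset synthetic dataset at desk scale, with train/val/test splits."""
    out = tmp_path_factory.mktemp("desk_dataset")
    params = replace(EASY, n_images=DESK_N, seed=DESK_SEED)
    manifest = lc.generate_dataset(params, out)
    manifest = lc.split_dataset(manifest, DESK_SPLIT)
    manifest.to_csv(out / "manifest.csv")
    return manifest


@pytest.fixture(scope="session")
def tiny_manifest(tmp_path_factory) -> lc.DatasetManifest:
    """16 small easy-preset images with masks and counts, all in one train split."""
    out = tmp_path_factory.mktemp("tiny_dataset")
    params = replace(EASY, n_images=16, canvas=(32, 32),
                     leaf_length_range=(8.0, 13.0), leaf_width_range=(2.5, 4.5),
                     radial_offset_range=(2.0, 5.0), seed=3)
    manifest = lc.generate_dataset(params, out)
    records = [lc.data.replace_record(r, split="train") for r in manifest.records]
    manifest = lc.DatasetManifest(manifest.root, records)
    manifest.to_csv(out / "manifest.csv")
    return manifest
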