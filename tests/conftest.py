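"""Shared fixtures: one phantom dataset reformatted once per session."""

from __future__ import annotations

import numpy as np
import pytest

from bitvox import DatasetMeta, make_phantom
from bitvox.synthgen import PhantomSpec, make_fixture_dataset

FIXTURE_SPEC = PhantomSpec()  # 300x256x200, 8-bit, seed 42
FIXTURE_BLOCK = 32


@pytest.fixture(scope="session")
def phantom_volume() -> np.ndarray:
    volume, _ = make_phantom(FIXTURE_SPEC)
    return volume


@pytest.fixture(scope="session")
def phantom_truth() -> list:
    _, truth = make_phantom(FIXTURE_SPEC)
    return truth


@pytest.fixture(scope="session")
def dataset(tmp_path_factory) -> tuple:
    """(root, meta) of the default phantom converted to a bitBlock tree."""
    root = tmp_path_factory.mktemp("store") / "phantom"
    meta = make_fixture_dataset(root, FIXTURE_SPEC, block_size=FIXTURE_BLOCK)
    return root, meta


@pytest.fixture(scope="session")
def dataset_meta(dataset) -> DatasetMeta:
    return dataset[1]
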