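"""Shared fixtures: the deterministic phantom battery and pipeline runs.

Session-scoped so the full pipeline executes once per fixture image and the
many assertions that follow read from the same results.
"""

from __future__ import annotations

import pytest

from cepquant.io import PixelCalibration
from cepquant.phantom import default_suite
from cepquant.pipeline import RunConfig, run_pipeline
from cepquant.region import find_dendrite_region

SUITE_SEED = 1


def per_dendrite(result):
    """Per-dendrite rows of a pipeline result (drop the aggregate row)."""
    return [r for r in result.report_rows if r["dendrite_index"] != "all"]


@pytest.fixture(scope="session")
def cal():
    return PixelCalibration(0.2)


@pytest.fixture(scope="session")
def suite():
    return default_suite(seed=SUITE_SEED)


@pytest.fixture(scope="session")
def pipeline_results(suite):
    cfg = RunConfig()
    return {
        name: run_pipeline(img, cfg, image_id=name)
        for name, (spec, img, gt) in suite.items()
    }


@pytest.fixture(scope="session")
def clean_crop(suite):
    _, img, _ = suite["clean"]
    return find_dendrite_region(img)
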