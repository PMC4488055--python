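"""Shared fixtures: a zero-noise synthetic circuit and a full pipeline run."""

from __future__ import annotations

import pytest
from hypothesis import settings

from mircircuit.pipeline import PipelineConfig, run_all
from mircircuit.synthetic_data import TruthConfig, generate_truth, write_dataset

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def zero_noise_truth():
    """A planted circuit with no background clusters and no label noise."""
    return generate_truth(TruthConfig(rng_seed=1, noise_cluster_rate=0.0))


@pytest.fixture(scope="session")
def zero_noise_run(zero_noise_truth, tmp_path_factory):
    """One complete run_all on the zero-noise dataset."""
    base = tmp_path_factory.mktemp("zero_noise")
    write_dataset(zero_noise_truth, base / "data")
    config = PipelineConfig.for_dataset(
        base / "data",
        base / "out",
        apply_cluster_filter=False,
        core_factor_ids=zero_noise_truth.core_factor_ids,
        rng_seed=1,
    )
    return zero_noise_truth, run_all(config)
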