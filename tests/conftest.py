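from __future__ import annotations

import pytest

from markdiv import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        n_pairs={"both": 60, "mixed": 60, "none": 60},
        n_background_genes=400,
        n_samples=40,
        n_codons=80,
        master_seed=101,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def small_dataset_dir(small_dataset, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("synth")
    small_dataset.write(outdir)
    return outdir
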