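from pathlib import Path

import pytest

from metaqtl_forge.pipeline import PipelineConfig, run_stage
from metaqtl_forge.simulate import SimulationConfig, simulate_all


@pytest.fixture(scope="session")
def bundle():
    """The default simulated input bundle (fixed generator seed)."""
    return simulate_all(SimulationConfig())


@pytest.fixture(scope="session")
def pipeline_dirs(tmp_path_factory) -> PipelineConfig:
    """A complete pipeline run on the default bundle, checkpointed to disk."""
    root = tmp_path_factory.mktemp("pipeline")
    cfg = PipelineConfig(input_dir=str(root / "in"), out_dir=str(root / "out"))
    run_stage("all", cfg)
    return cfg


@pytest.fixture()
def out_dir(pipeline_dirs) -> Path:
    return Path(pipeline_dirs.out_dir)
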