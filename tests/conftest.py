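from pathlib import Path

import pytest

from anemotox import PipelineConfig
from anemotox.synthetic_data import SimulationConfig

DATA_DIR = Path(__file__).parent.parent / "src" / "anemotox" / "data"


@pytest.fixture
def cfg() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture
def sim_cfg() -> SimulationConfig:
    return SimulationConfig(seed=11)


@pytest.fixture
def fasta_file(tmp_path):
    def _make(content: str, name: str = "input.fasta") -> Path:
        path = tmp_path / name
        path.write_text(content)
        return path

    return _make
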