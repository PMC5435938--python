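from __future__ import annotations

import pytest

from mzview import indexer
from mzview.model import Compression, Precision
from mzview.synth import GeneratedRun, SynthConfig, generate_run


@pytest.fixture(scope="session")
def run_small(tmp_path_factory) -> GeneratedRun:
    """5 MS1 scans, each with 2 MS2 children and one MS3 grandchild (20 scans)."""
    cfg = SynthConfig(n_ms1=5, msn_per_ms1=((2, 2), (3, 1)), seed=11)
    return generate_run(cfg, tmp_path_factory.mktemp("run_small"))


@pytest.fixture(scope="session")
def run200(tmp_path_factory) -> GeneratedRun:
    """200-spectrum fixture (50 MS1 x [2 MS2 + 1 MS3 each])."""
    cfg = SynthConfig(n_ms1=50, msn_per_ms1=((2, 2), (3, 1)), seed=42)
    return generate_run(cfg, tmp_path_factory.mktemp("run200"))


@pytest.fixture(scope="session")
def run_noref(tmp_path_factory) -> GeneratedRun:
    """Twin of run_small without explicit parent references, so the
    nearest-preceding-scan inference path is exercised."""
    cfg = SynthConfig(
        n_ms1=4, msn_per_ms1=((2, 2), (3, 1)), seed=11, write_parent_refs=False
    )
    return generate_run(cfg, tmp_path_factory.mktemp("run_noref"))


@pytest.fixture(scope="session")
def run_zlib_f32(tmp_path_factory) -> GeneratedRun:
    cfg = SynthConfig(
        n_ms1=4,
        msn_per_ms1=((2, 1),),
        seed=5,
        precision=Precision.F32,
        compression=Compression.ZLIB,
    )
    return generate_run(cfg, tmp_path_factory.mktemp("run_zlib_f32"))


@pytest.fixture(scope="session")
def run_empty(tmp_path_factory) -> GeneratedRun:
    cfg = SynthConfig(n_ms1=0, msn_per_ms1=(), seed=1)
    return generate_run(cfg, tmp_path_factory.mktemp("run_empty"))


@pytest.fixture(scope="session")
def index_small_mzml(run_small):
    return indexer.build_index(run_small.mzml_path)


@pytest.fixture(scope="session")
def index_small_mzxml(run_small):
    return indexer.build_index(run_small.mzxml_path)


@pytest.fixture(scope="session")
def index200_mzml(run200):
    return indexer.build_index(run200.mzml_path)


@pytest.fixture(scope="session")
def index200_mzxml(run200):
    return indexer.build_index(run200.mzxml_path)
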