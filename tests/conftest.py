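"""Shared fixtures: a scaled-down synthetic dataset generated once per session."""

import numpy as np
import pytest

from clipcircuit import PipelineConfig, SimulationConfig, write_dataset
from clipcircuit.simulate import simulate_transcriptome


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Reduced-scale study conditions: fast enough for per-test pipelines."""
    return SimulationConfig(
        seed=11, n_mrna=300, n_lncrna=30, depth_per_library=60_000, n_rrna_repeats=3
    )


@pytest.fixture(scope="session")
def small_transcriptome(small_config):
    return simulate_transcriptome(small_config)


@pytest.fixture(scope="session")
def dataset_dir(tmp_path_factory, small_config):
    out = tmp_path_factory.mktemp("dataset")
    write_dataset(small_config, out)
    return out


@pytest.fixture()
def pipeline_config(dataset_dir, tmp_path) -> PipelineConfig:
    return PipelineConfig(
        fasta=str(dataset_dir / "transcripts.fasta"),
        annotations=str(dataset_dir / "annotations.gff3"),
        mirnas=str(dataset_dir / "mirnas.tsv"),
        reads_wt=str(dataset_dir / "reads_WT.bed"),
        reads_sponge_mut=str(dataset_dir / "reads_sponge_mut.bed"),
        reads_mirna_ko=str(dataset_dir / "reads_mirna_ko.bed"),
        contrast_mutant=str(dataset_dir / "contrast_mutant.tsv"),
        contrast_ko=str(dataset_dir / "contrast_ko.tsv"),
        outdir=str(tmp_path / "run"),
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
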