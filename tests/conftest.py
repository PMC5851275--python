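import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from sgenes.pipeline import run_pipeline
from sgenes.synthetic import SyntheticConfig, simulate_dataset

#: A reduced dataset for fast unit/determinism tests.
SMALL = dict(seed=11, n_sgenes=6, n_full_transfers=2, n_innovations=2,
             n_operon_fusions=2, n_intron_families=2, n_euk_donor_domains=6,
             n_bacteria=10, n_archaea=10, domain_library_size=40)


@pytest.fixture(scope="session")
def study_dataset(tmp_path_factory):
    """The planted-recovery study conditions (the generator defaults)."""
    outdir = tmp_path_factory.mktemp("study_data")
    dataset, truth = simulate_dataset(SyntheticConfig(), outdir)
    return dataset, truth, outdir


@pytest.fixture(scope="session")
def study_run(tmp_path_factory):
    """Full pipeline run on the noiseless study dataset."""
    outdir = tmp_path_factory.mktemp("study_run")
    manifest = run_pipeline({"seed": 42, "synthetic": {"seed": 42}}, outdir)
    return outdir, manifest


@pytest.fixture(scope="session")
def noisy_run(tmp_path_factory):
    """Same study conditions with 5% hit noise."""
    outdir = tmp_path_factory.mktemp("noisy_run")
    manifest = run_pipeline(
        {"seed": 42, "synthetic": {"seed": 42, "hit_noise": 0.05}}, outdir)
    return outdir, manifest


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("small_data")
    dataset, truth = simulate_dataset(SyntheticConfig(**SMALL), outdir)
    return dataset, truth, outdir
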