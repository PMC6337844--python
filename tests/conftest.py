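from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from intronkit.synthetic_data import (
    conserved_intron_demo_config,
    generate_family,
)


@pytest.fixture(scope="session")
def demo_family():
    """Three-taxon family with 2 universal + 3 pairwise + 2 private introns."""
    return generate_family(conserved_intron_demo_config(seed=7))


@pytest.fixture(scope="session")
def reference_dataset_path() -> Path:
    """User-supplied FASTA of the published Notch-repressor protein and
    genomic sequences (not distributed with the package)."""
    return Path(__file__).resolve().parent.parent / "data" / "reference"
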