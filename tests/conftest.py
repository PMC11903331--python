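import numpy as np
import pytest

from njatlas.junction_catalog import TranscriptModel, build_annotation_index
from njatlas.synthetic_data import (
    SimulationConfig,
    default_plant_specs,
    generate_reference,
    plant_and_emit_cohort,
)


@pytest.fixture(scope="session")
def toy_transcript():
    """One +strand gene: exons 101-200, 301-400, 501-600; CDS 120-580."""
    return TranscriptModel(
        "TX1", "GENE1", "chr1", "+",
        [(101, 200), (301, 400), (501, 600)],
        cds_span=(120, 580),
        median_tpm_by_subtype={"A": 50.0},
    )


@pytest.fixture(scope="session")
def toy_index(toy_transcript):
    return build_annotation_index([toy_transcript])


@pytest.fixture(scope="session")
def planted_cohort():
    """Seeded cohort: 20 tumour + 50 normal samples, 30 planted junctions.

    Frequencies and PSRs sit at least twice the calling thresholds, so the
    cohort gates recover the planted truth without ambiguity.
    """
    config = SimulationConfig(
        seed=20240101,
        n_genes=30,
        n_tumour_samples=20,
        n_normal_samples=50,
        n_cases=2,
        regions_per_case=5,
        normal_leak_rate=0.0,
    )
    reference = generate_reference(config)
    config.planted_junctions = default_plant_specs(
        reference, 30, np.random.default_rng(20240102)
    )
    return config, plant_and_emit_cohort(config, reference)
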