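import numpy as np
import pytest

from proteoquant.psm_io import PSM, ProteinRecord, average_mass_kda
from proteoquant.simulate import SimulationConfig, simulate_proteome, simulate_psms


def make_record(pid: str, sequence: str = "ACDEFGHIKLMNPQR") -> ProteinRecord:
    return ProteinRecord(
        protein_id=pid, sequence=sequence, molecular_mass_kDa=average_mass_kda(sequence)
    )


def make_psm(
    spectrum_id: str = "s1",
    peptide: str = "PEPTIDEK",
    protein_ids: tuple[str, ...] = ("P1",),
    log_expectation: float = -3.0,
    confidence: float | None = 0.9995,
    intensities: dict[str, float] | None = None,
) -> PSM:
    return PSM(
        spectrum_id=spectrum_id,
        peptide=peptide,
        protein_ids=protein_ids,
        log_expectation=log_expectation,
        confidence=confidence,
        reporter_intensities=intensities,
    )


@pytest.fixture(scope="session")
def small_simulation():
    """A modest simulated run shared across read-only tests."""
    config = SimulationConfig(n_proteins=120, seed=7)
    records, truth = simulate_proteome(config)
    psms = simulate_psms(records, truth, config)
    return config, records, truth, psms


@pytest.fixture
def rng():
    return np.random.default_rng(123)
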