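import numpy as np
import pytest

from paralogkit.io import SequenceRecord
from paralogkit.simulate import SimulationConfig, simulate


def make_seq(id: str, residues: str) -> SequenceRecord:
    return SequenceRecord(id=id, residues=residues)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def mutated_copy(rng: np.random.Generator, seq: str, divergence: float) -> str:
    chars = list(seq)
    k = max(1, int(round(divergence * len(chars))))
    for i in rng.choice(len(chars), size=k, replace=False):
        chars[i] = "ACGT"[(("ACGT".index(chars[i])) + 1 + int(rng.integers(3))) % 4]
    return "".join(chars)


@pytest.fixture(scope="session")
def small_dataset():
    """A 30-gene planted-duplication dataset shared across tests."""
    return simulate(SimulationConfig(n_ancestral_genes=30, seed=42))


@pytest.fixture(scope="session")
def small_workflow(small_dataset):
    """The workflow run once on the 30-gene dataset."""
    from paralogkit.workflow import run_workflow

    pairs, summary = run_workflow(
        small_dataset.transcripts,
        small_dataset.isogroup_map,
        small_dataset.contigs,
        small_dataset.linkage_map,
    )
    return pairs, summary


@pytest.fixture(scope="session")
def coding_model():
    from paralogkit.coding import default_model

    return default_model()
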