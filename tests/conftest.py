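import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from tcemtools.motifs import ProteomeIndex
from tcemtools.simulate import SimulationConfig, gen_study_attributes


@pytest.fixture(scope="session")
def config() -> SimulationConfig:
    """The default synthetic study conditions."""
    return SimulationConfig(seed=3)


@pytest.fixture(scope="session")
def study(config):
    """Full synthetic attribute pipeline, built once per session."""
    return gen_study_attributes(config)


@pytest.fixture(scope="session")
def toy_index() -> ProteomeIndex:
    return ProteomeIndex.build([
        ("P1", "ACDEFGHIK"),
        ("P2", "AAAAAAAAAA"),
        ("P3", "MKVLAYCDEFGHIKW"),
    ])


def brute_force_tcem_counts(proteins):
    """Independent oracle: count 5-mer starts with >= 3 upstream and >= 1
    downstream residues in the same protein, all 9 residues standard."""
    from tcemtools.motifs import _AA_SET  # noqa: the alphabet constant

    counts = {}
    for _pid, seq in proteins:
        seq = seq.upper()
        for p in range(len(seq)):
            if p < 3 or p + 5 + 1 > len(seq):
                continue
            window = seq[p - 3 : p + 6]
            if any(ch not in _AA_SET for ch in window):
                continue
            motif = seq[p : p + 5]
            counts[motif] = counts.get(motif, 0) + 1
    return counts


def random_proteome(rng: np.random.Generator, n_proteins=8, max_len=60,
                    nonstandard_rate=0.0):
    from tcemtools.motifs import AMINO_ACIDS

    letters = list(AMINO_ACIDS)
    records = []
    for i in range(n_proteins):
        length = int(rng.integers(1, max_len))
        seq = [str(rng.choice(letters)) for _ in range(length)]
        for j in range(length):
            if rng.random() < nonstandard_rate:
                seq[j] = "X"
        records.append((f"R{i}", "".join(seq)))
    return records
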