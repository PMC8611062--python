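import numpy as np
import pytest

from pulsedyn.atoms import PoleGrid
from pulsedyn.preprocess import Chunk, ChunkedDataset


@pytest.fixture
def tiny_grid() -> PoleGrid:
    """Origin plus one real pole: the smallest grid with a nontrivial choice."""
    return PoleGrid(poles=np.array([0.0 + 0.0j, 0.5 + 0.0j]))


@pytest.fixture
def mixed_grid() -> PoleGrid:
    """Real poles plus one conjugate pair."""
    p = 0.6 * np.exp(1j * np.pi / 5)
    return PoleGrid(poles=np.array([0.0, 0.4, p, np.conj(p)], dtype=complex))


def make_dataset(chunks_spec, participant="p") -> ChunkedDataset:
    """Build a ChunkedDataset from [(u, s), ...] pairs."""
    chunks = tuple(
        Chunk(
            chunk_id=i + 1,
            start_minute=100 * i,
            u=np.asarray(u, dtype=float),
            s=np.asarray(s, dtype=np.int8),
        )
        for i, (u, s) in enumerate(chunks_spec)
    )
    return ChunkedDataset(participant_id=participant, chunks=chunks)


@pytest.fixture
def single_smoking_minute() -> ChunkedDataset:
    """One chunk of length 1 with zero stress and a smoking minute."""
    return make_dataset([([0.0], [1])])


@pytest.fixture
def small_training_set() -> ChunkedDataset:
    """A small dataset with both smoking and non-smoking minutes.

    Sustained stress in the middle of chunk 1 drives smoking; chunk 2 is
    stress-quiet and smoke-free.
    """
    u1 = np.array([0.1, 0.9, 0.9, 0.9, 0.9, 0.2, 0.1, 0.1])
    s1 = np.array([0, 0, 1, 1, 1, 1, 0, 0])
    u2 = np.array([0.1, 0.1, 0.2, 0.1, 0.1, 0.05])
    s2 = np.zeros(6, dtype=int)
    return make_dataset([(u1, s1), (u2, s2)])
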