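import numpy as np
import pytest

from alnsafe import AlignmentParams, build_suboptimal_dag, load_builtin_matrix


@pytest.fixture(scope="session")
def identity():
    return load_builtin_matrix("IDENTITY")


@pytest.fixture(scope="session")
def blosum62():
    return load_builtin_matrix("BLOSUM62")


@pytest.fixture(scope="session")
def blosum50():
    return load_builtin_matrix("BLOSUM50")


@pytest.fixture
def single_path_dag(identity):
    """'ACD' vs 'ACD' at delta=0: a unique optimal path of three matches."""
    params = AlignmentParams(matrix=identity, gap_open=2, gap_extend=1, delta=0)
    return build_suboptimal_dag("ACD", "ACD", params)


@pytest.fixture
def detour_dag(identity):
    """'A' vs 'A' with free gap opening and delta=3: the diagonal plus the
    two indel-indel detours, five edges and three alignments."""
    params = AlignmentParams(matrix=identity, gap_open=0, gap_extend=1, delta=3)
    return build_suboptimal_dag("A", "A", params)


def random_seq(rng: np.random.Generator, alphabet: str, lo: int, hi: int) -> str:
    n = int(rng.integers(lo, hi + 1))
    return "".join(alphabet[int(k)] for k in rng.integers(0, len(alphabet), size=n))
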