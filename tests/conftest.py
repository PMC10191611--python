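import itertools

import numpy as np
import pytest

_LETTERS = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_seq(rng: np.random.Generator, length: int) -> str:
    return _LETTERS[rng.integers(0, 4, size=length)].tobytes().decode()


def all_strings(alphabet: str, max_len: int):
    """Every string over ``alphabet`` with length 0..max_len."""
    out = [""]
    for length in range(1, max_len + 1):
        out.extend("".join(t) for t in itertools.product(alphabet, repeat=length))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
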