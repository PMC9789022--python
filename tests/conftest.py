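import numpy as np
import pytest

from clonescribe import DEFAULT_DESIGN

TEMPLATE = DEFAULT_DESIGN.stg_template  # 20-nt stgRNA template


@pytest.fixture(scope="session")
def template() -> str:
    return TEMPLATE


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)


def substitute(seq: str, pos: int, rng_or_base) -> str:
    """Replace seq[pos] with a different base (deterministic if a base given)."""
    if isinstance(rng_or_base, str):
        new = rng_or_base
    else:
        new = rng_or_base.choice([b for b in "ACGT" if b != seq[pos]])
    assert new != seq[pos]
    return seq[:pos] + new + seq[pos + 1 :]
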