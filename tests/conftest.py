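from __future__ import annotations

import numpy as np
import pytest

from introscan import load_model, parse_descriptor
from introscan.nullsim import default_composition


@pytest.fixture(scope="session")
def iia():
    return load_model("IIA_DI")


@pytest.fixture(scope="session")
def iib():
    return load_model("IIB_DI")


@pytest.fixture(scope="session")
def composition():
    return default_composition()


@pytest.fixture()
def rng():
    return np.random.default_rng(20230917)


@pytest.fixture(scope="session")
def hairpin():
    return parse_descriptor(
        """
name: hp
elements:
  - {type: helix5, id: h1, min: 4, max: 4}
  - {type: strand, id: loop, min: 4, max: 4}
  - {type: helix3, id: h1}
"""
    )


def make_random_descriptor(rng, max_helices: int = 3):
    """A small random (but always valid) descriptor for oracle comparisons."""
    lines = ["name: rnd", "elements:"]
    counter = [0]

    def fresh(prefix):
        counter[0] += 1
        return f"{prefix}{counter[0]}"

    def strand_line(optional=True):
        sid = fresh("s")
        lo = int(rng.integers(0 if optional else 1, 4))
        hi = lo + int(rng.integers(0, 3))
        return f"  - {{type: strand, id: {sid}, min: {lo}, max: {hi}}}"

    def emit(depth, budget):
        made = 0
        while budget[0] > 0 and made < 2:
            if rng.random() < 0.6:
                budget[0] -= 1
                made += 1
                hid = fresh("h")
                lo = int(rng.integers(1, 4))
                hi = lo + int(rng.integers(0, 2))
                lines.append(
                    f"  - {{type: helix5, id: {hid}, min: {lo}, max: {hi}}}"
                )
                if rng.random() < 0.7:
                    lines.append(strand_line(optional=False))
                emit(depth + 1, budget)
                lines.append(f"  - {{type: helix3, id: {hid}}}")
            else:
                lines.append(strand_line())
                made += 1

    lines.append(strand_line())
    emit(0, [int(rng.integers(1, max_helices + 1))])
    lines.append(strand_line())
    return parse_descriptor("\n".join(lines))
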