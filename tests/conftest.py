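import numpy as np
import pytest

import dacnc as D


@pytest.fixture(scope="session")
def cnc_7740():
    """The full-size crystal of the standard build (built once per run)."""
    return D.build_cnc(7, 7, 40)


@pytest.fixture(scope="session")
def small_crystal():
    return D.build_cnc(3, 3, 4)


@pytest.fixture()
def single_chain():
    return D.build_cnc(1, 1, 2)


def make_frame(names, positions, chain_ids=None, resids=None,
               resnames=None, box=None):
    """Hand-built Frame for constructed-geometry tests."""
    from dacnc.frames import Frame, guess_element
    n = len(names)
    names = np.array(names, dtype=object)
    return Frame(
        names=names,
        elements=np.array([guess_element(str(x)) for x in names], dtype=object),
        resnames=np.array(resnames if resnames is not None else ["MOL"] * n,
                          dtype=object),
        resids=np.array(resids if resids is not None else [1] * n, dtype=int),
        chain_ids=np.array(chain_ids if chain_ids is not None else [0] * n,
                           dtype=int),
        positions=np.asarray(positions, dtype=float),
        box=box,
    )
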