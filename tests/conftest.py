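import numpy as np
import pytest

import qpiphase as q


@pytest.fixture(scope="session")
def gold_stack():
    """50 nm gold on glass, air backing, 633 nm — the canonical SPR case."""
    return q.LayerStack(1.52, ((q.material_index("gold", 633.0), 50.0),),
                        1.0, 633.0, label="spr#3")


@pytest.fixture(scope="session")
def pmma_stack():
    """1000 nm PMMA on glass, air backing, 633 nm — lossless waveguide."""
    return q.LayerStack(1.52, ((q.material_index("PMMA", 633.0), 1000.0),),
                        1.0, 633.0, label="waveguide#2")


@pytest.fixture(scope="session")
def grid64():
    return q.build_pupil_grid(64, 1.49, 633.0, 1.52)


@pytest.fixture(scope="session")
def grid128():
    return q.build_pupil_grid(128, 1.49, 633.0, 1.52)


@pytest.fixture(scope="session")
def grid256():
    return q.build_pupil_grid(256, 1.49, 633.0, 1.52)


@pytest.fixture(scope="session")
def gold_field128(grid128, gold_stack):
    return q.compute_bfp_fields(grid128, gold_stack)


@pytest.fixture(scope="session")
def gold_field256(grid256, gold_stack):
    return q.compute_bfp_fields(grid256, gold_stack)
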