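import pytest

from lqfrac import load_reference_cell_lines, load_reference_grid


@pytest.fixture(scope="session")
def cell_lines():
    return load_reference_cell_lines()


@pytest.fixture(scope="session")
def f10b16(cell_lines):
    return cell_lines["F10B16"]


@pytest.fixture(scope="session")
def t4t1(cell_lines):
    return cell_lines["4T1"]


@pytest.fixture(scope="session")
def reference_grid():
    return load_reference_grid()
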