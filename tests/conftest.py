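import pytest

from clonetrace import data, variant_io

# variant keys of the case-study grid
G719D = "7:55241708:G:A"
R776G = "7:55249028:C:G"
PTEN_INS = "10:89692972:T:TA"
R175H = "17:7578406:C:T"
R110C = "17:7579359:G:A"
R273C = "17:7577121:G:A"

SGS1_CLADE = frozenset({
    "SGS1-A Bulk", "SGS1-A P4", "SGS1-A P17",
    "SGS1-B Bulk", "SGS1-B P4", "SGS1-B P18",
    "SGS1-C P4", "SGS1-C P17",
})


@pytest.fixture(scope="session")
def sector_grid():
    return data.load_sector_grid()


@pytest.fixture(scope="session")
def sector_matrix(sector_grid):
    calls, sheet = sector_grid
    return variant_io.build_variant_matrix(calls, sheet, presence_threshold=0.05)


@pytest.fixture(scope="session")
def tmz_table():
    return data.load_tmz_contexts()
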