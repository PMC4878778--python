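import pytest

from exomecarrier import make_panel, make_table1_fixture


@pytest.fixture(scope="session")
def panel():
    return make_panel()


@pytest.fixture(scope="session")
def table1(panel):
    return make_table1_fixture(panel)


@pytest.fixture(scope="session")
def table1_cell(table1):
    index = {(o.mutation_key, o.population, o.cohort): o for o in table1}

    def cell(mutation_key, population, cohort):
        return index[(mutation_key, population, cohort)]

    return cell
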