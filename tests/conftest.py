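import pytest

from plastdeg.synthetic import default_template, fixture_table1, fixture_tree, synthesize_plastome


@pytest.fixture(scope="session")
def study_matrix():
    return fixture_table1()[0]


@pytest.fixture(scope="session")
def study_regions():
    return fixture_table1()[1]


@pytest.fixture(scope="session")
def study_tree():
    return fixture_tree()


@pytest.fixture(scope="session")
def type1_plastome():
    """One unedited type-I synthetic plastome with its truth bundle."""
    return synthesize_plastome(default_template("I"), seed=17)


@pytest.fixture(scope="session")
def type2_plastome():
    return synthesize_plastome(default_template("II"), seed=23)
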