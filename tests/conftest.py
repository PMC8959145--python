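import pytest

from boolseg import make_ruleset


@pytest.fixture
def negation_ruleset():
    """One gene repressing itself-off: A := NOT protein(A) (simplified)."""
    return make_ruleset({"A": "NOT protein(A)"})


@pytest.fixture
def toggle_ruleset():
    """Classic mutual-repression pair in simplified mode."""
    return make_ruleset({"A": "NOT protein(B)", "B": "NOT protein(A)"})


@pytest.fixture
def late_ruleset():
    from boolseg import reference

    return reference.late_ruleset()


@pytest.fixture
def early_ruleset():
    from boolseg import reference

    return reference.early_ruleset()
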