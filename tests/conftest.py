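import pytest

from quaddle import default_catalogue, full_default_spec


@pytest.fixture(scope="session")
def catalogue():
    return default_catalogue()


@pytest.fixture()
def full_spec(catalogue):
    return full_default_spec(catalogue, "full")


def different_value(catalogue, sub, current):
    """A legal value for a sub-dimension different from ``current``."""
    for v in catalogue.subdimension_values(sub):
        if v != current:
            return v
    raise AssertionError(f"no alternative value for {sub}")


@pytest.fixture(scope="session")
def disjoint_pair(catalogue):
    """Two specs sharing no value in any scored sub-dimension.

    Both have every part present, so every sub-dimension carries a real
    (non-"none") value on both sides, and each differs between the two.
    """
    a = full_default_spec(catalogue, "a")
    b_values = {sub: different_value(catalogue, sub, a.values[sub])
                for sub in catalogue.subdimension_names}
    from quaddle import ObjectSpec
    from quaddle.features import validate_spec
    b = ObjectSpec(object_id="b", values=b_values)
    validate_spec(b, catalogue)
    return a, b
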