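import pytest

from glycoelucidate import datasets


@pytest.fixture(scope="session")
def eps_unit():
    """The published branched hexasaccharide repeat unit."""
    return datasets.eps35624_repeat_unit()


@pytest.fixture(scope="session")
def eps_observations():
    return datasets.eps35624_observations()


@pytest.fixture(scope="session")
def os211():
    """The tetrasaccharide hydrolysis fragment Glc-6dTal-GalA-Gal."""
    from glycoelucidate import parse_condensed

    return parse_condensed("β-D-Glcp-(1→4)-α-L-6dTalp-(1→4)-α-D-GalpA-(1→4)-D-Galp")
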