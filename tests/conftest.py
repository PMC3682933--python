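import pytest

import snpanel as sp


@pytest.fixture(scope="session")
def fixtures():
    return sp.fixture_suite()


@pytest.fixture(scope="session")
def panel6_profiles(fixtures):
    """Three OTU consensi: A/B differ at 1-3, A/C at 4-6, B/C at 1-6."""
    cons = fixtures["panel6"]["consensi"]
    return [sp.profile_from_string(seq, otu_id=name) for name, seq in sorted(cons.items())]


@pytest.fixture(scope="session")
def panel6_pool(panel6_profiles):
    return sp.extract_candidates(panel6_profiles, frame=None)


@pytest.fixture(scope="session")
def small_alignment():
    return sp.Alignment([
        sp.SequenceRecord("x1", "speciesA", "ATGAAATTTGGG"),
        sp.SequenceRecord("x2", "speciesA", "ATGAAATTTGGG"),
        sp.SequenceRecord("y1", "speciesB", "ATGAAATTTGGA"),
    ])


@pytest.fixture(scope="session")
def simulated(fixtures):
    cfg = fixtures["bimodal"]["config"]
    return sp.simulate_alignment(cfg)
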