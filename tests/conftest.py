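import numpy as np
import pytest

import tadscape as ts
import tadscape.synthetic as syn


@pytest.fixture(scope="session")
def small_design():
    """1 Mb synthetic genome at the default contact density."""
    return ts.SyntheticDesign(
        genome=ts.GenomeLayout((("chrS", 1_000_000),)), depth=2.7e6, seed=3
    )


@pytest.fixture(scope="session")
def small_truth(small_design):
    fragments = syn.make_fragment_map(small_design)
    return syn.build_ground_truth(small_design, fragments)


@pytest.fixture(scope="session")
def small_matrix(small_design, small_truth):
    m = ts.simulate_contact_matrix(small_design, small_truth.fragments, small_truth)
    return ts.ice_normalize(m)


@pytest.fixture(scope="session")
def small_tads(small_matrix):
    return ts.call_domains_dp(small_matrix, ts.CallerConfig(max_domain_bins=600))


@pytest.fixture
def tiny_fragments():
    """Two chromosomes with hand-laid fragment boundaries."""
    genome = ts.GenomeLayout((("chr1", 1000), ("chr2", 600)))
    return ts.FragmentMap(
        genome,
        starts={"chr1": np.array([0, 200, 500, 900]), "chr2": np.array([0, 300])},
        ends={"chr1": np.array([200, 500, 900, 1000]), "chr2": np.array([300, 600])},
    )
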