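import numpy as np
import pytest

from imescan import AnnotatedReplicon, PlasmidSpec


def random_sequence(rng, n, letters="ACGT"):
    return "".join(rng.choice(list(letters), size=n))


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_901)


@pytest.fixture
def small_spec():
    """A compact plasmid layout for fast end-to-end tests."""
    return PlasmidSpec(
        length_bp=6000, ori_position=3000, ter_position=100,
        iteron_start=3100, dnaa_position=3240, at_rich_start=3320,
        orit_start=5500, att_position=4500,
        terminal_repeat_positions=(500, 1500, 2500),
        cds_len_range=(300, 600), cds_gap_range=(30, 80), seed=11)


def make_replicon(seq, circular=False, features=None, rid="toy"):
    return AnnotatedReplicon(rid, seq, circular=circular,
                             features=list(features or []))
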