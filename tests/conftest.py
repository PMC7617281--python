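"""Shared fixtures.

The full 1-ms dictionary and the 256-pixel phantom are expensive, so
they are session-scoped and shared between the unit and acceptance
tests.
"""

import numpy as np
import pytest

from ssfse_t2.dictionary import build_dictionary
from ssfse_t2.phantom import make_fetal_phantom
from ssfse_t2.sequences import SequenceParams


@pytest.fixture(scope="session")
def preset_seqs():
    return [SequenceParams.from_te_preset(te) for te in (80, 180, 400)]


@pytest.fixture(scope="session")
def full_dictionary(preset_seqs):
    """Default dictionary: T2 = 25..3000 ms at 1 ms, fixed T1 = 3000 ms."""
    return build_dictionary(preset_seqs)


@pytest.fixture(scope="session")
def coarse_dictionary(preset_seqs):
    """Fast 25-ms-step dictionary for structural tests."""
    from ssfse_t2.dictionary import default_t2_grid

    return build_dictionary(preset_seqs, t2_grid=default_t2_grid(step=25.0))


@pytest.fixture(scope="session")
def reduced_flip_seqs():
    """SS-FSE presets with a reduced-angle refocusing train."""
    return [
        SequenceParams.from_te_preset(
            te, first_refocus_flip=162.0, steady_refocus_flip=120.0
        )
        for te in (80, 180, 400)
    ]


@pytest.fixture(scope="session")
def reduced_flip_dictionary(reduced_flip_seqs):
    return build_dictionary(reduced_flip_seqs)


@pytest.fixture(scope="session")
def phantom256():
    return make_fetal_phantom(size=256, seed=1)
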