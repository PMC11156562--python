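"""Shared fixtures: synthetic benchmark sessions processed once per run."""

from __future__ import annotations

import numpy as np
import pytest

from helpers import ProcessedSession


@pytest.fixture(scope="session")
def bench():
    """Noiseless retinotopic benchmark session (lag 0)."""
    return ProcessedSession("noiseless-retinotopic", seed=3)


@pytest.fixture(scope="session")
def lagged100():
    """Noiseless retinotopic session with a 100-ms response lag."""
    return ProcessedSession("lagged-100", seed=31)


@pytest.fixture(scope="session")
def face_session():
    """Face-selective session: units 0-3 boosted by face-ROI overlap."""
    return ProcessedSession("face-selective", seed=21, with_grids=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
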