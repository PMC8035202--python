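"""Shared fixtures: one identification-scale synthetic study per session.

The bundle (8 identities x 7 views + 120 view-uncontrolled faces + 160
non-face objects), its 500-candidate fragment bank and the precomputed
bank response matrices are expensive (~30 s) and read-only, so they are
built once per session and shared across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

from fragface.experiments import (
    IDENTIFICATION_SET,
    compute_bank_responses,
    make_bundle,
    make_fragment_bank,
)

MASTER_SEED = 0


@pytest.fixture(scope="session")
def ident_bundle():
    return make_bundle(MASTER_SEED, IDENTIFICATION_SET)


@pytest.fixture(scope="session")
def ident_bank(ident_bundle):
    return make_fragment_bank(ident_bundle, n_candidates=500, seed=MASTER_SEED)


@pytest.fixture(scope="session")
def ident_responses(ident_bundle, ident_bank):
    return compute_bank_responses(ident_bundle, ident_bank)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
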