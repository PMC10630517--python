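import numpy as np
import pytest

import scfcmap as sm


@pytest.fixture(scope="session")
def small_sc():
    """Seeded synthetic SC on 10 nodes with coordinates and hemispheres."""
    sc, coords, hemis = sm.gen_sc(10, density=0.6, seed=42)
    return sc, coords, hemis


@pytest.fixture(scope="session")
def seeded_pair():
    """Seeded SC/FC pair (n=10) with planted truth, plus decompositions."""
    sc, coords, hemis = sm.gen_sc(10, density=0.6, seed=42)
    smodes = sm.decompose_sc(sc)
    rng = np.random.default_rng(7)
    w = rng.standard_normal(10)
    w /= np.linalg.norm(w)
    truth = sm.SyntheticTruth(seed=7, planted_weights=w, planted_spectrum=sm.default_spectrum(10, n_active=6))
    fc = sm.gen_fc_planted(smodes, truth)
    fmodes = sm.decompose_fc(fc)
    return sc, fc, smodes, fmodes, truth


@pytest.fixture(scope="session")
def correlation_fc():
    """A strict random 8x8 Pearson-correlation FC (unit diagonal)."""
    rng = np.random.default_rng(3)
    signals = rng.standard_normal((200, 8))
    return sm.ConnectomeMatrix(np.corrcoef(signals, rowvar=False), role="functional")
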