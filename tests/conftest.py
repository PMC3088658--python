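import numpy as np
import pytest

import tempocode as tc
from tempocode import likelihood as lk
from tempocode import stimulus_models as sm
from tempocode import synthetic as syn

# Canonical sessions: one 30-minute band-limited noise stimulus (the
# standard session length for the codeword analysis), encoded once by the
# purely linear surrogate (burst_gain = 0, the negative control) and once
# by the bursty surrogate (the positive control).
STIM_SEED = 2
ENCODE_SEED = 3
BURST_GAIN = 30.0
SESSION_MS = 1_800_000.0


@pytest.fixture(scope="session")
def stim600():
    return tc.generate_stimulus(SESSION_MS, seed=STIM_SEED)


@pytest.fixture(scope="session")
def space600(stim600):
    return sm.fit_reduced_space(stim600)


def _session(stim, burst_gain):
    spec = syn.EncoderSpec(burst_gain=burst_gain)
    train = syn.encode(stim, spec, seed=ENCODE_SEED)
    singlet, doublets = sm.collect_isolated_patterns(train, stim, max_isi_ms=12.0)
    return {"train": train, "singlet": singlet, "doublets": doublets, "spec": spec}


@pytest.fixture(scope="session")
def linear_session(stim600):
    return _session(stim600, 0.0)


@pytest.fixture(scope="session")
def bursty_session(stim600):
    return _session(stim600, BURST_GAIN)


@pytest.fixture(scope="session")
def bursty_scan(bursty_session, space600):
    return lk.offset_scan(
        bursty_session["doublets"],
        bursty_session["singlet"],
        space600,
        offsets_ms=np.arange(-3, 13),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
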