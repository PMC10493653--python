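import numpy as np
import pytest

import dcahrv as d


@pytest.fixture
def abp_default():
    """A 10-minute synthetic ABP recording at 10 Hz."""
    return d.generate_abp(d.ABPSpec(seed=1))


@pytest.fixture
def lead50_pair():
    """ABP with CBFV from a first-order lead tuned to 50 deg at 0.09 Hz.

    The ABP uses broadband in-band excitation (noise-dominated rather than
    a single Mayer tone) and low output noise, so per-bin transfer-function
    estimates are essentially leakage- and noise-free: in-band coherence
    exceeds 0.9 everywhere.
    """
    abp = d.generate_abp(d.ABPSpec(seed=1, mayer_amp_mmHg=1.0,
                                   noise_sd_mmHg=2.0, drift_amp_mmHg=0.5))
    filt = d.AutoregFilterSpec.lead_for_phase(
        50.0, 0.09, dc_gain=0.65, noise_sd=0.05, noise_seed=2)
    return abp, d.apply_autoreg_filter(abp, filt), filt


@pytest.fixture
def clean_nn_series():
    """A two-tone NN series with equal LF/HF amplitudes and no ectopics."""
    return d.generate_nn_series(d.NNSpec(seed=3))
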