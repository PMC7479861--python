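import numpy as np
import pytest

from aepkit import EffectParams, make_paired_pulse_schedule


@pytest.fixture
def quiet_params():
    """Deterministic subject: no noise, fully phase-locked, no induced burst."""
    return EffectParams(noise_sd=0.0, plf_kappa=np.inf, induced_gain=0.0,
                        late_delta_drop=0.0)


@pytest.fixture
def short_schedule():
    """Ten fast paired-pulse trials for cheap simulations."""
    return make_paired_pulse_schedule(n_trials=10, s1_s2_gap=0.5,
                                      inter_trial_gap=1.0)
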