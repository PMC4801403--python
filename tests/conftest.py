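import numpy as np
import pytest

from strikewatch import synthetic as syn
from strikewatch.tags import PhaseDurationSet


def phase_set_from_truth(truth) -> PhaseDurationSet:
    """Ground-truth t_e / t_ne from a generator cycle log: t_ne pairs the
    silent ascent + IDI of one cycle with the next cycle's silent descent."""
    t_e = truth["echo_min"].to_numpy()
    t_ne = (truth["asc_min"] + truth["idi_min"]).to_numpy()[:-1] \
        + truth["desc_min"].to_numpy()[1:]
    return PhaseDurationSet(t_e, t_ne)


@pytest.fixture(scope="session")
def calibrated_truth():
    """Per-cycle truth log of 10000 dive cycles under the default calibration."""
    cfg = syn.TagSimConfig(n_cycles=10000, seed=123)
    return syn.draw_cycle_durations(cfg, np.random.default_rng(cfg.seed))


@pytest.fixture(scope="session")
def calibrated_phases(calibrated_truth):
    return phase_set_from_truth(calibrated_truth)


@pytest.fixture(scope="session")
def small_tag_series():
    return syn.generate_tag_series(syn.TagSimConfig(n_cycles=11, seed=3))
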